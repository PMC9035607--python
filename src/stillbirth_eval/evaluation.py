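"""Observed-scale PTA, approximate reliabilities, and trends.

A bull's underlying solution is epsilon = random-effect solution plus his
birth-year group solution.  The reported scale is anchored to a genetic
base (a bull birth-year cohort) and a phenotypic base %SB* (the
record-weighted heifer stillbirth percentage over the base birth years):
the anchor t = T + c is chosen so the base cohort averages %SB*, and a
bull's PTA on the observed scale is

    %SB(bull) = 100 * (1 - F(t - epsilon)),

with F the standard normal CDF.  The default anchor solves
mean_base[1 - F(t - eps*)] = %SB* exactly; ``anchor="linear"`` uses the
interchange-of-mean closed form t = mean_base[F^{-1}(1 - %SB*) + eps*],
which agrees when the base solutions are tightly clustered.

Reliabilities use only the diagonal of the mixed-model equations,
rel_i = 1 - d_i^{-1} / sigma_a^2 (floored at zero), which ignores
relationships and can therefore be inflated relative to the exact
prediction-error variance.

Trends are ordinary least squares of yearly means on year; smoothing
splines (roughness chosen by generalized cross-validation) are for
plotting only and never enter slope tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import linregress

from .data_prep import EditedDataset
from .pedigree import RelationshipInverse, SireMgsPedigree
from .threshold_mcmc import Design, MCMCResult

__all__ = [
    "BaseDefinition",
    "TrendEstimate",
    "underlying_solutions",
    "observed_scale",
    "reliability",
    "mme_diagonals",
    "phenotypic_base",
    "pta_table",
    "heifer_sb_by_sire_birth_year",
    "phenotypic_trend",
    "genetic_trend",
    "spline_smooth",
]


@dataclass
class BaseDefinition:
    sire_base_years: tuple[int, int] = (2011, 2015)
    mgs_base_years: tuple[int, int] = (2006, 2010)


@dataclass
class TrendEstimate:
    slope: float
    intercept: float
    p_value: float
    yearly_means: pd.Series
    smoothed: pd.Series | None = None


def underlying_solutions(
    random_solutions: pd.Series,
    group_solutions: pd.Series,
    bull_groups: pd.Series | dict,
) -> pd.Series:
    """epsilon = bull solution + his birth-year group solution."""
    groups = pd.Series(bull_groups)
    missing = [b for b in random_solutions.index if b not in groups.index]
    if missing:
        raise KeyError(f"bull {missing[0]!r} has no birth-year group assignment")
    eps = random_solutions + groups.loc[random_solutions.index].map(group_solutions).astype(float)
    return eps


def _solutions_for_role(result: MCMCResult, role: str) -> pd.Series:
    design = result.design
    if role == "sire":
        random = result.bull_solution_means("sire")
        groups = design.sire_group_of_bull
        group_sol = result.solution_means("sire_birth_group")
    elif role == "mgs":
        random = result.bull_solution_means("mgs")
        groups = design.mgs_group_of_bull
        group_sol = result.solution_means("mgs_birth_group")
    else:
        raise ValueError(f"role must be 'sire' or 'mgs', got {role!r}")
    used = pd.Index(sorted(groups))
    return underlying_solutions(random.loc[used], group_sol, groups)


def observed_scale(
    epsilons: pd.Series,
    base_ids,
    base_pct: float,
    anchor: str = "exact",
) -> pd.Series:
    """Convert underlying solutions to %SB anchored at the base cohort."""
    if not 0.0 < base_pct < 100.0:
        raise ValueError("base %SB must lie strictly between 0 and 100")
    base_ids = [b for b in base_ids]
    if not base_ids:
        raise ValueError("base bull set is empty; the base defines the reported scale")
    eps_star = epsilons.loc[base_ids].to_numpy(dtype=float)
    p_star = base_pct / 100.0
    z_star = ndtri(1.0 - p_star)
    if anchor == "linear":
        t = float(np.mean(z_star + eps_star))
    elif anchor == "exact":
        def gap(t):
            return float(np.mean(1.0 - ndtr(t - eps_star)) - p_star)

        lo = z_star + eps_star.min() - 10.0
        hi = z_star + eps_star.max() + 10.0
        t = float(brentq(gap, lo, hi, xtol=1e-12))
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return pd.Series(
        100.0 * (1.0 - ndtr(t - epsilons.to_numpy(dtype=float))), index=epsilons.index
    )


def reliability(mme_diagonal, genetic_variance: float):
    """rel = 1 - d^{-1}/sigma_a^2, floored at 0 (diagonal-only approximation)."""
    d = np.asarray(mme_diagonal, dtype=float)
    if np.any(d <= 0) or genetic_variance <= 0:
        raise ValueError("MME diagonals and the genetic variance must be positive")
    rel = 1.0 - (1.0 / d) / genetic_variance
    out = np.maximum(rel, 0.0)
    return out if out.ndim else float(out)


def mme_diagonals(
    design: Design, a_inverse: RelationshipInverse, g0: np.ndarray, role: str
) -> pd.Series:
    """Diagonal of the coefficient-matrix row for each bull's effect.

    d_b = (records with the bull in that role) + A^{-1}_bb * (G0^{-1})_rr.
    """
    g0inv = np.linalg.inv(np.asarray(g0, dtype=float))
    nb = len(design.bull_ids)
    if role == "sire":
        counts = np.bincount(design.sire_code, minlength=nb).astype(float)
        gterm = g0inv[0, 0]
    elif role == "mgs":
        counts = np.bincount(design.mgs_code, minlength=nb).astype(float)
        gterm = g0inv[1, 1]
    else:
        raise ValueError(f"role must be 'sire' or 'mgs', got {role!r}")
    diag = counts + a_inverse.matrix.diagonal() * gterm
    return pd.Series(diag, index=design.bull_ids)


def phenotypic_base(
    dataset: EditedDataset,
    pedigree: SireMgsPedigree,
    role: str,
    base_years: tuple[int, int],
) -> float:
    """Record-weighted heifer (parity-1) %SB over the base birth years."""
    df = dataset.records
    byear = dict(zip(pedigree.bull_ids, pedigree.entries["birth_year"]))
    col = "sire_id" if role == "sire" else "mgs_id"
    years = df[col].map(byear)
    sub = df[(df["parity_class"] == 1) & years.between(*base_years)]
    if sub.empty:
        raise ValueError(f"no heifer records with {role} born in {base_years}")
    return float(100.0 * (sub["sb"] == 2).mean())


def pta_table(
    result: MCMCResult,
    a_inverse: RelationshipInverse,
    dataset: EditedDataset,
    pedigree: SireMgsPedigree,
    base: BaseDefinition | None = None,
    anchor: str = "exact",
) -> pd.DataFrame:
    """PTA report for both roles: epsilon, observed-scale %SB, reliability."""
    base = base or BaseDefinition()
    design = result.design
    byear = dict(zip(pedigree.bull_ids, pedigree.entries["birth_year"]))
    g0 = np.array(
        [
            [result.var_samples["sigma_s2"].mean(), result.var_samples["sigma_s_mgs"].mean()],
            [result.var_samples["sigma_s_mgs"].mean(), result.var_samples["sigma_mgs2"].mean()],
        ]
    )
    nb = len(design.bull_ids)
    frames = []
    for role, years, sigma_a2 in (
        ("service_sire", base.sire_base_years, g0[0, 0]),
        ("mgs", base.mgs_base_years, g0[1, 1]),
    ):
        short = "sire" if role == "service_sire" else "mgs"
        eps = _solutions_for_role(result, short)
        base_ids = [b for b in eps.index if years[0] <= byear[b] <= years[1]]
        if not base_ids:
            raise ValueError(f"no {short} base bulls born in {years}; cannot anchor the scale")
        pct_star = phenotypic_base(dataset, pedigree, short, years)
        pta = observed_scale(eps, base_ids, pct_star, anchor=anchor)
        diag = mme_diagonals(design, a_inverse, g0, short).loc[eps.index]
        rel = reliability(diag.to_numpy(), float(sigma_a2))
        counts = np.bincount(
            design.sire_code if short == "sire" else design.mgs_code, minlength=nb
        )
        count_of = pd.Series(counts, index=design.bull_ids).loc[eps.index]
        frames.append(
            pd.DataFrame(
                {
                    "bull_id": eps.index,
                    "role": role,
                    "birth_year": [byear[b] for b in eps.index],
                    "epsilon": eps.to_numpy(),
                    "pta_pct": pta.to_numpy(),
                    "reliability": rel,
                    "n_progeny": count_of.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def heifer_sb_by_sire_birth_year(
    dataset: EditedDataset, pedigree: SireMgsPedigree
) -> pd.Series:
    """Yearly heifer %SB by sire birth year (input to the phenotypic trend)."""
    df = dataset.records
    byear = dict(zip(pedigree.bull_ids, pedigree.entries["birth_year"]))
    sub = df[df["parity_class"] == 1].copy()
    sub["sire_birth_year"] = sub["sire_id"].map(byear)
    g = sub.groupby("sire_birth_year")["sb"].agg(lambda s: 100.0 * (s == 2).mean())
    return g.sort_index()


def _ols_trend(series: pd.Series, smoothed: bool = False) -> TrendEstimate:
    series = series.dropna().sort_index()
    if len(series) < 3:
        raise ValueError("need at least 3 yearly means for a trend")
    x = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        est = TrendEstimate(0.0, float(y[0]), 1.0, series)
    else:
        fit = linregress(x, y)
        est = TrendEstimate(float(fit.slope), float(fit.intercept), float(fit.pvalue), series)
    if smoothed and len(series) >= 5:
        est.smoothed = spline_smooth(series)
    return est


def phenotypic_trend(yearly_pct_sb: pd.Series, smoothed: bool = False) -> TrendEstimate:
    """OLS of mean heifer %SB on sire birth year, two-sided slope test."""
    return _ols_trend(yearly_pct_sb, smoothed)


def genetic_trend(pta_by_birth_year: pd.Series, smoothed: bool = False) -> TrendEstimate:
    """OLS of mean %SSB (or %DSB) on bull birth year."""
    return _ols_trend(pta_by_birth_year, smoothed)


def spline_smooth(series: pd.Series, lam: float | None = None) -> pd.Series:
    """Cubic smoothing spline (GCV-chosen roughness when ``lam`` is None)."""
    series = series.dropna().sort_index()
    if len(series) < 5:
        raise ValueError("need at least 5 points to smooth")
    x = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    spl = make_smoothing_spline(x, y, lam=lam)
    return pd.Series(spl(x), index=series.index)
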
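"""Bayesian sire-MGS threshold model fit by Gibbs sampling.

The liability model per calving record is

    l = hy + YS + PS + sB + mB + sPSB + mPSB + s + m + e,  e ~ N(0, 1),

with the binary stillbirth outcome the indicator l > 0 (threshold fixed
at zero for identification; the overall level is carried by the
year-season effects, and the reporting threshold is recovered downstream
in the observed-scale conversion where only differences matter).
Herd-year is random with variance sigma_hy^2; the per-bull (sire, MGS)
pairs are jointly MVN(0, G0 kron A).  The residual variance is fixed at
1 and never updated.

Sampling scheme per iteration: truncated-normal data augmentation for
liabilities, factor-block draws for fixed and herd-year effects (levels
of one factor are conditionally independent), sequential 2x2 joint
(s, m) draws per bull with the A^{-1} neighbour coupling, a scaled
inverse-chi-square draw for sigma_hy^2, and an inverse-Wishart draw for
G0 from the bull-effect quadratic form with A^{-1}.

Priors are weakly informative: inverse-Wishart(df, df * G0_start) for G0
and scaled inverse-chi-square(df, hy_start) for sigma_hy^2.  Fixed-effect
identifiability: year-season keeps all levels (it absorbs the
intercept); parity-sex, sire and MGS birth-year groups drop their first
level; interaction cells collinear with the margins are detected by a
sequential rank screen on the Gram matrix and pinned to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from ._kernels import gibbs_kernel
from .data_prep import EditedDataset
from .pedigree import RelationshipInverse, SireMgsPedigree

__all__ = [
    "Design",
    "MCMCConfig",
    "MCMCResult",
    "build_design",
    "run_gibbs",
    "geweke_z",
    "build_dense_mme",
]

VARIANCE_NAMES = ["sigma_s2", "sigma_mgs2", "sigma_s_mgs", "sigma_hy2"]

FIXED_FACTORS = ["year_season", "parity_sex", "sire_birth_group", "mgs_birth_group",
                 "sire_ps_birth", "mgs_ps_birth"]


class LinkageError(KeyError):
    """A record references a bull absent from the pedigree."""


@dataclass
class Design:
    """Incidence structure of the mixed model for one edited dataset."""

    factor_names: list            # fixed factors then "herd_year"
    factor_levels: dict           # name -> list of level labels
    fcodes: np.ndarray            # int32[F, n] absolute loc-column per record
    f_off: np.ndarray             # int32[F+1]
    free: np.ndarray              # bool[P] (False = pinned to zero)
    sb2: np.ndarray               # uint8[n]
    sire_code: np.ndarray         # int32[n] bull row in pedigree order
    mgs_code: np.ndarray          # int32[n]
    bull_ids: list
    sire_group_of_bull: dict      # bull_id -> sire_birth_group label (bulls used as sires)
    mgs_group_of_bull: dict
    n_records: int = 0

    @property
    def n_loc(self) -> int:
        return int(self.f_off[-1])

    def columns(self) -> pd.DataFrame:
        rows = []
        for fi, name in enumerate(self.factor_names):
            for j, lev in enumerate(self.factor_levels[name]):
                rows.append((name, lev, int(self.f_off[fi]) + j))
        return pd.DataFrame(rows, columns=["factor", "level", "col"])


def _birth_year_groups(years: pd.Series, bin_width: int = 5, pool_min: int = 3) -> pd.Series:
    """Bull birth-year classes for the fixed genetic-group effects.

    Default is 5-year classes: at feasibility-study data sizes single-year
    classes multiply the parity-sex x birth-year interaction into hundreds
    of sparse cells that soak up liability noise and inflate heritability.
    ``bin_width=1`` gives single years with sparse years (fewer than
    ``pool_min`` bulls) pooled into 5-year classes.
    """
    if bin_width > 1:
        def label(y: int) -> str:
            b = (y // bin_width) * bin_width
            return f"{b}-{b + bin_width - 1}"

        return years.map(label)
    counts = years.value_counts()
    rich = set(counts[counts >= pool_min].index)

    def label(y: int) -> str:
        if y in rich:
            return str(y)
        b = (y // 5) * 5
        return f"{b}-{b + 4}"

    return years.map(label)


def build_design(
    dataset: EditedDataset,
    pedigree: SireMgsPedigree,
    birth_year_bin: int = 5,
    birth_group_pool_min: int = 3,
) -> Design:
    """Incidence maps and full-rank constraints for the updated S-MGS model."""
    df = dataset.records
    n = len(df)
    if n == 0:
        raise ValueError("cannot build a design from an empty dataset")
    for col in ("sire_id", "mgs_id"):
        missing = ~df[col].isin(pedigree._index)
        if missing.any():
            bad = df.loc[missing, col].iloc[0]
            raise LinkageError(f"{col} {bad!r} not in pedigree")

    sire_code = df["sire_id"].map(pedigree._index).to_numpy(dtype=np.int32)
    mgs_code = df["mgs_id"].map(pedigree._index).to_numpy(dtype=np.int32)
    byear = dict(zip(pedigree.bull_ids, pedigree.entries["birth_year"]))

    ps = "p" + df["parity_class"].astype(str) + ":" + df["calf_sex"]
    s_by = df["sire_id"].map(byear).astype(int)
    m_by = df["mgs_id"].map(byear).astype(int)

    # group on distinct bulls, not records, so heavy-use bulls do not
    # decide pooling alone
    sgroups = _birth_year_groups(
        pd.Series({b: byear[b] for b in df["sire_id"].unique()}),
        birth_year_bin, birth_group_pool_min,
    )
    mgroups = _birth_year_groups(
        pd.Series({b: byear[b] for b in df["mgs_id"].unique()}),
        birth_year_bin, birth_group_pool_min,
    )
    sB = df["sire_id"].map(sgroups)
    mB = df["mgs_id"].map(mgroups)
    sPSB = ps + "|" + sB
    mPSB = ps + "|" + mB

    factors = {
        "year_season": df["year_season"],
        "parity_sex": ps,
        "sire_birth_group": sB,
        "mgs_birth_group": mB,
        "sire_ps_birth": sPSB,
        "mgs_ps_birth": mPSB,
        "herd_year": df["herd_year"],
    }
    names = list(factors)
    levels = {}
    codes = {}
    for name, series in factors.items():
        cats = pd.Categorical(series)
        levels[name] = sorted(cats.categories.tolist())
        lookup = {lev: i for i, lev in enumerate(levels[name])}
        codes[name] = series.map(lookup).to_numpy(dtype=np.int32)

    f_off = np.zeros(len(names) + 1, dtype=np.int32)
    for i, name in enumerate(names):
        f_off[i + 1] = f_off[i] + len(levels[name])
    P = int(f_off[-1])

    fcodes = np.empty((len(names), n), dtype=np.int32)
    for i, name in enumerate(names):
        fcodes[i] = codes[name] + f_off[i]

    free = np.ones(P, dtype=bool)
    # reference constraints: YS keeps all levels (intercept), the other
    # main factors drop their first level
    for i, name in enumerate(names):
        if name in ("parity_sex", "sire_birth_group", "mgs_birth_group"):
            if len(levels[name]) > 0:
                free[f_off[i]] = False

    _prune_collinear(fcodes, f_off, free, names, n)

    design = Design(
        factor_names=names,
        factor_levels=levels,
        fcodes=fcodes,
        f_off=f_off,
        free=free,
        sb2=(df["sb"].to_numpy() == 2).astype(np.uint8),
        sire_code=sire_code,
        mgs_code=mgs_code,
        bull_ids=pedigree.bull_ids,
        sire_group_of_bull=sgroups.to_dict(),
        mgs_group_of_bull=mgroups.to_dict(),
        n_records=n,
    )
    return design


def _prune_collinear(fcodes, f_off, free, names, n, tol=1e-8):
    """Pin interaction cells (and any stray collinear level) to zero.

    Sequential rank screen on the fixed-effect Gram matrix with main
    effects ordered before interaction cells: a column whose residual
    after projection on the kept set is numerically zero is dropped.
    """
    fixed_idx = [i for i, name in enumerate(names) if name != "herd_year"]
    cols = []
    for i in fixed_idx:
        for c in range(f_off[i], f_off[i + 1]):
            if free[c]:
                cols.append((i, c))
    if not cols:
        return
    col_ids = [c for _, c in cols]
    pos = {c: k for k, c in enumerate(col_ids)}
    rows_all, cols_all = [], []
    for i in fixed_idx:
        for r in range(n):
            c = fcodes[i, r]
            if c in pos:
                rows_all.append(r)
                cols_all.append(pos[c])
    X = sp.coo_matrix(
        (np.ones(len(rows_all)), (rows_all, cols_all)), shape=(n, len(col_ids))
    ).tocsc()
    G = (X.T @ X).toarray()

    kept: list[int] = []
    R = np.zeros((len(col_ids), len(col_ids)))  # upper-tri Cholesky of kept Gram
    for k in range(len(col_ids)):
        g = G[kept, k] if kept else np.zeros(0)
        if kept:
            w = scipy.linalg.solve_triangular(
                R[: len(kept), : len(kept)], g, trans="T", lower=False
            )
        else:
            w = np.zeros(0)
        resid = G[k, k] - w @ w
        if resid <= tol * max(G[k, k], 1.0):
            free[col_ids[k]] = False
            continue
        R[: len(kept), len(kept)] = w
        R[len(kept), len(kept)] = np.sqrt(resid)
        kept.append(k)


@dataclass
class MCMCConfig:
    """Chain sizes default to desk scale; the production schedule is
    500,000 iterations / 100,000 burn-in / thin 100."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    g0_start: np.ndarray = field(
        default_factory=lambda: np.array([[0.02, 0.003], [0.003, 0.012]])
    )
    hy_var_start: float = 0.05
    prior_df: float = 4.0
    prior_scale: np.ndarray | None = None  # default: g0_start * prior_df
    hy_prior_df: float = 4.0
    hy_prior_scale: float | None = None  # default: hy_var_start

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        g0 = np.asarray(self.g0_start, dtype=float)
        if np.linalg.eigvalsh(g0).min() <= 0:
            raise ValueError("g0_start must be positive definite")
        self.g0_start = g0
        if self.prior_scale is None:
            self.prior_scale = g0 * self.prior_df
        if self.hy_prior_scale is None:
            self.hy_prior_scale = self.hy_var_start

    @classmethod
    def from_file(cls, path) -> "MCMCConfig":
        """Read a ``key = value`` text file; g0_start as s2,cov,mgs2."""
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key == "g0_start":
                    s2, cov, g2 = (float(v) for v in value.split(","))
                    kwargs[key] = np.array([[s2, cov], [cov, g2]])
                elif key in ("n_iter", "burn_in", "thin", "seed"):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class MCMCResult:
    """Retained draws: variance components and every location solution."""

    var_samples: pd.DataFrame      # columns VARIANCE_NAMES, one row per draw
    loc_samples: np.ndarray        # (n_keep, P + 2*n_bulls)
    loc_index: pd.DataFrame        # factor, level, col
    design: Design
    config: MCMCConfig

    @property
    def n_samples(self) -> int:
        return len(self.var_samples)

    def solution_means(self, factor: str) -> pd.Series:
        sub = self.loc_index[self.loc_index["factor"] == factor]
        means = self.loc_samples[:, sub["col"].to_numpy()].mean(axis=0)
        return pd.Series(means, index=sub["level"].tolist())

    def bull_solution_means(self, role: str) -> pd.Series:
        P = self.design.n_loc
        nb = len(self.design.bull_ids)
        off = P if role == "sire" else P + nb
        means = self.loc_samples[:, off : off + nb].mean(axis=0)
        return pd.Series(means, index=self.design.bull_ids)

    def diagnostics(self) -> pd.DataFrame:
        import arviz as az

        rows = []
        for name in VARIANCE_NAMES:
            chain = self.var_samples[name].to_numpy()
            z = geweke_z(chain)
            ess = float(az.ess(np.asarray(chain)[None, :]))
            rows.append((name, z, ess))
        return pd.DataFrame(rows, columns=["parameter", "geweke_z", "ess"])


def run_gibbs(
    design: Design,
    a_inverse: RelationshipInverse,
    config: MCMCConfig,
    liabilities: np.ndarray | None = None,
    fix_variances: bool = False,
    sample_noise: bool = True,
) -> MCMCResult:
    """Run the Gibbs sampler; fixed seed gives an identical sample stream.

    ``liabilities`` switches to debug mode: the latent variables are held
    at the given values instead of being re-drawn, so with
    ``fix_variances=True`` and ``sample_noise=False`` the sweep is a
    Gauss-Seidel solve of the mixed-model equations.
    """
    ai = a_inverse.matrix.tocsr()
    nb = ai.shape[0]
    n = design.n_records

    order = np.argsort(design.sire_code, kind="stable")
    s_rec = order.astype(np.int32)
    s_indptr = np.searchsorted(design.sire_code[order], np.arange(nb + 1)).astype(np.int32)
    order = np.argsort(design.mgs_code, kind="stable")
    m_rec = order.astype(np.int32)
    m_indptr = np.searchsorted(design.mgs_code[order], np.arange(nb + 1)).astype(np.int32)
    both = design.sire_code == design.mgs_code
    n_both = np.bincount(design.sire_code[both], minlength=nb).astype(np.float64)

    ncol = np.zeros(design.n_loc)
    for fi in range(len(design.factor_names)):
        np.add.at(ncol, design.fcodes[fi], 1.0)

    if liabilities is not None:
        liab_init = np.asarray(liabilities, dtype=float).copy()
        sample_liab = 0
    else:
        liab_init = np.where(design.sb2 == 1, 0.5, -0.5).astype(float)
        sample_liab = 1

    is_hy = np.array(
        [1 if name == "herd_year" else 0 for name in design.factor_names], dtype=np.uint8
    )

    var_out, loc_out = gibbs_kernel(
        int(config.seed) % (2**31),
        design.sb2,
        design.fcodes,
        design.f_off.astype(np.int32),
        is_hy,
        design.free.astype(np.uint8),
        ncol,
        design.sire_code,
        design.mgs_code,
        s_indptr,
        s_rec,
        m_indptr,
        m_rec,
        n_both,
        ai.indptr.astype(np.int32),
        ai.indices.astype(np.int32),
        ai.data.astype(np.float64),
        ai.diagonal().astype(np.float64),
        np.asarray(config.g0_start, dtype=float),
        float(config.hy_var_start),
        float(config.prior_df),
        np.asarray(config.prior_scale, dtype=float),
        float(config.hy_prior_df),
        float(config.hy_prior_scale),
        int(config.n_iter),
        int(config.burn_in),
        int(config.thin),
        sample_liab,
        1 if sample_noise else 0,
        1 if fix_variances else 0,
        liab_init,
    )
    var_df = pd.DataFrame(var_out, columns=VARIANCE_NAMES)
    return MCMCResult(
        var_samples=var_df,
        loc_samples=loc_out,
        loc_index=design.columns(),
        design=design,
        config=config,
    )


def geweke_z(chain: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z: first 10% vs last 50% means, spectral variances."""
    x = np.asarray(chain, dtype=float)
    if x.size < 50:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 50)")
    if np.var(x) == 0:
        raise ValueError("constant chain: Geweke diagnostic undefined")
    na = max(int(first_frac * x.size), 2)
    nbt = max(int(last_frac * x.size), 2)
    a = x[:na]
    b = x[-nbt:]

    def spectral0(y: np.ndarray) -> float:
        y = y - y.mean()
        ny = y.size
        lag_max = min(ny - 1, max(1, int(np.sqrt(ny))))
        acov = np.correlate(y, y, mode="full")[ny - 1 :] / ny
        weights = 1.0 - np.arange(1, lag_max + 1) / (lag_max + 1)
        return float(acov[0] + 2.0 * np.sum(weights * acov[1 : lag_max + 1]))

    sa = spectral0(a)
    sb = spectral0(b)
    return float((a.mean() - b.mean()) / np.sqrt(sa / na + sb / nbt))


def build_dense_mme(
    design: Design,
    a_inverse: RelationshipInverse,
    g0: np.ndarray,
    hy_var: float,
    liabilities: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Dense mixed-model equations C x = rhs for the free effects.

    A small-scale oracle for the Gibbs conditional means and for exact
    prediction-error variances; column order is the free location columns
    followed by all sire effects then all MGS effects.
    """
    n = design.n_records
    nb = len(design.bull_ids)
    free_cols = np.flatnonzero(design.free)
    col_of = {c: k for k, c in enumerate(free_cols)}
    p_free = len(free_cols)
    p_tot = p_free + 2 * nb

    rows, cols, vals = [], [], []
    for fi in range(len(design.factor_names)):
        for r in range(n):
            c = design.fcodes[fi, r]
            if c in col_of:
                rows.append(r)
                cols.append(col_of[c])
                vals.append(1.0)
    for r in range(n):
        rows.append(r)
        cols.append(p_free + design.sire_code[r])
        vals.append(1.0)
        rows.append(r)
        cols.append(p_free + nb + design.mgs_code[r])
        vals.append(1.0)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, p_tot)).tocsr()

    C = (W.T @ W).toarray()
    ai = a_inverse.matrix.toarray()
    g0inv = np.linalg.inv(np.asarray(g0, dtype=float))
    C[p_free : p_free + nb, p_free : p_free + nb] += g0inv[0, 0] * ai
    C[p_free : p_free + nb, p_free + nb :] += g0inv[0, 1] * ai
    C[p_free + nb :, p_free : p_free + nb] += g0inv[1, 0] * ai
    C[p_free + nb :, p_free + nb :] += g0inv[1, 1] * ai
    hy_i = design.factor_names.index("herd_year")
    for c in range(design.f_off[hy_i], design.f_off[hy_i + 1]):
        if c in col_of:
            k = col_of[c]
            C[k, k] += 1.0 / hy_var

    rhs = W.T @ np.asarray(liabilities, dtype=float)
    meta_rows = []
    cdf = design.columns()
    lab = dict(zip(cdf["col"], zip(cdf["factor"], cdf["level"])))
    for c in free_cols:
        meta_rows.append((*lab[c], len(meta_rows)))
    for b in design.bull_ids:
        meta_rows.append(("sire_effect", b, len(meta_rows)))
    for b in design.bull_ids:
        meta_rows.append(("mgs_effect", b, len(meta_rows)))
    meta = pd.DataFrame(meta_rows, columns=["factor", "level", "col"])
    return C, rhs, meta
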
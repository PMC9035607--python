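"""Generative model for sire-MGS stillbirth data.

The simulator is the exact inverse of the estimator's assumptions: a
latent liability per calving

    l = YS(year-season) + PS(parity-sex) + hy + s(sire) + m(MGS) + e,
    e ~ N(0, 1),

with herd-year effects hy ~ N(0, sigma_hy^2) and the per-bull pair
(s, m) drawn jointly from N(0, G0 kron A) by simulating down the
pedigree: founders from N(0, G0), descendants via

    u_child = 1/2 u_sire + 1/4 u_MGS + phi,   phi ~ N(0, d * G0),

with the same Mendelian-sampling d (11/16, 3/4, 15/16, 1) that the
relationship-inverse rules assume.  The livability score is 2 when the
liability exceeds the threshold T, else 1; a configurable fraction of
score-2 records is relabeled 3 (died within 48 h) to exercise the
recoding edit.  Calving ease is a monotone 5-bin discretisation of the
same liability (summary plumbing only; it is never fitted).

Dams are pure links: a dam id carries its sire (the MGS) but has no
genetic effect of her own.  Default rates mimic the Jersey margins of
the national data: female-calf probability by parity (0.75, 0.64, 0.59)
reflecting sexed-semen use in heifers, parity mix (0.37, 0.26, 0.37).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import RECORD_COLUMNS, assign_year_season
from .pedigree import UNKNOWN, SireMgsPedigree, _mendelian_d

__all__ = [
    "SimulationConfig",
    "TrueValues",
    "InvalidConfigError",
    "generate_pedigree",
    "simulate_calving_records",
    "write_fixture",
    "read_truth",
]


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


DEFAULT_PARITY_SEX_EFFECTS = {
    # liability shifts: heifer calvings hardest, male calves riskier
    (1, "M"): 0.25,
    (1, "F"): 0.10,
    (2, "M"): 0.02,
    (2, "F"): 0.00,
    (3, "M"): 0.07,
    (3, "F"): 0.05,
}


@dataclass
class SimulationConfig:
    n_sires: int = 300
    n_mgs: int = 300
    # AI bulls sire calves and, a generation later, are the sires of dams:
    # the service-sire and MGS cohorts overlap in any real evaluation, and
    # the overlap is what identifies the sire-MGS covariance directly
    allow_overlap: bool = True
    n_herds: int = 40
    years: tuple[int, int] = (2000, 2017)
    mean_records_per_herd_year: float = 35.0
    parity_distribution: tuple[float, float, float] = (0.37, 0.26, 0.37)
    sex_ratio_by_parity: tuple[float, float, float] = (0.75, 0.64, 0.59)  # P(female)
    g0_true: np.ndarray = field(
        default_factory=lambda: np.array([[0.016, 0.005], [0.005, 0.014]])
    )
    herd_year_variance: float = 0.05
    threshold: float | None = None
    target_incidence: float | None = 0.05
    fixed_effects_true: dict = field(default_factory=dict)  # keys: "year_season", "parity_sex"
    pedigree_depth: int = 2
    bull_birth_years: tuple[int, int] = (1995, 2015)
    score3_fraction: float = 0.2
    unknown_mgs_fraction: float = 0.03
    crossbred_fraction: float = 0.02
    breed: str = "JE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires < 1 or self.n_mgs < 1:
            raise InvalidConfigError("n_sires and n_mgs must be >= 1")
        g0 = np.asarray(self.g0_true, dtype=float)
        if g0.shape != (2, 2) or not np.allclose(g0, g0.T):
            raise InvalidConfigError("g0_true must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(g0).min() < -1e-12:
            raise InvalidConfigError("g0_true must be positive semi-definite")
        self.g0_true = g0
        if self.herd_year_variance < 0:
            raise InvalidConfigError("herd_year_variance must be >= 0")
        p = np.asarray(self.parity_distribution, dtype=float)
        if p.min() < 0 or p.max() > 1 or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("parity_distribution must be probabilities summing to 1")
        sr = np.asarray(self.sex_ratio_by_parity, dtype=float)
        if sr.min() < 0 or sr.max() > 1:
            raise InvalidConfigError("sex ratios must lie in [0, 1]")
        if self.threshold is None and self.target_incidence is None:
            raise InvalidConfigError("one of threshold / target_incidence is required")
        if self.pedigree_depth < 0:
            raise InvalidConfigError("pedigree_depth must be >= 0")

    @property
    def parity_sex_effects(self) -> dict:
        return self.fixed_effects_true.get("parity_sex", DEFAULT_PARITY_SEX_EFFECTS)

    @property
    def year_season_effects(self) -> dict:
        return self.fixed_effects_true.get("year_season", {})


@dataclass
class TrueValues:
    """Everything the generator drew, re-addable in tests.

    ``liability_components`` has one row per record with the exact summands
    (fixed, hy, s, m, e) whose sum is the liability.
    """

    bull_effects: pd.DataFrame  # bull_id, s, m
    herd_year_effects: pd.DataFrame  # herd_id, year, effect
    liability_components: pd.DataFrame  # calf_id, fixed, hy, s, m, e, liability
    threshold: float
    g0: np.ndarray


def generate_pedigree(config: SimulationConfig) -> SireMgsPedigree:
    """Bull pedigree with ``pedigree_depth`` ancestor generations above the tips.

    Tip bulls (the service sires and MGS referenced by records) are spread
    over ``bull_birth_years`` so the PTA base cohorts are populated;
    ancestor generations occupy earlier 5-year windows and founders have
    unknown parents.
    """
    rng = np.random.default_rng(config.seed)
    depth = config.pedigree_depth
    y0, y1 = config.bull_birth_years

    n_tips = config.n_sires + config.n_mgs
    if config.allow_overlap:
        n_tips = max(
            config.n_sires, config.n_mgs, int(0.75 * (config.n_sires + config.n_mgs))
        )
    n_anc = max(2, n_tips // 4)

    rows: list[tuple[str, str, str, int]] = []
    prev_gen: list[str] = []
    counter = 0
    for g in range(depth):
        gen_ids = []
        base_year = y0 - 5 * (depth - g)
        for _ in range(n_anc):
            counter += 1
            bid = f"B{counter:05d}"
            if prev_gen:
                sire = str(rng.choice(prev_gen)) if rng.random() > 0.05 else UNKNOWN
                mgs = str(rng.choice(prev_gen)) if rng.random() > 0.10 else UNKNOWN
            else:
                sire = mgs = UNKNOWN
            year = base_year + int(rng.integers(0, 5))
            rows.append((bid, sire, mgs, year))
            gen_ids.append(bid)
        prev_gen = gen_ids

    tip_years = np.sort(rng.integers(y0, y1 + 1, size=n_tips))
    for year in tip_years:
        counter += 1
        bid = f"B{counter:05d}"
        if prev_gen:
            sire = str(rng.choice(prev_gen)) if rng.random() > 0.05 else UNKNOWN
            mgs = str(rng.choice(prev_gen)) if rng.random() > 0.10 else UNKNOWN
        else:
            sire = mgs = UNKNOWN
        rows.append((bid, sire, mgs, int(year)))

    return SireMgsPedigree(
        pd.DataFrame(rows, columns=["bull_id", "sire_id", "mgs_id", "birth_year"])
    )


def _draw_bull_effects(
    pedigree: SireMgsPedigree, g0: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Joint (s, m) pairs down the pedigree: N(0, G0 kron A) by recursion."""
    w, v = np.linalg.eigh(g0)
    chol_like = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))  # works for PSD G0
    n = pedigree.n_bulls
    u = np.zeros((n, 2))
    idx = pedigree._index
    for i, (bull, sire, mgs) in enumerate(
        pedigree.entries[["bull_id", "sire_id", "mgs_id"]].itertuples(index=False)
    ):
        mean = np.zeros(2)
        sk = sire != UNKNOWN
        mk = mgs != UNKNOWN
        if sk:
            mean += 0.5 * u[idx[sire]]
        if mk:
            mean += 0.25 * u[idx[mgs]]
        d = _mendelian_d(sk, mk)
        u[i] = mean + np.sqrt(d) * (chol_like @ rng.standard_normal(2))
    return pd.DataFrame(
        {"bull_id": pedigree.bull_ids, "s": u[:, 0], "m": u[:, 1]}
    )


def simulate_calving_records(
    config: SimulationConfig, pedigree: SireMgsPedigree
) -> tuple[pd.DataFrame, TrueValues]:
    """Draw calving records and the truth behind them from the liability model."""
    g0 = np.asarray(config.g0_true, dtype=float)
    if np.linalg.eigvalsh(g0).min() < -1e-12:
        raise InvalidConfigError("g0_true must be positive semi-definite")
    rng = np.random.default_rng(config.seed + 1)

    bulls = _draw_bull_effects(pedigree, g0, rng)
    effect_s = dict(zip(bulls["bull_id"], bulls["s"]))
    effect_m = dict(zip(bulls["bull_id"], bulls["m"]))

    # tips are in birth-year order: the MGS cohort is the older end (sires
    # of dams), service sires the younger end; with overlap the two share
    # the middle of the cohort
    tips_df = pedigree.entries[
        pedigree.entries["birth_year"].between(*config.bull_birth_years)
    ].sort_values("birth_year", kind="stable")
    tips = tips_df["bull_id"].tolist()
    if config.allow_overlap:
        mgs_pool = tips[: config.n_mgs]
        sire_pool = tips[-config.n_sires :]
    else:
        mgs_pool = tips[: config.n_mgs]
        sire_pool = tips[config.n_mgs : config.n_mgs + config.n_sires]
    if len(sire_pool) < config.n_sires or len(mgs_pool) < config.n_mgs:
        raise InvalidConfigError("pedigree has too few tip bulls for the requested pools")

    y_lo, y_hi = config.years
    years = np.arange(y_lo, y_hi + 1)
    hy_rows = []
    rec = {k: [] for k in RECORD_COLUMNS}
    comp = {k: [] for k in ["fixed", "hy", "s", "m", "e"]}
    ps_eff = config.parity_sex_effects
    ys_eff = config.year_season_effects
    pd_probs = np.asarray(config.parity_distribution, dtype=float)
    sexf = np.asarray(config.sex_ratio_by_parity, dtype=float)

    # dam pools per herd: each dam carries one MGS (or unknown)
    calf = 0
    for h in range(config.n_herds):
        herd_id = f"H{h + 1:03d}"
        n_dams = max(4, int(config.mean_records_per_herd_year))
        dam_mgs = []
        for d in range(n_dams):
            if rng.random() < config.unknown_mgs_fraction:
                dam_mgs.append(UNKNOWN)
            else:
                dam_mgs.append(str(rng.choice(mgs_pool)))
        for year in years:
            hy = rng.normal(0.0, np.sqrt(config.herd_year_variance))
            hy_rows.append((herd_id, int(year), hy))
            n_rec = rng.poisson(config.mean_records_per_herd_year)
            for _ in range(n_rec):
                calf += 1
                parity_class = int(rng.choice([1, 2, 3], p=pd_probs))
                parity_raw = parity_class
                if parity_class == 3:
                    parity_raw = 3 + int(rng.geometric(0.5) - 1)
                sex = "F" if rng.random() < sexf[parity_class - 1] else "M"
                month = int(rng.integers(1, 13))
                ys_label = assign_year_season(int(year), month)
                sire = str(rng.choice(sire_pool))
                dam_i = int(rng.integers(0, n_dams))
                mgs = dam_mgs[dam_i]
                s_val = effect_s[sire]
                if mgs == UNKNOWN:
                    # the dam's sire exists but is unrecorded
                    m_val = rng.normal(0.0, np.sqrt(max(g0[1, 1], 0.0)))
                else:
                    m_val = effect_m[mgs]
                fixed = ps_eff.get((parity_class, sex), 0.0) + ys_eff.get(ys_label, 0.0)
                e = rng.standard_normal()
                crossbred = rng.random() < config.crossbred_fraction
                rec["calf_id"].append(f"C{calf:07d}")
                rec["sire_id"].append(sire)
                rec["dam_id"].append(f"{herd_id}D{dam_i:04d}")
                rec["mgs_id"].append(mgs)
                rec["herd_id"].append(herd_id)
                rec["calving_year"].append(int(year))
                rec["calving_month"].append(month)
                rec["parity"].append(parity_raw)
                rec["calf_sex"].append(sex)
                rec["ce_score"].append(0)  # filled from liability below
                rec["livability"].append(0)
                rec["sire_breed"].append(config.breed)
                rec["dam_breed"].append("XX" if crossbred else config.breed)
                rec["dam_birth_year"].append(int(year) - 1 - parity_class)
                comp["fixed"].append(fixed)
                comp["hy"].append(hy)
                comp["s"].append(s_val)
                comp["m"].append(m_val)
                comp["e"].append(e)

    records = pd.DataFrame(rec)
    components = pd.DataFrame(comp)
    liability = components.sum(axis=1).to_numpy()

    if config.threshold is not None:
        threshold = float(config.threshold)
    else:
        threshold = float(np.quantile(liability, 1.0 - config.target_incidence))

    dead = liability > threshold
    livability = np.where(dead, 2, 1)
    relabel = dead & (rng.random(len(records)) < config.score3_fraction)
    livability = np.where(relabel, 3, livability)
    records["livability"] = livability

    # monotone 5-bin discretisation of the same liability
    cuts = np.quantile(liability, [0.70, 0.90, 0.97, 0.995])
    records["ce_score"] = np.searchsorted(cuts, liability, side="right") + 1

    truth = TrueValues(
        bull_effects=bulls,
        herd_year_effects=pd.DataFrame(hy_rows, columns=["herd_id", "year", "effect"]),
        liability_components=pd.concat(
            [records[["calf_id"]], components], axis=1
        ).assign(liability=liability),
        threshold=threshold,
        g0=g0,
    )
    return records, truth


def write_fixture(records: pd.DataFrame, pedigree: SireMgsPedigree, truth: TrueValues, outdir) -> dict:
    """Write records/pedigree/truth as delimited text; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "records": os.path.join(outdir, "records.csv"),
        "pedigree": os.path.join(outdir, "pedigree.csv"),
        "truth_bulls": os.path.join(outdir, "truth_bulls.csv"),
        "truth_herd_years": os.path.join(outdir, "truth_herd_years.csv"),
        "truth_liabilities": os.path.join(outdir, "truth_liabilities.csv"),
    }
    records.to_csv(paths["records"], index=False)
    pedigree.to_csv(paths["pedigree"])
    truth.bull_effects.to_csv(paths["truth_bulls"], index=False)
    truth.herd_year_effects.to_csv(paths["truth_herd_years"], index=False)
    truth.liability_components.to_csv(paths["truth_liabilities"], index=False)
    return paths


def read_truth(paths: dict) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    bulls = pd.read_csv(paths["truth_bulls"], dtype={"bull_id": str})
    hy = pd.read_csv(paths["truth_herd_years"], dtype={"herd_id": str})
    liab = pd.read_csv(paths["truth_liabilities"], dtype={"calf_id": str})
    return bulls, hy, liab
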
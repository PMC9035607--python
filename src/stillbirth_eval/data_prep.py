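"""Editing of national calving records and descriptive stillbirth summaries.

Calf livability is reported on a 3-point scale (1 = born alive, 2 = born
dead, 3 = died within 48 h).  Scores 2 and 3 are pooled into a single
stillbirth category, making stillbirth (SB) a binary trait.  The edit
rules keep purebred calvings within a dam-birth-year window, drop records
with unknown maternal grandsire, drop herds that never reported a
stillbirth (to avoid herds that only report live calves), and require
herd-year contemporary groups of at least five records.  Parities three
and later are collapsed into a single third-parity class.  Year-season
groups start in October and May.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, SireMgsPedigree

RECORD_COLUMNS = [
    "calf_id",
    "sire_id",
    "dam_id",
    "mgs_id",
    "herd_id",
    "calving_year",
    "calving_month",
    "parity",
    "calf_sex",
    "ce_score",
    "livability",
    "sire_breed",
    "dam_breed",
    "dam_birth_year",
]

EDIT_RULES = [
    "dam_birth_year_window",
    "not_purebred",
    "unknown_mgs",
    "herd_without_stillbirth",
    "small_herd_year_group",
]

__all__ = [
    "RECORD_COLUMNS",
    "EDIT_RULES",
    "ParseError",
    "EditedDataset",
    "read_records",
    "read_pedigree",
    "assign_year_season",
    "apply_edits",
    "summarize_by_parity_sex",
    "overall_stillbirth_rate",
    "stillbirth_by_calving_ease",
]


class ParseError(ValueError):
    """Malformed record file (bad enum value or missing column)."""


class UndefinedRateError(ZeroDivisionError):
    """Stillbirth rate requested over zero records."""


@dataclass
class EditedDataset:
    """Edited calving records plus per-rule removal counts.

    ``records`` carries the derived columns ``sb`` ({1,2} after pooling
    livability 2/3), ``parity_class`` ({1,2,3} with 3 = third and later),
    ``year_season`` and ``herd_year``.
    """

    records: pd.DataFrame
    edit_log: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.records)


def read_records(path) -> pd.DataFrame:
    """Read a comma-delimited calving-record file, validating every enum."""
    df = pd.read_csv(
        path,
        dtype={
            "calf_id": str,
            "sire_id": str,
            "dam_id": str,
            "mgs_id": str,
            "herd_id": str,
            "sire_breed": str,
            "dam_breed": str,
        },
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"record file missing columns: {missing}")
    checks = [
        ("livability", df["livability"].isin([1, 2, 3])),
        ("ce_score", df["ce_score"].isin([1, 2, 3, 4, 5])),
        ("calf_sex", df["calf_sex"].isin(["M", "F"])),
        ("calving_month", df["calving_month"].between(1, 12)),
        ("parity", df["parity"] >= 1),
    ]
    for col, ok in checks:
        if not ok.all():
            # +2: one for the header row, one for 0- vs 1-based numbering
            line = int(np.flatnonzero(~ok.to_numpy())[0]) + 2
            raise ParseError(f"bad {col} value at line {line} of {path}")
    return df


def read_pedigree(path) -> SireMgsPedigree:
    return SireMgsPedigree.from_csv(path)


def assign_year_season(calving_year: int, calving_month: int) -> str:
    """Map a calving date to its year-season group (seasons start May and October).

    May-September is season A of the calving year; October-December season B
    of the calving year; January-April continues the previous October's
    season B.
    """
    if not 1 <= calving_month <= 12:
        raise ValueError(f"calving month must be in 1..12, got {calving_month}")
    if 5 <= calving_month <= 9:
        return f"{calving_year}-A"
    if calving_month >= 10:
        return f"{calving_year}-B"
    return f"{calving_year - 1}-B"


def _year_season_vec(years: pd.Series, months: pd.Series) -> pd.Series:
    yr = years.to_numpy()
    mo = months.to_numpy()
    season_year = np.where(mo <= 4, yr - 1, yr)
    season = np.where((mo >= 5) & (mo <= 9), "A", "B")
    return pd.Series([f"{y}-{s}" for y, s in zip(season_year, season)], index=years.index)


def apply_edits(
    records: pd.DataFrame,
    dam_birth_year_range: tuple[int, int] = (1995, 2018),
    min_group_size: int = 5,
) -> EditedDataset:
    """Apply the edit rules in their fixed order and log per-rule removals.

    Order: dam-birth-year window, purebred filter, stillbirth recode,
    parity collapsing, unknown-MGS removal, herd-without-stillbirth
    removal, then year-season/herd-year assignment with the minimum
    contemporary-group size.  The last two removals interact (dropping a
    small group can strip a herd's only stillbirth), so they are iterated
    to a fixpoint; the log attributes each removal to the rule that fired.
    """
    df = records.copy()
    log = {rule: 0 for rule in EDIT_RULES}
    n_input = len(df)

    lo, hi = dam_birth_year_range
    keep = df["dam_birth_year"].between(lo, hi)
    log["dam_birth_year_window"] = int((~keep).sum())
    df = df[keep]

    keep = df["sire_breed"] == df["dam_breed"]
    log["not_purebred"] = int((~keep).sum())
    df = df[keep]

    df = df.copy()
    df["sb"] = np.where(df["livability"].isin([2, 3]), 2, 1)
    df["parity_class"] = df["parity"].clip(upper=3)

    keep = df["mgs_id"].notna() & (df["mgs_id"] != UNKNOWN) & (df["mgs_id"] != "")
    log["unknown_mgs"] = int((~keep).sum())
    df = df[keep].copy()

    df["year_season"] = _year_season_vec(df["calving_year"], df["calving_month"])
    df["herd_year"] = df["herd_id"].astype(str) + ":" + df["calving_year"].astype(str)

    while not df.empty:
        herd_has_sb = df.groupby("herd_id")["sb"].transform(lambda s: (s == 2).any())
        n_drop = int((~herd_has_sb).sum())
        log["herd_without_stillbirth"] += n_drop
        df = df[herd_has_sb]

        group_n = df.groupby("herd_year")["sb"].transform("size")
        keep = group_n >= min_group_size
        n_drop2 = int((~keep).sum())
        log["small_herd_year_group"] += n_drop2
        df = df[keep]
        if n_drop == 0 and n_drop2 == 0:
            break

    log["retained"] = len(df)
    assert sum(log[r] for r in EDIT_RULES) + log["retained"] == n_input
    return EditedDataset(records=df.reset_index(drop=True), edit_log=log)


def summarize_by_parity_sex(dataset: EditedDataset) -> pd.DataFrame:
    """Record counts and %SB per (parity class, calf sex) cell."""
    df = dataset.records
    if df.empty:
        raise ValueError("cannot summarize an empty dataset")
    grouped = df.groupby(["parity_class", "calf_sex"])
    out = grouped["sb"].agg(N="size", n_sb=lambda s: int((s == 2).sum()))
    out["pct_sb"] = 100.0 * out["n_sb"] / out["N"]
    return out.reset_index()


def overall_stillbirth_rate(table: pd.DataFrame) -> float:
    """N-weighted mean of cell %SB; equals 100 x total stillbirths / total records."""
    n = table["N"].to_numpy(dtype=float)
    if n.sum() <= 0:
        raise UndefinedRateError("overall stillbirth rate undefined for zero records")
    return float((n * table["pct_sb"].to_numpy(dtype=float)).sum() / n.sum())


def stillbirth_by_calving_ease(dataset: EditedDataset) -> pd.DataFrame:
    """%SB by calving-ease score (1 = no problem ... 5 = extreme difficulty)."""
    df = dataset.records
    grouped = df.groupby("ce_score")
    out = grouped["sb"].agg(N="size", n_sb=lambda s: int((s == 2).sum()))
    out["pct_sb"] = 100.0 * out["n_sb"] / out["N"]
    return out.reset_index()
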
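import numpy as np
import pandas as pd
import pytest

from stillbirth_eval import (
    SimulationConfig,
    apply_edits,
    generate_pedigree,
    simulate_calving_records,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across test modules."""
    cfg = SimulationConfig(
        n_sires=40,
        n_mgs=40,
        n_herds=8,
        years=(2004, 2015),
        mean_records_per_herd_year=25.0,
        seed=42,
    )
    ped = generate_pedigree(cfg)
    records, truth = simulate_calving_records(cfg, ped)
    return cfg, ped, records, truth


@pytest.fixture(scope="session")
def small_edited(small_sim):
    cfg, ped, records, truth = small_sim
    return apply_edits(records)


def make_records(rows):
    """Hand-built calving records from compact tuples.

    Each row: (herd, year, month, parity, sex, livability, mgs, sire_breed,
    dam_breed, dam_birth_year).
    """
    out = []
    for i, (herd, year, month, parity, sex, liv, mgs, sbrd, dbrd, dby) in enumerate(rows):
        out.append(
            {
                "calf_id": f"C{i}",
                "sire_id": "S1",
                "dam_id": f"D{i}",
                "mgs_id": mgs,
                "herd_id": herd,
                "calving_year": year,
                "calving_month": month,
                "parity": parity,
                "calf_sex": sex,
                "ce_score": 1,
                "livability": liv,
                "sire_breed": sbrd,
                "dam_breed": dbrd,
                "dam_birth_year": dby,
            }
        )
    return pd.DataFrame(out)
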
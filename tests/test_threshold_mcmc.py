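"""Design construction, Gibbs sampler correctness, convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest

from stillbirth_eval import (
    MCMCConfig,
    SimulationConfig,
    apply_edits,
    build_a_inverse,
    build_design,
    generate_pedigree,
    geweke_z,
    run_gibbs,
    simulate_calving_records,
)
from stillbirth_eval.data_prep import EditedDataset
from stillbirth_eval.pedigree import UNKNOWN, SireMgsPedigree
from stillbirth_eval.threshold_mcmc import LinkageError, build_dense_mme


def toy_dataset(n_sires=6, n_mgs=6, seed=0, n_herds=3, years=(2009, 2012)):
    cfg = SimulationConfig(
        n_sires=n_sires, n_mgs=n_mgs, n_herds=n_herds, years=years,
        mean_records_per_herd_year=20.0, seed=seed, pedigree_depth=1,
    )
    ped = generate_pedigree(cfg)
    rec, truth = simulate_calving_records(cfg, ped)
    return apply_edits(rec), ped, truth


def manual_dataset(rows, ped):
    """EditedDataset straight from (sire, mgs, sb, parity, sex, ys, hy) tuples."""
    df = pd.DataFrame(
        rows, columns=["sire_id", "mgs_id", "sb", "parity_class", "calf_sex",
                       "year_season", "herd_year"]
    )
    return EditedDataset(records=df, edit_log={})


def founder_ped(ids, year=2010):
    return SireMgsPedigree(
        pd.DataFrame([(b, UNKNOWN, UNKNOWN, year) for b in ids],
                     columns=["bull_id", "sire_id", "mgs_id", "birth_year"])
    )


def test_design_counts_parity_sex_levels():
    ped = founder_ped(["S1", "S2", "G1"])
    rows = [
        ("S1", "G1", 1, 1, "M", "2010-A", "H1:2010"),
        ("S1", "G1", 2, 1, "F", "2010-A", "H1:2010"),
        ("S2", "G1", 1, 2, "M", "2010-A", "H1:2010"),
        ("S2", "G1", 1, 2, "F", "2010-A", "H1:2010"),
        ("S1", "G1", 1, 1, "M", "2010-A", "H1:2010"),
        ("S2", "G1", 2, 2, "F", "2010-A", "H1:2010"),
    ]
    design = build_design(manual_dataset(rows, ped), ped)
    assert len(design.factor_levels["parity_sex"]) == 4  # populated cells only
    assert len(design.factor_levels["herd_year"]) == 1  # single hy column
    assert design.n_records == 6


def test_design_dimensions_match_hand_count():
    ped = founder_ped(["S1", "S2", "G1", "G2"])
    rows = [
        ("S1", "G1", 1, 1, "M", "2010-A", "H1:2010"),
        ("S1", "G2", 2, 1, "M", "2010-A", "H1:2010"),
        ("S2", "G1", 1, 1, "F", "2010-B", "H1:2010"),
        ("S2", "G2", 1, 2, "F", "2010-B", "H2:2010"),
        ("S1", "G1", 2, 2, "M", "2010-B", "H2:2010"),
        ("S2", "G2", 1, 1, "M", "2011-A", "H2:2011"),
        ("S1", "G1", 1, 1, "F", "2011-A", "H2:2011"),
        ("S2", "G1", 2, 3, "M", "2011-A", "H1:2011"),
        ("S1", "G2", 1, 3, "F", "2011-A", "H1:2011"),
        ("S2", "G2", 1, 1, "M", "2011-B", "H1:2011"),
    ]
    design = build_design(manual_dataset(rows, ped), ped)
    # hand count: YS 4, PS 6 populated cells, sB 1, mB 1, hy 4 levels
    assert len(design.factor_levels["year_season"]) == 4
    assert len(design.factor_levels["parity_sex"]) == 6
    assert len(design.factor_levels["sire_birth_group"]) == 1
    assert len(design.factor_levels["herd_year"]) == 4
    # every record maps to exactly one level of each factor
    for fi in range(len(design.factor_names)):
        codes = design.fcodes[fi]
        assert ((codes >= design.f_off[fi]) & (codes < design.f_off[fi + 1])).all()


def test_design_rejects_unknown_bull():
    ped = founder_ped(["S1", "G1"])
    rows = [("S9", "G1", 1, 1, "M", "2010-A", "H1:2010")]
    with pytest.raises(LinkageError):
        build_design(manual_dataset(rows, ped), ped)


def test_gibbs_deterministic_under_seed():
    ds, ped, _ = toy_dataset(seed=4)
    design = build_design(ds, ped)
    ainv = build_a_inverse(ped)
    cfg = MCMCConfig(n_iter=400, burn_in=100, thin=3, seed=12)
    r1 = run_gibbs(design, ainv, cfg)
    r2 = run_gibbs(design, ainv, cfg)
    pd.testing.assert_frame_equal(r1.var_samples, r2.var_samples)
    assert np.array_equal(r1.loc_samples, r2.loc_samples)
    assert r1.n_samples == (400 - 100) // 3


def test_gibbs_gauss_seidel_matches_dense_mme():
    """With fixed liabilities, variances, and no noise, the sweep solves the MME."""
    ds, ped, truth = toy_dataset(seed=5)
    design = build_design(ds, ped)
    ainv = build_a_inverse(ped)
    liab = (
        truth.liability_components.set_index("calf_id")
        .loc[ds.records["calf_id"], "liability"]
        .to_numpy()
    )
    g0 = np.array([[0.016, 0.005], [0.005, 0.014]])
    cfg = MCMCConfig(n_iter=4000, burn_in=3999, thin=1, seed=1, g0_start=g0, hy_var_start=0.05)
    res = run_gibbs(design, ainv, cfg, liabilities=liab, fix_variances=True, sample_noise=False)
    C, rhs, _ = build_dense_mme(design, ainv, g0, 0.05, liab)
    x = np.linalg.solve(C, rhs)
    P, nb = design.n_loc, len(design.bull_ids)
    last = res.loc_samples[-1]
    gibbs = np.concatenate(
        [last[np.flatnonzero(design.free)], last[P : P + nb], last[P + nb :]]
    )
    assert len(x) <= 300
    assert np.abs(gibbs - x).max() < 1e-6


@pytest.mark.parametrize("mu", [-3.0, -1.7, 0.0, 0.8, 2.5])
def test_liability_draws_match_truncated_normal_moments(mu):
    """One-sided truncated draws reproduce the closed-form mean and variance."""
    from numba import njit
    from scipy.stats import truncnorm

    from stillbirth_eval._kernels import trunc_normal_above, trunc_normal_below

    @njit
    def draw(mu, n, seed, above):
        np.random.seed(seed)
        out = np.empty(n)
        for i in range(n):
            u = np.random.random()
            if above:
                out[i] = trunc_normal_above(mu, 0.0, u)
            else:
                out[i] = trunc_normal_below(mu, 0.0, u)
        return out

    n = 100_000
    x = draw(mu, n, 1, True)
    ref = truncnorm(-mu, np.inf, loc=mu, scale=1)
    assert x.min() > 0
    assert x.mean() == pytest.approx(ref.mean(), abs=4 * ref.std() / np.sqrt(n))
    assert x.var() == pytest.approx(ref.var(), rel=0.05)
    y = draw(mu, n, 2, False)
    refb = truncnorm(-np.inf, -mu, loc=mu, scale=1)
    assert y.max() <= 0
    assert y.mean() == pytest.approx(refb.mean(), abs=4 * refb.std() / np.sqrt(n))
    assert y.var() == pytest.approx(refb.var(), rel=0.05)


def test_gibbs_null_signal_concentrates_near_zero():
    """Zero generative genetic signal: posterior sire variance collapses."""
    cfg_sim = SimulationConfig(
        n_sires=30, n_mgs=30, n_herds=6, years=(2006, 2013),
        mean_records_per_herd_year=30.0,
        g0_true=np.zeros((2, 2)), seed=6,
    )
    ped = generate_pedigree(cfg_sim)
    rec, _ = simulate_calving_records(cfg_sim, ped)
    ds = apply_edits(rec)
    design = build_design(ds, ped)
    g0_start = np.array([[1e-4, 0.0], [0.0, 1e-4]])
    res = run_gibbs(
        design,
        build_a_inverse(ped),
        MCMCConfig(n_iter=4000, burn_in=1000, thin=5, seed=8, g0_start=g0_start),
    )
    assert res.var_samples["sigma_s2"].mean() < 0.01


def test_posterior_g0_always_positive_definite():
    ds, ped, _ = toy_dataset(seed=7)
    design = build_design(ds, ped)
    res = run_gibbs(design, build_a_inverse(ped), MCMCConfig(n_iter=600, burn_in=100, thin=2, seed=9))
    v = res.var_samples
    dets = v["sigma_s2"] * v["sigma_mgs2"] - v["sigma_s_mgs"] ** 2
    assert (v["sigma_s2"] > 0).all() and (dets > 0).all()


def test_geweke_calibrated_on_iid_chains():
    rng = np.random.default_rng(0)
    zs = np.array([geweke_z(rng.standard_normal(10_000)) for _ in range(500)])
    assert np.mean(np.abs(zs) < 3) >= 0.99


def test_geweke_detects_mean_shift():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(10_000)
    x[5000:] += 1.0
    assert abs(geweke_z(x)) > 5


def test_geweke_rejects_constant_and_short_chains():
    with pytest.raises(ValueError):
        geweke_z(np.ones(1000))
    with pytest.raises(ValueError):
        geweke_z(np.arange(10.0))


def test_mcmc_config_round_trips_through_key_value_file(tmp_path):
    path = tmp_path / "mcmc.cfg"
    path.write_text(
        "n_iter = 1000\nburn_in = 200\nthin = 4\nseed = 9\n"
        "g0_start = 0.02, 0.003, 0.012  # s2, cov, mgs2\nhy_var_start = 0.07\n"
    )
    cfg = MCMCConfig.from_file(path)
    assert (cfg.n_iter, cfg.burn_in, cfg.thin, cfg.seed) == (1000, 200, 4, 9)
    assert np.allclose(cfg.g0_start, [[0.02, 0.003], [0.003, 0.012]])
    assert cfg.hy_var_start == 0.07


def test_a_inverse_triplet_export(tmp_path):
    from test_pedigree import random_pedigree

    ped = random_pedigree(30, 5)
    inv = build_a_inverse(ped)
    path = tmp_path / "ainv.csv"
    inv.to_triplets(path)
    trip = pd.read_csv(path)
    import scipy.sparse as sp

    back = sp.coo_matrix((trip["value"], (trip["row"], trip["col"])),
                         shape=inv.matrix.shape).tocsr()
    assert np.abs((back - inv.matrix)).max() < 1e-12
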
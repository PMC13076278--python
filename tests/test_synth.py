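"""Tests for the synthetic panel generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from effdyn.dea import score_panel, solve_input_oriented, ProductionPanel
from effdyn.markov import stationary_of_matrix
from effdyn.synth import (
    SyntheticConfig,
    frontier_inputs,
    generate_adjacency,
    generate_covariates,
    generate_panel,
    simulate_states,
)


def test_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SyntheticConfig(true_transition=np.array([[0.5, 0.4], [0.5, 0.5]]),
                        state_inefficiency_levels=(0.8, 1.0))
    with pytest.raises(ValueError, match="positive"):
        SyntheticConfig(n_regions=0)
    with pytest.raises(ValueError, match="top state"):
        SyntheticConfig(state_inefficiency_levels=(0.7, 0.8, 0.9))
    with pytest.raises(ValueError, match="spatial_coupling"):
        SyntheticConfig(spatial_coupling=1.5)
    with pytest.raises(ValueError, match="unknown covariates"):
        SyntheticConfig(covariate_effects={"bogus": 1.0})


def test_identical_seed_identical_panel():
    cfg = SyntheticConfig(n_regions=6, n_years=5, seed=99)
    p1, t1 = generate_panel(cfg)
    p2, t2 = generate_panel(SyntheticConfig(n_regions=6, n_years=5, seed=99))
    assert p1.data.to_csv() == p2.data.to_csv()  # byte-for-byte
    assert t1.table.to_csv() == t2.table.to_csv()
    p3, _ = generate_panel(SyntheticConfig(n_regions=6, n_years=5, seed=100))
    assert not p1.data.equals(p3.data)


def test_panel_is_complete_and_positive():
    cfg = SyntheticConfig(n_regions=7, n_years=4, seed=1)
    panel, truth = generate_panel(cfg)
    assert len(panel.data) == 28
    assert not panel.data.duplicated(["region_id", "year"]).any()
    assert (panel.inputs > 0).all() and (panel.outputs > 0).all()
    assert set(truth.table["state"]) <= {1, 2, 3}
    levels = np.asarray(cfg.state_inefficiency_levels)
    assert np.allclose(truth.table["true_efficiency"],
                       levels[truth.table["state"] - 1])


def test_identity_kernel_freezes_states():
    cfg = SyntheticConfig(
        n_regions=5, n_years=20, seed=3,
        true_transition=np.eye(3), state_inefficiency_levels=(0.8, 0.9, 1.0),
    )
    _, truth = generate_panel(cfg)
    per_region = truth.latent_states.groupby("region_id")["state"].nunique()
    assert (per_region == 1).all()


def test_single_frontier_unit_scores_one():
    cfg = SyntheticConfig(
        n_regions=1, n_years=1, noise_sd=0.0, seed=0,
        initial_state_distribution=(0.0, 0.0, 1.0),
    )
    panel, truth = generate_panel(cfg)
    assert truth.table["true_efficiency"].item() == 1.0
    theta = solve_input_oriented(0, panel.inputs, panel.outputs, "VRS").theta
    assert theta == pytest.approx(1.0, abs=1e-9)


def test_grid_adjacency_shapes():
    # 2x2 rook lattice: 4 edges
    assert len(generate_adjacency(SyntheticConfig(n_regions=4, n_years=1)).edges) == 4
    # n=3 has no rectangle with aspect <= 2: falls back to the 1x3 path
    assert len(generate_adjacency(SyntheticConfig(n_regions=3, n_years=1)).edges) == 2
    # 31 regions on a 4x8 lattice with one unused cell: degrees 2..4, no islands
    w = generate_adjacency(SyntheticConfig(n_regions=31, n_years=1))
    assert len(w.islands) == 0
    degrees = [len(w.neighbors(r)) for r in w.regions]
    assert min(degrees) >= 2 and max(degrees) <= 4


def test_latent_transition_frequencies_recover_kernel():
    cfg = SyntheticConfig(seed=7)  # 31 regions x 20 years, published kernel
    _, truth = generate_panel(cfg)
    df = truth.latent_states.sort_values(["region_id", "year"])
    counts = np.zeros((3, 3))
    for _, g in df.groupby("region_id"):
        s = g["state"].to_numpy()
        for a, b in zip(s[:-1], s[1:]):
            counts[a - 1, b - 1] += 1
    assert counts.sum() == 31 * 19
    P_hat = counts / counts.sum(axis=1, keepdims=True)
    assert np.max(np.abs(P_hat - cfg.true_transition)) <= 0.08


def test_long_chain_state_frequencies_match_stationary():
    cfg = SyntheticConfig(n_regions=1, n_years=20_000, seed=13)
    seq = simulate_states(cfg, np.random.default_rng(13))[0]
    freqs = np.bincount(seq, minlength=4)[1:] / len(seq)
    pi = stationary_of_matrix(cfg.true_transition).pi
    assert freqs == pytest.approx(pi, abs=0.03)


def test_noise_free_frontier_units_are_bcc_efficient():
    cfg = SyntheticConfig(n_regions=10, n_years=2, noise_sd=0.0, seed=17)
    panel, truth = generate_panel(cfg)
    eff = score_panel(panel, frontier_scope="pooled")
    merged = eff.merge(truth.table, on=["region_id", "year"])
    frontier = merged[merged["state"] == 3]
    assert len(frontier) > 0
    assert np.allclose(frontier["pte"], 1.0, atol=1e-7)
    # no unit can beat its own technology-implied efficiency
    assert (merged["pte"] >= merged["true_efficiency"] - 1e-7).all()


def test_matched_output_mix_recovers_configured_level():
    # an inefficient unit sharing a frontier unit's outputs scores exactly
    # its configured state level
    spec = {
        "weights": np.array([[0.6, 0.4], [0.3, 0.7], [0.5, 0.5]]),
        "exponents": np.array([1.2, 1.3, 1.15]),
        "input_base": np.array([400.0, 600.0, 800.0]),
        "output_base": np.array([1000.0, 200.0]),
    }
    y = np.array([[900.0, 180.0], [1500.0, 260.0], [700.0, 120.0]])
    xf = frontier_inputs(y, spec)
    level = 0.78
    X = np.vstack([xf, xf[0] / level])  # unit 3 = unit 0's outputs, inefficient
    Y = np.vstack([y, y[0]])
    theta = solve_input_oriented(3, X, Y, "VRS").theta
    assert theta == pytest.approx(level, abs=1e-6)


def test_covariates_table_shape_and_accessor():
    cfg = SyntheticConfig(n_regions=5, n_years=4, seed=2)
    _, truth = generate_panel(cfg)
    cov = generate_covariates(cfg, truth)
    assert len(cov) == 20
    assert {"doctor_nurse_ratio", "staff_per_10k", "beds_per_staff", "ln_gdp_pc"} <= set(cov)
    assert (cov["beds_per_staff"] > 0).all()
    # effect pairs: scalar means upward-only
    cfg2 = SyntheticConfig(covariate_effects={"beds_per_staff": 1.5,
                                              "ln_gdp_pc": (-0.2, 0.1)})
    assert cfg2.effect_pair("beds_per_staff") == (1.5, 0.0)
    assert cfg2.effect_pair("ln_gdp_pc") == (-0.2, 0.1)
    assert cfg2.effect_pair("staff_per_10k") == (0.0, 0.0)


def test_spatial_coupling_requires_weights():
    cfg = SyntheticConfig(n_regions=4, n_years=3, spatial_coupling=0.5,
                          adjacency_scheme="supplied_edge_list")
    with pytest.raises(ValueError, match="SpatialWeights"):
        generate_panel(cfg)
    # grid scheme generates its own lattice
    cfg2 = SyntheticConfig(n_regions=4, n_years=3, spatial_coupling=0.5, seed=4)
    panel, _ = generate_panel(cfg2)
    assert len(panel.data) == 12
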
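"""Tests for mobility outcomes and linear-probability transition models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from effdyn.synth import SyntheticConfig, generate_covariates, generate_panel
from effdyn.states import StatePanel
from effdyn.transitions import DEFAULT_COVARIATES, build_outcomes, fit_lpm


def _covariates_for(outcomes, seed=0):
    rng = np.random.default_rng(seed)
    keys = outcomes[["region_id", "year"]].drop_duplicates()
    cov = keys.copy()
    for name in DEFAULT_COVARIATES:
        cov[name] = rng.normal(1.0, 0.3, size=len(cov))
    return cov


def _groups(outcomes):
    regions = sorted(outcomes["region_id"].unique())
    return {r: ("g1" if i % 2 == 0 else "g2") for i, r in enumerate(regions)}


def test_monotone_sequence_outcomes(state_panel_factory):
    sp = state_panel_factory({"A": [1, 2, 3]})
    out = build_outcomes(sp)
    assert out["upward"].tolist() == [1, 1]
    assert out["downward"].tolist() == [0, 0]


def test_top_state_excluded_from_upward_at_risk(state_panel_factory):
    sp = state_panel_factory({"A": [3, 3, 2], "B": [1, 1, 1]})
    out = build_outcomes(sp)
    top = out[out["state"] == 3]
    assert (top["at_risk_up"] == 0).all()
    bottom = out[out["state"] == 1]
    assert (bottom["at_risk_down"] == 0).all()


def test_at_risk_accounting_identity(state_panel_factory):
    rng = np.random.default_rng(4)
    sp = state_panel_factory({f"R{i}": rng.integers(1, 4, size=12).tolist() for i in range(8)})
    out = build_outcomes(sp)
    n_top = int((out["state"] == 3).sum())
    assert out["at_risk_up"].sum() + n_top == len(out)
    n_bottom = int((out["state"] == 1).sum())
    assert out["at_risk_down"].sum() + n_bottom == len(out)


def test_constant_zero_outcome_gives_zero_slopes(state_panel_factory):
    # everyone stays in the medium state: downward outcome is identically 0
    sp = state_panel_factory({f"R{i}": [2] * 6 for i in range(6)})
    out = build_outcomes(sp)
    cov = _covariates_for(out)
    res = fit_lpm(out, cov, outcome="downward", region_groups=_groups(out))
    assert res.params[list(DEFAULT_COVARIATES)].abs().max() < 1e-10
    assert res.r_squared == 0.0


def test_fixed_effect_reference_level_invariance(state_panel_factory):
    rng = np.random.default_rng(8)
    sp = state_panel_factory({f"R{i}": rng.integers(1, 4, size=10).tolist() for i in range(10)})
    out = build_outcomes(sp)
    cov = _covariates_for(out, seed=1)
    g1 = _groups(out)
    g2 = {r: {"g1": "zz_late", "g2": "aa_early"}[g] for r, g in g1.items()}  # flips dummy drop
    r1 = fit_lpm(out, cov, outcome="upward", region_groups=g1)
    r2 = fit_lpm(out, cov, outcome="upward", region_groups=g2)
    for name in DEFAULT_COVARIATES:
        assert r1.params[name] == pytest.approx(r2.params[name], abs=1e-9)
        assert r1.std_errors[name] == pytest.approx(r2.std_errors[name], abs=1e-9)


def test_row_duplication_leaves_coefficients_and_cluster_ses_stable(state_panel_factory):
    rng = np.random.default_rng(12)
    sp = state_panel_factory({f"R{i}": rng.integers(1, 4, size=10).tolist() for i in range(10)})
    out = build_outcomes(sp)
    cov = _covariates_for(out, seed=2)
    groups = _groups(out)
    base = fit_lpm(out, cov, outcome="upward", region_groups=groups)
    doubled = fit_lpm(pd.concat([out, out], ignore_index=True), cov,
                      outcome="upward", region_groups=groups)
    name = "beds_per_staff"
    assert doubled.params[name] == pytest.approx(base.params[name], abs=1e-9)
    # same clusters, identical residual pattern: the cluster-robust SE moves
    # only through the finite-sample factor, far less than the 1/sqrt(2)
    # shrinkage a naive iid SE would show
    ratio = doubled.std_errors[name] / base.std_errors[name]
    assert 0.85 < ratio <= 1.01
    assert doubled.n_obs == 2 * base.n_obs


def test_singleton_clusters_reduce_to_hc1(state_panel_factory):
    rng = np.random.default_rng(21)
    sp = state_panel_factory({f"R{i}": rng.integers(1, 4, size=3).tolist() for i in range(40)})
    out = build_outcomes(sp).reset_index(drop=True)
    out["unit"] = np.arange(len(out))
    cov = _covariates_for(out, seed=3)
    df = out.merge(cov, on=["region_id", "year"])
    df = df[df["at_risk_up"] == 1]
    X = sm.add_constant(df[list(DEFAULT_COVARIATES)].to_numpy())
    hc1 = sm.OLS(df["upward"].to_numpy(float), X).fit(cov_type="HC1")

    res = fit_lpm(
        out,
        cov,
        outcome="upward",
        region_fe="none",
        year_fe=False,
        cluster_col="unit",
    )
    for i, name in enumerate(DEFAULT_COVARIATES, start=1):
        assert res.std_errors[name] == pytest.approx(hc1.bse[i], rel=1e-9)


def test_effect_recovery_single_panel():
    beta = 1.0
    cfg = SyntheticConfig(seed=5, covariate_effects={"beds_per_staff": beta})
    _, truth = generate_panel(cfg)
    sp = StatePanel(truth.latent_states, np.array([np.nan, np.nan]), "truth")
    out = build_outcomes(sp)
    cov = generate_covariates(cfg, truth)
    groups = {r: f"g{i % 4}" for i, r in enumerate(cfg.region_ids)}
    res = fit_lpm(out, cov, outcome="upward", region_groups=groups)
    est, se = res.params["beds_per_staff"], res.std_errors["beds_per_staff"]
    assert abs(est - beta) <= 2 * se
    assert res.n_obs == int(out["at_risk_up"].sum())
    assert res.summary_table().loc[
        res.summary_table()["variable"] == "beds_per_staff", "stars"
    ].item() in ("**", "***")


def test_upward_downward_at_risk_samples_differ(state_panel_factory):
    rng = np.random.default_rng(30)
    # bottom-heavy occupancy: states mostly 1, so the upward at-risk sample
    # is much larger than the downward one
    seqs = {f"R{i}": np.minimum(rng.integers(1, 4, size=12), rng.integers(1, 4, size=12)).tolist()
            for i in range(10)}
    sp = state_panel_factory(seqs)
    out = build_outcomes(sp)
    cov = _covariates_for(out, seed=6)
    up = fit_lpm(out, cov, outcome="upward", region_fe="none", year_fe=False)
    down = fit_lpm(out, cov, outcome="downward", region_fe="none", year_fe=False)
    # bottom-heavy occupancy: many at risk of moving up, few of moving down
    assert up.n_obs != down.n_obs
    assert up.n_obs == int(out["at_risk_up"].sum())
    assert down.n_obs == int(out["at_risk_down"].sum())


def test_rank_deficiency_and_cluster_count_guards(state_panel_factory):
    sp = state_panel_factory({"A": [1, 2, 1, 2], "B": [2, 1, 2, 1]})
    out = build_outcomes(sp)
    cov = _covariates_for(out, seed=7)
    cov["beds_per_staff"] = cov["doctor_nurse_ratio"]  # exact collinearity
    with pytest.raises(ValueError, match="rank deficient"):
        fit_lpm(out, cov, outcome="upward", region_fe="none")

    sp1 = state_panel_factory({"A": [1, 2, 1, 2, 1]})
    out1 = build_outcomes(sp1)
    with pytest.raises(ValueError, match="clusters"):
        fit_lpm(out1, _covariates_for(out1), outcome="upward", region_fe="none", year_fe=False)
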
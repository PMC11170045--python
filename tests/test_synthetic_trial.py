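"""Generator calibration, dropout mechanism, and closed-form ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import trialcea as tc
from trialcea import costing, pipeline
from trialcea.clinical_outcomes import remission, response
from trialcea.errors import ConfigurationError
from trialcea.synthetic_trial import (
    DiscreteTruncatedScoreSpec,
    DropoutSpec,
    TruncatedNormalSpec,
    apply_dropout,
    arm_endpoint_probabilities,
    calibrated_config,
    expected_increments,
    generate_trial,
    null_config,
)


@pytest.fixture(scope="module")
def big_trial():
    """One large complete trial for consistency checks (10^5 per arm)."""
    cfg = calibrated_config(99).replace(n_per_arm=(100_000, 100_000))
    return cfg, generate_trial(cfg)


def test_determinism_bit_identical():
    cfg = calibrated_config(5).replace(n_per_arm=(60, 60))
    a, b = generate_trial(cfg), generate_trial(cfg)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_arm_sizes_and_ids(calibrated):
    ds = generate_trial(calibrated)
    assert ds.n_participants == 1249
    assert ds.arm_sizes() == {"SbS": 614, "EUC": 635}


def test_all_baselines_pass_eligibility(small_complete):
    b = small_complete.baseline()
    assert (b["phq9"] > 10).all()
    assert (b["whodas12"] > 16).all()
    assert (b["age"] >= 18).all()


def test_baseline_calibration_targets(calibrated):
    """Sample moments at n=1249 match the published baseline table."""
    b = generate_trial(calibrated).baseline()
    assert b["phq9"].mean() == pytest.approx(16.4, abs=0.3)
    assert b["whodas12"].mean() == pytest.approx(33.0, abs=0.5)


def test_null_config_symmetry():
    cfg = null_config(13).replace(n_per_arm=(4000, 4000))
    ds = generate_trial(cfg)
    t2 = ds.df[ds.df["assessment"] == "t2"]
    phq_diff = (
        t2[t2["arm"] == "SbS"]["phq9"].mean() - t2[t2["arm"] == "EUC"]["phq9"].mean()
    )
    assert abs(phq_diff) < 0.3  # ~3 SEs at this n
    wide = pipeline.build_analysis_table(ds)
    for col in ("healthcare_cost_t2", "productivity_cost_t2"):
        diff = (
            wide[wide["arm"] == "SbS"][col].mean()
            - wide[wide["arm"] == "EUC"][col].mean()
        )
        assert abs(diff) < 15.0


def test_cost_components_nonnegative(small_complete):
    for item in costing.MEDICAL_ITEMS + ("absent_days", "cutback_days"):
        assert (small_complete.df[item] >= 0).all()


def test_zero_inflation_mass_reproduced(big_trial):
    cfg, ds = big_trial
    t0 = ds.df[(ds.df["assessment"] == "t0") & (ds.df["arm"] == "EUC")]
    n = len(t0)
    for item, (p_use, _) in cfg.cost_components.item_mix.items():
        frac = (t0[item] > 0).mean()
        se = np.sqrt(p_use * (1 - p_use) / n)
        assert frac == pytest.approx(p_use, abs=max(4 * se, 1e-3)), item


def test_dropout_zero_targets_is_identity(small_complete, calibrated):
    cfg = calibrated.replace(
        dropout=DropoutSpec(
            t1_targets={"SbS": 0.0, "EUC": 0.0}, t2_targets={"SbS": 0.0, "EUC": 0.0}
        )
    )
    out = apply_dropout(small_complete, cfg)
    pd.testing.assert_frame_equal(out.df, small_complete.df)


def test_dropout_rates_match_targets_on_average(calibrated):
    """Mean realized t2 missingness over replicate seeds within 0.02."""
    ds = generate_trial(calibrated)
    rates = {"SbS": [], "EUC": []}
    for seed in range(200):
        out = apply_dropout(ds, calibrated, seed=seed)
        for arm in rates:
            rates[arm].append(out.missing_share("t2", arm))
    assert np.mean(rates["SbS"]) == pytest.approx(0.681, abs=0.02)
    assert np.mean(rates["EUC"]) == pytest.approx(0.583, abs=0.02)


def test_dropout_monotone_and_baseline_preserved(small_with_dropout):
    wide = small_with_dropout.wide()
    assert (wide["observed_t0"] == 1).all()
    lost_t1 = wide["observed_t1"] == 0
    assert (wide.loc[lost_t1, "observed_t2"] == 0).all()


def test_mar_dropouts_are_more_depressed(calibrated):
    """Positive MAR coefficient on baseline PHQ-9: dropouts sicker on average."""
    ds = generate_trial(calibrated)
    diffs = []
    for seed in range(60):
        out = apply_dropout(ds, calibrated, seed=seed)
        wide = out.wide(columns=("phq9",))
        lost = wide["observed_t2"] == 0
        diffs.append(wide.loc[lost, "phq9_t0"].mean() - wide.loc[~lost, "phq9_t0"].mean())
    assert np.mean(diffs) > 0.3


def test_expected_increments_null_is_zero():
    eff = expected_increments(null_config())
    assert eff.delta_cost_healthcare == 0.0
    assert eff.delta_cost_societal == 0.0
    assert eff.delta_response == pytest.approx(0.0, abs=1e-12)
    assert eff.delta_remission == pytest.approx(0.0, abs=1e-12)


def test_expected_increments_intervention_cost_only():
    cfg = null_config().replace(intervention_budget=122_320.0)
    eff = expected_increments(cfg)
    assert eff.delta_cost_healthcare == pytest.approx(26.0255, abs=1e-3)
    assert eff.delta_cost_societal == pytest.approx(26.0255, abs=1e-3)
    assert eff.delta_response == pytest.approx(0.0, abs=1e-12)


def test_calibrated_increments_match_design_targets(calibrated):
    """Shipped defaults encode the published incremental quantities."""
    eff = expected_increments(calibrated)
    assert eff.delta_cost_healthcare == pytest.approx(28.0, abs=0.5)
    assert eff.delta_cost_societal == pytest.approx(-24.0, abs=0.5)
    assert eff.delta_response == pytest.approx(0.228, abs=0.005)
    assert eff.delta_remission == pytest.approx(0.058, abs=0.005)


def test_large_n_empirical_increments_match_closed_form(big_trial):
    """Monte-Carlo consistency of the generator with its own closed form."""
    cfg, ds = big_trial
    truth = expected_increments(cfg)
    wide = pipeline.build_analysis_table(ds)
    n = 100_000
    per_user = costing.intervention_cost("SbS", cfg.intervention_budget, cfg.annual_capacity)

    resp = response(wide["phq9_t0"], wide["phq9_t2"])
    rem = remission(wide["phq9_t2"])
    sbs = (wide["arm"] == "SbS").to_numpy()
    d_resp = resp[sbs].mean() - resp[~sbs].mean()
    d_rem = rem[sbs].mean() - rem[~sbs].mean()
    se_p = np.sqrt(2 * 0.5 * 0.5 / n)
    assert d_resp == pytest.approx(truth.delta_response, abs=3 * se_p)
    assert d_rem == pytest.approx(truth.delta_remission, abs=3 * se_p)

    for key, target in (
        ("healthcare_cost", truth.delta_cost_healthcare),
        ("societal_cost", truth.delta_cost_societal),
    ):
        cum = costing.cumulative_cost(
            wide[f"{key}_t0"], wide[f"{key}_t1"], wide[f"{key}_t2"]
        ) + per_user * sbs
        d = cum[sbs].mean() - cum[~sbs].mean()
        se = np.sqrt(cum[sbs].var() / n + cum[~sbs].var() / n)
        assert d == pytest.approx(target, abs=3 * se)


def test_arm_endpoint_probabilities_are_probabilities(calibrated):
    probs = arm_endpoint_probabilities(calibrated)
    for arm in ("SbS", "EUC"):
        assert 0 < probs[arm]["remission"] < probs[arm]["response"] < 1
    assert probs["SbS"]["response"] > probs["EUC"]["response"]


@pytest.mark.parametrize(
    "mutate",
    [
        lambda c: c.replace(n_per_arm=(0, 10)),
        lambda c: c.replace(
            baseline_phq=DiscreteTruncatedScoreSpec(mu=15, sd=-1, exclusive_lower=10, upper=27)
        ),
        lambda c: c.replace(
            baseline_whodas=TruncatedNormalSpec(mu=33, sd=0.0, lower=16, upper=60)
        ),
        lambda c: c.replace(
            dropout=DropoutSpec(t1_targets={"SbS": 0.5, "EUC": 0.5},
                                t2_targets={"SbS": 0.4, "EUC": 0.6})
        ),
        lambda c: c.replace(
            dropout=DropoutSpec(t1_targets={"SbS": 0.5, "EUC": 0.5},
                                t2_targets={"SbS": 1.2, "EUC": 0.6})
        ),
    ],
)
def test_invalid_configurations_rejected(calibrated, mutate):
    with pytest.raises(ConfigurationError):
        mutate(calibrated)


def test_trajectory_effect_field(calibrated):
    tr = calibrated.trajectory
    assert calibrated.effect_phq_t2 == pytest.approx(tr.beta["SbS"] - tr.beta["EUC"])
    assert calibrated.effect_phq_t2 < 0  # intervention lowers symptom severity
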
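"""SUR estimation, bootstrap, ICER, plane quadrants, CEAC, WTP queries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from trialcea import econ_eval
from trialcea.econ_eval import (
    CEACurve,
    ICERCloud,
    SureSpec,
    bootstrap_cloud,
    ceac,
    fgls_sur,
    fit_sure,
    icer,
    quadrant_shares,
    wtp_at_probability,
)
from trialcea.errors import ConfigurationError, DegenerateDataError, ValidationError

# 6-participant worked fixture: cumulative cost, baseline cost, endpoint
SIX = pd.DataFrame(
    {
        "arm": ["SbS", "SbS", "SbS", "EUC", "EUC", "EUC"],
        "cumulative_cost": [120.0, 80.0, 150.0, 100.0, 60.0, 140.0],
        "baseline_cost": [30.0, 10.0, 50.0, 40.0, 20.0, 60.0],
        "response": [1, 1, 0, 0, 1, 0],
    }
)


def _cloud(dc, de):
    return ICERCloud(
        delta_cost=np.asarray(dc, float), delta_effect=np.asarray(de, float)
    )


def _no_covariate_frame(rng, n=300):
    arm = np.repeat(["SbS", "EUC"], n)
    cost = np.concatenate(
        [rng.gamma(0.8, 150, n) + 30, rng.gamma(0.8, 140, n)]
    )
    resp = np.concatenate(
        [rng.random(n) < 0.5, rng.random(n) < 0.3]
    ).astype(int)
    return pd.DataFrame({"arm": arm, "cumulative_cost": cost, "response": resp})


def test_identical_regressors_reduce_to_ols(rng):
    """Classical SUR result: same X in both equations => FGLS == OLS."""
    frame = _no_covariate_frame(rng)
    spec = SureSpec(cost_covariates=())
    fit = fit_sure(frame, spec)
    X = np.column_stack(
        [np.ones(len(frame)), (frame["arm"] == "SbS").to_numpy(float)]
    )
    for y, got in (
        (frame["cumulative_cost"].to_numpy(float), fit.cost_coefficients),
        (frame["response"].to_numpy(float), fit.effect_coefficients),
    ):
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(got, ols, rtol=1e-10)


def test_saturated_model_recovers_mean_differences(rng):
    frame = _no_covariate_frame(rng)
    fit = fit_sure(frame, SureSpec(cost_covariates=()))
    sbs = frame["arm"] == "SbS"
    dc = frame.loc[sbs, "cumulative_cost"].mean() - frame.loc[~sbs, "cumulative_cost"].mean()
    de = frame.loc[sbs, "response"].mean() - frame.loc[~sbs, "response"].mean()
    assert fit.delta_cost == pytest.approx(dc, rel=1e-10)
    assert fit.delta_effect == pytest.approx(de, rel=1e-10)


def test_six_participant_fixture_matches_dense_gls_oracle():
    """Independent oracle: explicit Kronecker GLS solve with matrix inversion."""
    arm = (SIX["arm"] == "SbS").to_numpy(float)
    X1 = np.column_stack([np.ones(6), arm, SIX["baseline_cost"].to_numpy(float)])
    X2 = np.column_stack([np.ones(6), arm])
    y1 = SIX["cumulative_cost"].to_numpy(float)
    y2 = SIX["response"].to_numpy(float)
    # one FGLS iteration, written the slow dense way
    b1 = np.linalg.inv(X1.T @ X1) @ X1.T @ y1
    b2 = np.linalg.inv(X2.T @ X2) @ X2.T @ y2
    E = np.column_stack([y1 - X1 @ b1, y2 - X2 @ b2])
    S = E.T @ E / 6
    Xbig = np.block(
        [[X1, np.zeros((6, 2))], [np.zeros((6, 3)), X2]]
    )
    W = np.kron(np.linalg.inv(S), np.eye(6))
    ybig = np.concatenate([y1, y2])
    beta = np.linalg.inv(Xbig.T @ W @ Xbig) @ Xbig.T @ W @ ybig

    fit = fit_sure(SIX, SureSpec())
    np.testing.assert_allclose(
        np.concatenate([fit.cost_coefficients, fit.effect_coefficients]),
        beta,
        rtol=1e-8,
    )
    assert fit.delta_cost == pytest.approx(beta[1], rel=1e-8)
    assert fit.delta_effect == pytest.approx(beta[4], rel=1e-8)


def test_constant_endpoint_is_degenerate():
    frame = SIX.assign(response=1)
    with pytest.raises(DegenerateDataError, match="constant"):
        fit_sure(frame, SureSpec())


def test_collinear_covariates_raise():
    frame = SIX.assign(dup=SIX["baseline_cost"])
    with pytest.raises(DegenerateDataError):
        fit_sure(frame, SureSpec(cost_covariates=("baseline_cost", "dup")))


def test_bootstrap_single_draw_deterministic():
    a = bootstrap_cloud(SIX, SureSpec(), B=1, seed=11)
    b = bootstrap_cloud(SIX, SureSpec(), B=1, seed=11)
    assert a.B == 1
    np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
    np.testing.assert_array_equal(a.delta_effect, b.delta_effect)


def test_bootstrap_preserves_arm_sizes_structurally(rng):
    """Stratified resampling: null data => ΔE_b centred on 0."""
    n = 250
    frame = pd.DataFrame(
        {
            "arm": np.repeat(["SbS", "EUC"], n),
            "cumulative_cost": rng.gamma(1.0, 100, 2 * n),
            "response": (rng.random(2 * n) < 0.4).astype(int),
        }
    )
    cloud = bootstrap_cloud(frame, SureSpec(cost_covariates=()), B=800, seed=2)
    frac_pos = (cloud.delta_effect > cloud.delta_effect.mean()).mean()
    assert 0.42 < frac_pos < 0.58


def test_bootstrap_se_matches_analytic_two_sample_se(rng):
    """No-covariate trial: bootstrap SE of ΔC within 10% of the closed form."""
    frame = _no_covariate_frame(rng, n=400)
    cloud = bootstrap_cloud(frame, SureSpec(cost_covariates=()), B=2500, seed=4)
    c = frame["cumulative_cost"].to_numpy()
    sbs = (frame["arm"] == "SbS").to_numpy()
    analytic = np.sqrt(c[sbs].var() / sbs.sum() + c[~sbs].var() / (~sbs).sum())
    assert cloud.delta_cost.std(ddof=1) == pytest.approx(analytic, rel=0.10)


def test_bootstrap_rejects_nonpositive_B():
    with pytest.raises(ConfigurationError):
        bootstrap_cloud(SIX, SureSpec(), B=0)


@pytest.mark.parametrize(
    "dc, de, value, cls",
    [
        (28, 0.23, 121.74, "ratio"),
        (-24, 0.228, -105.26, "dominant"),
        (23, 0.228, 100.88, "ratio"),
        (10, -0.1, -100.0, "dominated"),
        (0, 0.5, 0.0, "cheaper-equal at positive effect"),
    ],
)
def test_icer_values_and_classification(dc, de, value, cls):
    res = icer(dc, de)
    assert res.value == pytest.approx(value, abs=0.01)
    assert res.classification == cls
    assert res.defined


def test_icer_zero_effect_is_flagged_not_raised():
    res = icer(5.0, 0.0)
    assert not res.defined
    assert np.isnan(res.value)
    assert "undefined" in res.classification


def test_quadrants_point_masses():
    assert quadrant_shares(_cloud([5.0], [0.1])) == {
        "NE": 1.0, "NW": 0.0, "SW": 0.0, "SE": 0.0
    }
    four = _cloud([1, 1, -1, -1], [0.1, -0.1, -0.1, 0.1])
    assert quadrant_shares(four) == {"NE": 0.25, "NW": 0.25, "SW": 0.25, "SE": 0.25}


def test_quadrant_tie_rules():
    # ΔE = 0 counts East, ΔC = 0 counts South
    shares = quadrant_shares(_cloud([1.0, 0.0, 0.0], [0.0, 0.1, -0.1]))
    assert shares == {"NE": 1 / 3, "NW": 0.0, "SW": 1 / 3, "SE": 1 / 3}


def test_quadrants_match_exhaustive_enumeration(rng):
    dc = rng.normal(size=20)
    de = rng.normal(size=20)
    shares = quadrant_shares(_cloud(dc, de))
    counts = {"NE": 0, "NW": 0, "SW": 0, "SE": 0}
    for c, e in zip(dc, de):  # brute-force, one draw at a time
        ns = "N" if c > 0 else "S"
        ew = "E" if e >= 0 else "W"
        counts[ns + ew] += 1
    for q in counts:
        assert shares[q] == pytest.approx(counts[q] / 20)


def test_ceac_trivial_examples():
    cloud = _cloud([-1.0, 1.0], [0.1, 0.1])
    curve = ceac(cloud, [0.0, 10.0, 20.0])
    assert curve.probability[0] == 0.5
    # at λ=10: 10*0.1-1 = 0 counts acceptable, and 10*0.1+1 > 0
    assert curve.probability[1] == 1.0
    assert curve.probability[2] == 1.0


def test_ceac_matches_direct_inequality(rng):
    dc = rng.normal(scale=30, size=20)
    de = rng.normal(loc=0.1, scale=0.2, size=20)
    grid = np.linspace(0, 400, 21)
    curve = ceac(_cloud(dc, de), grid)
    for lam, p in zip(curve.wtp, curve.probability):
        assert p == pytest.approx(np.mean(lam * de - dc >= 0))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    dc=hnp.arrays(float, st.integers(1, 40), elements=st.floats(-200, 200)),
    de=hnp.arrays(float, st.integers(1, 40), elements=st.floats(-0.5, 0.5)),
)
def test_quadrant_and_ceac_invariants(dc, de):
    n = min(dc.size, de.size)
    cloud = _cloud(dc[:n], de[:n])
    shares = quadrant_shares(cloud)
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
    curve = ceac(cloud, [0.0, 50.0, 100.0])
    # CEAC at zero WTP equals the South (cost-saving) share, exactly
    assert curve.probability[0] == pytest.approx(shares["SW"] + shares["SE"], abs=1e-12)
    if np.all(cloud.delta_effect >= 0):
        assert np.all(np.diff(curve.probability) >= 0)


def test_wtp_interpolation_on_three_point_fixture():
    curve = CEACurve(
        wtp=np.array([0.0, 100.0, 200.0]),
        probability=np.array([0.14, 0.60, 0.95]),
    )
    # crossing 0.8 between 100 and 200: 100 + (0.8-0.6)/(0.95-0.6)*100
    assert wtp_at_probability(curve, 0.8) == pytest.approx(157.142857, abs=1e-6)
    assert wtp_at_probability(curve, 0.10) == 0.0  # below the curve minimum
    flat = CEACurve(wtp=np.array([0.0, 1.0]), probability=np.array([0.5, 0.5]))
    assert wtp_at_probability(flat, 0.8) == "unattained"


def test_wtp_non_monotone_curve_first_crossing():
    curve = CEACurve(
        wtp=np.array([0.0, 1.0, 2.0, 3.0]),
        probability=np.array([0.2, 0.9, 0.4, 0.95]),
    )
    got = wtp_at_probability(curve, 0.8)
    assert 0.0 < got < 1.0


def test_wtp_probability_domain():
    curve = CEACurve(wtp=np.array([0.0, 1.0]), probability=np.array([0.1, 0.9]))
    with pytest.raises(ConfigurationError):
        wtp_at_probability(curve, 1.0)


def test_validation_errors():
    with pytest.raises(ValidationError):
        quadrant_shares(_cloud([], []))
    with pytest.raises(ValidationError):
        ceac(_cloud([], []), [0.0])
    with pytest.raises(ValidationError):
        CEACurve(wtp=np.array([0.0, 0.0]), probability=np.array([0.1, 0.2]))
    with pytest.raises(ValidationError):
        CEACurve(wtp=np.array([0.0, 1.0]), probability=np.array([0.1, 1.2]))


def test_estimate_increments_bundles_cis(rng):
    frame = _no_covariate_frame(rng, n=120)
    est, cloud = econ_eval.estimate_increments(
        frame, SureSpec(cost_covariates=()), B=200, seed=8
    )
    assert est.B == cloud.B == 200
    assert est.ci_cost[0] <= est.delta_cost <= est.ci_cost[1]
    assert est.ci_effect[0] <= est.delta_effect <= est.ci_effect[1]
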
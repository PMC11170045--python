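"""Seemingly unrelated regressions, bootstrap, ICER, plane and CEAC.

The estimation target is the pair (ΔC, ΔE): incremental cumulative cost
and incremental effect (response or remission probability) of the
intervention arm over the comparator.  A two-equation SUR system is
estimated by feasible generalized least squares:

* cost equation: cumulative cost ~ intercept + arm + baseline period cost
  (adjusting for chance baseline cost imbalance);
* effect equation (linear probability model): endpoint ~ intercept + arm,
  so the arm coefficient is the absolute risk difference.

Equation-by-equation OLS provides residuals, their 2x2 cross-equation
covariance feeds one FGLS step, and the arm coefficients are (ΔC, ΔE).
Because cost data are heavily skewed, inference is nonparametric: the
participant-level bootstrap (stratified by arm, preserving the
randomization ratio) yields a cloud of (ΔC_b, ΔE_b) pairs that drives
the cost-effectiveness plane quadrant shares, the acceptability curve
CEAC(λ) = P(λ·ΔE_b − ΔC_b ≥ 0), and willingness-to-pay queries.

Tie rules (measure-zero in practice, fixed for exactness): ΔE = 0 counts
East, ΔC = 0 counts South, net benefit exactly 0 counts acceptable —
hence CEAC(0) = SW + SE share identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError, ValidationError

QUADRANTS = ("NE", "NW", "SW", "SE")

#: default WTP grids per outcome, US $ per unit effect (plane axis ranges)
DEFAULT_WTP_MAX = {"response": 500, "remission": 1500}


@dataclass(frozen=True)
class SureSpec:
    """Column roles for the two-equation system."""

    cost_outcome: str = "cumulative_cost"
    effect_outcome: str = "response"
    cost_covariates: tuple = ("baseline_cost",)
    effect_covariates: tuple = ()
    arm_column: str = "arm"
    intervention_arm: str = "SbS"


@dataclass(frozen=True)
class SureFit:
    delta_cost: float
    delta_effect: float
    cost_coefficients: np.ndarray
    effect_coefficients: np.ndarray
    residual_covariance: np.ndarray


@dataclass(frozen=True)
class ICERCloud:
    """Paired bootstrap draws of (ΔC_b, ΔE_b) with provenance."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int | None = None
    provenance: dict = field(default_factory=dict)
    n_redraws: int = 0

    @property
    def B(self) -> int:
        return self.delta_cost.size

    def __post_init__(self):
        if self.delta_cost.shape != self.delta_effect.shape:
            raise ValidationError("cloud arrays must be aligned")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_cost, "delta_effect": self.delta_effect}
        )


@dataclass(frozen=True)
class IncrementalEstimate:
    """Point estimates with bootstrap uncertainty."""

    delta_cost: float
    delta_effect: float
    se_cost: float
    se_effect: float
    ci_cost: tuple
    ci_effect: tuple
    B: int

    def __post_init__(self):
        if not (self.ci_cost[0] <= self.delta_cost <= self.ci_cost[1]):
            warnings.warn(
                "cost CI does not bracket the point estimate", stacklevel=2
            )


@dataclass(frozen=True)
class CEACurve:
    """Probability of cost-effectiveness along a WTP grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.wtp) <= 0):
            raise ValidationError("WTP grid must be strictly increasing")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


@dataclass(frozen=True)
class ICERResult:
    value: float  # NaN when undefined
    classification: str
    delta_cost: float
    delta_effect: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)


# ---------------------------------------------------------------------------
# SUR estimation
# ---------------------------------------------------------------------------


def _design(frame: pd.DataFrame, spec: SureSpec, covariates) -> np.ndarray:
    arm = (frame[spec.arm_column] == spec.intervention_arm).to_numpy(float)
    cols = [np.ones(len(frame)), arm]
    for c in covariates:
        cols.append(frame[c].to_numpy(float))
    return np.column_stack(cols)


def _ols(X, y):
    XtX = X.T @ X
    try:
        beta = np.linalg.solve(XtX, X.T @ y)
    except np.linalg.LinAlgError:
        raise DegenerateDataError("collinear covariates (rank error)") from None
    return beta


def fgls_sur(y1, X1, y2, X2) -> SureFit:
    """Two-equation SUR: per-equation OLS, then one FGLS step.

    The FGLS step weights the stacked normal equations by the inverse of
    the estimated cross-equation residual covariance.  With identical
    regressor matrices this reproduces OLS exactly (classical result).
    """
    n = y1.size
    b1, b2 = _ols(X1, y1), _ols(X2, y2)
    e1, e2 = y1 - X1 @ b1, y2 - X2 @ b2
    S = np.array(
        [[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]]
    ) / n
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise DegenerateDataError(
            "singular residual covariance between equations"
        ) from None
    s11, s12, s22 = Sinv[0, 0], Sinv[0, 1], Sinv[1, 1]
    p1, p2 = X1.shape[1], X2.shape[1]
    A = np.empty((p1 + p2, p1 + p2))
    A[:p1, :p1] = s11 * (X1.T @ X1)
    A[:p1, p1:] = s12 * (X1.T @ X2)
    A[p1:, :p1] = A[:p1, p1:].T
    A[p1:, p1:] = s22 * (X2.T @ X2)
    rhs = np.concatenate(
        [s11 * (X1.T @ y1) + s12 * (X1.T @ y2), s12 * (X2.T @ y1) + s22 * (X2.T @ y2)]
    )
    try:
        beta = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        raise DegenerateDataError("collinear covariates (rank error)") from None
    return SureFit(
        delta_cost=float(beta[1]),
        delta_effect=float(beta[p1 + 1]),
        cost_coefficients=beta[:p1],
        effect_coefficients=beta[p1:],
        residual_covariance=S,
    )


def fit_sure(frame: pd.DataFrame, spec: SureSpec) -> SureFit:
    """Estimate (ΔC, ΔE) on a completed dataset.

    The arm coefficient of each equation is the incremental quantity.
    Raises on a constant endpoint (degenerate linear probability model).
    """
    y2 = frame[spec.effect_outcome].to_numpy(float)
    if np.isnan(y2).any() or np.isnan(
        frame[spec.cost_outcome].to_numpy(float)
    ).any():
        raise ValidationError("fit_sure requires complete (imputed) data")
    if np.all(y2 == y2[0]):
        raise DegenerateDataError(
            f"endpoint {spec.effect_outcome!r} is constant (all {y2[0]:g})"
        )
    X1 = _design(frame, spec, spec.cost_covariates)
    X2 = _design(frame, spec, spec.effect_covariates)
    y1 = frame[spec.cost_outcome].to_numpy(float)
    return fgls_sur(y1, X1, y2, X2)


def bootstrap_cloud(
    frame: pd.DataFrame, spec: SureSpec, B: int = 2500, seed: int = 0
) -> ICERCloud:
    """Nonparametric participant bootstrap of the SUR system.

    Resamples participants with replacement *within arm* (preserving the
    per-arm sizes), refits the system per replicate and collects
    (ΔC_b, ΔE_b).  Degenerate resamples (e.g. a constant endpoint) are
    redrawn; the redraw count is recorded on the cloud.
    """
    if B <= 0:
        raise ConfigurationError("B must be >= 1")
    y1 = frame[spec.cost_outcome].to_numpy(float)
    y2 = frame[spec.effect_outcome].to_numpy(float)
    X1 = _design(frame, spec, spec.cost_covariates)
    X2 = _design(frame, spec, spec.effect_covariates)
    arm_idx = [
        np.flatnonzero(frame[spec.arm_column].to_numpy() == a)
        for a in np.unique(frame[spec.arm_column])
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    dc = np.empty(B)
    de = np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        take = np.concatenate(
            [idx[rng.integers(0, idx.size, idx.size)] for idx in arm_idx]
        )
        try:
            if np.all(y2[take] == y2[take[0]]):
                raise DegenerateDataError("constant endpoint in resample")
            fit = fgls_sur(y1[take], X1[take], y2[take], X2[take])
        except DegenerateDataError:
            redraws += 1
            if redraws > 100 * B:
                raise
            continue
        dc[b], de[b] = fit.delta_cost, fit.delta_effect
        b += 1
    return ICERCloud(
        delta_cost=dc,
        delta_effect=de,
        seed=seed,
        provenance={
            "B": B,
            "cost_outcome": spec.cost_outcome,
            "effect_outcome": spec.effect_outcome,
        },
        n_redraws=redraws,
    )


def estimate_increments(
    frame: pd.DataFrame, spec: SureSpec, B: int = 2500, seed: int = 0
) -> tuple[IncrementalEstimate, ICERCloud]:
    """Point estimates plus bootstrap SEs and percentile 95% CIs."""
    fit = fit_sure(frame, spec)
    cloud = bootstrap_cloud(frame, spec, B=B, seed=seed)
    lo_c, hi_c = np.percentile(cloud.delta_cost, [2.5, 97.5])
    lo_e, hi_e = np.percentile(cloud.delta_effect, [2.5, 97.5])
    est = IncrementalEstimate(
        delta_cost=fit.delta_cost,
        delta_effect=fit.delta_effect,
        se_cost=float(cloud.delta_cost.std(ddof=1)),
        se_effect=float(cloud.delta_effect.std(ddof=1)),
        ci_cost=(float(lo_c), float(hi_c)),
        ci_effect=(float(lo_e), float(hi_e)),
        B=cloud.B,
    )
    return est, cloud


# ---------------------------------------------------------------------------
# decision analytics
# ---------------------------------------------------------------------------


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost-effectiveness ratio with dominance classification.

    ΔC/ΔE when ΔE is nonzero.  "dominant": better effects for less cost
    (ΔC < 0, ΔE > 0); "dominated": worse effects for more cost (ΔC > 0,
    ΔE < 0).  A zero ΔE yields an undefined (NaN) value, flagged in the
    classification rather than raised.
    """
    if delta_effect == 0:
        return ICERResult(
            value=float("nan"),
            classification="undefined (zero incremental effect)",
            delta_cost=delta_cost,
            delta_effect=delta_effect,
        )
    value = delta_cost / delta_effect
    if delta_cost < 0 and delta_effect > 0:
        cls = "dominant"
    elif delta_cost > 0 and delta_effect < 0:
        cls = "dominated"
    elif delta_cost == 0 and delta_effect > 0:
        cls = "cheaper-equal at positive effect"
    else:
        cls = "ratio"
    return ICERResult(
        value=float(value),
        classification=cls,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
    )


def quadrant_shares(cloud: ICERCloud) -> dict:
    """Cost-effectiveness plane quadrant shares; they sum to exactly 1.

    East is ΔE >= 0, North is ΔC > 0 (ties: ΔE = 0 East, ΔC = 0 South).
    """
    if cloud.B == 0:
        raise ValidationError("empty bootstrap cloud")
    east = cloud.delta_effect >= 0
    north = cloud.delta_cost > 0
    n = cloud.B
    return {
        "NE": float(np.sum(east & north)) / n,
        "NW": float(np.sum(~east & north)) / n,
        "SW": float(np.sum(~east & ~north)) / n,
        "SE": float(np.sum(east & ~north)) / n,
    }


def ceac(cloud: ICERCloud, wtp_grid) -> CEACurve:
    """Acceptability curve: P(net benefit λ·ΔE_b − ΔC_b >= 0) over the grid."""
    if cloud.B == 0:
        raise ValidationError("empty bootstrap cloud")
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty WTP grid")
    nb = grid[:, None] * cloud.delta_effect[None, :] - cloud.delta_cost[None, :]
    prob = (nb >= 0).mean(axis=1)
    return CEACurve(wtp=grid, probability=prob)


def wtp_at_probability(curve: CEACurve, p: float):
    """Smallest WTP at which the (interpolated) curve reaches probability p.

    Returns the grid minimum when the curve starts at or above p, the
    linearly interpolated first crossing otherwise, and the string
    ``"unattained"`` when the curve never reaches p on the grid.  A
    non-monotone curve is still answered (first crossing) with a warning.
    """
    if not 0 < p < 1:
        raise ConfigurationError("p must be in (0, 1)")
    prob, wtp = curve.probability, curve.wtp
    if np.any(np.diff(prob) < 0):
        # expected whenever some draws have negative incremental effect
        logging.getLogger("trialcea.econ_eval").warning(
            "CEAC is not monotone; returning the first crossing"
        )
    if prob[0] >= p:
        return float(wtp[0])
    above = np.flatnonzero(prob >= p)
    if above.size == 0:
        return "unattained"
    i = above[0]
    w0, w1 = wtp[i - 1], wtp[i]
    p0, p1 = prob[i - 1], prob[i]
    if p1 == p0:
        return float(w1)
    return float(w0 + (p - p0) / (p1 - p0) * (w1 - w0))
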
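"""Imputation of follow-up PHQ-9 scores and aggregate period costs.

Two strategies mirror a trial analysis plan:

* **regression imputation** (base case): a single deterministic linear
  model per target, fitted on complete cases; missing entries get the
  fitted conditional mean, with no residual noise added.
* **MICE with predictive mean matching** (sensitivity): m completed
  datasets from chained equations; every imputed value is an observed
  donor value, the donor drawn uniformly among the ``k_donors`` complete
  cases whose predicted means are closest.

Predictors combine outcome predictors (baseline societal costs, PHQ-9,
gender, age, education, WHO-5) and missingness predictors (randomization
arm, marital/partner status, employment, baseline WHODAS-12).  Targets
are imputed in time order (t1 before t2).  PHQ-9 imputations are kept on
the score's natural scale (integer, 0-27); costs are floored at zero.
Observed cells are never modified; endpoints are computed only after
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError

DEFAULT_OUTCOME_PREDICTORS = (
    "societal_cost_t0",
    "phq9_t0",
    "gender",
    "age",
    "education",
    "who5_t0",
)
DEFAULT_MISSINGNESS_PREDICTORS = (
    "arm",
    "marital",
    "employment",
    "whodas12_t0",
)
DEFAULT_TARGETS = (
    "phq9_t1",
    "healthcare_cost_t1",
    "productivity_cost_t1",
    "phq9_t2",
    "healthcare_cost_t2",
    "productivity_cost_t2",
)

PHQ_RANGE = (0, 27)


@dataclass(frozen=True)
class ImputationSpec:
    outcome_predictors: tuple = DEFAULT_OUTCOME_PREDICTORS
    missingness_predictors: tuple = DEFAULT_MISSINGNESS_PREDICTORS
    targets: tuple = DEFAULT_TARGETS
    method: str = "regression"
    m: int = 20
    k_donors: int = 5
    n_iterations: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("regression", "mice_pmm"):
            raise ConfigurationError(f"unknown imputation method {self.method!r}")
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.k_donors < 1:
            raise ConfigurationError("k_donors must be >= 1")

    @property
    def predictors(self) -> tuple:
        seen, out = set(), []
        for p in self.outcome_predictors + self.missingness_predictors:
            if p not in seen:
                seen.add(p)
                out.append(p)
        return tuple(out)


def _design_matrix(frame: pd.DataFrame, columns) -> np.ndarray:
    """Intercept + numeric passthrough + one-hot (drop-first) categoricals."""
    pieces = [pd.Series(1.0, index=frame.index, name="const")]
    for col in columns:
        if col not in frame.columns:
            raise ConfigurationError(f"predictor column {col!r} not in data")
        s = frame[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(s.astype(float))
    return pd.concat(pieces, axis=1).to_numpy(dtype=float)


def _fit_predict(X_fit, y_fit, X_all, target: str):
    n, p = X_fit.shape
    if n < p + 2:
        raise DegenerateDataError(
            f"target {target!r}: only {n} complete cases for {p} regressors "
            "(rank deficiency)"
        )
    beta, _, rank, _ = np.linalg.lstsq(X_fit, y_fit, rcond=None)
    if rank < min(n, p) and rank < p:
        # collinear dummies are tolerated: lstsq returns the min-norm solution
        pass
    return X_all @ beta


def _postprocess(values: np.ndarray, target: str) -> np.ndarray:
    """Keep PHQ-9 imputations on the instrument scale; leave costs alone.

    Cost predictions are deliberately NOT floored at zero: they are
    estimation inputs, not observable costs, and truncating the (near-)
    zero-cost strata asymmetrically across arms would bias the arm
    contrast of these semicontinuous outcomes.
    """
    if target.startswith("phq9"):
        lo, hi = PHQ_RANGE
        return np.clip(np.rint(values), lo, hi)
    return values


def regression_impute(frame: pd.DataFrame, spec: ImputationSpec) -> pd.DataFrame:
    """Deterministic conditional-mean imputation, one linear model per target.

    Missing entries of each target are replaced by the fitted mean from
    an ordinary least-squares model on the union of outcome and
    missingness predictors, estimated on that target's complete cases.
    Same input, same output: no randomness.
    """
    if spec.method != "regression":
        raise ConfigurationError("spec.method must be 'regression'")
    out = frame.copy()
    X_all = _design_matrix(out, spec.predictors)
    for target in spec.targets:
        y = out[target].to_numpy(dtype=float)
        miss = np.isnan(y)
        if not miss.any():
            continue
        if miss.all():
            raise DegenerateDataError(f"target {target!r} has no observed values")
        pred = _fit_predict(X_all[~miss], y[~miss], X_all, target)
        y[miss] = _postprocess(pred[miss], target)
        out[target] = y
    return out


def mice_pmm(frame: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations with predictive mean matching.

    Returns ``spec.m`` completed datasets.  Each chained pass cycles over
    the targets in time order; the conditional model for a target uses
    the shared predictor set plus the other targets at their current
    values.  Every imputed cell holds an observed donor value.
    Reproducible given ``spec.seed``.
    """
    if spec.method != "mice_pmm":
        raise ConfigurationError("spec.method must be 'mice_pmm'")
    base = frame.copy()
    target_vals = {t: base[t].to_numpy(dtype=float) for t in spec.targets}
    miss_masks = {t: np.isnan(target_vals[t]) for t in spec.targets}
    for t, mask in miss_masks.items():
        if mask.all():
            raise DegenerateDataError(f"target {t!r} has no observed values")
    X_pred = _design_matrix(base, spec.predictors)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 271828]))
    completed = []
    for _ in range(spec.m):
        cur = {t: v.copy() for t, v in target_vals.items()}
        # initial fill: random observed donors
        for t in spec.targets:
            mask = miss_masks[t]
            if mask.any():
                obs = cur[t][~mask]
                cur[t][mask] = rng.choice(obs, size=mask.sum(), replace=True)
        any_missing = any(m.any() for m in miss_masks.values())
        n_sweeps = spec.n_iterations if any_missing else 0
        for _ in range(n_sweeps):
            for t in spec.targets:
                mask = miss_masks[t]
                if not mask.any():
                    continue
                others = np.column_stack(
                    [cur[o] for o in spec.targets if o != t]
                )
                X = np.column_stack([X_pred, others])
                yhat = _fit_predict(X[~mask], cur[t][~mask], X, t)
                donors = _pmm_draw(
                    yhat_obs=yhat[~mask],
                    y_obs=cur[t][~mask],
                    yhat_mis=yhat[mask],
                    k=spec.k_donors,
                    rng=rng,
                )
                cur[t][mask] = donors
        out = base.copy()
        for t in spec.targets:
            out[t] = cur[t]
        completed.append(out)
    return completed


class RegressionImputer:
    """Precompiled regression imputation for repeated (bootstrap) use.

    Builds the design matrix and missingness masks once; each call to
    :meth:`impute_rows` re-fits the per-target linear models on a row
    subset (a bootstrap resample) and returns the completed target
    arrays for those rows.  This is what lets the bootstrap propagate
    imputation-model uncertainty at negligible cost.
    """

    def __init__(self, frame: pd.DataFrame, spec: ImputationSpec):
        if spec.method != "regression":
            raise ConfigurationError("spec.method must be 'regression'")
        self.spec = spec
        self.X = _design_matrix(frame, spec.predictors)
        self.targets = {t: frame[t].to_numpy(dtype=float) for t in spec.targets}
        self.miss = {t: np.isnan(v) for t, v in self.targets.items()}
        for t, mask in self.miss.items():
            if mask.all():
                raise DegenerateDataError(f"target {t!r} has no observed values")

    def impute_rows(self, rows: np.ndarray) -> dict:
        """Completed target arrays for the given row indices (with repeats)."""
        X = self.X[rows]
        out = {}
        for t, values in self.targets.items():
            y = values[rows].copy()
            mask = self.miss[t][rows]
            if mask.any():
                pred = _fit_predict(X[~mask], y[~mask], X, t)
                y[mask] = _postprocess(pred[mask], t)
            out[t] = y
        return out

    def impute_full(self) -> dict:
        return self.impute_rows(np.arange(self.X.shape[0]))


def _pmm_draw(yhat_obs, y_obs, yhat_mis, k, rng):
    """For each missing case, draw one of the k nearest-prediction donors."""
    k = min(k, yhat_obs.size)
    dist = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    choice = rng.integers(0, k, size=yhat_mis.size)
    return y_obs[nearest[np.arange(yhat_mis.size), choice]]
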
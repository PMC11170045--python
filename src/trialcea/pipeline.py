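"""End-to-end evaluation: load/generate -> cost -> impute -> estimate -> decide.

One :func:`run_evaluation` call reproduces a single analysis cell
(perspective x outcome x imputation method); :func:`run_grid` runs all
eight cells and assembles a combined summary table (base-case and
sensitivity analyses for both perspectives and both endpoints).

Every report records its provenance (config, seed, package version) and
is bit-reproducible from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import clinical_outcomes, costing, econ_eval, missing_data
from .datasets import ARMS, ASSESSMENTS, TrialDataset
from .errors import ConfigurationError, DegenerateDataError
from .synthetic_trial import GeneratorConfig, apply_dropout, generate_trial

logger = logging.getLogger("trialcea")

OUTCOMES = ("response", "remission")
IMPUTATION_METHODS = ("regression", "mice")


@dataclass(frozen=True)
class EvalConfig:
    """One analysis cell: data source, perspective, outcome, imputation."""

    source: object  # CSV path, TrialDataset, or GeneratorConfig
    perspective: str = "healthcare"
    outcome: str = "response"
    imputation: str = "regression"
    B: int = 2500
    seed: int = 2019
    m: int = 20
    wtp_max: float | None = None  # default depends on the outcome
    wtp_step: float = 1.0
    unit_costs: str | None = None  # CSV path; None -> packaged table
    program_budget: float = costing.TOTAL_BUDGET
    annual_capacity: int = costing.ANNUAL_CAPACITY
    out_dir: str | None = None

    def __post_init__(self):
        if self.perspective not in costing.PERSPECTIVES:
            raise ConfigurationError(f"unknown perspective {self.perspective!r}")
        if self.outcome not in OUTCOMES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.imputation not in IMPUTATION_METHODS:
            raise ConfigurationError(f"unknown imputation {self.imputation!r}")
        if self.B < 1:
            raise ConfigurationError("B must be >= 1")

    def wtp_grid(self) -> np.ndarray:
        top = self.wtp_max or econ_eval.DEFAULT_WTP_MAX[self.outcome]
        return np.arange(0.0, top + self.wtp_step / 2, self.wtp_step)

    def replace(self, **kw) -> "EvalConfig":
        return dataclasses.replace(self, **kw)

    def provenance(self) -> dict:
        src = self.source
        if isinstance(src, TrialDataset):
            src_desc = f"<dataset n={src.n_participants}>"
        elif isinstance(src, GeneratorConfig):
            src_desc = f"<generator seed={src.seed} n_per_arm={src.n_per_arm}>"
        else:
            src_desc = str(src)
        d = dataclasses.asdict(self.replace(source=None))
        d["source"] = src_desc
        d["package_version"] = _pkg_version
        return d


@dataclass
class EvaluationReport:
    config_provenance: dict
    cost_table: pd.DataFrame  # per-arm period + cumulative means
    estimate: econ_eval.IncrementalEstimate
    icer: econ_eval.ICERResult
    quadrants: dict
    ceac: econ_eval.CEACurve
    cloud: econ_eval.ICERCloud
    wtp_at_50: object
    wtp_at_80: object
    counts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "delta_cost": self.estimate.delta_cost,
            "delta_effect": self.estimate.delta_effect,
            "se_cost": self.estimate.se_cost,
            "se_effect": self.estimate.se_effect,
            "ci_cost": list(self.estimate.ci_cost),
            "ci_effect": list(self.estimate.ci_effect),
            "icer": None if not self.icer.defined else self.icer.value,
            "icer_classification": self.icer.classification,
            "quadrants": self.quadrants,
            "wtp_at_50": self.wtp_at_50,
            "wtp_at_80": self.wtp_at_80,
            "B": self.cloud.B,
            "counts": self.counts,
            "provenance": self.config_provenance,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cloud.to_frame().round(2).to_csv(out / "icer_cloud.csv", index=False)
        self.ceac.to_frame().round(4).to_csv(out / "ceac.csv", index=False)
        self.cost_table.round(2).to_csv(out / "cost_table.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def load_dataset(source, dropout_seed: int | None = None) -> TrialDataset:
    """Resolve the configured data source to a TrialDataset."""
    if isinstance(source, TrialDataset):
        return source
    if isinstance(source, GeneratorConfig):
        ds = generate_trial(source)
        return apply_dropout(ds, source, seed=dropout_seed)
    return TrialDataset.from_csv(source)


def build_analysis_table(
    dataset: TrialDataset, table: costing.UnitCostTable | None = None
) -> pd.DataFrame:
    """Wide per-participant frame with aggregate period costs.

    Adds ``healthcare_cost_t*`` and ``productivity_cost_t*`` (NaN where
    the assessment was lost to dropout) and ``societal_cost_t0`` (a
    baseline imputation predictor).
    """
    table = table or costing.default_unit_cost_table()
    wide = dataset.wide()
    for t in ASSESSMENTS:
        hc = np.zeros(len(wide))
        for item in costing.MEDICAL_ITEMS:
            hc = hc + wide[f"{item}_{t}"].to_numpy(float) * table.price(item)
        wide[f"healthcare_cost_{t}"] = hc
        wide[f"productivity_cost_{t}"] = costing.productivity_cost_vector(
            wide[f"absent_days_{t}"],
            wide[f"cutback_days_{t}"],
            wide["wage_stratum"],
            wide["employment"],
            table,
        )
        wide[f"societal_cost_{t}"] = (
            wide[f"healthcare_cost_{t}"] + wide[f"productivity_cost_{t}"]
        )
    return wide


def complete_analysis_frames(
    wide: pd.DataFrame, config: EvalConfig
) -> list[pd.DataFrame]:
    """Impute missing PHQ-9 and period costs; one frame (regression) or m."""
    if config.imputation == "regression":
        spec = missing_data.ImputationSpec(method="regression")
        frames = [missing_data.regression_impute(wide, spec)]
    else:
        spec = missing_data.ImputationSpec(
            method="mice_pmm", m=config.m, seed=config.seed
        )
        frames = missing_data.mice_pmm(wide, spec)
    return frames


def prepare_estimation_frame(
    frame: pd.DataFrame, config: EvalConfig
) -> pd.DataFrame:
    """Attach endpoints, cumulative cost and baseline cost columns."""
    out = frame.copy()
    out["response"] = clinical_outcomes.response(out["phq9_t0"], out["phq9_t2"])
    out["remission"] = clinical_outcomes.remission(out["phq9_t2"])
    per_user = costing.intervention_cost(
        "SbS", config.program_budget, config.annual_capacity
    )
    for t in ASSESSMENTS:
        out[f"societal_cost_{t}"] = (
            out[f"healthcare_cost_{t}"] + out[f"productivity_cost_{t}"]
        )
    key = "healthcare_cost" if config.perspective == "healthcare" else "societal_cost"
    cum = costing.cumulative_cost(
        out[f"{key}_t0"], out[f"{key}_t1"], out[f"{key}_t2"]
    )
    out["cumulative_cost"] = cum + per_user * (out["arm"] == "SbS").to_numpy(float)
    out["baseline_cost"] = out[f"{key}_t0"]
    return out


def arm_cost_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean period and cumulative costs by category (report shape).

    Cumulative figures exclude the per-user intervention cost, mirroring
    how trial cost tables are usually presented.
    """
    rows = []
    w = costing.CUMULATIVE_WEIGHTS
    for category in ("healthcare", "productivity", "societal"):
        for arm in ARMS[::-1]:  # comparator first
            sub = frame[frame["arm"] == arm]
            t = [sub[f"{category}_cost_{a}"].mean() for a in ASSESSMENTS]
            rows.append(
                {
                    "category": category,
                    "arm": arm,
                    "t0": t[0],
                    "t1": t[1],
                    "t2": t[2],
                    "cumulative": w[0] * t[0] + w[1] * t[1] + w[2] * t[2],
                }
            )
    return pd.DataFrame(rows).set_index(["category", "arm"])


def _reimputing_bootstrap(
    wide: pd.DataFrame, config: EvalConfig, B: int, seed: int
) -> econ_eval.ICERCloud:
    """Stratified bootstrap that re-runs regression imputation per resample.

    Re-fitting the (deterministic) imputation models inside every
    replicate propagates imputation-model uncertainty into the cloud;
    with ~60% of follow-up cells imputed, freezing them would shrink the
    bootstrap variance far below the true sampling variance.
    """
    imputer = missing_data.RegressionImputer(
        wide, missing_data.ImputationSpec(method="regression")
    )
    arm = (wide["arm"] == "SbS").to_numpy()
    arm_idx = [np.flatnonzero(arm), np.flatnonzero(~arm)]
    phq_t0 = wide["phq9_t0"].to_numpy(float)
    hc_t0 = wide["healthcare_cost_t0"].to_numpy(float)
    prod_t0 = wide["productivity_cost_t0"].to_numpy(float)
    per_user = costing.intervention_cost(
        "SbS", config.program_budget, config.annual_capacity
    )
    w0, w1, w2 = costing.CUMULATIVE_WEIGHTS
    healthcare = config.perspective == "healthcare"

    rng = np.random.default_rng(np.random.SeedSequence([seed, 32452843]))
    dc, de = np.empty(B), np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        rows = np.concatenate(
            [idx[rng.integers(0, idx.size, idx.size)] for idx in arm_idx]
        )
        try:
            vals = imputer.impute_rows(rows)
        except DegenerateDataError:
            redraws += 1
            if redraws > 100 * B:
                raise
            continue
        t0 = phq_t0[rows]
        t2 = vals["phq9_t2"]
        if config.outcome == "response":
            y2 = ((t0 - t2) / t0 >= clinical_outcomes.RESPONSE_FRACTION).astype(
                float
            )
        else:
            y2 = (t2 < clinical_outcomes.REMISSION_CUTOFF).astype(float)
        if np.all(y2 == y2[0]):
            redraws += 1
            if redraws > 100 * B:
                raise DegenerateDataError("endpoint constant in resamples")
            continue
        hc = (
            w0 * hc_t0[rows]
            + w1 * vals["healthcare_cost_t1"]
            + w2 * vals["healthcare_cost_t2"]
        )
        if healthcare:
            cum = hc
            base = hc_t0[rows]
        else:
            cum = hc + (
                w0 * prod_t0[rows]
                + w1 * vals["productivity_cost_t1"]
                + w2 * vals["productivity_cost_t2"]
            )
            base = hc_t0[rows] + prod_t0[rows]
        a = arm[rows].astype(float)
        cum = cum + per_user * a
        ones = np.ones(rows.size)
        X1 = np.column_stack([ones, a, base])
        X2 = np.column_stack([ones, a])
        try:
            fit = econ_eval.fgls_sur(cum, X1, y2, X2)
        except DegenerateDataError:
            redraws += 1
            continue
        dc[b], de[b] = fit.delta_cost, fit.delta_effect
        b += 1
    return econ_eval.ICERCloud(
        delta_cost=dc,
        delta_effect=de,
        seed=seed,
        provenance={
            "B": B,
            "perspective": config.perspective,
            "outcome": config.outcome,
            "reimputed": True,
        },
        n_redraws=redraws,
    )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def run_evaluation(config: EvalConfig) -> EvaluationReport:
    """Execute the full stage sequence for one analysis cell."""
    dataset = load_dataset(config.source, dropout_seed=config.seed)
    counts = {
        "randomized": dataset.n_participants,
        "arm_sizes": dataset.arm_sizes(),
        "missing_t1": round(dataset.missing_share("t1"), 4),
        "missing_t2": round(dataset.missing_share("t2"), 4),
    }
    logger.info("stage load: %s", counts)
    wide = build_analysis_table(
        dataset,
        costing.build_unit_cost_table(pd.read_csv(config.unit_costs))
        if config.unit_costs
        else None,
    )
    frames = complete_analysis_frames(wide, config)
    logger.info("stage impute: %d completed dataset(s)", len(frames))

    spec = econ_eval.SureSpec(effect_outcome=config.outcome)
    seeds = np.random.SeedSequence([config.seed, 9001]).generate_state(len(frames))
    fits = [
        econ_eval.fit_sure(prepare_estimation_frame(f, config), spec)
        for f in frames
    ]
    if config.imputation == "regression":
        # base case: re-impute inside every resample so the cloud carries
        # imputation-model uncertainty
        cloud = _reimputing_bootstrap(
            wide, config, B=config.B, seed=int(seeds[0]) % 2**31
        )
    else:
        # sensitivity: full bootstrap per completed dataset, clouds
        # concatenated; the m streams carry between-imputation variance
        clouds = [
            econ_eval.bootstrap_cloud(
                prepare_estimation_frame(frame, config),
                spec,
                B=config.B,
                seed=int(s) % 2**31,
            )
            for frame, s in zip(frames, seeds)
        ]
        cloud = econ_eval.ICERCloud(
            delta_cost=np.concatenate([c.delta_cost for c in clouds]),
            delta_effect=np.concatenate([c.delta_effect for c in clouds]),
            seed=config.seed,
            provenance={
                "B": sum(c.B for c in clouds),
                "m": len(frames),
                "perspective": config.perspective,
                "outcome": config.outcome,
            },
            n_redraws=sum(c.n_redraws for c in clouds),
        )
    delta_cost = float(np.mean([f.delta_cost for f in fits]))
    delta_effect = float(np.mean([f.delta_effect for f in fits]))
    lo_c, hi_c = np.percentile(cloud.delta_cost, [2.5, 97.5])
    lo_e, hi_e = np.percentile(cloud.delta_effect, [2.5, 97.5])
    estimate = econ_eval.IncrementalEstimate(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        se_cost=float(cloud.delta_cost.std(ddof=1)),
        se_effect=float(cloud.delta_effect.std(ddof=1)),
        ci_cost=(float(lo_c), float(hi_c)),
        ci_effect=(float(lo_e), float(hi_e)),
        B=cloud.B,
    )
    curve = econ_eval.ceac(cloud, config.wtp_grid())
    report = EvaluationReport(
        config_provenance=config.provenance(),
        cost_table=arm_cost_table(prepare_estimation_frame(frames[0], config)),
        estimate=estimate,
        icer=econ_eval.icer(delta_cost, delta_effect),
        quadrants=econ_eval.quadrant_shares(cloud),
        ceac=curve,
        cloud=cloud,
        wtp_at_50=econ_eval.wtp_at_probability(curve, 0.5),
        wtp_at_80=econ_eval.wtp_at_probability(curve, 0.8),
        counts=counts,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def run_grid(config: EvalConfig) -> tuple[dict, pd.DataFrame]:
    """All 8 analysis cells (2 imputations x 2 perspectives x 2 outcomes).

    Returns the reports keyed by (imputation, perspective, outcome) and a
    combined summary table (one row per cell) mirroring the usual
    base-case/sensitivity presentation.
    """
    reports, rows = {}, []
    for method in IMPUTATION_METHODS:
        for perspective in costing.PERSPECTIVES:
            for outcome in OUTCOMES:
                cell = config.replace(
                    perspective=perspective,
                    outcome=outcome,
                    imputation=method,
                    out_dir=None,
                )
                rep = run_evaluation(cell)
                reports[(method, perspective, outcome)] = rep
                q = rep.quadrants
                rows.append(
                    {
                        "analysis": "base case"
                        if method == "regression"
                        else "sensitivity",
                        "perspective": perspective,
                        "outcome": outcome,
                        "incremental_cost": rep.estimate.delta_cost,
                        "incremental_effect": rep.estimate.delta_effect,
                        "icer": rep.icer.classification
                        if not rep.icer.defined
                        or rep.icer.classification == "dominant"
                        else round(rep.icer.value),
                        "NE": 100 * q["NE"],
                        "NW": 100 * q["NW"],
                        "SW": 100 * q["SW"],
                        "SE": 100 * q["SE"],
                    }
                )
    summary = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.round(2).to_csv(out / "grid_summary.csv", index=False)
        for (method, perspective, outcome), rep in reports.items():
            rep.write(out / f"{method}_{perspective}_{outcome}")
    return reports, summary
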
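"""Eligibility screening and PHQ-9 economic endpoints.

The trial screens adults in Lebanon for moderate-to-severe depressive
symptoms (PHQ-9 strictly above 10) with impaired functioning (WHODAS-12
strictly above 16).  For the economic evaluation the continuous PHQ-9
score is converted to two binary endpoints measured at the final
follow-up (t2, 20 weeks post baseline):

* **response** — at least a 50% improvement in PHQ-9 between baseline
  (t0) and t2; ties at exactly 50% count as response;
* **remission** — a t2 PHQ-9 score strictly below 5.

Endpoints are always computed *after* imputation of missing PHQ-9
scores, never imputed directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError

PHQ_MIN, PHQ_MAX = 0, 27
PHQ_ELIGIBILITY_THRESHOLD = 10  # eligible strictly above
WHODAS_ELIGIBILITY_THRESHOLD = 16  # eligible strictly above
MIN_AGE = 18
RESPONSE_FRACTION = 0.5
REMISSION_CUTOFF = 5  # remission strictly below


@dataclass(frozen=True)
class ScreeningRecord:
    """One screener submission, as collected by the intake questionnaire."""

    age: float
    phq9: int
    whodas12: float
    resides_flag: bool = True
    language_flag: bool = True
    internet_flag: bool = True
    imminent_suicide_risk: bool = False

    def __post_init__(self) -> None:
        for name in ("age", "phq9", "whodas12"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValidationError(f"screening field {name!r} is missing")
        if not PHQ_MIN <= self.phq9 <= PHQ_MAX:
            raise ValidationError(
                f"phq9={self.phq9} outside the instrument range [0, 27]"
            )


def is_eligible(record: ScreeningRecord) -> bool:
    """Apply the trial inclusion/exclusion rules to one screening record.

    Inclusion requires age >= 18, residence/language/internet access flags,
    PHQ-9 > 10 and WHODAS-12 > 16; imminent suicide risk excludes.
    """
    return (
        record.age >= MIN_AGE
        and record.resides_flag
        and record.language_flag
        and record.internet_flag
        and record.phq9 > PHQ_ELIGIBILITY_THRESHOLD
        and record.whodas12 > WHODAS_ELIGIBILITY_THRESHOLD
        and not record.imminent_suicide_risk
    )


def _require_present(value, what: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.isnan(arr).any():
        raise MissingDataError(
            f"{what} contains missing values; impute PHQ-9 scores before "
            "converting them to endpoints"
        )


def response(phq_t0, phq_t2):
    """Binary treatment response: >= 50% PHQ-9 improvement from t0 to t2.

    Vectorised; accepts scalars or arrays.  Baseline scores must be
    positive (eligibility guarantees > 10).
    """
    t0 = np.asarray(phq_t0, dtype=float)
    _require_present(t0, "phq_t0")
    _require_present(phq_t2, "phq_t2")
    t2 = np.asarray(phq_t2, dtype=float)
    if np.any(t0 <= 0):
        raise ValidationError("phq_t0 must be positive to define % improvement")
    out = ((t0 - t2) / t0 >= RESPONSE_FRACTION).astype(int)
    return out if out.ndim else int(out)


def remission(phq_t2):
    """Binary remission: t2 PHQ-9 strictly below 5. Vectorised."""
    _require_present(phq_t2, "phq_t2")
    t2 = np.asarray(phq_t2, dtype=float)
    out = (t2 < REMISSION_CUTOFF).astype(int)
    return out if out.ndim else int(out)


def endpoints_from_scores(phq_t0, phq_t2) -> pd.DataFrame:
    """Both endpoints as a two-column frame (``response``, ``remission``)."""
    return pd.DataFrame(
        {"response": response(phq_t0, phq_t2), "remission": remission(phq_t2)}
    )
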
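"""Trial data container: long-format records, one row per participant-assessment.

The whole pipeline consumes a single long table with three rows per
participant (assessments ``t0``, ``t1``, ``t2``), carrying demographics,
PHQ-9 / WHODAS-12 / WHO-5 scores, last-4-week resource-use counts per
unit-cost item, lost workdays, and an ``observed`` flag (0 marks an
assessment lost to dropout; its outcome and cost fields are NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costing import MEDICAL_ITEMS
from .errors import ValidationError

ASSESSMENTS = ("t0", "t1", "t2")
ARMS = ("SbS", "EUC")

ID_COLUMNS = (
    "participant_id",
    "arm",
    "nationality",
    "gender",
    "age",
    "marital",
    "education",
    "employment",
    "wage_stratum",
)
SCORE_COLUMNS = ("phq9", "whodas12", "who5")
DAY_COLUMNS = ("absent_days", "cutback_days")
#: per-assessment fields that dropout wipes out
OUTCOME_COLUMNS = SCORE_COLUMNS + MEDICAL_ITEMS + DAY_COLUMNS
LONG_COLUMNS = ID_COLUMNS + ("assessment",) + OUTCOME_COLUMNS + ("observed",)


@dataclass
class TrialDataset:
    """Long-format trial records plus light validation and reshaping."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"trial table lacks columns: {missing}")
        bad_arm = set(self.df["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise ValidationError(f"unknown arm labels: {sorted(bad_arm)}")
        bad_t = set(self.df["assessment"].unique()) - set(ASSESSMENTS)
        if bad_t:
            raise ValidationError(f"unknown assessments: {sorted(bad_t)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.df["participant_id"].nunique()

    def arm_sizes(self) -> dict[str, int]:
        return (
            self.df.drop_duplicates("participant_id")["arm"]
            .value_counts()
            .to_dict()
        )

    def baseline(self) -> pd.DataFrame:
        """One row per participant: identifiers plus t0 measurements."""
        t0 = self.df[self.df["assessment"] == "t0"]
        return t0.set_index("participant_id")

    # -- reshaping ---------------------------------------------------------
    def wide(self, columns=OUTCOME_COLUMNS) -> pd.DataFrame:
        """Pivot to one row per participant, fields suffixed _t0/_t1/_t2."""
        idcols = list(ID_COLUMNS)
        ids = self.df.drop_duplicates("participant_id")[idcols].set_index(
            "participant_id"
        )
        pieces = [ids]
        for t in ASSESSMENTS:
            sub = (
                self.df[self.df["assessment"] == t]
                .set_index("participant_id")[list(columns) + ["observed"]]
                .add_suffix(f"_{t}")
            )
            pieces.append(sub)
        out = pd.concat(pieces, axis=1)
        out.index.name = "participant_id"
        return out

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        return cls(pd.read_csv(path))

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy())

    def equals(self, other: "TrialDataset") -> bool:
        return self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True)
        )

    def missing_share(self, assessment: str, arm: str | None = None) -> float:
        """Share of participants with the given assessment lost to dropout."""
        sub = self.df[self.df["assessment"] == assessment]
        if arm is not None:
            sub = sub[sub["arm"] == arm]
        return float(1.0 - sub["observed"].mean())
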
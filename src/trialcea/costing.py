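"""Costing: unit prices, period costs, 20-week accumulation, intervention cost.

All prices are in US $ at the 2019 price level (the trial year; the then
official exchange rate of LBP 1507.50 per US $ is carried as metadata
only — inputs are already in dollars).

Resource use is collected retrospectively over the last 4 weeks at each
of the three assessments (t0 baseline, t1 at week 8, t2 at week 20), so
the 20-week horizon spans five 4-week periods: two between t0 and t1 and
three between t1 and t2.  Cumulative cost uses linear interpolation of
the per-period cost between assessments (trapezoid rule), which reduces
to the fixed weights ``c0 + 2.5*c1 + 1.5*c2``.

Two perspectives are supported: *healthcare* (direct medical costs only)
and *societal* (healthcare plus productivity losses from absenteeism and
presenteeism, valued by the human-capital approach at stratum wages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingDataError, ValidationError

PRICE_YEAR = 2019
CURRENCY = "USD"
LBP_PER_USD = 1507.50  # metadata only; no conversion performed

#: linear-interpolation (trapezoid) weights over the five 4-week periods
CUMULATIVE_WEIGHTS = (1.0, 2.5, 1.5)

#: annual program budget components, US $ 2019
PERSONNEL_BUDGET = 59_520.0  # 0.2 FTE supervisor + 1 coordinator + 1 senior e-helper + 2 e-helpers
NONPERSONNEL_BUDGET = 62_800.0  # 36,000 hosting + 14,800 office/overhead + 2,000 advertising
TOTAL_BUDGET = PERSONNEL_BUDGET + NONPERSONNEL_BUDGET
ANNUAL_CAPACITY = 4_700

#: direct-medical resource items counted under the healthcare perspective
MEDICAL_ITEMS = (
    "gp",
    "nurse",
    "social_worker",
    "psychiatrist",
    "neurologist",
    "psychologist",
    "psych_ward_day",
    "mental_hospital_day",
    "ambulance",
    "er_visit",
    "antidepressant_ddd",
    "anxiolytic_ddd",
    "hypnotic_ddd",
)

PERSPECTIVES = ("healthcare", "societal")

#: wage strata for valuing productivity losses (US $ per workday)
WAGE_STRATA = ("syrian", "lebanese", "mixed")

#: employment states that accrue productivity costs, and at which rate
PAID_EMPLOYMENT = "employed"
UNPAID_EMPLOYMENT = "homemaker"

_MIDPOINT_TOL = 0.011  # printed prices carry 2 decimals


@dataclass(frozen=True)
class UnitCostTable:
    """Resource item -> unit price lookup (US $, 2019)."""

    entries: pd.DataFrame  # indexed by item
    currency: str = CURRENCY
    price_year: int = PRICE_YEAR
    lbp_per_usd: float = LBP_PER_USD
    _prices: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_prices", self.entries["mean_usd"].to_dict()
        )

    def price(self, item: str) -> float:
        try:
            return self._prices[item]
        except KeyError:
            raise ValidationError(f"unknown resource item {item!r}") from None

    def wage(self, stratum: str) -> float:
        """Daily wage for a paid-work stratum (Syrian/Lebanese/mixed mean)."""
        row = self.entries.loc["paid_workday"]
        wages = {
            "syrian": row["public_usd"],
            "lebanese": row["private_usd"],
            "mixed": row["mean_usd"],
        }
        if stratum not in wages or pd.isna(wages[stratum]):
            raise ValidationError(f"unknown wage stratum {stratum!r}")
        return float(wages[stratum])

    @property
    def unpaid_workday(self) -> float:
        return self.price("unpaid_workday")


def build_unit_cost_table(raw_entries) -> UnitCostTable:
    """Validate raw price rows and fill missing means as public/private midpoints.

    ``raw_entries`` is a DataFrame (or list of dicts) with columns
    ``item, category, unit, mean_usd, public_usd, private_usd, source``.
    Every item needs a mean or a public/private pair; where all three are
    present the mean must equal the midpoint to printed precision.
    """
    df = pd.DataFrame(raw_entries).copy()
    for col in ("mean_usd", "public_usd", "private_usd"):
        if col not in df:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.set_index("item") if "item" in df.columns else df

    for item, row in df.iterrows():
        mean, pub, priv = row["mean_usd"], row["public_usd"], row["private_usd"]
        has_pair = pd.notna(pub) and pd.notna(priv)
        if pd.isna(mean) and not has_pair:
            raise ValidationError(
                f"item {item!r} has neither a mean price nor a public/private pair"
            )
        if has_pair:
            if pub > priv:
                raise ValidationError(
                    f"item {item!r}: public price {pub} exceeds private price {priv}"
                )
            midpoint = (pub + priv) / 2.0
            if pd.isna(mean):
                df.loc[item, "mean_usd"] = round(midpoint, 2)
            elif abs(mean - midpoint) > _MIDPOINT_TOL:
                raise ValidationError(
                    f"item {item!r}: mean {mean} is not the public/private "
                    f"midpoint {midpoint:.3f}"
                )
        for label, value in (("mean", mean), ("public", pub), ("private", priv)):
            if pd.notna(value) and value < 0:
                raise ValidationError(f"item {item!r}: negative {label} price {value}")
    return UnitCostTable(entries=df)


def default_unit_cost_table() -> UnitCostTable:
    """The 2019 Lebanon price table shipped with the package."""
    with resources.files("trialcea.data").joinpath("unit_costs_2019.csv").open() as fh:
        return build_unit_cost_table(pd.read_csv(fh))


def period_cost(use, table: UnitCostTable, perspective: str):
    """Last-4-week cost of one resource-use record under a perspective.

    ``use`` maps resource items to counts; it may also carry
    ``absent_days``, ``cutback_days``, ``wage_stratum`` and ``employment``
    which are used (only) under the societal perspective.  Linear in counts.
    """
    if perspective not in PERSPECTIVES:
        raise ConfigurationError(
            f"perspective must be one of {PERSPECTIVES}, got {perspective!r}"
        )
    if isinstance(use, pd.Series):
        use = use.to_dict()
    non_items = {"absent_days", "cutback_days", "wage_stratum", "employment"}
    total = 0.0
    for item, count in use.items():
        if item in non_items:
            continue
        if count < 0:
            raise ValidationError(f"negative count {count} for item {item!r}")
        if item not in MEDICAL_ITEMS:
            raise ValidationError(f"unknown resource item {item!r}")
        total += count * table.price(item)
    if perspective == "societal":
        total += productivity_cost(
            use.get("absent_days", 0.0),
            use.get("cutback_days", 0.0),
            use.get("wage_stratum", "mixed"),
            use.get("employment", PAID_EMPLOYMENT),
            table=table,
        )
    return total


def productivity_cost(
    absent_days,
    cutback_days,
    stratum: str = "mixed",
    employment: str = PAID_EMPLOYMENT,
    table: UnitCostTable | None = None,
):
    """Value lost workdays (absenteeism + presenteeism work cutback).

    Human-capital approach: paid workers lose their stratum's daily wage;
    homemakers' lost days are valued at the unpaid-work opportunity cost;
    students, unemployed and retired participants accrue no productivity
    cost.  No friction period is applied.
    """
    if table is None:
        table = default_unit_cost_table()
    if absent_days < 0 or cutback_days < 0:
        raise ValidationError("lost workdays must be non-negative")
    days = absent_days + cutback_days
    if employment == PAID_EMPLOYMENT:
        return days * table.wage(stratum)
    if employment == UNPAID_EMPLOYMENT:
        return days * table.unpaid_workday
    return 0.0


def productivity_cost_vector(
    absent_days, cutback_days, stratum, employment, table: UnitCostTable
) -> np.ndarray:
    """Vectorised :func:`productivity_cost` over aligned arrays."""
    absent = np.asarray(absent_days, dtype=float)
    cutback = np.asarray(cutback_days, dtype=float)
    observed = ~(np.isnan(absent) | np.isnan(cutback))
    if np.any((absent[observed] < 0) | (cutback[observed] < 0)):
        raise ValidationError("lost workdays must be non-negative")
    days = absent + cutback
    stratum_map = {s: table.wage(s) for s in WAGE_STRATA}
    rate = np.array([stratum_map[s] for s in np.asarray(stratum)])
    employment = np.asarray(employment)
    rate = np.where(employment == PAID_EMPLOYMENT, rate, 0.0)
    rate = np.where(employment == UNPAID_EMPLOYMENT, table.unpaid_workday, rate)
    return days * rate


def cumulative_cost(c0, c1, c2):
    """20-week cumulative cost from the three last-4-week period costs.

    Linear interpolation between assessments integrated over the five
    4-week periods: ``(c0+c1)/2 * 2 + (c1+c2)/2 * 3 = c0 + 2.5*c1 + 1.5*c2``.
    Vectorised.
    """
    arrs = [np.asarray(c, dtype=float) for c in (c0, c1, c2)]
    if any(np.isnan(a).any() for a in arrs):
        raise MissingDataError(
            "cumulative cost needs all three period costs; impute missing "
            "cost data first"
        )
    w0, w1, w2 = CUMULATIVE_WEIGHTS
    out = w0 * arrs[0] + w1 * arrs[1] + w2 * arrs[2]
    return out if out.ndim else float(out)


def intervention_cost(
    arm: str,
    program_budget: float = TOTAL_BUDGET,
    annual_capacity: int = ANNUAL_CAPACITY,
) -> float:
    """Per-user intervention cost, added once to SbS-arm cumulative costs.

    The EUC arm's psychoeducational message costs next to nothing and is
    ignored.
    """
    if annual_capacity <= 0:
        raise ConfigurationError("annual_capacity must be positive")
    if arm == "SbS":
        return program_budget / annual_capacity
    return 0.0
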
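"""SDQ responses → serves-per-day profiles.

SDQ items are answered numerically in mixed units.  Per-day answers pass
through unchanged; per-week answers (serves or times) are divided by 7;
"times per week" items rely on the instrument's stated assumption that each
time consumed equates to one serve.  Alcohol items are first re-expressed as
10 g-ethanol standard serves using the schema's drink table, then divided
by 7.  Missing answers follow the same per-group threshold policy as the
FFQ pipeline.
"""

from __future__ import annotations

import logging

from .ffq_pipeline import DailyServesProfile
from .instruments import (
    DrinkDefinition,
    FoodGroup,
    InstrumentSchema,
    RespondentResponse,
)

logger = logging.getLogger("dietscreen")

__all__ = [
    "DrinkDefinition",
    "weekly_to_daily",
    "times_to_serves",
    "standardize_alcohol",
    "sdq_to_profile",
    "sdq_to_profiles",
]


def weekly_to_daily(value_per_week: float) -> float:
    """Divide a weekly quantity by 7 to obtain its daily equivalent."""
    if value_per_week < 0:
        raise ValueError("weekly value must be non-negative")
    return value_per_week / 7.0


def times_to_serves(times: float) -> float:
    """One reported time consumed equates to one serve (identity)."""
    if times < 0:
        raise ValueError("times must be non-negative")
    return times


def standardize_alcohol(reported_drinks_per_week: float, drink: DrinkDefinition) -> float:
    """Re-express reported drinks/week as 10 g-ethanol standard serves/week."""
    if reported_drinks_per_week < 0:
        raise ValueError("reported drinks must be non-negative")
    return reported_drinks_per_week * drink.ethanol_g_per_reported_drink / 10.0


def sdq_to_profile(
    response: RespondentResponse,
    schema: InstrumentSchema,
    missing_threshold: float = 0.2,
) -> DailyServesProfile:
    """Convert one respondent's SDQ answers to a serves/day profile."""
    if schema.kind != "sdq":
        raise ValueError("sdq_to_profile requires an SDQ schema")

    totals: dict[FoodGroup, float] = {}
    n_items: dict[FoodGroup, int] = {}
    n_missing: dict[FoodGroup, int] = {}

    for item in schema.items:
        group = item.food_group
        n_items[group] = n_items.get(group, 0) + 1
        raw = response.answers.get(item.item_id)
        if raw is None:
            n_missing[group] = n_missing.get(group, 0) + 1
            continue
        value = float(raw)
        if value < 0:
            raise ValueError(f"negative answer for {item.item_id!r}")
        if group is FoodGroup.ALCOHOL:
            if item.drink_type not in schema.drinks:
                raise ValueError(f"unknown drink_type {item.drink_type!r}")
            weekly = standardize_alcohol(value, schema.drinks[item.drink_type])
            daily = weekly_to_daily(weekly)
        elif item.unit == "serves_per_day":
            daily = value
        elif item.unit == "serves_per_week":
            daily = weekly_to_daily(value)
        else:  # times_per_week
            daily = weekly_to_daily(times_to_serves(value))
        totals[group] = totals.get(group, 0.0) + daily

    serves: dict[FoodGroup, float] = {}
    for group in schema.groups():
        total = n_items.get(group, 0)
        missing = n_missing.get(group, 0)
        if total > 0 and missing / total >= missing_threshold:
            serves[group] = float("nan")
            logger.warning(
                "respondent %s: group %s marked missing (%d/%d items unanswered)",
                response.respondent_id, group.value, missing, total,
            )
        else:
            serves[group] = totals.get(group, 0.0)
    return DailyServesProfile(
        respondent_id=response.respondent_id,
        serves=serves,
        provenance="sdq",
        age_years=response.age_years,
    )


def sdq_to_profiles(
    responses: list[RespondentResponse],
    schema: InstrumentSchema,
    missing_threshold: float = 0.2,
) -> list[DailyServesProfile]:
    return [sdq_to_profile(r, schema, missing_threshold) for r in responses]
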
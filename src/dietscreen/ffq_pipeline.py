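"""FFQ responses → serves-per-day profiles.

The conversion chain per item is: frequency label → fraction of a day →
grams/day (frequency × portion mass × seasonal factor), accumulated within
each food group and divided by the group's standard serve mass.  Two groups
use a different currency: discretionary foods accumulate energy (kJ/day,
divided by 600 kJ per serve) and alcoholic drinks accumulate ethanol
(g/day, divided by the 10 g standard serve).

Free-text items (cereal/oil "please specify" questions) are resolved against
the composition table before conversion; the matched entry supplies the
portion mass and, for cereals, the GI class that decides whether the grams
count toward the low- or high-GI cereal group.

Missing answers are handled per group: if fewer than ``missing_threshold``
(default 20%) of a group's items are unanswered they contribute zero,
otherwise the whole group is marked missing for that respondent and excluded
pairwise downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .instruments import (
    CompositionEntry,
    FFQItem,
    FoodGroup,
    FrequencyMap,
    InstrumentSchema,
    RespondentResponse,
    lookup_composition,
)

logger = logging.getLogger("dietscreen")

__all__ = [
    "DailyServesProfile",
    "frequency_to_daily",
    "item_daily_grams",
    "group_serves_by_mass",
    "group_serves_by_energy",
    "alcohol_serves",
    "ffq_to_profile",
    "ffq_to_profiles",
    "profiles_to_frame",
    "frame_to_profiles",
]


@dataclass
class DailyServesProfile:
    """A respondent's serves/day per food group — the common currency of
    both instruments.  Missing groups hold NaN."""

    respondent_id: str
    serves: dict[FoodGroup, float]
    provenance: str  # "ffq" or "sdq"
    age_years: Optional[int] = None

    def get(self, group: FoodGroup) -> float:
        return self.serves.get(group, float("nan"))


def frequency_to_daily(label: str, freq_map: FrequencyMap) -> float:
    """Map a categorical frequency label to its fraction of one day."""
    return freq_map.value(label)


def item_daily_grams(daily_freq: float, item: FFQItem) -> float:
    """Grams/day for one item: frequency × portion mass × seasonal factor."""
    if daily_freq < 0:
        raise ValueError("daily frequency must be non-negative")
    return daily_freq * item.serve_mass_g * item.seasonal_factor


def group_serves_by_mass(total_grams_per_day: float, standard_serve_g: float) -> float:
    """Serves/day from total grams/day and the group's standard serve mass
    (e.g. 150 g for fresh fruit)."""
    if standard_serve_g <= 0:
        raise ValueError("standard serve mass must be positive")
    return total_grams_per_day / standard_serve_g


def group_serves_by_energy(total_kj_per_day: float, kj_per_serve: float = 600.0) -> float:
    """Serves/day for variable-portion groups, from energy: 1 serve = 600 kJ."""
    if kj_per_serve <= 0:
        raise ValueError("kJ per serve must be positive")
    return total_kj_per_day / kj_per_serve


def alcohol_serves(total_ethanol_g_per_day: float, g_per_serve: float = 10.0) -> float:
    """Standard serves/day from ethanol grams/day: 1 serve = 10 g ethanol."""
    if total_ethanol_g_per_day < 0:
        raise ValueError("ethanol grams must be non-negative")
    if g_per_serve <= 0:
        raise ValueError("grams per serve must be positive")
    return total_ethanol_g_per_day / g_per_serve


def _resolve_item(
    item: FFQItem,
    response: RespondentResponse,
    composition: Optional[list[CompositionEntry]],
) -> FFQItem:
    """For free-text items, substitute composition-table values when the
    respondent named a product we can match; otherwise keep schema defaults."""
    if not item.free_text:
        return item
    text = response.free_text.get(item.item_id)
    if not text or not composition:
        return item
    entry = lookup_composition(text, composition)
    if entry is None:
        return item
    update: dict = {"serve_mass_g": entry.serve_mass_g}
    if entry.gi_class != "na":
        update["gi_class"] = entry.gi_class
    if item.food_group in (FoodGroup.LOW_GI_CEREALS, FoodGroup.HIGH_GI_CEREALS):
        update["food_group"] = (
            FoodGroup.LOW_GI_CEREALS if entry.gi_class == "low" else FoodGroup.HIGH_GI_CEREALS
        )
    if entry.energy_kj_per_serve > 0:
        update["energy_kj_per_serve"] = entry.energy_kj_per_serve
    return item.model_copy(update=update)


def ffq_to_profile(
    response: RespondentResponse,
    schema: InstrumentSchema,
    composition: Optional[list[CompositionEntry]] = None,
    missing_threshold: float = 0.2,
) -> DailyServesProfile:
    """Convert one respondent's FFQ answers to a serves/day profile."""
    if schema.kind != "ffq":
        raise ValueError("ffq_to_profile requires an FFQ schema")
    fmap = schema.frequency_map

    mass_g: dict[FoodGroup, float] = {}
    energy_kj = 0.0
    ethanol_g = 0.0
    n_items: dict[FoodGroup, int] = {}
    n_missing: dict[FoodGroup, int] = {}

    for item in schema.items:
        declared = item.food_group
        n_items[declared] = n_items.get(declared, 0) + 1
        raw = response.answers.get(item.item_id)
        if raw is None:
            n_missing[declared] = n_missing.get(declared, 0) + 1
            continue
        freq = frequency_to_daily(str(raw), fmap)
        eff = _resolve_item(item, response, composition)
        group = eff.food_group
        if group is FoodGroup.ALCOHOL:
            ethanol_g += freq * eff.ethanol_g_per_serve * eff.seasonal_factor
        elif group is FoodGroup.DISCRETIONARY:
            energy_kj += freq * eff.energy_kj_per_serve * eff.seasonal_factor
        else:
            mass_g[group] = mass_g.get(group, 0.0) + item_daily_grams(freq, eff)

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
            continue
        if group is FoodGroup.ALCOHOL:
            serves[group] = alcohol_serves(ethanol_g, schema.alcohol_g_per_serve)
        elif group is FoodGroup.DISCRETIONARY:
            serves[group] = group_serves_by_energy(energy_kj, schema.discretionary_kj_per_serve)
        else:
            std = schema.group_serve_mass_g.get(group)
            if std is None:
                raise ValueError(f"no standard serve mass configured for {group.value}")
            serves[group] = group_serves_by_mass(mass_g.get(group, 0.0), std)
    return DailyServesProfile(
        respondent_id=response.respondent_id,
        serves=serves,
        provenance="ffq",
        age_years=response.age_years,
    )


def ffq_to_profiles(
    responses: list[RespondentResponse],
    schema: InstrumentSchema,
    composition: Optional[list[CompositionEntry]] = None,
    missing_threshold: float = 0.2,
) -> list[DailyServesProfile]:
    return [ffq_to_profile(r, schema, composition, missing_threshold) for r in responses]


def profiles_to_frame(profiles: list[DailyServesProfile]) -> pd.DataFrame:
    """Profile table: respondent_id, age, provenance, one column per group."""
    groups = [g for g in FoodGroup if any(g in p.serves for p in profiles)]
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "respondent_id": p.respondent_id,
            "age_years": p.age_years,
            "provenance": p.provenance,
        }
        for g in groups:
            row[g.value] = p.serves.get(g, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(frame: pd.DataFrame) -> list[DailyServesProfile]:
    """Inverse of :func:`profiles_to_frame` (round-trips NaN as missing)."""
    group_cols = [c for c in frame.columns if c in {g.value for g in FoodGroup}]
    out = []
    for _, row in frame.iterrows():
        serves = {FoodGroup(c): float(row[c]) for c in group_cols}
        age = row.get("age_years")
        out.append(
            DailyServesProfile(
                respondent_id=str(row["respondent_id"]),
                serves=serves,
                provenance=str(row.get("provenance", "")),
                age_years=None if pd.isna(age) else int(age),
            )
        )
    return out
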
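"""Diet-adequacy scoring: banded component points and 30-point totals.

Each food group's criteria partition [0, inf) into half-open bands
[lower, upper) carrying integer points; a serves value scores the points of
the unique band containing it, so a value exactly on a boundary falls in the
higher band.  Adequacy groups award more points for higher intake, moderation
groups (red meat, processed meat, high-GI cereals, discretionary foods,
alcohol) the reverse.  Missing group serves score 0 and are flagged, and are
excluded from cohort-level "proportion meeting the recommendation" counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .ffq_pipeline import DailyServesProfile
from .instruments import FoodGroup, GroupCriteria, ScoringCriteria

logger = logging.getLogger("dietscreen")

__all__ = [
    "DietScore",
    "score_component",
    "total_score",
    "score_profiles",
    "proportion_meeting",
    "scores_to_frame",
    "frame_to_scores",
]


@dataclass
class DietScore:
    respondent_id: str
    provenance: str
    component_points: dict[FoodGroup, int]
    total: int
    max_total: int
    missing_groups: list[FoodGroup] = field(default_factory=list)


def score_component(serves_per_day: float, criteria: GroupCriteria) -> int:
    """Points of the band containing ``serves_per_day``; NaN scores 0."""
    if serves_per_day is None or math.isnan(serves_per_day):
        return 0
    if serves_per_day < 0:
        raise ValueError("serves must be non-negative")
    for band in criteria.bands:
        if band.lower <= serves_per_day < band.upper:
            return band.points
    raise AssertionError("bands do not cover the value")  # unreachable: bands tile [0, inf)


def total_score(profile: DailyServesProfile, criteria: ScoringCriteria) -> DietScore:
    """Component-wise scoring then integer sum, out of ``criteria.max_total``."""
    component: dict[FoodGroup, int] = {}
    missing: list[FoodGroup] = []
    for group, gc in criteria.groups.items():
        if not isinstance(group, FoodGroup):
            raise ValueError(f"criteria group {group!r} is not a known food group")
        serves = profile.serves.get(group, float("nan"))
        if isinstance(serves, float) and math.isnan(serves):
            missing.append(group)
            logger.warning(
                "respondent %s: group %s missing, scored 0",
                profile.respondent_id, group.value,
            )
        component[group] = score_component(serves, gc)
    return DietScore(
        respondent_id=profile.respondent_id,
        provenance=profile.provenance,
        component_points=component,
        total=sum(component.values()),
        max_total=criteria.max_total,
        missing_groups=missing,
    )


def score_profiles(
    profiles: list[DailyServesProfile], criteria: ScoringCriteria
) -> list[DietScore]:
    return [total_score(p, criteria) for p in profiles]


def proportion_meeting(
    profiles: list[DailyServesProfile], criteria: ScoringCriteria
) -> dict[FoodGroup, float]:
    """Percent of respondents achieving each group's maximum points.

    "Meeting the recommendation" means scoring the group's top band.
    Respondents with a missing group are excluded from that group's
    denominator.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    out: dict[FoodGroup, float] = {}
    for group, gc in criteria.groups.items():
        best = gc.max_points
        n = met = 0
        for p in profiles:
            serves = p.serves.get(group, float("nan"))
            if isinstance(serves, float) and math.isnan(serves):
                continue
            n += 1
            if score_component(serves, gc) == best:
                met += 1
        out[group] = 100.0 * met / n if n else float("nan")
    return out


def scores_to_frame(scores: list[DietScore]) -> pd.DataFrame:
    """Scores CSV layout: respondent_id, provenance, component columns, total."""
    groups = [g for g in FoodGroup if any(g in s.component_points for s in scores)]
    rows = []
    for s in scores:
        row: dict[str, object] = {
            "respondent_id": s.respondent_id,
            "provenance": s.provenance,
        }
        for g in groups:
            row[g.value] = s.component_points.get(g, 0)
        row["total"] = s.total
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_scores(frame: pd.DataFrame, max_total: int = 30) -> list[DietScore]:
    group_cols = [c for c in frame.columns if c in {g.value for g in FoodGroup}]
    out = []
    for _, row in frame.iterrows():
        comp = {FoodGroup(c): int(row[c]) for c in group_cols}
        out.append(
            DietScore(
                respondent_id=str(row["respondent_id"]),
                provenance=str(row.get("provenance", "")),
                component_points=comp,
                total=int(row["total"]),
                max_total=max_total,
            )
        )
    return out
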
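"""Data model and I/O for questionnaire schemas, responses and scoring config.

Two instruments share one in-memory schema type:

* a long food-frequency questionnaire (FFQ) whose items carry a portion mass
  in grams (plus energy for discretionary items and ethanol grams for
  alcoholic drinks) and are answered with categorical frequency labels, and
* a short dietary questionnaire (SDQ) whose items are answered numerically in
  one of three units: serves/day, serves/week, or times/week.

Schemas, scoring criteria, reporting thresholds, the composition lookup table
and the standard-drink table are all YAML (human-editable config); respondent
responses are CSV, one row per respondent.  Missing cells are recorded as
missing, never as zero — the imputation policy lives in the pipelines.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger("dietscreen")

__all__ = [
    "FoodGroup",
    "FrequencyMap",
    "DEFAULT_FREQUENCY_MAP",
    "FFQItem",
    "SDQItem",
    "DrinkDefinition",
    "InstrumentSchema",
    "RespondentResponse",
    "CompositionEntry",
    "Band",
    "GroupCriteria",
    "ScoringCriteria",
    "ReportingThresholds",
    "SchemaValidationError",
    "ResponseParseError",
    "load_instrument_schema",
    "save_instrument_schema",
    "load_scoring_criteria",
    "save_scoring_criteria",
    "load_thresholds",
    "load_composition",
    "read_responses",
    "write_responses",
    "normalize_food_name",
    "lookup_composition",
]


class SchemaValidationError(ValueError):
    """A schema, criteria or thresholds file violated an invariant."""


class ResponseParseError(ValueError):
    """A response cell could not be parsed; message names the row and column."""


class FoodGroup(str, Enum):
    """The food groups reported by both instruments.

    Fifteen of these are scored; white meat is reported (it appears in the
    intake-comparison tables) but carries no points under the default
    scoring criteria.
    """

    TOTAL_VEGETABLES = "total_vegetables"
    DARK_GREEN_LEAFY = "dark_green_leafy_vegetables"
    FRUIT = "fruit"
    WATER = "water"
    RED_MEAT = "red_meat"
    PROCESSED_MEAT = "processed_meat"
    WHITE_MEAT = "white_meat"
    FISH_SEAFOOD = "fish_seafood"
    LEGUMES = "legumes"
    NUTS = "nuts"
    EGGS = "eggs"
    LOW_GI_CEREALS = "low_gi_cereals"
    HIGH_GI_CEREALS = "high_gi_cereals"
    DISCRETIONARY = "discretionary"
    ALCOHOL = "alcohol"
    FATS_OILS = "fats_oils"


class FrequencyMap(BaseModel):
    """Ordered mapping from FFQ frequency labels to fractions of one day.

    The first option must map to 0 and values must be non-decreasing in
    option order, so that choosing a later option can never reduce intake.
    """

    options: list[tuple[str, float]]

    @field_validator("options")
    @classmethod
    def _check(cls, v: list[tuple[str, float]]) -> list[tuple[str, float]]:
        if not v:
            raise ValueError("frequency map must have at least one option")
        labels = [lab for lab, _ in v]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate frequency labels")
        values = [val for _, val in v]
        if values[0] != 0:
            raise ValueError("first frequency option must map to 0")
        if any(val < 0 for val in values):
            raise ValueError("frequency values must be non-negative")
        if any(b < a for a, b in zip(values, values[1:])):
            raise ValueError("frequency values must be non-decreasing")
        return v

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.options]

    @property
    def values(self) -> list[float]:
        return [val for _, val in self.options]

    def value(self, label: str) -> float:
        for lab, val in self.options:
            if lab == label:
                return val
        raise KeyError(f"unknown frequency label: {label!r}")

    def nearest_label(self, daily_freq: float) -> str:
        """Label whose value is closest to ``daily_freq``; ties go to the
        earlier (lower) option."""
        if daily_freq < 0:
            raise ValueError("daily frequency must be non-negative")
        best_i = min(
            range(len(self.options)),
            key=lambda i: (abs(self.options[i][1] - daily_freq), i),
        )
        return self.options[best_i][0]


#: Daily-fraction equivalents of the nine FFQ frequency options.
DEFAULT_FREQUENCY_MAP = FrequencyMap(
    options=[
        ("Never", 0.0),
        ("Less than 1 per month", 0.02),
        ("1–3 per month", 0.07),
        ("1 per week", 0.14),
        ("2–4 per week", 0.43),
        ("5–6 per week", 0.79),
        ("1 per day", 1.0),
        ("2–3 per day", 2.5),
        ("4+ per day", 4.0),
    ]
)


class FFQItem(BaseModel):
    """One FFQ line item: a food with a predefined portion size.

    ``energy_kj_per_serve`` feeds the energy-based serve conversion used for
    discretionary foods; ``ethanol_g_per_serve`` feeds the standard-drink
    conversion for alcoholic drinks.  ``seasonal_factor`` is a multiplicative
    availability adjustment (default 1.0, i.e. no adjustment).  Items marked
    ``free_text`` expect a companion free-response naming the actual product
    (cereal or oil brand), resolved against the composition table.
    """

    item_id: str
    food_group: FoodGroup
    serve_mass_g: float = Field(gt=0)
    energy_kj_per_serve: float = Field(default=0.0, ge=0)
    ethanol_g_per_serve: float = Field(default=0.0, ge=0)
    gi_class: Literal["low", "high", "na"] = "na"
    seasonal_factor: float = Field(default=1.0, gt=0)
    free_text: bool = False

    @model_validator(mode="after")
    def _group_requirements(self) -> "FFQItem":
        if self.food_group is FoodGroup.DISCRETIONARY and self.energy_kj_per_serve <= 0:
            raise ValueError(
                f"discretionary item {self.item_id!r} requires energy_kj_per_serve > 0"
            )
        if self.food_group is FoodGroup.ALCOHOL and self.ethanol_g_per_serve <= 0:
            raise ValueError(
                f"alcohol item {self.item_id!r} requires ethanol_g_per_serve > 0"
            )
        return self


class DrinkDefinition(BaseModel):
    """Ethanol content of one reported drink of a given type, in grams."""

    ethanol_g_per_reported_drink: float = Field(gt=0)


class SDQItem(BaseModel):
    """One SDQ line item with its reporting unit.

    ``times_per_week`` items are interpreted under the stated assumption that
    each time consumed equates to one serve.  Alcohol items carry a
    ``drink_type`` key into the schema's drink table so reported drinks can be
    re-expressed as 10 g-ethanol standard serves.
    """

    item_id: str
    food_group: FoodGroup
    unit: Literal["serves_per_day", "serves_per_week", "times_per_week"]
    drink_type: Optional[str] = None

    @model_validator(mode="after")
    def _alcohol_needs_drink(self) -> "SDQItem":
        if self.food_group is FoodGroup.ALCOHOL and not self.drink_type:
            raise ValueError(f"alcohol item {self.item_id!r} requires a drink_type")
        return self


class InstrumentSchema(BaseModel):
    """Item definitions and unit semantics for one questionnaire.

    FFQ schemas additionally carry the frequency map, the per-group standard
    serve masses used for gram→serve conversion, and the energy/ethanol serve
    constants.  SDQ schemas carry the standard-drink table.
    """

    model_config = ConfigDict(validate_assignment=True)

    kind: Literal["ffq", "sdq"]
    name: str = ""
    items: Union[list[FFQItem], list[SDQItem]]
    frequency_map: FrequencyMap = DEFAULT_FREQUENCY_MAP
    #: grams per standard serve, per mass-converted food group
    group_serve_mass_g: dict[FoodGroup, float] = Field(default_factory=dict)
    discretionary_kj_per_serve: float = Field(default=600.0, gt=0)
    alcohol_g_per_serve: float = Field(default=10.0, gt=0)
    drinks: dict[str, DrinkDefinition] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "InstrumentSchema":
        want = FFQItem if self.kind == "ffq" else SDQItem
        for it in self.items:
            if not isinstance(it, want):
                raise ValueError(
                    f"{self.kind} schema contains a {type(it).__name__} "
                    f"({getattr(it, 'item_id', '?')!r})"
                )
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise ValueError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)
        if any(m <= 0 for m in self.group_serve_mass_g.values()):
            raise ValueError("group standard serve masses must be positive")
        if self.kind == "sdq":
            for it in self.items:
                if it.drink_type is not None and it.drink_type not in self.drinks:
                    raise ValueError(
                        f"item {it.item_id!r} references unknown drink_type "
                        f"{it.drink_type!r}"
                    )
        return self

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str):
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def items_by_group(self) -> dict[FoodGroup, list]:
        out: dict[FoodGroup, list] = {}
        for it in self.items:
            out.setdefault(it.food_group, []).append(it)
        return out

    def groups(self) -> list[FoodGroup]:
        """Groups with at least one item, in enumeration order."""
        present = {it.food_group for it in self.items}
        return [g for g in FoodGroup if g in present]


class RespondentResponse(BaseModel):
    """One respondent's raw answers against a single instrument.

    ``answers`` maps item_id to the raw response: a frequency label (str) for
    FFQ items, a non-negative number for SDQ items.  Unanswered items are
    simply absent.  ``free_text`` carries companion free-response strings
    (e.g. the named cereal brand) keyed by item_id.
    """

    respondent_id: str
    age_years: int = Field(ge=0)
    answers: dict[str, Union[str, float]] = Field(default_factory=dict)
    free_text: dict[str, str] = Field(default_factory=dict)


class CompositionEntry(BaseModel):
    """One row of the mini food-composition lookup for free-text items."""

    name: str
    food_group: FoodGroup
    serve_mass_g: float = Field(gt=0)
    energy_kj_per_serve: float = Field(default=0.0, ge=0)
    gi_class: Literal["low", "high", "na"] = "na"


class Band(BaseModel):
    """Half-open serves interval [lower, upper) awarding a fixed point value."""

    lower: float = Field(ge=0)
    upper: float
    points: int = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "Band":
        if not self.upper > self.lower:
            raise ValueError(f"band upper ({self.upper}) must exceed lower ({self.lower})")
        return self


class GroupCriteria(BaseModel):
    """Banded criteria for one food group.

    Adequacy groups (more is better) must have non-decreasing points across
    bands; moderation groups (less is better) non-increasing.  Bands must
    partition [0, inf) with no gaps or overlaps; the last band is unbounded.
    """

    direction: Literal["adequacy", "moderation"]
    bands: list[Band]

    @field_validator("bands")
    @classmethod
    def _partition(cls, v: list[Band]) -> list[Band]:
        if not v:
            raise ValueError("at least one band required")
        if v[0].lower != 0:
            raise ValueError("first band must start at 0")
        for a, b in zip(v, v[1:]):
            if b.lower != a.upper:
                raise ValueError(
                    f"bands must tile [0, inf): gap/overlap at {a.upper} vs {b.lower}"
                )
        if not math.isinf(v[-1].upper):
            raise ValueError("last band must extend to infinity")
        return v

    @model_validator(mode="after")
    def _monotone(self) -> "GroupCriteria":
        pts = [b.points for b in self.bands]
        if self.direction == "adequacy":
            if any(b < a for a, b in zip(pts, pts[1:])):
                raise ValueError("adequacy points must be non-decreasing with serves")
        else:
            if any(b > a for a, b in zip(pts, pts[1:])):
                raise ValueError("moderation points must be non-increasing with serves")
        return self

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bands)


class ScoringCriteria(BaseModel):
    """Per-group banded cut points; group maxima must sum to ``max_total``."""

    groups: dict[FoodGroup, GroupCriteria]
    max_total: int = 30

    @model_validator(mode="after")
    def _total(self) -> "ScoringCriteria":
        s = sum(gc.max_points for gc in self.groups.values())
        if s != self.max_total:
            raise ValueError(
                f"sum of group maxima ({s}) must equal max_total ({self.max_total})"
            )
        return self


class ReportingThresholds(BaseModel):
    """Analysis conventions: negligible-correlation cut, alpha, age split,
    and the limits-of-agreement SD multiplier (2, not 1.96)."""

    negligible_r: float = Field(default=0.30, gt=0, lt=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    age_cut_years: int = 80
    loa_sd_multiplier: float = Field(default=2.0, gt=0)


# ---------------------------------------------------------------------------
# YAML I/O


def _load_yaml(path: Path | str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaValidationError(f"{path}: expected a mapping at top level")
    return data


def load_instrument_schema(path: Path | str, kind: Literal["ffq", "sdq"]) -> InstrumentSchema:
    """Load and validate a questionnaire schema from YAML.

    Items are validated one at a time so that an invalid field names the
    offending item in the error message.
    """
    data = _load_yaml(path)
    if data.get("kind", kind) != kind:
        raise SchemaValidationError(
            f"{path}: schema kind {data.get('kind')!r} does not match requested {kind!r}"
        )
    raw_items = data.pop("items", [])
    cls = FFQItem if kind == "ffq" else SDQItem
    items = []
    for raw in raw_items:
        try:
            items.append(cls.model_validate(raw))
        except Exception as exc:
            raise SchemaValidationError(
                f"invalid item {raw.get('item_id', '?')!r}: {exc}"
            ) from exc
    data["kind"] = kind
    data["items"] = items
    try:
        return InstrumentSchema.model_validate(data)
    except Exception as exc:
        raise SchemaValidationError(str(exc)) from exc


def save_instrument_schema(schema: InstrumentSchema, path: Path | str) -> None:
    payload = schema.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def load_scoring_criteria(path: Path | str) -> ScoringCriteria:
    data = _load_yaml(path)
    try:
        return ScoringCriteria.model_validate(data)
    except Exception as exc:
        raise SchemaValidationError(str(exc)) from exc


def save_scoring_criteria(criteria: ScoringCriteria, path: Path | str) -> None:
    payload = criteria.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def load_thresholds(path: Path | str) -> ReportingThresholds:
    try:
        return ReportingThresholds.model_validate(_load_yaml(path))
    except Exception as exc:
        raise SchemaValidationError(str(exc)) from exc


def load_composition(path: Path | str) -> list[CompositionEntry]:
    data = _load_yaml(path)
    try:
        return [CompositionEntry.model_validate(e) for e in data["entries"]]
    except Exception as exc:
        raise SchemaValidationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Responses CSV

_TEXT_SUFFIX = "__text"


def read_responses(path: Path | str, schema: InstrumentSchema) -> list[RespondentResponse]:
    """Parse a responses CSV against a schema.

    Expected columns: ``respondent_id``, ``age_years``, one column per
    answered item (FFQ cells are frequency labels, SDQ cells non-negative
    numbers), and optional ``<item_id>__text`` columns for free-response
    companions.  Empty cells are missing answers.  Every malformed cell
    raises a :class:`ResponseParseError` naming its row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if "respondent_id" not in df.columns or "age_years" not in df.columns:
        raise ResponseParseError(f"{path}: need respondent_id and age_years columns")
    known = set(schema.item_ids)
    item_cols, text_cols = [], []
    for col in df.columns:
        if col in ("respondent_id", "age_years"):
            continue
        if col.endswith(_TEXT_SUFFIX):
            base = col[: -len(_TEXT_SUFFIX)]
            if base not in known:
                raise ResponseParseError(f"unknown free-text column {col!r}")
            text_cols.append(col)
        elif col in known:
            item_cols.append(col)
        else:
            raise ResponseParseError(f"unknown item column {col!r}")

    labels = set(schema.frequency_map.labels)
    out: list[RespondentResponse] = []
    for i, row in df.iterrows():
        rid = row["respondent_id"]
        if pd.isna(rid) or str(rid).strip() == "":
            raise ResponseParseError(f"row {i}: missing respondent_id")
        try:
            age = int(float(row["age_years"]))
        except (TypeError, ValueError) as exc:
            raise ResponseParseError(
                f"row {i} column age_years: {row['age_years']!r} is not an integer"
            ) from exc
        answers: dict[str, Union[str, float]] = {}
        for col in item_cols:
            cell = row[col]
            if pd.isna(cell) or str(cell).strip() == "":
                continue  # missing, not zero
            cell = str(cell).strip()
            if schema.kind == "ffq":
                if cell not in labels:
                    raise ResponseParseError(
                        f"row {i} column {col!r}: label {cell!r} not in frequency map"
                    )
                answers[col] = cell
            else:
                try:
                    val = float(cell)
                except ValueError as exc:
                    raise ResponseParseError(
                        f"row {i} column {col!r}: {cell!r} is not a number"
                    ) from exc
                if val < 0:
                    raise ResponseParseError(
                        f"row {i} column {col!r}: negative value {val}"
                    )
                answers[col] = val
        free_text = {}
        for col in text_cols:
            cell = row[col]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            free_text[col[: -len(_TEXT_SUFFIX)]] = str(cell).strip()
        out.append(
            RespondentResponse(
                respondent_id=str(rid), age_years=age, answers=answers, free_text=free_text
            )
        )
    return out


def write_responses(
    responses: list[RespondentResponse], schema: InstrumentSchema, path: Path | str
) -> None:
    """Write responses in the CSV dialect :func:`read_responses` consumes."""
    cols = ["respondent_id", "age_years"] + schema.item_ids
    text_items = (
        [it.item_id for it in schema.items if getattr(it, "free_text", False)]
        if schema.kind == "ffq"
        else []
    )
    cols += [f"{i}{_TEXT_SUFFIX}" for i in text_items]
    rows = []
    for r in responses:
        row: dict[str, object] = {"respondent_id": r.respondent_id, "age_years": r.age_years}
        for iid in schema.item_ids:
            if iid in r.answers:
                row[iid] = r.answers[iid]
        for iid in text_items:
            if iid in r.free_text:
                row[f"{iid}{_TEXT_SUFFIX}"] = r.free_text[iid]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Composition lookup


def normalize_food_name(name: str) -> str:
    """Trim, case-fold and collapse internal whitespace."""
    return " ".join(name.strip().casefold().split())


def lookup_composition(
    free_text: str, table: list[CompositionEntry]
) -> Optional[CompositionEntry]:
    """Match a free-response food name against the composition table.

    Matching is exact after :func:`normalize_food_name` on both sides.
    Unmatched inputs return ``None`` and are logged as a warning — never
    silently dropped.
    """
    if not table:
        raise ValueError("composition table is empty")
    key = normalize_food_name(free_text)
    for entry in table:
        if normalize_food_name(entry.name) == key:
            return entry
    logger.warning("composition lookup: no match for %r", free_text)
    return None
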
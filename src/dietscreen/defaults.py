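"""Accessors for the bundled default configuration.

The bundled questionnaire schemas are synthetic but structurally faithful:
145 FFQ items and 36 SDQ items distributed over the sixteen food groups, a
~20-entry composition lookup for free-text cereal/oil responses, a default
30-point scoring-criteria table, and the reporting thresholds.  All of them
are plain YAML under ``dietscreen/data`` and fully replaceable by user files.
"""

from __future__ import annotations

from importlib.resources import as_file, files

from .instruments import (
    CompositionEntry,
    InstrumentSchema,
    ReportingThresholds,
    ScoringCriteria,
    load_composition,
    load_instrument_schema,
    load_scoring_criteria,
    load_thresholds,
)

_DATA = files("dietscreen") / "data"


def _path(name: str):
    return as_file(_DATA / name)


def default_ffq_schema() -> InstrumentSchema:
    with _path("ffq_schema.yaml") as p:
        return load_instrument_schema(p, "ffq")


def default_sdq_schema() -> InstrumentSchema:
    with _path("sdq_schema.yaml") as p:
        return load_instrument_schema(p, "sdq")


def default_composition() -> list[CompositionEntry]:
    with _path("composition.yaml") as p:
        return load_composition(p)


def default_criteria() -> ScoringCriteria:
    with _path("criteria_default.yaml") as p:
        return load_scoring_criteria(p)


def default_thresholds() -> ReportingThresholds:
    with _path("thresholds.yaml") as p:
        return load_thresholds(p)
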
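"""Domain types, validation and delimited-text I/O for satiety-interoception cohorts.

A cohort is one row per participant of a single-visit drink paradigm:
a trait questionnaire (the 7-item difficulty-identifying-feelings, DIF,
subscale scored 1-5 per item), anthropometrics, expected-satiety and
confidence visual-analogue ratings made before and after tasting the
drink, a fullness rating 15 min into the session, and hunger plus blood
glucose sampled on the fixed grid {0, 15, 30, 60} minutes.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger("interosat")

TIME_GRID = (0.0, 15.0, 30.0, 60.0)
"""Minutes at which hunger and blood glucose are sampled."""

DIF_MIN, DIF_MAX = 7, 35


class Condition(str, enum.Enum):
    """Drink arm: caloric (flavour-nutrient congruent) vs non-caloric."""

    GLUCOSE = "GLUCOSE"
    SUCRALOSE = "SUCRALOSE"


class ICVariant(str, enum.Enum):
    SIGNED = "SIGNED"
    ABSOLUTE = "ABSOLUTE"


class SDTransform(str, enum.Enum):
    NONE = "NONE"
    ARCSINE = "ARCSINE"


class CooksMode(str, enum.Enum):
    """Influence threshold for the outlier policy.

    CONVENTIONAL_4_OVER_N flags Cook's D > 4/n (the standard rule);
    PAPER_0_2 flags D > 0.2, replicating a fixed-cutoff reading.
    """

    CONVENTIONAL_4_OVER_N = "CONVENTIONAL_4_OVER_N"
    PAPER_0_2 = "PAPER_0_2"


class CohortValidationError(ValueError):
    """Raised when one or more cohort rows violate a stated invariant."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(self.diagnostics))


class SchemaError(ValueError):
    """Raised when a required column is absent from a cohort file."""


def score_dif(items: Sequence[int]) -> int:
    """Sum the 7 DIF items (each 1-5) to the 7-35 trait score.

    Higher scores indicate more difficulty identifying feelings.
    """
    items = list(items)
    if len(items) != 7:
        raise ValueError(f"DIF requires exactly 7 items, got {len(items)}")
    for i, v in enumerate(items):
        if int(v) != v or not (1 <= int(v) <= 5):
            raise ValueError(f"DIF item {i + 1} must be an integer in 1..5, got {v!r}")
    return int(sum(int(v) for v in items))


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if not weight_kg > 0:
        raise ValueError(f"weight_kg must be > 0, got {weight_kg}")
    if not height_m > 0:
        raise ValueError(f"height_m must be > 0, got {height_m}")
    return weight_kg / height_m**2


def _check_vas(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"{name}={value} outside VAS range [0, 100]")


class ParticipantRecord(BaseModel):
    """One participant of the paradigm.

    VAS fields are millimetres on a 0-100 line; glucose is mmol/L.
    ``hunger_t`` and ``glucose_t`` are the four samples on ``TIME_GRID``.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    condition: Condition
    dif_score: int = Field(ge=DIF_MIN, le=DIF_MAX)
    dif_items: Optional[tuple[int, int, int, int, int, int, int]] = None
    height_m: Optional[float] = None
    weight_kg: Optional[float] = None
    bmi: float = Field(gt=0)
    exp_satiety_bt: float
    exp_satiety_at: float
    esc_bt: float
    esc_at: float
    fullness_15: float
    hunger_t: tuple[float, float, float, float]
    glucose_t: tuple[float, float, float, float]
    sweetness: Optional[float] = None
    liking: Optional[float] = None

    @model_validator(mode="after")
    def _invariants(self) -> "ParticipantRecord":
        for name in ("exp_satiety_bt", "exp_satiety_at", "esc_bt", "esc_at", "fullness_15"):
            _check_vas(name, getattr(self, name))
        for i, h in enumerate(self.hunger_t):
            _check_vas(f"hunger_t[{i}]", h)
        for i, g in enumerate(self.glucose_t):
            if not g > 0:
                raise ValueError(f"glucose_t[{i}]={g} must be > 0 mmol/L")
        for name in ("sweetness", "liking"):
            v = getattr(self, name)
            if v is not None:
                _check_vas(name, v)
        if self.dif_items is not None and score_dif(self.dif_items) != self.dif_score:
            raise ValueError(
                f"dif_score={self.dif_score} does not equal sum of dif_items"
            )
        if self.height_m is not None and self.weight_kg is not None:
            expected = compute_bmi(self.weight_kg, self.height_m)
            if abs(expected - self.bmi) > 1e-9:
                raise ValueError(
                    f"bmi={self.bmi} inconsistent with weight/height ({expected})"
                )
        return self


class CohortTable(BaseModel):
    """Ordered collection of participant records with provenance metadata."""

    model_config = ConfigDict(frozen=True)

    records: tuple[ParticipantRecord, ...]
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "CohortTable":
        if not self.records:
            raise ValueError("cohort must be non-empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique")
        return self

    def __len__(self) -> int:
        return len(self.records)

    def condition_mask(self, condition: Condition) -> np.ndarray:
        return np.array([r.condition == condition for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_record_to_row(r) for r in self.records])


class AnalysisConfig(BaseModel):
    """Pipeline options: FDR level, index variants, outlier policy, time grid."""

    model_config = ConfigDict(frozen=True)

    fdr_level: float = 0.05
    ic_variant: ICVariant = ICVariant.SIGNED
    sd_transform: SDTransform = SDTransform.ARCSINE
    cooks_threshold_mode: CooksMode = CooksMode.CONVENTIONAL_4_OVER_N
    time_grid: tuple[float, ...] = TIME_GRID
    rng_seed: int = 0

    @model_validator(mode="after")
    def _invariants(self) -> "AnalysisConfig":
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError(f"fdr_level must be in (0, 1), got {self.fdr_level}")
        return self


# ---------------------------------------------------------------------------
# Delimited-text I/O (comma-separated, header row, UTF-8, '.' decimal)
# ---------------------------------------------------------------------------

_SCALAR_COLUMNS = [
    "id",
    "condition",
    "dif_score",
    "height_m",
    "weight_kg",
    "bmi",
    "exp_satiety_bt",
    "exp_satiety_at",
    "esc_bt",
    "esc_at",
    "fullness_15",
    "sweetness",
    "liking",
]
_HUNGER_COLUMNS = [f"hunger_{int(t)}" for t in TIME_GRID]
_GLUCOSE_COLUMNS = [f"glucose_{int(t)}" for t in TIME_GRID]
_DIF_ITEM_COLUMNS = [f"dif_item_{i}" for i in range(1, 8)]

COHORT_COLUMNS = _SCALAR_COLUMNS + _HUNGER_COLUMNS + _GLUCOSE_COLUMNS
"""Canonical cohort CSV column order (DIF items optional, appended if present)."""

_REQUIRED_COLUMNS = [
    c for c in COHORT_COLUMNS
    if c not in ("height_m", "weight_kg", "sweetness", "liking")
]


def _record_to_row(r: ParticipantRecord) -> dict:
    row = {
        "id": r.id,
        "condition": r.condition.value,
        "dif_score": r.dif_score,
        "height_m": r.height_m,
        "weight_kg": r.weight_kg,
        "bmi": r.bmi,
        "exp_satiety_bt": r.exp_satiety_bt,
        "exp_satiety_at": r.exp_satiety_at,
        "esc_bt": r.esc_bt,
        "esc_at": r.esc_at,
        "fullness_15": r.fullness_15,
        "sweetness": r.sweetness,
        "liking": r.liking,
    }
    for col, v in zip(_HUNGER_COLUMNS, r.hunger_t):
        row[col] = v
    for col, v in zip(_GLUCOSE_COLUMNS, r.glucose_t):
        row[col] = v
    if r.dif_items is not None:
        for col, v in zip(_DIF_ITEM_COLUMNS, r.dif_items):
            row[col] = v
    return row


def _opt(row: pd.Series, col: str):
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def _row_to_record(row: pd.Series) -> ParticipantRecord:
    dif_items = None
    if all(c in row.index for c in _DIF_ITEM_COLUMNS):
        vals = [_opt(row, c) for c in _DIF_ITEM_COLUMNS]
        if all(v is not None for v in vals):
            dif_items = tuple(int(v) for v in vals)
    height = _opt(row, "height_m")
    weight = _opt(row, "weight_kg")
    sweetness = _opt(row, "sweetness")
    liking = _opt(row, "liking")
    return ParticipantRecord(
        id=str(row["id"]),
        condition=Condition(str(row["condition"])),
        dif_score=int(row["dif_score"]),
        dif_items=dif_items,
        height_m=None if height is None else float(height),
        weight_kg=None if weight is None else float(weight),
        bmi=float(row["bmi"]),
        exp_satiety_bt=float(row["exp_satiety_bt"]),
        exp_satiety_at=float(row["exp_satiety_at"]),
        esc_bt=float(row["esc_bt"]),
        esc_at=float(row["esc_at"]),
        fullness_15=float(row["fullness_15"]),
        hunger_t=tuple(float(row[c]) for c in _HUNGER_COLUMNS),
        glucose_t=tuple(float(row[c]) for c in _GLUCOSE_COLUMNS),
        sweetness=None if sweetness is None else float(sweetness),
        liking=None if liking is None else float(liking),
    )


def read_cohort(path, schema: Optional[dict] = None) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV file with a header row, one participant per row.
    schema
        Optional map from canonical column names (``COHORT_COLUMNS``) to the
        column names used in the file.

    Raises
    ------
    SchemaError
        If a required column is absent.
    CohortValidationError
        If any row violates a record invariant; the message names every
        offending row and field.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records, problems = [], []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(_row_to_record(row))
        except (ValueError, KeyError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise CohortValidationError(problems)
    return CohortTable(records=tuple(records), metadata={"source": str(path)})


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as canonical CSV (round-trips through :func:`read_cohort`)."""
    df = cohort.to_dataframe()
    cols = [c for c in COHORT_COLUMNS + _DIF_ITEM_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)
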
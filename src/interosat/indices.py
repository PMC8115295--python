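"""Per-participant interoceptive indices.

Each index quantifies one facet of precision-weighted satiety inference:

- satiety divergence (SD): 1 - |E - A| / (E + A), the normalised agreement
  between expected satiety E and actual (post-prandial) satiety A.  High SD
  means the post-prandial state matched the expectation, i.e. the report is
  expectation-driven.  Computed before tasting (SD-BT, visual expectation
  only) and after tasting (SD-AT, visual + gustatory expectation).
- interoceptive coherence (IC): the sign-reversed within-person Pearson
  correlation between the blood-glucose and hunger trajectories, so that
  +1 means hunger falls exactly as glucose rises.  An absolute variant
  |r| treats strong positive and strong negative coupling alike.
- expected-satiety confidence (ESC) update: confidence after minus before
  tasting, a readout of how gustatory evidence changed prior precision.
- rebound-hunger AUCi: baseline-anchored incremental trapezoidal area of
  hunger over 0-60 min; positive under post-prandial rebound, negative
  under suppression.
- glucose delta: G(60) - G(0), a coarse glucose-tolerance readout.

Undefined values (0/0 divergence, zero-variance correlation) propagate as
NaN with a logged warning, never as silent zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AnalysisConfig,
    CohortTable,
    ICVariant,
    ParticipantRecord,
    SDTransform,
)

logger = logging.getLogger("interosat")

_EPS = 1e-9


def satiety_divergence(expected: float, actual: float) -> float:
    """1 - |E - A| / (E + A) for VAS ratings in [0, 100].

    Symmetric and scale-invariant; 1 iff E == A; NaN (with a warning)
    for the degenerate 0/0 case.
    """
    for name, v in (("expected", expected), ("actual", actual)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name}={v} outside VAS range [0, 100]")
    if expected == 0.0 and actual == 0.0:
        logger.warning("satiety_divergence undefined for E = A = 0; returning NaN")
        return math.nan
    return 1.0 - abs(expected - actual) / (expected + actual)


def arcsine_transform(x: float) -> float:
    """arcsin(x) in radians for x in [0, 1] (tolerance 1e-9, then clipped)."""
    if not (-_EPS <= x <= 1.0 + _EPS):
        raise ValueError(f"arcsine_transform requires x in [0, 1], got {x}")
    return math.asin(min(max(x, 0.0), 1.0))


def interoceptive_coherence(
    glucose: Sequence[float],
    hunger: Sequence[float],
    variant: ICVariant = ICVariant.SIGNED,
) -> float:
    """Within-person glucose-hunger coupling over the 4-point trajectory.

    SIGNED returns -pearson(glucose, hunger); ABSOLUTE returns |pearson|.
    Zero variance in either series yields NaN with a warning.
    """
    g = np.asarray(glucose, dtype=float)
    h = np.asarray(hunger, dtype=float)
    if g.shape != (4,) or h.shape != (4,):
        raise ValueError("glucose and hunger must each have exactly 4 values")
    if np.ptp(g) == 0.0 or np.ptp(h) == 0.0:
        logger.warning("interoceptive_coherence undefined for zero-variance series")
        return math.nan
    gc, hc = g - g.mean(), h - h.mean()
    r = float(np.dot(gc, hc) / math.sqrt(np.dot(gc, gc) * np.dot(hc, hc)))
    r = min(max(r, -1.0), 1.0)
    return abs(r) if variant == ICVariant.ABSOLUTE else -r


def rebound_hunger_auci(
    hunger: Sequence[float], grid: Sequence[float] = (0.0, 15.0, 30.0, 60.0)
) -> float:
    """Baseline-anchored incremental area (mm*min) of hunger over the grid.

    Trapezoidal area of H(t) - H(0); negative when hunger stays suppressed
    below baseline, positive under rebound.
    """
    h = np.asarray(hunger, dtype=float)
    t = np.asarray(grid, dtype=float)
    if h.shape != t.shape or h.ndim != 1 or h.size != 4:
        raise ValueError("hunger must have exactly 4 values on the 4-point grid")
    return float(np.trapezoid(h - h[0], t))


def glucose_delta(glucose: Sequence[float]) -> float:
    """G(60) - G(0) in mmol/L over the 4-point trajectory."""
    g = np.asarray(glucose, dtype=float)
    if g.shape != (4,):
        raise ValueError("glucose must have exactly 4 values")
    return float(g[3] - g[0])


@dataclass(frozen=True)
class InteroceptiveIndices:
    """Derived per-participant statistics (NaN marks an undefined index)."""

    sd_bt: float
    sd_at: float
    sd_bt_x: Optional[float]
    sd_at_x: Optional[float]
    ic: float
    ic_abs: float
    esc_update: float
    exp_satiety_update: float
    auci_hunger: float
    glucose_delta_60: float


def compute_indices(
    record: ParticipantRecord, config: AnalysisConfig | None = None
) -> InteroceptiveIndices:
    """All indices for one participant; see module docstring for definitions."""
    config = config or AnalysisConfig()
    sd_bt = satiety_divergence(record.exp_satiety_bt, record.fullness_15)
    sd_at = satiety_divergence(record.exp_satiety_at, record.fullness_15)
    if config.sd_transform == SDTransform.ARCSINE:
        sd_bt_x = arcsine_transform(sd_bt) if not math.isnan(sd_bt) else math.nan
        sd_at_x = arcsine_transform(sd_at) if not math.isnan(sd_at) else math.nan
    else:
        sd_bt_x = sd_at_x = None
    return InteroceptiveIndices(
        sd_bt=sd_bt,
        sd_at=sd_at,
        sd_bt_x=sd_bt_x,
        sd_at_x=sd_at_x,
        ic=interoceptive_coherence(record.glucose_t, record.hunger_t, ICVariant.SIGNED),
        ic_abs=interoceptive_coherence(
            record.glucose_t, record.hunger_t, ICVariant.ABSOLUTE
        ),
        esc_update=record.esc_at - record.esc_bt,
        exp_satiety_update=record.exp_satiety_at - record.exp_satiety_bt,
        auci_hunger=rebound_hunger_auci(record.hunger_t, config.time_grid),
        glucose_delta_60=glucose_delta(record.glucose_t),
    )


INDEX_COLUMNS = [
    "sd_bt",
    "sd_at",
    "sd_bt_x",
    "sd_at_x",
    "ic",
    "ic_abs",
    "esc_update",
    "exp_satiety_update",
    "auci_hunger",
    "glucose_delta_60",
]


def indices_table(cohort: CohortTable, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Indices for every participant, keyed by id, with condition and traits.

    Columns: id, condition, dif, bmi, esc_bt, esc_at, the raw before/after
    ratings, and one column per index (``INDEX_COLUMNS``).
    """
    config = config or AnalysisConfig()
    rows = []
    for r in cohort.records:
        ix = compute_indices(r, config)
        row = {
            "id": r.id,
            "condition": r.condition.value,
            "dif": r.dif_score,
            "bmi": r.bmi,
            "esc_bt": r.esc_bt,
            "esc_at": r.esc_at,
            "exp_satiety_bt": r.exp_satiety_bt,
            "exp_satiety_at": r.exp_satiety_at,
            "sweetness": r.sweetness if r.sweetness is not None else math.nan,
            "liking": r.liking if r.liking is not None else math.nan,
        }
        for c in INDEX_COLUMNS:
            v = getattr(ix, c)
            row[c] = math.nan if v is None else v
        for t, h in zip(config.time_grid, r.hunger_t):
            row[f"hunger_{int(t)}"] = h
        for t, g in zip(config.time_grid, r.glucose_t):
            row[f"glucose_{int(t)}"] = g
        rows.append(row)
    return pd.DataFrame(rows)
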
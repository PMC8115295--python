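"""Synthetic cohorts from a precision-weighted Bayesian-observer model.

Each simulated participant holds a prior belief about post-drink hunger
and receives a bottom-up physiological signal; the reported hunger is
their precision-weighted combination,

    H(t) = (pi_prior * H_pred + pi_sens * H_phys(t)) / (pi_prior + pi_sens),

so the sensory weight w = pi_sens / (pi_prior + pi_sens) governs whether
reports track expectations (w -> 0) or physiology (w -> 1).  The trait
score (DIF, difficulty identifying feelings) drives both precisions
log-linearly: higher DIF lowers prior precision and raises sensory
precision, the individual-difference structure the analysis pipeline is
meant to detect.

Generative components:

- glucose: the caloric arm follows a single-peak rise-fall curve
  G(t) = G0 + amp * (t/tp) * exp(1 - t/tp) (peak ``amp`` above the
  fasting baseline at ``tp`` minutes, decaying back toward baseline by
  60 min); the non-caloric arm stays flat at G0.  Meter noise is added
  on top of the true curve.
- physiological hunger: H_phys(t) = H0 - k * (G_true(t) - G0), plus a
  positive rebound drift rho * max(0, t - 15) in the non-caloric arm
  (the flavour-nutrient mismatch signal).
- prior-predicted hunger: H_pred = H0 - s (the drink is expected to
  suppress hunger by s mm).
- expected satiety is the 100-complement of predicted hunger; tasting
  shifts it upward by u0 * w (low-precision priors assimilate the
  gustatory evidence more).  Fullness at 15 min is the 100-complement
  of the precision-weighted hunger at 15 min.
- confidence is a logistic readout of log prior precision, with a
  positive post-tasting boost only above a precision threshold (only
  confident observers become more confident after tasting).
- BMI couples positively to DIF.

All VAS reports get i.i.d. Gaussian noise and are clipped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .data_model import CohortTable, Condition, ParticipantRecord, TIME_GRID


class SimulationConfig(BaseModel):
    """Generative parameters of the Bayesian-observer cohort.

    Defaults emulate the study conditions of the paradigm: 31
    participants per drink arm matched on DIF (arm means ~16.6-16.9,
    SD ~5.4-5.8), a 75 g oral glucose load peaking ~3 mmol/L above a
    5 mmol/L fasting baseline at 30 min, fasting hunger ~65 mm, and
    moderate VAS report noise.
    """

    model_config = ConfigDict(frozen=True)

    n: int = 31                       # participants per condition
    seed: int = 0

    # trait distribution (7-35 scale)
    dif_mean: float = 16.7
    dif_sd: float = 5.6

    # log-linear precision maps: log pi_prior = a0 - a1*z, log pi_sens = b0 + b1*z
    prior_precision_a0: float = 0.0
    prior_precision_a1: float = 0.5
    sensory_precision_b0: float = 0.0
    sensory_precision_b1: float = 1.5

    # glucose kinetics (mmol/L, minutes)
    glucose_baseline: float = 5.0
    glucose_peak_amp: float = 3.0
    glucose_peak_time: float = 30.0
    glucose_noise_sd: float = 0.25

    # hunger model (mm, mm per mmol/L, mm, mm/min)
    hunger_baseline: float = 65.0
    hunger_glucose_gain: float = 14.0
    prior_suppression: float = 14.0
    rebound_drift: float = 0.6

    # report noise (mm)
    vas_noise_sd: float = 3.5

    # confidence map: ESC = 100 * logistic(c0 + c1 * log pi_prior (+ boost))
    conf_intercept: float = 0.2
    conf_slope: float = 1.2
    conf_boost_threshold: float = 0.0
    conf_boost_gain: float = 1.0

    # expected-satiety updating (mm of upward shift at full sensory weight)
    exp_update_gain: float = 4.0

    # anthropometrics (kg/m^2) and hedonics (mm)
    bmi_mean: float = 24.3
    bmi_sd: float = 3.0
    bmi_dif_coupling: float = 1.2
    sweetness_mean: float = 50.0
    liking_mean: float = 60.0
    hedonic_sd: float = 12.0

    @model_validator(mode="after")
    def _invariants(self) -> "SimulationConfig":
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("dif_sd", "glucose_noise_sd", "vas_noise_sd", "bmi_sd", "hedonic_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.glucose_peak_time < 60.0):
            raise ValueError("glucose_peak_time must lie in (0, 60) minutes")
        return self


def null_config(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A trait-decoupled configuration: DIF drives neither precisions nor BMI.

    Used for type-I-error experiments; every trait-index association is
    null by construction.
    """
    base = base or SimulationConfig()
    return base.model_copy(
        update=dict(
            prior_precision_a1=0.0,
            sensory_precision_b1=0.0,
            bmi_dif_coupling=0.0,
            **overrides,
        )
    )


@dataclass(frozen=True)
class SimulatedTruth:
    """Per-participant generating values, for parameter-recovery checks."""

    id: str
    dif_z: float
    pi_prior: float
    pi_sens: float
    w: float                       # sensory weight pi_sens/(pi_prior+pi_sens)
    h_pred: float
    h_phys: tuple[float, float, float, float]


def _glucose_shape(t: np.ndarray, tp: float) -> np.ndarray:
    """Unit-peak rise-fall curve (t/tp) * exp(1 - t/tp)."""
    return (t / tp) * np.exp(1.0 - t / tp)


def _clip_vas(x: float) -> float:
    return float(min(max(x, 0.0), 100.0))


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _generate_record(
    config: SimulationConfig,
    condition: Condition,
    dif_score: int,
    pid: str,
    rng: np.random.Generator,
) -> tuple[ParticipantRecord, SimulatedTruth]:
    c = config
    t = np.asarray(TIME_GRID)
    z = (dif_score - c.dif_mean) / c.dif_sd

    pi_prior = math.exp(c.prior_precision_a0 - c.prior_precision_a1 * z)
    pi_sens = math.exp(c.sensory_precision_b0 + c.sensory_precision_b1 * z)
    w = pi_sens / (pi_prior + pi_sens)

    # true glucose trajectory and meter readings
    if condition == Condition.GLUCOSE:
        g_true = c.glucose_baseline + c.glucose_peak_amp * _glucose_shape(
            t, c.glucose_peak_time
        )
    else:
        g_true = np.full(t.size, c.glucose_baseline)
    g_meas = g_true + rng.normal(0.0, c.glucose_noise_sd, size=t.size)
    g_meas = np.maximum(g_meas, 0.1)

    # latent hunger: physiological signal, prior prediction, weighted report
    h_phys = c.hunger_baseline - c.hunger_glucose_gain * (g_true - c.glucose_baseline)
    if condition == Condition.SUCRALOSE:
        h_phys = h_phys + c.rebound_drift * np.maximum(0.0, t - 15.0)
    h_pred = c.hunger_baseline - c.prior_suppression
    h_latent = (1.0 - w) * h_pred + w * h_phys
    hunger = tuple(
        _clip_vas(h + rng.normal(0.0, c.vas_noise_sd)) for h in h_latent
    )

    # expected satiety (100-complement of predicted hunger) and fullness
    e_bt_latent = 100.0 - h_pred
    e_at_latent = e_bt_latent + c.exp_update_gain * w
    exp_satiety_bt = _clip_vas(e_bt_latent + rng.normal(0.0, c.vas_noise_sd))
    exp_satiety_at = _clip_vas(e_at_latent + rng.normal(0.0, c.vas_noise_sd))
    fullness_15 = _clip_vas(100.0 - h_latent[1] + rng.normal(0.0, c.vas_noise_sd))

    # confidence: logistic readout of log prior precision, thresholded boost
    log_pi = math.log(pi_prior)
    esc_bt_latent = 100.0 * _logistic(c.conf_intercept + c.conf_slope * log_pi)
    boost = c.conf_boost_gain if log_pi > c.conf_boost_threshold else 0.0
    esc_at_latent = 100.0 * _logistic(c.conf_intercept + c.conf_slope * (log_pi + boost))
    esc_bt = _clip_vas(esc_bt_latent + rng.normal(0.0, c.vas_noise_sd))
    esc_at = _clip_vas(esc_at_latent + rng.normal(0.0, c.vas_noise_sd))

    bmi = c.bmi_mean + c.bmi_dif_coupling * z + rng.normal(0.0, c.bmi_sd)
    bmi = float(max(bmi, 16.0))
    sweetness = _clip_vas(c.sweetness_mean + rng.normal(0.0, c.hedonic_sd))
    liking = _clip_vas(c.liking_mean + rng.normal(0.0, c.hedonic_sd))

    record = ParticipantRecord(
        id=pid,
        condition=condition,
        dif_score=dif_score,
        bmi=bmi,
        exp_satiety_bt=exp_satiety_bt,
        exp_satiety_at=exp_satiety_at,
        esc_bt=esc_bt,
        esc_at=esc_at,
        fullness_15=fullness_15,
        hunger_t=hunger,
        glucose_t=tuple(float(g) for g in g_meas),
        sweetness=sweetness,
        liking=liking,
    )
    truth = SimulatedTruth(
        id=pid,
        dif_z=float(z),
        pi_prior=float(pi_prior),
        pi_sens=float(pi_sens),
        w=float(w),
        h_pred=float(h_pred),
        h_phys=tuple(float(h) for h in h_phys),
    )
    return record, truth


def _draw_dif(config: SimulationConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    raw = np.round(rng.normal(config.dif_mean, config.dif_sd, size=size))
    return np.clip(raw, 7, 35).astype(int)


def simulate_participant(
    config: SimulationConfig,
    condition: Condition,
    rng: np.random.Generator,
    pid: str = "P001",
) -> tuple[ParticipantRecord, SimulatedTruth]:
    """One participant: draw the trait, then generate the session."""
    dif = int(_draw_dif(config, 1, rng)[0])
    return _generate_record(config, condition, dif, pid, rng)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortTable, list[SimulatedTruth]]:
    """Simulate n participants per arm, matched on DIF.

    Trait scores are drawn once for the whole cohort, sorted, and within
    each consecutive pair the two condition labels are assigned in random
    order — so the arms are matched on the DIF distribution, as in the
    paradigm's allocation.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    total = 2 * config.n
    dif = np.sort(_draw_dif(config, total, rng))
    conditions = np.empty(total, dtype=object)
    for k in range(config.n):
        pair = [Condition.GLUCOSE, Condition.SUCRALOSE]
        if rng.random() < 0.5:
            pair.reverse()
        conditions[2 * k], conditions[2 * k + 1] = pair
    width = max(3, len(str(total)))
    records, truths = [], []
    for i in range(total):
        pid = f"P{i + 1:0{width}d}"
        rec, truth = _generate_record(config, conditions[i], int(dif[i]), pid, rng)
        records.append(rec)
        truths.append(truth)
    cohort = CohortTable(
        records=tuple(records),
        metadata={"source": "simulated", "seed": config.seed, "n_per_condition": config.n},
    )
    return cohort, truths


def truths_table(truths: list[SimulatedTruth]):
    """Ground-truth sidecar as a DataFrame keyed by participant id."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [t.id for t in truths],
            "dif_z": [t.dif_z for t in truths],
            "pi_prior": [t.pi_prior for t in truths],
            "pi_sens": [t.pi_sens for t in truths],
            "w": [t.w for t in truths],
        }
    )
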
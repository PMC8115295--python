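"""End-to-end orchestration: cohort -> indices -> statistical battery -> report.

``run_pipeline`` reproduces the paradigm's full analysis battery on any
validated cohort: per-condition zero-order correlation matrices among the
interoceptive indices and traits with BH-FDR, partial correlations of the
trait with each index controlling BMI, two-group comparisons across drink
arms, the mixed-design ANCOVAs (expected-satiety updating, confidence
updating, satiety divergence, interoceptive coherence, hunger and glucose
trajectories, sweetness/liking), and the follow-up correlation probes of
the interactions.  The Cook's-distance outlier policy is applied to the
satiety-divergence variables (only) before they enter any test.

``recovery_experiment`` and ``type_one_error_experiment`` run the
pipeline on simulated cohorts to check that the generating parameters of
the Bayesian-observer model are recoverable and that the FDR machinery
controls false positives under a trait-decoupled null.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import AnalysisConfig, CohortTable, Condition, ICVariant, SDTransform
from .indices import indices_table
from .stats import (
    bh_fdr,
    cooks_outlier_policy,
    independent_t,
    median_split,
    oneway_ancova,
    partial_correlation,
    pearson,
    rm_ancova_2level,
    rm_ancova_4level,
)
from .synthetic import SimulationConfig, null_config, simulate_cohort, truths_table

logger = logging.getLogger("interosat")

CORRELATION_VARIABLES = ["esc_bt", "esc_at", "sd_bt", "sd_at", "ic", "dif", "bmi"]
TRAIT_VARIABLES = ["dif", "bmi"]

CORRELATION_COLUMNS = ["condition", "x", "y", "r", "n", "p", "p_adj", "significant"]
COMPARISON_COLUMNS = [
    "variable", "mean_glucose", "se_glucose", "n_glucose",
    "mean_sucralose", "se_sucralose", "n_sucralose",
    "t", "df", "p", "ci_low", "ci_high", "levene_p",
]
ANCOVA_COLUMNS = ["analysis", "effect", "F", "df1", "df2", "p", "pes"]
PROBE_COLUMNS = ["probe", "subset", "x", "y", "r", "n", "p"]


@dataclass
class AnalysisReport:
    """All tables of one pipeline run, plus provenance."""

    indices: pd.DataFrame
    correlations: pd.DataFrame
    partial_correlations: pd.DataFrame
    comparisons: pd.DataFrame
    ancova: pd.DataFrame
    probes: pd.DataFrame
    split_probes: pd.DataFrame
    outliers: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _analysis_table(cohort: CohortTable, config: AnalysisConfig) -> pd.DataFrame:
    """Indices table with the analysis-ready SD and IC columns added.

    ``sd_bt_a``/``sd_at_a`` are the (optionally arcsine-transformed)
    divergence scores that enter every test; ``ic_a`` is the configured
    coherence variant.
    """
    tbl = indices_table(cohort, config)
    if config.sd_transform == SDTransform.ARCSINE:
        tbl["sd_bt_a"] = tbl["sd_bt_x"]
        tbl["sd_at_a"] = tbl["sd_at_x"]
    else:
        tbl["sd_bt_a"] = tbl["sd_bt"]
        tbl["sd_at_a"] = tbl["sd_at"]
    tbl["ic_a"] = tbl["ic_abs"] if config.ic_variant == ICVariant.ABSOLUTE else tbl["ic"]
    return tbl


_ANALYSIS_COLUMN = {"sd_bt": "sd_bt_a", "sd_at": "sd_at_a", "ic": "ic_a"}


def _col(tbl: pd.DataFrame, var: str) -> np.ndarray:
    return tbl[_ANALYSIS_COLUMN.get(var, var)].to_numpy(dtype=float)


def _apply_outlier_policy(tbl: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Cook's-distance policy on the SD variables, predictor = DIF."""
    summary = {}
    for var in ("sd_bt_a", "sd_at_a"):
        cleaned, report = cooks_outlier_policy(
            tbl[var].to_numpy(dtype=float),
            tbl["dif"].to_numpy(dtype=float),
            config.cooks_threshold_mode,
        )
        tbl[var] = cleaned
        summary[var] = {
            "threshold": report.threshold,
            "replaced_ids": [str(tbl["id"].iloc[i]) for i in report.replaced],
            "replacement_value": report.replacement_value,
        }
    return summary


def _correlation_family(
    tbl: pd.DataFrame, condition_label: str, delta: float
) -> pd.DataFrame:
    rows = []
    for x, y in itertools.combinations(CORRELATION_VARIABLES, 2):
        res = pearson(_col(tbl, x), _col(tbl, y), x, y)
        rows.append([condition_label, x, y, res.r, res.n, res.p])
    df = pd.DataFrame(rows, columns=CORRELATION_COLUMNS[:6])
    reject, p_adj = bh_fdr(df["p"].to_numpy(), delta)
    df["p_adj"] = p_adj
    df["significant"] = reject
    return df


def run_pipeline(cohort: CohortTable, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full statistical battery; see module docstring."""
    config = config or AnalysisConfig()
    tbl = _analysis_table(cohort, config)
    outliers = _apply_outlier_policy(tbl, config)
    skipped: list[dict] = []

    cond_tables = {
        c.value: tbl[tbl["condition"] == c.value] for c in Condition
    }

    # --- per-condition zero-order correlation matrices with BH-FDR ---
    corr_frames = []
    for cond, sub in cond_tables.items():
        if len(sub) < 4:
            reason = f"correlations[{cond}]: n={len(sub)} < 4"
            logger.warning("skipping %s", reason)
            skipped.append({"test": f"correlations[{cond}]", "reason": reason})
            continue
        corr_frames.append(_correlation_family(sub, cond, config.fdr_level))
    correlations = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(columns=CORRELATION_COLUMNS)
    )

    # --- partial correlations of DIF with each index, controlling BMI ---
    prows = []
    if len(tbl) >= 5:
        for var in ("esc_bt", "esc_at", "sd_bt", "sd_at", "ic"):
            res = partial_correlation(
                _col(tbl, "dif"), _col(tbl, var), _col(tbl, "bmi"), "dif", var
            )
            prows.append(["pooled", "dif", var, res.r, res.n, res.p])
    else:
        skipped.append({"test": "partial_correlations", "reason": f"n={len(tbl)} < 5"})
    partials = pd.DataFrame(prows, columns=CORRELATION_COLUMNS[:6])
    if len(partials):
        reject, p_adj = bh_fdr(partials["p"].to_numpy(), config.fdr_level)
        partials["p_adj"] = p_adj
        partials["significant"] = reject

    # --- two-group comparisons across drink arms ---
    g = cond_tables[Condition.GLUCOSE.value]
    s = cond_tables[Condition.SUCRALOSE.value]
    crows = []
    for var in ("esc_bt", "esc_at", "sd_bt", "sd_at", "ic", "auci_hunger"):
        gv = _col(g, var) if var != "auci_hunger" else g["auci_hunger"].to_numpy(float)
        sv = _col(s, var) if var != "auci_hunger" else s["auci_hunger"].to_numpy(float)
        gv, sv = gv[~np.isnan(gv)], sv[~np.isnan(sv)]
        if gv.size < 2 or sv.size < 2:
            reason = f"independent_t[{var}]: group n < 2"
            logger.warning("skipping %s", reason)
            skipped.append({"test": f"independent_t[{var}]", "reason": reason})
            continue
        res = independent_t(gv, sv, label=var)
        crows.append([
            var, res.mean_1, res.se_1, res.n_1, res.mean_2, res.se_2, res.n_2,
            res.t, res.df, res.p, res.ci95[0], res.ci95[1], res.levene_p,
        ])
    comparisons = pd.DataFrame(crows, columns=COMPARISON_COLUMNS)

    # --- ANCOVA battery ---
    arows = []

    def _add(analysis: str, results) -> None:
        for r in results:
            arows.append([analysis, r.effect, r.F, r.df_num, r.df_den, r.p, r.partial_eta_sq])

    between = tbl["condition"].to_numpy()
    dif = _col(tbl, "dif")

    def _try(analysis: str, fn) -> None:
        try:
            _add(analysis, fn())
        except ValueError as exc:
            logger.warning("skipping %s: %s", analysis, exc)
            skipped.append({"test": analysis, "reason": str(exc)})

    _try("expected_satiety", lambda: rm_ancova_2level(
        _col(tbl, "exp_satiety_bt"), _col(tbl, "exp_satiety_at"),
        between, _col(tbl, "esc_bt"), within_label="taste"))
    _try("confidence", lambda: rm_ancova_2level(
        _col(tbl, "esc_bt"), _col(tbl, "esc_at"), between, dif, within_label="taste"))
    _try("satiety_divergence", lambda: rm_ancova_2level(
        _col(tbl, "sd_bt"), _col(tbl, "sd_at"), between, dif, within_label="taste"))
    _try("interoceptive_coherence", lambda: oneway_ancova(_col(tbl, "ic"), between, dif))
    hunger_cols = [f"hunger_{int(t)}" for t in config.time_grid]
    glucose_cols = [f"glucose_{int(t)}" for t in config.time_grid]
    _try("hunger", lambda: rm_ancova_4level(
        tbl[hunger_cols].to_numpy(float), between, dif, within_label="time"))
    _try("glucose", lambda: rm_ancova_4level(
        tbl[glucose_cols].to_numpy(float), between, dif, within_label="time"))
    if tbl["sweetness"].notna().any():
        _try("sweetness", lambda: oneway_ancova(_col(tbl, "sweetness"), between, dif))
    if tbl["liking"].notna().any():
        _try("liking", lambda: oneway_ancova(_col(tbl, "liking"), between, dif))
    ancova = pd.DataFrame(arows, columns=ANCOVA_COLUMNS)

    # --- follow-up correlation probes of the interactions ---
    probe_specs = [
        ("sd_at_vs_dif", Condition.GLUCOSE.value, "dif", "sd_at"),
        ("sd_at_vs_dif", Condition.SUCRALOSE.value, "dif", "sd_at"),
        ("esc_at_vs_dif", "pooled", "dif", "esc_at"),
        ("esc_update_vs_dif", "pooled", "dif", "esc_update"),
        ("ic_vs_dif", "pooled", "dif", "ic"),
        ("hunger_30_vs_dif", Condition.SUCRALOSE.value, "dif", "hunger_30"),
        ("hunger_60_vs_dif", Condition.SUCRALOSE.value, "dif", "hunger_60"),
        ("glucose_delta_60_vs_dif", Condition.GLUCOSE.value, "dif", "glucose_delta_60"),
        ("exp_satiety_update_vs_esc_bt", "pooled", "esc_bt", "exp_satiety_update"),
    ]
    probe_rows = []
    for name, subset, x, y in probe_specs:
        sub = tbl if subset == "pooled" else cond_tables[subset]
        res = pearson(_col(sub, x), _col(sub, y), x, y)
        probe_rows.append([name, subset, x, y, res.r, res.n, res.p])
    probes = pd.DataFrame(probe_rows, columns=PROBE_COLUMNS)

    # --- median-split probe: rebound AUCi by DIF half, per condition ---
    split_rows = []
    for cond, sub in cond_tables.items():
        try:
            halves = median_split(sub["dif"].to_numpy(float))
        except ValueError as exc:
            skipped.append({"test": f"median_split[{cond}]", "reason": str(exc)})
            continue
        lo = sub["auci_hunger"].to_numpy(float)[halves == "LOW"]
        hi = sub["auci_hunger"].to_numpy(float)[halves == "HIGH"]
        if lo.size < 2 or hi.size < 2:
            skipped.append({"test": f"auci_split[{cond}]", "reason": "half with n < 2"})
            continue
        res = independent_t(hi, lo, label=f"auci_hunger[{cond}]")
        split_rows.append([
            f"auci_by_dif_split[{cond}]", cond, float(lo.mean()), float(hi.mean()),
            float(hi.mean() - lo.mean()), res.t, res.df, res.p,
        ])
    split_probes = pd.DataFrame(
        split_rows,
        columns=["probe", "condition", "mean_low_dif", "mean_high_dif",
                 "diff_high_minus_low", "t", "df", "p"],
    )

    provenance = {
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "seed": cohort.metadata.get("seed"),
        "source": cohort.metadata.get("source"),
        "n": len(cohort),
        "version": __version__,
    }
    return AnalysisReport(
        indices=tbl,
        correlations=correlations,
        partial_correlations=partials,
        comparisons=comparisons,
        ancova=ancova,
        probes=probes,
        split_probes=split_probes,
        outliers=outliers,
        skipped=skipped,
        provenance=provenance,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Emit the report as one CSV per table plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "indices.csv": report.indices,
        "correlations.csv": report.correlations,
        "partial_correlations.csv": report.partial_correlations,
        "comparisons.csv": report.comparisons,
        "ancova.csv": report.ancova,
        "probes.csv": report.probes,
        "split_probes.csv": report.split_probes,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, index=False)
    manifest = {
        "provenance": report.provenance,
        "outliers": report.outliers,
        "skipped": report.skipped,
        "tables": sorted(tables),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Simulation-backed experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryReport:
    """Can the pipeline recover the generating observer parameters?

    ``corr_w_ic``: Pearson r between the generating sensory weight w and
    the interoceptive-coherence index, in the glucose arm (the arm with
    a physiological signal for IC to track).
    ``corr_prior_sd_at``: Pearson r between generating prior precision
    and SD after tasting, pooled.
    ``dif_esc_at_r``: trait-confidence correlation (expected negative).
    ``hunger_interaction_p`` and ``hunger_df``: the Time x Drink x DIF
    term of the hunger mixed ANCOVA.
    ``auci_split_diff``: sucralose-arm rebound AUCi, high- minus low-DIF
    half (expected positive).
    """

    n_per_condition: int
    seed: int
    corr_w_ic: float
    corr_prior_sd_at: float
    dif_esc_at_r: float
    hunger_interaction_p: float
    hunger_df: tuple[int, int]
    auci_split_diff: float

    def to_dict(self) -> dict:
        return {
            "n_per_condition": self.n_per_condition,
            "seed": self.seed,
            "corr_w_ic": self.corr_w_ic,
            "corr_prior_sd_at": self.corr_prior_sd_at,
            "dif_esc_at_r": self.dif_esc_at_r,
            "hunger_interaction_p": self.hunger_interaction_p,
            "hunger_df": list(self.hunger_df),
            "auci_split_diff": self.auci_split_diff,
        }


def recovery_experiment(
    config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
) -> RecoveryReport:
    """Simulate a cohort, run the pipeline, compare against ground truth."""
    config = config or SimulationConfig()
    analysis_config = analysis_config or AnalysisConfig()
    cohort, truths = simulate_cohort(config)
    tbl = _analysis_table(cohort, analysis_config)
    tbl = tbl.merge(truths_table(truths), on="id", validate="one_to_one")

    g = tbl[tbl["condition"] == Condition.GLUCOSE.value]
    s = tbl[tbl["condition"] == Condition.SUCRALOSE.value]

    corr_w_ic = pearson(g["w"], g["ic"]).r
    corr_prior_sd_at = pearson(tbl["pi_prior"], tbl["sd_at"]).r
    dif_esc_at = pearson(tbl["dif"], tbl["esc_at"]).r

    hunger_cols = [f"hunger_{int(t)}" for t in analysis_config.time_grid]
    results = rm_ancova_4level(
        tbl[hunger_cols].to_numpy(float),
        tbl["condition"].to_numpy(),
        tbl["dif"].to_numpy(float),
        within_label="time",
    )
    inter = next(r for r in results if r.effect == "time_x_drink_x_cov")

    halves = median_split(s["dif"].to_numpy(float))
    auci = s["auci_hunger"].to_numpy(float)
    split_diff = float(auci[halves == "HIGH"].mean() - auci[halves == "LOW"].mean())

    return RecoveryReport(
        n_per_condition=config.n,
        seed=config.seed,
        corr_w_ic=float(corr_w_ic),
        corr_prior_sd_at=float(corr_prior_sd_at),
        dif_esc_at_r=float(dif_esc_at),
        hunger_interaction_p=float(inter.p),
        hunger_df=(inter.df_num, inter.df_den),
        auci_split_diff=split_diff,
    )


def type_one_error_experiment(
    base_config: SimulationConfig | None = None,
    n_reps: int = 200,
    seed: int = 0,
    delta: float = 0.05,
) -> dict:
    """BH family-wise false-positive rate under the trait-decoupled null.

    Simulates ``n_reps`` cohorts in which DIF drives neither precision
    map nor BMI, so every trait-index association is null by
    construction.  For each cohort and condition, the family of
    trait-association p-values (DIF and BMI against each index, plus
    DIF-BMI) is BH-corrected at ``delta``; returns the fraction of
    families with at least one discovery.
    """
    base = null_config(base_config)
    n_families = 0
    n_flagged = 0
    for i in range(n_reps):
        cfg = base.model_copy(update={"seed": (seed + 10_007 * i) % (2**31 - 1)})
        cohort, _ = simulate_cohort(cfg)
        tbl = _analysis_table(cohort, AnalysisConfig())
        for cond in Condition:
            sub = tbl[tbl["condition"] == cond.value]
            pvals = []
            for trait in TRAIT_VARIABLES:
                for var in ("esc_bt", "esc_at", "sd_bt", "sd_at", "ic"):
                    pvals.append(pearson(_col(sub, trait), _col(sub, var)).p)
            pvals.append(pearson(_col(sub, "dif"), _col(sub, "bmi")).p)
            reject, _ = bh_fdr(pvals, delta)
            n_families += 1
            n_flagged += int(reject.any())
    return {
        "n_reps": n_reps,
        "n_families": n_families,
        "family_discovery_rate": n_flagged / n_families,
        "delta": delta,
    }
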
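"""Statistical battery for the interoceptive indices.

Zero-order and partial Pearson correlations, Benjamini-Hochberg FDR,
independent t tests with a Levene homogeneity gate, Pearson chi-square,
mixed-design (split-plot) ANCOVAs with a continuous covariate, Cook's
distance outlier policy, and a median split for interaction probes.

The mixed ANCOVAs use the exact decomposition for a within-subject factor
crossed with one 2-level between factor and one covariate: within-subject
effects come from least squares on orthonormal within-subject contrasts,
between-subject effects from least squares on the (orthonormal) subject
mean.  Sums of squares are Type III (full vs drop-one-term model
comparison), the covariate is centred at its grand mean and the between
factor is effect-coded (+1/-1).  Sphericity is assumed (no correction),
so with N subjects and t within levels the within-term denominator df is
(t-1)(N-4) — e.g. (3, 174) for N = 62 — and between-term df is N-4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("interosat")

__all__ = [
    "CorrelationResult",
    "AncovaResult",
    "GroupComparisonResult",
    "pearson",
    "partial_correlation",
    "bh_fdr",
    "independent_t",
    "chi_square_2x2",
    "oneway_ancova",
    "rm_ancova_2level",
    "rm_ancova_4level",
    "cooks_outlier_policy",
    "median_split",
]


@dataclass
class CorrelationResult:
    """Pearson (or partial) correlation between a labelled variable pair."""

    x_label: str
    y_label: str
    r: float
    n: int
    p: float
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None


@dataclass(frozen=True)
class AncovaResult:
    """One effect line of an ANCOVA table."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-group comparison with per-group mean (se) and a 95% CI."""

    label: str
    mean_1: float
    se_1: float
    n_1: int
    mean_2: float
    se_2: float
    n_2: int
    t: float
    df: float
    p: float
    ci95: tuple[float, float]
    levene_p: float


def _pairwise(*arrays: Sequence[float]) -> list[np.ndarray]:
    """Drop rows where any array is NaN (pairwise deletion)."""
    cols = [np.asarray(a, dtype=float) for a in arrays]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("series must have equal length")
    keep = ~np.any(np.isnan(np.column_stack(cols)), axis=1)
    return [c[keep] for c in cols]


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    x_label: str = "x",
    y_label: str = "y",
) -> CorrelationResult:
    """Product-moment correlation; two-sided p from the t transform, n-2 df.

    NaN pairs are dropped; n < 3 or zero variance yields a NaN result.
    """
    xv, yv = _pairwise(x, y)
    n = int(xv.size)
    if n < 3 or np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        logger.warning(
            "pearson(%s, %s) undefined (n=%d or zero variance)", x_label, y_label, n
        )
        return CorrelationResult(x_label, y_label, math.nan, n, math.nan)
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(x_label, y_label, float(r), n, float(p))


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariate: Sequence[float],
    x_label: str = "x",
    y_label: str = "y",
) -> CorrelationResult:
    """Correlation of x and y after removing the covariate by least squares.

    Both series are residualised on [1, covariate]; the residual Pearson r
    is tested with n-3 df.  A zero-variance covariate falls back to the
    plain Pearson correlation with a warning.
    """
    xv, yv, cv = _pairwise(x, y, covariate)
    n = int(xv.size)
    if n < 4:
        logger.warning("partial_correlation undefined for n=%d < 4", n)
        return CorrelationResult(x_label, y_label, math.nan, n, math.nan)
    if np.ptp(cv) == 0.0:
        logger.warning(
            "partial_correlation: degenerate covariate; falling back to pearson"
        )
        return pearson(xv, yv, x_label, y_label)
    design = np.column_stack([np.ones(n), cv])
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    if np.allclose(rx, 0.0, atol=1e-10) or np.allclose(ry, 0.0, atol=1e-10):
        logger.warning("partial_correlation: residuals degenerate; returning NaN")
        return CorrelationResult(x_label, y_label, math.nan, n, math.nan)
    r = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = min(max(r, -1.0), 1.0)
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(x_label, y_label, r, n, p)


def bh_fdr(
    pvalues: Sequence[float], delta: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Returns (reject flags, adjusted p-values) in input order.  NaN
    p-values (degenerate tests) are excluded from the family and come
    back as (False, NaN), with a logged count.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    valid = ~np.isnan(p)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("bh_fdr: excluding %d undefined p-values from family", n_dropped)
    reject = np.zeros(p.size, dtype=bool)
    p_adj = np.full(p.size, math.nan)
    if valid.any():
        rej, adj, _, _ = multipletests(p[valid], alpha=delta, method="fdr_bh")
        reject[valid] = rej
        p_adj[valid] = adj
    return reject, p_adj


def independent_t(
    group_1: Sequence[float],
    group_2: Sequence[float],
    label: str = "",
    welch: bool = False,
) -> GroupComparisonResult:
    """Two-sided independent-samples t test (pooled variance by default).

    Reports per-group mean (se), the 95% CI of the mean difference
    (group_1 - group_2) and Levene's homogeneity p (centre = mean).
    """
    g1, = _pairwise(group_1)
    g2, = _pairwise(group_2)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs n >= 2, got {n1} and {n2}")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0 and g1.mean() != g2.mean():
        raise ValueError("degenerate groups: zero within-group variance, unequal means")
    t_stat, p = sps.ttest_ind(g1, g2, equal_var=not welch)
    if welch:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    diff = g1.mean() - g2.mean()
    tcrit = float(sps.t.ppf(0.975, df))
    if v1 == 0.0 or v2 == 0.0:
        logger.warning("independent_t: a group has zero variance; Levene degenerate")
        levene_p = math.nan
    else:
        _, levene_p = sps.levene(g1, g2, center="mean")
    return GroupComparisonResult(
        label=label,
        mean_1=float(g1.mean()),
        se_1=float(math.sqrt(v1 / n1)),
        n_1=int(n1),
        mean_2=float(g2.mean()),
        se_2=float(math.sqrt(v2 / n2)),
        n_2=int(n2),
        t=float(t_stat),
        df=float(df),
        p=float(p),
        ci95=(float(diff - tcrit * se), float(diff + tcrit * se)),
        levene_p=float(levene_p),
    )


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table.

    Returns (chi2, p); a zero row or column marginal yields (NaN, NaN).
    """
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        logger.warning("chi_square_2x2 undefined for a zero marginal")
        return math.nan, math.nan
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# ANCOVA machinery
# ---------------------------------------------------------------------------


def _effect_code(between: Sequence) -> np.ndarray:
    """+1/-1 coding of a 2-level factor (levels in sorted order)."""
    b = np.asarray(between)
    levels = sorted(set(b.tolist()))
    if len(levels) != 2:
        raise ValueError(f"between factor must have exactly 2 levels, got {levels}")
    return np.where(b == levels[0], 1.0, -1.0)


def _between_design(between: Sequence, covariate: Sequence[float]) -> np.ndarray:
    d = _effect_code(between)
    c = np.asarray(covariate, dtype=float)
    c = c - c.mean()
    return np.column_stack([np.ones(d.size), d, c, d * c])


def _sse(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares of Y (column-stacked) on X, pooled."""
    if X.shape[1] == 0:
        return float(np.sum(Y * Y))
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return float(np.sum(resid * resid))

_BETWEEN_TERMS = {"intercept": 0, "drink": 1, "cov": 2, "drink_x_cov": 3}


def _type3_lines(
    Y: np.ndarray,
    X: np.ndarray,
    term_names: dict[str, str],
    df_per_term: int,
) -> tuple[list[tuple[str, float]], float, int]:
    """Type III SS per term of the 4-column between design, pooled over Y columns."""
    sse_full = _sse(X, Y)
    lines = []
    for term, label in term_names.items():
        j = _BETWEEN_TERMS[term]
        Xr = np.delete(X, j, axis=1)
        lines.append((label, _sse(Xr, Y) - sse_full))
    return lines, sse_full, df_per_term


def _within_contrasts(t: int) -> np.ndarray:
    """Orthonormal contrast matrix: column 0 the mean, columns 1..t-1 the rest."""
    M = np.vander(np.arange(t, dtype=float), t, increasing=True)
    Q, _ = np.linalg.qr(M)
    # fix sign so the mean column is positive
    if Q[0, 0] < 0:
        Q = -Q
    return Q


def _mixed_ancova(
    Y: np.ndarray,
    between: Sequence,
    covariate: Sequence[float],
    within_label: str,
) -> list[AncovaResult]:
    """Split-plot ANCOVA for an N x t response matrix; see module docstring."""
    Y = np.asarray(Y, dtype=float)
    between = np.asarray(between)
    covariate = np.asarray(covariate, dtype=float)
    complete = ~(np.any(np.isnan(Y), axis=1) | np.isnan(covariate))
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("mixed ANCOVA: dropping %d incomplete subjects", n_dropped)
    Y, between, covariate = Y[complete], between[complete], covariate[complete]
    n, t = Y.shape
    if n <= 4:
        raise ValueError(f"mixed ANCOVA requires more than 4 complete subjects, got {n}")
    X = _between_design(between, covariate)
    Q = _within_contrasts(t)
    Z_within = Y @ Q[:, 1:]            # N x (t-1), within-subject part
    u_between = Y @ Q[:, :1]           # N x 1, orthonormal subject mean

    # strata whose total SS is at rounding level relative to the data are
    # degenerate: report F = 0 rather than ratios of float noise
    data_scale = float(np.sum(Y * Y)) + 1e-300

    results: list[AncovaResult] = []

    within_terms = {
        "intercept": within_label,
        "drink": f"{within_label}_x_drink",
        "cov": f"{within_label}_x_cov",
        "drink_x_cov": f"{within_label}_x_drink_x_cov",
    }
    df_err_w = (t - 1) * (n - 4)
    if float(np.sum(Z_within * Z_within)) <= 1e-20 * data_scale:
        for label in within_terms.values():
            results.append(AncovaResult(label, 0.0, t - 1, df_err_w, 1.0, 0.0))
    else:
        lines, sse_w, _ = _type3_lines(Z_within, X, within_terms, t - 1)
        for label, ss in lines:
            results.append(_f_line(label, ss, t - 1, sse_w, df_err_w))

    between_terms = {"drink": "drink", "cov": "cov", "drink_x_cov": "drink_x_cov"}
    lines, sse_b, _ = _type3_lines(u_between, X, between_terms, 1)
    df_err_b = n - 4
    for label, ss in lines:
        results.append(_f_line(label, ss, 1, sse_b, df_err_b))
    return results


def _f_line(label: str, ss: float, df_num: int, sse: float, df_err: int) -> AncovaResult:
    ss = max(ss, 0.0)
    if sse <= 0.0:
        # saturated fit: an exact-zero error stratum
        F = math.inf if ss > 0 else 0.0
        p = 0.0 if ss > 0 else 1.0
        pes = 1.0 if ss > 0 else 0.0
        return AncovaResult(label, F, df_num, df_err, p, pes)
    F = (ss / df_num) / (sse / df_err)
    p = float(sps.f.sf(F, df_num, df_err))
    return AncovaResult(label, float(F), df_num, df_err, p, ss / (ss + sse))


def rm_ancova_2level(
    y_pre: Sequence[float],
    y_post: Sequence[float],
    between: Sequence,
    covariate: Sequence[float],
    within_label: str = "taste",
) -> list[AncovaResult]:
    """2 (within) x 2 (between) mixed ANCOVA with a continuous covariate.

    For a 2-level within factor this is exactly a linear model on the
    (orthonormal) difference score for within-subject terms and on the
    subject mean for between-subject terms.  Returns the seven effect
    lines {within, within x drink, within x cov, within x drink x cov,
    drink, cov, drink x cov}.
    """
    Y = np.column_stack([np.asarray(y_pre, float), np.asarray(y_post, float)])
    return _mixed_ancova(Y, between, covariate, within_label)


def rm_ancova_4level(
    Y: np.ndarray,
    between: Sequence,
    covariate: Sequence[float],
    within_label: str = "time",
) -> list[AncovaResult]:
    """4 (within: 0/15/30/60 min) x 2 (between) mixed ANCOVA with covariate.

    Univariate sums of squares with sphericity assumed; for N = 62 the
    within-term df are (3, 174).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 4:
        raise ValueError("Y must be an N x 4 matrix of repeated measurements")
    return _mixed_ancova(Y, between, covariate, within_label)


def oneway_ancova(
    y: Sequence[float],
    between: Sequence,
    covariate: Sequence[float],
) -> list[AncovaResult]:
    """Univariate ANCOVA: 2-level factor x continuous covariate on one DV.

    Type III effects {drink, cov, drink x cov} with error df N - 4.
    """
    yv = np.asarray(y, dtype=float)
    between = np.asarray(between)
    cov = np.asarray(covariate, dtype=float)
    complete = ~(np.isnan(yv) | np.isnan(cov))
    if (~complete).sum():
        logger.warning("oneway_ancova: dropping %d incomplete subjects", int((~complete).sum()))
    yv, between, cov = yv[complete], between[complete], cov[complete]
    n = yv.size
    if n <= 4:
        raise ValueError("oneway_ancova requires more than 4 complete subjects")
    X = _between_design(between, cov)
    terms = {"drink": "drink", "cov": "cov", "drink_x_cov": "drink_x_cov"}
    lines, sse, _ = _type3_lines(yv[:, None], X, terms, 1)
    return [_f_line(label, ss, 1, sse, n - 4) for label, ss in lines]


# ---------------------------------------------------------------------------
# Outlier policy and probes
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    """Which observations the Cook's distance policy replaced, and why."""

    threshold: float
    cooks_d: np.ndarray
    replaced: list[int] = field(default_factory=list)
    replacement_value: float = math.nan


def cooks_outlier_policy(
    y: Sequence[float],
    x: Sequence[float],
    threshold_mode: str = "CONVENTIONAL_4_OVER_N",
) -> tuple[np.ndarray, OutlierReport]:
    """Flag influential points of the simple regression of y on x.

    Cook's distance is computed from y ~ 1 + x; points above the
    threshold (4/n conventionally, or the fixed 0.2 replication cutoff)
    have their y value replaced by the mean of the unflagged y values.
    NaN positions are passed through untouched.  Returns the cleaned y
    and a report with the flagged positional indices.
    """
    yv = np.asarray(y, dtype=float).copy()
    xv = np.asarray(x, dtype=float)
    if yv.size != xv.size:
        raise ValueError("y and x must have equal length")
    valid = ~(np.isnan(yv) | np.isnan(xv))
    n = int(valid.sum())
    mode = str(getattr(threshold_mode, "value", threshold_mode))
    threshold = 0.2 if mode == "PAPER_0_2" else 4.0 / max(n, 1)
    if n < 5:
        logger.warning("cooks_outlier_policy: n=%d < 5; no flagging", n)
        return yv, OutlierReport(threshold, np.full(yv.size, math.nan))
    xs, ys = xv[valid], yv[valid]
    if np.ptp(xs) == 0.0:
        logger.warning("cooks_outlier_policy: degenerate regression; no flagging")
        return yv, OutlierReport(threshold, np.full(yv.size, math.nan))
    X = np.column_stack([np.ones(n), xs])
    beta, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ beta
    p = 2
    rss = float(resid @ resid)
    mse = rss / (n - p)
    hat = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
    if rss <= 1e-16 * (float(ys @ ys) + 1e-300):
        # exact fit up to rounding: no point is influential
        d = np.zeros(n)
    else:
        d = resid**2 / (p * mse) * hat / (1.0 - hat) ** 2
    cooks = np.full(yv.size, math.nan)
    cooks[valid] = d
    flagged_local = np.where(d > threshold)[0]
    flagged = np.where(valid)[0][flagged_local]
    report = OutlierReport(threshold, cooks, replaced=flagged.tolist())
    if flagged.size:
        keep = np.setdiff1d(np.where(valid)[0], flagged)
        replacement = float(yv[keep].mean())
        yv[flagged] = replacement
        report.replacement_value = replacement
        logger.info(
            "cooks_outlier_policy: replaced %d values (threshold %.4g) with mean %.4g",
            flagged.size, threshold, replacement,
        )
    return yv, report


def median_split(values: Sequence[float]) -> np.ndarray:
    """Dichotomise at the median: 'LOW' if value <= median else 'HIGH'.

    Ties at the median go LOW.  A constant series cannot be split.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median_split requires n >= 2")
    if np.ptp(v[~np.isnan(v)]) == 0.0:
        raise ValueError("median_split impossible: all values identical")
    med = float(np.nanmedian(v))
    out = np.where(v <= med, "LOW", "HIGH")
    out = out.astype(object)
    out[np.isnan(v)] = None
    return out
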
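"""Cohort-level aggregation and the study's comparison structure.

Raw-threshold comparisons (each post-onset timepoint vs baseline; each
dynamic pattern vs tonic at a timepoint; the extended 60-90-min window vs
t = 60) are paired, two-sided, within-animal tests at alpha = 0.05 with no
multiplicity correction.  Slope and FWHM contrasts operate on the retained
(QC-passing) fits only, pairing animals that have both members of the
contrast.  Omnibus repeated-measures tests are computed and reported for
context but do not gate the cell-level comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError
from .fitting import PATTERNS

__all__ = [
    "ALPHA",
    "ComparisonResult",
    "PatternSummary",
    "timepoint_vs_baseline",
    "pattern_vs_tonic",
    "extended_period_test",
    "slope_contrasts",
    "summarize_patterns",
    "pwt_omnibus",
    "metric_mixed_model",
    "comparisons_to_frame",
]

ALPHA = 0.05

#: Dynamic (non-tonic) patterns, in reporting order.
TDP_PATTERNS = tuple(p for p in PATTERNS if p != "tonic")

MIN_PAIRS = 3


@dataclass(frozen=True)
class ComparisonResult:
    """One paired contrast: label, test statistic, p-value, decision."""

    contrast: str
    pattern: str
    timepoint: float | None
    metric: str
    n: int
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class PatternSummary:
    """Per-pattern mean +/- SEM of fitted metrics and raw PWT by timepoint."""

    pattern: str
    n_fitted: int
    n_retained: int
    metric_mean_sem: dict[str, tuple[float, float]]
    pwt_mean_sem: dict[float, tuple[float, float]]


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan"), float("nan")
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return float(np.mean(x)), sem


def _paired_t(
    a: np.ndarray,
    b: np.ndarray,
    *,
    contrast: str,
    pattern: str,
    timepoint: float | None,
    metric: str,
    alpha: float,
) -> ComparisonResult:
    """Two-sided paired t-test of a vs b after dropping incomplete pairs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = int(a.size)
    if n < MIN_PAIRS:
        raise InsufficientDataError(
            f"{contrast} [{pattern}]: only {n} complete pairs (need >= {MIN_PAIRS})")
    diffs = a - b
    if np.allclose(diffs, diffs[0]) and np.std(diffs) == 0.0:
        return ComparisonResult(
            contrast=contrast, pattern=pattern, timepoint=timepoint,
            metric=metric, n=n, statistic=float("nan"), p_value=float("nan"),
            significant=False, degenerate=True,
            note="zero variance of paired differences")
    t_stat, p = sps.ttest_rel(a, b)
    return ComparisonResult(
        contrast=contrast, pattern=pattern, timepoint=timepoint, metric=metric,
        n=n, statistic=float(t_stat), p_value=float(p),
        significant=bool(p < alpha))


def _wide_pwt(df: pd.DataFrame, pattern: str) -> pd.DataFrame:
    sub = df[df["pattern"] == pattern]
    return sub.pivot_table(index="animal_id", columns="time_min",
                           values="pwt_g", aggfunc="first")


def timepoint_vs_baseline(
    df: pd.DataFrame,
    pattern: str,
    window: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0),
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Paired comparison of PWT(t) vs PWT(0) for each t in the window.

    Cohorts are aggregated (both designs share the first 60 min); each
    animal contributes one pair per timepoint.
    """
    wide = _wide_pwt(df, pattern)
    if 0.0 not in wide.columns:
        raise InsufficientDataError(f"{pattern}: no t = 0 baseline observations")
    results = []
    for t in window:
        if t not in wide.columns:
            continue
        results.append(_paired_t(
            wide[t].to_numpy(), wide[0.0].to_numpy(),
            contrast="timepoint_vs_baseline", pattern=pattern,
            timepoint=float(t), metric="pwt_g", alpha=alpha))
    if not results:
        raise InsufficientDataError(
            f"{pattern}: no timepoints from {window} present")
    return results


def pattern_vs_tonic(
    df: pd.DataFrame,
    t: float,
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Paired comparison of each dynamic pattern's PWT vs tonic's at time t.

    Animals missing either session at t are dropped pairwise; the n of
    complete pairs is reported per contrast.
    """
    tonic = _wide_pwt(df, "tonic")
    if t not in tonic.columns:
        raise InsufficientDataError(f"tonic has no observations at t = {t}")
    results = []
    for pattern in TDP_PATTERNS:
        wide = _wide_pwt(df, pattern)
        if t not in wide.columns:
            continue
        joined = pd.concat(
            {"tdp": wide[t], "tonic": tonic[t]}, axis=1, join="inner")
        results.append(_paired_t(
            joined["tdp"].to_numpy(), joined["tonic"].to_numpy(),
            contrast="pattern_vs_tonic", pattern=pattern,
            timepoint=float(t), metric="pwt_g", alpha=alpha))
    return results


def extended_period_test(
    df: pd.DataFrame,
    pattern: str,
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Cohort-2 degradation test: PWT(75) and PWT(90) each vs PWT(60).

    Only animals on the 90-min design contribute.  A significant negative
    difference indicates loss of efficacy under continued stimulation.
    """
    sub = df[df["cohort"] == 2]
    if len(sub) == 0:
        raise InsufficientDataError("no cohort-2 (90-min design) data")
    wide = _wide_pwt(sub, pattern)
    if 60.0 not in wide.columns:
        raise InsufficientDataError(f"{pattern}: no t = 60 observations in cohort 2")
    results = []
    for t in (75.0, 90.0):
        if t not in wide.columns:
            continue
        results.append(_paired_t(
            wide[t].to_numpy(), wide[60.0].to_numpy(),
            contrast="extended_vs_60", pattern=pattern,
            timepoint=float(t), metric="pwt_g", alpha=alpha))
    if not results:
        raise InsufficientDataError(f"{pattern}: no t = 75/90 observations")
    return results


def _retained(fit_table: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in fit_table.columns:
        return fit_table[~fit_table["excluded"].astype(bool)]
    return fit_table


def slope_contrasts(
    fit_table: pd.DataFrame,
    metrics: tuple[str, ...] = ("slope1", "slope2"),
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Paired contrast of each dynamic pattern's slope (and other fitted
    metrics) against tonic, on QC-retained fits only.

    Animals whose tonic or dynamic fit was excluded contribute nothing to
    that pairing.  A contrast with fewer than three complete pairs is
    reported as unavailable (NaN statistic), not raised.
    """
    kept = _retained(fit_table)
    results = []
    for metric in metrics:
        wide = kept.pivot_table(index="animal_id", columns="pattern",
                                values=metric, aggfunc="first")
        for pattern in TDP_PATTERNS:
            if pattern not in wide.columns or "tonic" not in wide.columns:
                results.append(ComparisonResult(
                    contrast="slope_vs_tonic", pattern=pattern, timepoint=None,
                    metric=metric, n=0, statistic=float("nan"),
                    p_value=float("nan"), significant=False, degenerate=True,
                    note="no retained fits for one side of the contrast"))
                continue
            try:
                results.append(_paired_t(
                    wide[pattern].to_numpy(), wide["tonic"].to_numpy(),
                    contrast="slope_vs_tonic", pattern=pattern,
                    timepoint=None, metric=metric, alpha=alpha))
            except InsufficientDataError as exc:
                results.append(ComparisonResult(
                    contrast="slope_vs_tonic", pattern=pattern, timepoint=None,
                    metric=metric, n=0, statistic=float("nan"),
                    p_value=float("nan"), significant=False, degenerate=True,
                    note=str(exc)))
    return results


def summarize_patterns(
    fit_table: pd.DataFrame,
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("slope1", "slope2", "fwhm_norm", "dev_pct"),
) -> list[PatternSummary]:
    """Per-pattern mean +/- SEM of fitted metrics and of raw PWT per timepoint.

    Fitted metrics are summarized over retained fits; ``dev_pct`` is
    additionally summarized over *all* fits (key ``dev_pct_all``),
    mirroring the dual before/after-exclusion reporting.  Raw PWT
    summaries use all animals regardless of fit QC.
    """
    kept = _retained(fit_table)
    summaries = []
    for pattern in PATTERNS:
        all_fits = fit_table[fit_table["pattern"] == pattern]
        kept_fits = kept[kept["pattern"] == pattern]
        metric_ms: dict[str, tuple[float, float]] = {}
        for metric in metrics:
            metric_ms[metric] = _mean_sem(kept_fits[metric].to_numpy()) \
                if metric in kept_fits.columns else (float("nan"), float("nan"))
        if "dev_pct" in all_fits.columns:
            metric_ms["dev_pct_all"] = _mean_sem(all_fits["dev_pct"].to_numpy())
        wide = _wide_pwt(df, pattern)
        pwt_ms = {float(t): _mean_sem(wide[t].to_numpy()) for t in wide.columns}
        summaries.append(PatternSummary(
            pattern=pattern,
            n_fitted=int(len(all_fits)),
            n_retained=int(len(kept_fits)),
            metric_mean_sem=metric_ms,
            pwt_mean_sem=pwt_ms,
        ))
    return summaries


def pwt_omnibus(df: pd.DataFrame, window: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)):
    """Two-way repeated-measures ANOVA (pattern x time) on raw PWT.

    Restricted to animals with complete cells over the window; returns the
    statsmodels ANOVA table, or None if the design is too sparse.  This is
    contextual: cell-level comparisons are not gated on it.
    """
    from statsmodels.stats.anova import AnovaRM

    sub = df[df["time_min"].isin(window)]
    counts = sub.groupby("animal_id").size()
    complete = counts[counts == len(PATTERNS) * len(window)].index
    sub = sub[sub["animal_id"].isin(complete)]
    if sub["animal_id"].nunique() < MIN_PAIRS:
        return None
    try:
        return AnovaRM(sub, depvar="pwt_g", subject="animal_id",
                       within=["pattern", "time_min"]).fit().anova_table
    except (ValueError, np.linalg.LinAlgError):
        return None


def metric_mixed_model(fit_table: pd.DataFrame, metric: str):
    """Mixed-effects model of a fitted metric with animal as random intercept.

    Pattern enters as a fixed effect (tonic as reference); accommodates
    the unbalanced cells left by QC exclusion.  Returns the fitted
    statsmodels results, or None on a degenerate design.
    """
    import statsmodels.formula.api as smf

    kept = _retained(fit_table)[["animal_id", "pattern", metric]].dropna()
    if kept["pattern"].nunique() < 2 or kept["animal_id"].nunique() < MIN_PAIRS:
        return None
    data = kept.rename(columns={metric: "y"}).copy()
    data["pattern"] = pd.Categorical(data["pattern"],
                                     categories=list(PATTERNS))
    try:
        model = smf.mixedlm("y ~ pattern", data=data, groups=data["animal_id"])
        return model.fit(reml=True, method="lbfgs", maxiter=200)
    except (ValueError, np.linalg.LinAlgError):
        return None


def comparisons_to_frame(results) -> pd.DataFrame:
    """Tidy table of ComparisonResult rows."""
    return pd.DataFrame([{
        "contrast": r.contrast,
        "pattern": r.pattern,
        "timepoint": r.timepoint,
        "metric": r.metric,
        "n": r.n,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "significant": r.significant,
        "degenerate": r.degenerate,
        "note": r.note,
    } for r in results])
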
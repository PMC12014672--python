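"""End-to-end orchestration: simulate/load -> fit -> QC -> stats -> report."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InsufficientDataError, SchemaError
from .fitting import (
    OptimizerSettings,
    apply_exclusion,
    fit_double_sigmoid,
    normalize_timecourse,
)
from .io import frame_to_timecourses, read_pwt_csv
from .simulate import SimulationConfig, simulate_study
from .stats import (
    ALPHA,
    comparisons_to_frame,
    extended_period_test,
    metric_mixed_model,
    pattern_vs_tonic,
    pwt_omnibus,
    slope_contrasts,
    summarize_patterns,
    timepoint_vs_baseline,
)
from .fitting import PATTERNS

__all__ = ["PipelineConfig", "fit_study", "analyze_study", "run_pipeline"]

log = logging.getLogger("sigwash")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` (long-format PWT table) or ``simulation``
    should be provided; when both are None a default simulated study is
    run from ``seed``.
    """

    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    dev_threshold: float = 50.0
    scale_threshold: float = 0.1
    alpha: float = ALPHA
    outdir: str = "sigwash_out"
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.dev_threshold <= 0 or self.scale_threshold <= 0:
            raise ValueError("QC thresholds must be positive")


def fit_study(
    df: pd.DataFrame,
    settings: OptimizerSettings | None = None,
    dev_threshold: float = 50.0,
    scale_threshold: float = 0.1,
) -> pd.DataFrame:
    """Fit every (animal, pattern) series and apply QC.

    Returns one row per time course with the fitted parameters, SSD, SSR,
    Dev%, temporal metrics, convergence flag, and the QC flags.
    """
    rows = []
    for tc in frame_to_timecourses(df):
        fr = fit_double_sigmoid(normalize_timecourse(tc), settings=settings)
        qc = apply_exclusion(fr, dev_threshold=dev_threshold,
                             scale_threshold=scale_threshold)
        log.debug("fit %s/%s: I=%.3f dev=%.1f%% excluded=%s",
                  tc.animal_id, tc.pattern, fr.params.I, fr.dev_pct, qc.excluded)
        rows.append({
            "animal_id": tc.animal_id,
            "pattern": tc.pattern,
            "cohort": tc.cohort,
            "t_stim_min": tc.t_stim_min,
            "I": fr.params.I,
            "a1": fr.params.a1,
            "a2": fr.params.a2,
            "t_mid1": fr.params.t_mid1,
            "t_mid2": fr.params.t_mid2,
            "ssd": fr.ssd,
            "ssr": fr.ssr,
            "dev_pct": fr.dev_pct,
            "slope1": fr.metrics.slope1,
            "slope2": fr.metrics.slope2,
            "fwhm_norm": fr.metrics.fwhm_norm,
            "converged": fr.converged,
            "n_points": fr.n_points,
            "excluded": qc.excluded,
            "high_deviation": qc.high_deviation,
            "small_scale": qc.small_scale,
            "negative_scale": qc.negative_scale,
        })
    return pd.DataFrame(rows)


def analyze_study(
    df: pd.DataFrame,
    fit_table: pd.DataFrame,
    alpha: float = ALPHA,
) -> dict:
    """Run the full comparison structure on a fitted study.

    Returns a dict with the tidy comparison table, the per-pattern
    summary table, and the omnibus model results (which are reported for
    context, not used to gate the cell-level comparisons).
    """
    comparisons = []
    for pattern in PATTERNS:
        try:
            comparisons += timepoint_vs_baseline(df, pattern, alpha=alpha)
        except InsufficientDataError as exc:
            log.warning("timepoint_vs_baseline skipped: %s", exc)
    for t in (15.0, 30.0, 45.0, 60.0):
        try:
            comparisons += pattern_vs_tonic(df, t, alpha=alpha)
        except InsufficientDataError as exc:
            log.warning("pattern_vs_tonic skipped at t=%s: %s", t, exc)
    if (df["cohort"] == 2).any():
        for pattern in PATTERNS:
            try:
                comparisons += extended_period_test(df, pattern, alpha=alpha)
            except InsufficientDataError as exc:
                log.warning("extended_period_test skipped: %s", exc)
    comparisons += slope_contrasts(
        fit_table, metrics=("slope1", "slope2", "fwhm_norm"), alpha=alpha)

    summaries = summarize_patterns(fit_table, df)
    summary_rows = []
    for s in summaries:
        row = {"pattern": s.pattern, "n_fitted": s.n_fitted,
               "n_retained": s.n_retained}
        for metric, (m, sem) in s.metric_mean_sem.items():
            row[f"{metric}_mean"] = m
            row[f"{metric}_sem"] = sem
        for t, (m, sem) in sorted(s.pwt_mean_sem.items()):
            row[f"pwt_{int(t)}_mean"] = m
            row[f"pwt_{int(t)}_sem"] = sem
        summary_rows.append(row)

    omnibus = pwt_omnibus(df)
    mixed = {m: metric_mixed_model(fit_table, m) for m in ("slope1", "slope2")}

    return {
        "comparisons": comparisons_to_frame(comparisons),
        "pattern_summary": pd.DataFrame(summary_rows),
        "omnibus_anova": omnibus,
        "mixed_models": mixed,
    }


def _write_report(path: Path, fit_table: pd.DataFrame, results: dict) -> None:
    lines = ["sigwash analysis report", "=" * 24, ""]
    n = len(fit_table)
    n_exc = int(fit_table["excluded"].sum())
    lines.append(f"Fitted time courses: {n}; excluded by QC: {n_exc}")
    lines.append("")
    lines.append("Per-pattern summary (retained fits):")
    lines.append(results["pattern_summary"].to_string(index=False,
                                                      float_format="%.4g"))
    lines.append("")
    lines.append("Comparisons (paired two-sided, uncorrected):")
    lines.append(results["comparisons"].to_string(index=False,
                                                  float_format="%.4g"))
    if results["omnibus_anova"] is not None:
        lines.append("")
        lines.append("Omnibus repeated-measures ANOVA (pattern x time, raw PWT):")
        lines.append(results["omnibus_anova"].to_string(float_format="%.4g"))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _plot_study(outdir: Path, df: pd.DataFrame, fit_table: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import SigmoidParams, double_sigmoid

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pattern, grp in df.groupby("pattern"):
        g = grp.groupby("time_min")["pwt_g"].agg(["mean", "sem"])
        ax.errorbar(g.index, g["mean"], yerr=g["sem"], marker="o",
                    capsize=3, label=pattern)
    ax.set_xlabel("time since stimulation onset (min)")
    ax.set_ylabel("PWT (g), mean ± SEM")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "pwt_group_means.png", dpi=150)
    plt.close(fig)

    # one example animal with fitted curves overlaid
    animal = df["animal_id"].iloc[0]
    sub = df[df["animal_id"] == animal]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    tt = np.linspace(0, sub["time_min"].max(), 300)
    for pattern, grp in sub.groupby("pattern"):
        base = grp.sort_values("time_min")["pwt_g"].iloc[0]
        row = fit_table[(fit_table["animal_id"] == animal)
                        & (fit_table["pattern"] == pattern)]
        pts = ax.plot(grp["time_min"], grp["pwt_g"], "o", label=pattern)
        if len(row):
            p = SigmoidParams(I=row["I"].iloc[0], a1=row["a1"].iloc[0],
                              a2=row["a2"].iloc[0], t_mid1=row["t_mid1"].iloc[0],
                              t_mid2=row["t_mid2"].iloc[0])
            ax.plot(tt, base * (1.0 + double_sigmoid(tt, p)), "-",
                    color=pts[0].get_color(), alpha=0.7)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("PWT (g)")
    ax.set_title(f"animal {animal}: raw points and fitted curves")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "example_fits.png", dpi=150)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute simulate/load -> fit -> QC -> stats -> report.

    Writes dataset, fit table, comparisons, pattern summary, report and a
    run manifest into ``cfg.outdir``; returns the in-memory artifacts.
    Idempotent for a fixed config and seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth_frame = None
    if cfg.input_csv is not None:
        log.info("reading %s", cfg.input_csv)
        df = read_pwt_csv(cfg.input_csv)
        source = {"input_csv": str(cfg.input_csv)}
    else:
        sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
        log.info("simulating study: %d + %d animals, seed %d",
                 sim.n_cohort1, sim.n_cohort2, sim.seed)
        ds = simulate_study(sim)
        df = ds.to_frame()
        truth_frame = ds.truth_frame()
        source = {
            "simulated": True,
            "n_cohort1": sim.n_cohort1,
            "n_cohort2": sim.n_cohort2,
            "baseline_mean": sim.baseline_mean,
            "baseline_sd": sim.baseline_sd,
            "noise_sd": sim.noise_sd,
            "quantize": sim.quantize,
            "seed": sim.seed,
        }
    if len(df) == 0:
        raise SchemaError("empty dataset")

    fit_table = fit_study(df, settings=cfg.optimizer,
                          dev_threshold=cfg.dev_threshold,
                          scale_threshold=cfg.scale_threshold)
    results = analyze_study(df, fit_table, alpha=cfg.alpha)

    # %.17g keeps the raw thresholds bit-exact through a CSV round trip,
    # so re-fitting the written dataset reproduces the fit table exactly
    df.to_csv(outdir / "dataset.csv", index=False, float_format="%.17g")
    if truth_frame is not None:
        truth_frame.to_csv(outdir / "truth.csv", index=False)
    fit_table.to_csv(outdir / "fits.csv", index=False)
    results["comparisons"].to_csv(outdir / "comparisons.csv", index=False)
    results["pattern_summary"].to_csv(outdir / "pattern_summary.csv", index=False)
    _write_report(outdir / "report.txt", fit_table, results)

    manifest = {
        "sigwash_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "qc": {"dev_threshold": cfg.dev_threshold,
               "scale_threshold": cfg.scale_threshold},
        "optimizer": cfg.optimizer.to_dict(),
        "source": source,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    if cfg.make_plots:
        _plot_study(outdir, df, fit_table)

    results.update({"dataset": df, "fit_table": fit_table, "outdir": outdir})
    return results
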
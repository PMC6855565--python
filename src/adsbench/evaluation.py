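"""Meta-evaluation of metrics against the dilution series.

For each metric, scoring every AP set of the series yields the output
matrix ``Output[i, j] = Metric(T, APS_ij)``.  Two summary statistics
quantify how good the metric itself is:

``RC``
    Spearman rank correlation between all output cells and their signal
    levels — how well the metric recovers the planted signal ordering;
``FPS``
    false-positive signal — the signal level at which each decoy FP set's
    score crosses the piecewise-linear curve of per-level output medians,
    maximised over FP sets and clipped to [0, 1] — how easily the metric is
    fooled by predictions carrying no information.

A good metric has RC near 1 and FPS near 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, spearmanr

from .annotations import AnnotationTable, propagate_truth
from .dilution import ADSSeries
from .metrics import MetricSpec, score_metric
from .ontology import ICTable, OntologyGraph

__all__ = [
    "OutputMatrix",
    "EvalSummary",
    "output_matrix",
    "rank_correlation",
    "fp_signal",
    "fps",
    "evaluate_metric",
    "summary_table",
    "plot_dilution",
    "plot_rc_fps",
]

log = logging.getLogger(__name__)


@dataclass
class OutputMatrix:
    """Metric scores per (replicate, signal level); NaN marks failed cells."""

    values: np.ndarray  # shape (N, |SR|)
    signal_levels: tuple[float, ...]
    metric: MetricSpec

    def medians(self) -> np.ndarray:
        return np.nanmedian(self.values, axis=0)


@dataclass
class EvalSummary:
    """Per-metric meta-evaluation result."""

    metric: str
    rc: float
    fps: float
    per_fp_signal: dict[str, float] = field(default_factory=dict)
    fp_scores: dict[str, float] = field(default_factory=dict)


def output_matrix(
    graph: OntologyGraph,
    truth: AnnotationTable,
    series: ADSSeries,
    spec: MetricSpec,
    ic_table: ICTable | None = None,
    max_missing: float = 0.1,
    **score_kwargs,
) -> OutputMatrix:
    """Score every AP set of the series with one metric.

    Cells where the metric fails are marked missing (NaN) and logged; more
    than ``max_missing`` missing cells aborts the run.
    """
    truth_prop = truth if truth.propagated else propagate_truth(graph, truth)
    n = series.n_replicates
    m = len(series.signal_levels)
    values = np.full((n, m), np.nan)
    n_failed = 0
    for (i, j), ap in series.ap_sets.items():
        try:
            values[i, j] = score_metric(
                spec, graph, truth, truth_prop, ap, ic_table, **score_kwargs
            )
        except Exception as exc:
            n_failed += 1
            log.warning("%s failed on AP set (%d, %d): %s", spec.name, i, j, exc)
    if n_failed > max_missing * n * m:
        raise RuntimeError(
            f"{spec.name}: {n_failed}/{n * m} AP sets failed to score"
        )
    return OutputMatrix(values, series.signal_levels, spec)


def rank_correlation(out: OutputMatrix, method: str = "spearman") -> float:
    """Rank correlation between pooled output cells and their signal levels."""
    signals = np.tile(out.signal_levels, (out.values.shape[0], 1)).ravel()
    values = out.values.ravel()
    keep = ~np.isnan(values)
    values, signals = values[keep], signals[keep]
    if len(np.unique(signals)) < 2:
        raise ValueError("need at least two distinct signal levels")
    if np.all(values == values[0]):
        log.warning("%s: zero variance in scores; RC set to 0", out.metric.name)
        return 0.0
    if method == "spearman":
        rho = spearmanr(values, signals).statistic
    elif method == "kendall":
        rho = kendalltau(values, signals).statistic
    else:
        raise ValueError(f"unknown rank correlation method: {method}")
    return float(rho)


def fp_signal(fp_score: float, out: OutputMatrix) -> float:
    """Signal level at which an FP set's score crosses the median curve.

    The per-level medians define a piecewise-linear curve over signal; the
    *largest* signal where the horizontal line at ``fp_score`` crosses it is
    returned (worst case for the metric), clipped to [0, 1]: a score above
    every median maps to 1, below every median to 0.
    """
    order = np.argsort(out.signal_levels)
    x = np.asarray(out.signal_levels)[order]
    m = out.medians()[order]
    if fp_score >= m[-1]:
        return 1.0
    for i in range(len(x) - 1, 0, -1):  # scan segments from high signal down
        lo, hi = m[i - 1], m[i]
        if min(lo, hi) <= fp_score <= max(lo, hi):
            if hi == lo:
                return float(x[i])  # flat segment: largest crossing
            frac = (fp_score - lo) / (hi - lo)
            return float(x[i - 1] + frac * (x[i] - x[i - 1]))
    return 0.0


def fps(per_fp: dict[str, float]) -> float:
    """Final FP score: the worst (maximum) signal over all FP sets."""
    if not per_fp:
        raise ValueError("no FP sets evaluated")
    return max(per_fp.values())


def evaluate_metric(
    graph: OntologyGraph,
    truth: AnnotationTable,
    series: ADSSeries,
    spec: MetricSpec,
    fp_sets: dict[str, "PredictionSet"],
    ic_table: ICTable | None = None,
    rc_method: str = "spearman",
    **score_kwargs,
) -> tuple[EvalSummary, OutputMatrix]:
    """Full meta-evaluation of one metric: output matrix, RC and FPS."""
    out = output_matrix(graph, truth, series, spec, ic_table, **score_kwargs)
    rc = rank_correlation(out, method=rc_method)
    truth_prop = truth if truth.propagated else propagate_truth(graph, truth)
    per_fp_score: dict[str, float] = {}
    per_fp_sig: dict[str, float] = {}
    for name, fp_set in fp_sets.items():
        score = score_metric(
            spec, graph, truth, truth_prop, fp_set, ic_table, **score_kwargs
        )
        per_fp_score[name] = score
        per_fp_sig[name] = fp_signal(score, out)
    summary = EvalSummary(
        metric=spec.name,
        rc=rc,
        fps=fps(per_fp_sig) if per_fp_sig else float("nan"),
        per_fp_signal=per_fp_sig,
        fp_scores=per_fp_score,
    )
    return summary, out


def summary_table(
    results: list[EvalSummary], t_rc: float = 0.95, t_fps: float = 0.16
) -> pd.DataFrame:
    """Tabulate RC / FPS with pass flags at the selection thresholds."""
    if not results:
        raise ValueError("no metrics evaluated")
    rows = []
    for r in results:
        row = {
            "metric": r.metric,
            "RC": r.rc,
            "FPS": r.fps,
            "RC_pass": r.rc > t_rc,
            "FPS_pass": r.fps < t_fps,
        }
        for name, sig in sorted(r.per_fp_signal.items()):
            row[f"fp_signal_{name}"] = sig
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

_FP_COLOURS = {"naive": "red", "small": "blue", "random": "green"}


def plot_dilution(
    out: OutputMatrix,
    fp_lines: dict[str, float] | None = None,
    path=None,
    rc: float | None = None,
    fps_value: float | None = None,
):
    """Boxplot of scores per signal level with FP sets as horizontal lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(out.signal_levels)[::-1]  # signal descending, 1 -> 0
    data = [out.values[:, j][~np.isnan(out.values[:, j])] for j in order]
    labels = [f"{out.signal_levels[j]:g}" for j in order]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(data, tick_labels=labels)
    for name, score in (fp_lines or {}).items():
        ax.axhline(
            score, color=_FP_COLOURS.get(name, "grey"), lw=1.2, label=name
        )
    title = out.metric.name
    annotations = []
    if rc is not None:
        annotations.append(f"RC={rc:.3f}")
    if fps_value is not None:
        annotations.append(f"FPS={fps_value:.3f}")
    if annotations:
        title += "  (" + ", ".join(annotations) + ")"
    ax.set_title(title)
    ax.set_xlabel("ADS signal")
    ax.set_ylabel("metric score")
    if fp_lines:
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_rc_fps(results: list[EvalSummary], path=None):
    """Scatter of RC against FPS; good metrics sit in the upper-left corner."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for r in results:
        ax.scatter(r.fps, r.rc, s=12, color="tab:blue")
        ax.annotate(r.metric, (r.fps, r.rc), fontsize=6, alpha=0.8)
    ax.set_xlabel("FPS (false positive signal)")
    ax.set_ylabel("RC (rank correlation)")
    ax.set_xlim(-0.05, 1.05)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
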
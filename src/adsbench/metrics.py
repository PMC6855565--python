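"""Evaluation metrics for GO prediction sets.

Three metric families are implemented, each scoring a prediction set
against a truth set:

* **rank-based** — AUC-ROC and AUC-PR, each in unstructured (US, pooled
  gene–term pairs), gene-centric (GC, averaged per gene) and term-centric
  (TC, averaged per term) form;
* **group-based** — F_max, plain Jaccard (SimUI), information-content
  weighted Jaccard (SimGIC gene-centric, SimGIC2 unstructured) and S_min
  (remaining uncertainty / misinformation), with either marginal (``ic``)
  or parent-conditional (``ic2``) weights;
* **semantic** — Resnik, Lin and ancestor-Jaccard pairwise term
  similarities, collapsed per gene by one of six summation rules (A–F) over
  the predicted-vs-correct similarity matrix.

Group and rank metrics operate on ancestor-propagated inputs and sweep a
threshold over the distinct prediction scores, reporting the best value;
semantic metrics consume unpropagated (direct) annotations because the
similarity measure itself accounts for the hierarchy.  S_min is
sign-flipped on return so every metric is oriented higher-is-better.

The candidate universe for metrics that need true negatives (the AUCs) is
the genes of the truth set crossed with every term occurring in the truth
or the predictions; (gene, term) pairs without an explicit prediction rank
below all scored pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .annotations import AnnotationTable, PredictionSet, propagate_predictions
from .ontology import ICTable, OntologyGraph

__all__ = [
    "MetricError",
    "MetricSpec",
    "confusion_counts",
    "fmax",
    "smin",
    "simgic",
    "jaccard_metric",
    "auc_roc",
    "auc_pr",
    "pairwise_similarity",
    "summarize_matrix",
    "semantic_metric",
    "metric_registry",
    "score_metric",
]


class MetricError(ValueError):
    """Raised when a metric is undefined on its input."""


# ---------------------------------------------------------------------------
# Metric registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSpec:
    """One entry of the metric battery."""

    name: str
    family: str                      # auc_roc | auc_pr | fmax | jaccard | simgic | smin | semantic
    structuring: str = "n/a"         # US | GC | TC | n/a
    ic_variant: str = "none"         # none | ic | ic2
    measure: str = "n/a"             # semantic: resnik | lin | ajacc; smin: 1 | 2
    summation: str = "n/a"           # semantic: A..F
    orientation: str = "higher_better"
    propagate_predictions: bool = True


def metric_registry() -> list[MetricSpec]:
    """Enumerate the full metric battery."""
    specs: list[MetricSpec] = []
    for family in ("auc_roc", "auc_pr"):
        label = "AUC-ROC" if family == "auc_roc" else "AUC-PR"
        for st in ("US", "GC", "TC"):
            specs.append(MetricSpec(f"{st} {label}", family, structuring=st))
    specs.append(MetricSpec("Fmax", "fmax", structuring="GC"))
    for st in ("US", "GC"):
        specs.append(MetricSpec(f"{st} Jacc", "jaccard", structuring=st))
    for ic in ("ic", "ic2"):
        specs.append(
            MetricSpec(f"{ic} SimGIC", "simgic", structuring="GC", ic_variant=ic)
        )
        specs.append(
            MetricSpec(f"{ic} SimGIC2", "simgic", structuring="US", ic_variant=ic)
        )
        for variant in ("1", "2"):
            specs.append(
                MetricSpec(
                    f"{ic} Smin{variant}",
                    "smin",
                    structuring="US" if variant == "1" else "GC",
                    ic_variant=ic,
                    measure=variant,
                    orientation="lower_better",
                )
            )
    for measure in ("Resnik", "Lin", "AJacc"):
        for method in "ABCDEF":
            specs.append(
                MetricSpec(
                    f"{measure} {method}",
                    "semantic",
                    ic_variant="ic",
                    measure=measure.lower(),
                    summation=method,
                    propagate_predictions=False,
                )
            )
    return specs


# ---------------------------------------------------------------------------
# Shared kernels
# ---------------------------------------------------------------------------

def _require_propagated(truth: AnnotationTable, pred: PredictionSet) -> None:
    if not truth.propagated or not pred.propagated:
        raise MetricError("group/rank metrics require ancestor-propagated inputs")


def _sorted_rows(pred: PredictionSet) -> tuple[list[str], list[str], np.ndarray]:
    """Prediction rows sorted by descending score (deduped by construction)."""
    df = pred.df.sort_values(
        ["score", "gene", "term"], ascending=[False, True, True], kind="mergesort"
    )
    return list(df["gene"]), list(df["term"]), df["score"].to_numpy(dtype=float)


def _boundaries(scores: np.ndarray) -> list[int]:
    """End index (exclusive) of each distinct-score group, scores descending."""
    ends = list(np.nonzero(np.diff(scores) != 0)[0] + 1)
    ends.append(len(scores))
    return ends


def confusion_counts(
    truth: AnnotationTable,
    pred: PredictionSet,
    th: float,
    scope: str = "pooled",
):
    """TP/FP/FN (and TN for the pooled scope) at a score threshold.

    ``pooled`` returns a single (TP, FP, FN, TN) over the candidate universe
    (truth genes × union of truth/prediction terms); ``per_gene`` and
    ``per_term`` return dicts of (TP, FP, FN) keyed by gene / term.
    """
    _require_propagated(truth, pred)
    truth_pairs = set(zip(truth.df["gene"], truth.df["term"]))
    sel = pred.df[pred.df["score"] >= th]
    pred_pairs = set(zip(sel["gene"], sel["term"]))
    if scope == "pooled":
        tp = len(truth_pairs & pred_pairs)
        fp = len(pred_pairs - truth_pairs)
        fn = len(truth_pairs - pred_pairs)
        genes = {g for g, _ in truth_pairs}
        terms = {t for _, t in truth_pairs} | {t for _, t in pred_pairs}
        tn = len(genes) * len(terms) - tp - fp - fn
        return tp, fp, fn, tn
    if scope in ("per_gene", "per_term"):
        pos = 0 if scope == "per_gene" else 1
        keys = {p[pos] for p in truth_pairs | pred_pairs}
        out = {}
        for key in sorted(keys):
            t_k = {p for p in truth_pairs if p[pos] == key}
            p_k = {p for p in pred_pairs if p[pos] == key}
            out[key] = (len(t_k & p_k), len(p_k - t_k), len(t_k - p_k))
        return out
    raise ValueError(f"unknown scope: {scope}")


# ---------------------------------------------------------------------------
# F_max
# ---------------------------------------------------------------------------

def fmax(truth: AnnotationTable, pred: PredictionSet) -> float:
    """Maximum over thresholds of the harmonic mean of precision and recall.

    CAFA convention: precision is averaged over genes with at least one
    prediction above the threshold, recall over all truth genes.
    """
    _require_propagated(truth, pred)
    if not len(pred):
        return 0.0
    truth_sets = truth.terms_by_gene()
    genes = sorted(set(truth_sets) | set(pred.df["gene"].unique()))
    g_index = {g: i for i, g in enumerate(genes)}
    n_truth = np.array([len(truth_sets.get(g, ())) for g in genes], dtype=float)
    truth_gene_mask = n_truth > 0

    p_genes, p_terms, scores = _sorted_rows(pred)
    tp = np.zeros(len(genes))
    n_pred = np.zeros(len(genes))
    best = 0.0
    start = 0
    for end in _boundaries(scores):
        for g, t in zip(p_genes[start:end], p_terms[start:end]):
            gi = g_index[g]
            n_pred[gi] += 1
            if t in truth_sets.get(g, ()):
                tp[gi] += 1
        start = end
        has_pred = n_pred > 0
        precision = float(np.mean(tp[has_pred] / n_pred[has_pred]))
        recall = float(np.mean(tp[truth_gene_mask] / n_truth[truth_gene_mask]))
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best


# ---------------------------------------------------------------------------
# S_min
# ---------------------------------------------------------------------------

def smin(
    truth: AnnotationTable,
    pred: PredictionSet,
    ic_table: ICTable,
    variant: str = "1",
    ic_variant: str = "ic",
) -> float:
    """Sign-flipped S_min (0 is perfect, more negative is worse).

    At each threshold, remaining uncertainty ``ru`` is the IC mass of truth
    terms not predicted and misinformation ``mi`` the IC mass of predicted
    terms not in the truth.  Variant "1" combines across-gene averages as
    sqrt(ru² + mi²); variant "2" averages the per-gene sqrt.  The minimum
    over thresholds is returned negated (higher is better).
    """
    _require_propagated(truth, pred)
    w = ic_table.weights(ic_variant)

    def weight(term: str) -> float:
        try:
            return w[term]
        except KeyError:
            raise MetricError(f"no information content for term {term}") from None

    truth_sets = truth.terms_by_gene()
    genes = sorted(set(truth_sets) | set(pred.df["gene"].unique()))
    g_index = {g: i for i, g in enumerate(genes)}
    ru = np.array(
        [sum(weight(t) for t in truth_sets.get(g, ())) for g in genes]
    )
    mi = np.zeros(len(genes))

    def combined() -> float:
        if variant == "1":
            return math.hypot(float(ru.mean()), float(mi.mean()))
        if variant == "2":
            return float(np.hypot(ru, mi).mean())
        raise ValueError(f"unknown S_min variant: {variant}")

    best = combined()  # threshold above all scores: nothing predicted
    p_genes, p_terms, scores = _sorted_rows(pred)
    start = 0
    for end in _boundaries(scores):
        for g, t in zip(p_genes[start:end], p_terms[start:end]):
            gi = g_index[g]
            if t in truth_sets.get(g, ()):
                ru[gi] -= weight(t)
            else:
                mi[gi] += weight(t)
        start = end
        best = min(best, combined())
    return -best


# ---------------------------------------------------------------------------
# SimGIC / Jaccard
# ---------------------------------------------------------------------------

def simgic(
    truth: AnnotationTable,
    pred: PredictionSet,
    ic_table: ICTable,
    structuring: str = "GC",
    ic_variant: str = "ic",
) -> float:
    """IC-weighted Jaccard between predicted and true term sets, max over th.

    GC computes the weighted Jaccard per gene and averages; US (SimGIC2)
    pools all (gene, term) pairs.  With unit weights this is the plain
    Jaccard metric (SimUI).
    """
    _require_propagated(truth, pred)
    w = ic_table.weights(ic_variant)

    def weight(term: str) -> float:
        try:
            return w[term]
        except KeyError:
            raise MetricError(f"no information content for term {term}") from None

    truth_sets = truth.terms_by_gene()
    genes = sorted(set(truth_sets) | set(pred.df["gene"].unique()))
    g_index = {g: i for i, g in enumerate(genes)}
    truth_ic = np.array(
        [sum(weight(t) for t in truth_sets.get(g, ())) for g in genes]
    )
    inter = np.zeros(len(genes))
    extra = np.zeros(len(genes))  # IC of predicted-only terms

    def score_now() -> float:
        union = truth_ic + extra
        if structuring == "GC":
            with np.errstate(invalid="ignore", divide="ignore"):
                per_gene = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
            return float(per_gene.mean()) if len(per_gene) else 0.0
        if structuring == "US":
            total = float(union.sum())
            return float(inter.sum()) / total if total > 0 else 0.0
        raise ValueError(f"unknown structuring: {structuring}")

    best = 0.0  # empty prediction boundary
    p_genes, p_terms, scores = _sorted_rows(pred)
    start = 0
    for end in _boundaries(scores):
        for g, t in zip(p_genes[start:end], p_terms[start:end]):
            gi = g_index[g]
            if t in truth_sets.get(g, ()):
                inter[gi] += weight(t)
            else:
                extra[gi] += weight(t)
        start = end
        best = max(best, score_now())
    return best


def jaccard_metric(
    truth: AnnotationTable, pred: PredictionSet, structuring: str = "GC"
) -> float:
    """Unweighted Jaccard (SimUI): SimGIC with unit information content."""
    terms = set(truth.df["term"]) | set(pred.df["term"])
    return simgic(truth, pred, ICTable.uniform(terms), structuring=structuring)


# ---------------------------------------------------------------------------
# AUC-ROC / AUC-PR
#
# Both curves are built from the explicit prediction list only: candidate
# points are the predicted (gene, term) pairs, labelled positive when the
# pair is in the propagated truth, and the area is accumulated step-wise
# over the descending distinct scores.  Truth pairs never predicted do not
# enter a curve; in the gene-/term-centric structurings a unit without
# usable predictions scores 0.  A consequence worth knowing: a unit whose
# scores are all identical collapses to a single curve point whose step
# area is 1 for ROC (and the class prevalence for PR, unless
# ``zero_when_constant``), which is precisely why constant-score decoy sets
# can saturate US/GC AUC-ROC.
# ---------------------------------------------------------------------------

def _explicit_pairs(truth: AnnotationTable, pred: PredictionSet):
    """Scores and truth labels of the explicit predicted pairs."""
    _require_propagated(truth, pred)
    truth_pairs = set(zip(truth.df["gene"], truth.df["term"]))
    df = pred.df
    labels = np.fromiter(
        ((g, t) in truth_pairs for g, t in zip(df["gene"], df["term"])),
        dtype=bool,
        count=len(df),
    )
    return (
        df["gene"].to_numpy(),
        df["term"].to_numpy(),
        df["score"].to_numpy(dtype=float),
        labels,
    )


def _step_points(y: np.ndarray, s: np.ndarray):
    """Cumulative (TP, FP) at each distinct-score boundary, descending."""
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order].astype(float)
    ends = np.nonzero(np.append(np.diff(s_sorted) != 0, True))[0]
    tp = np.cumsum(y_sorted)[ends]
    n_at = ends + 1.0
    return tp, n_at - tp  # TP, FP at each boundary


def _roc_step(y: np.ndarray, s: np.ndarray, strict: bool = False) -> float:
    """Step-wise area under the ROC curve of one prediction list.

    Ties share a threshold, so a fully tied list is a single point whose
    step area is 1.  ``strict`` raises when a class is missing (US scope);
    otherwise such units score 0 (no positives / no false-positive axis) or
    1 (no negatives among the predictions).
    """
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        if strict:
            raise MetricError("AUC-ROC undefined: need both classes")
        return 0.0 if n_pos == 0 else 1.0
    tp, fp = _step_points(y, s)
    tpr = tp / n_pos
    d_fpr = np.diff(np.concatenate(([0.0], fp))) / n_neg
    return float(np.sum(tpr * d_fpr))


def _auc_midrank(y: np.ndarray, s: np.ndarray) -> float:
    """Mann–Whitney AUC with midrank tie handling (cross-check variant)."""
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: need both classes")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _pr_step(
    y: np.ndarray, s: np.ndarray, zero_when_constant: bool, strict: bool = False
) -> float:
    """Step-wise area under the precision–recall curve.

    When every score in scope is identical the curve collapses to a single
    point whose area is the class prevalence — or 0 under the
    ``zero_when_constant`` correction (an uninformative constant predictor
    should not be rewarded for class imbalance).
    """
    n_pos = int(y.sum())
    if n_pos == 0:
        if strict:
            raise MetricError("AUC-PR undefined: no positives in scope")
        return 0.0
    if s.max() == s.min():
        return 0.0 if zero_when_constant else n_pos / y.size
    tp, fp = _step_points(y, s)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    d_recall = np.diff(np.concatenate(([0.0], recall)))
    return float(np.sum(d_recall * precision))


def _grouped_auc(truth, pred, structuring, unit_fn) -> float:
    """Apply a per-unit curve area across the US / GC / TC structurings.

    GC averages over the truth genes, TC over the propagated truth terms;
    units with no explicit predictions score 0.
    """
    genes, terms, scores, labels = _explicit_pairs(truth, pred)
    if structuring == "US":
        if len(scores) == 0:
            raise MetricError("no predictions to rank")
        return unit_fn(labels, scores, True)
    if structuring == "GC":
        units = truth.genes
        keys = genes
    elif structuring == "TC":
        units = sorted(set(truth.df["term"]))
        keys = terms
    else:
        raise ValueError(f"unknown structuring: {structuring}")
    by_unit: dict[str, list[int]] = {u: [] for u in units}
    for i, k in enumerate(keys):
        if k in by_unit:
            by_unit[k].append(i)
    values = []
    for u in units:
        idx = by_unit[u]
        if not idx:
            values.append(0.0)  # nothing predicted for this unit
            continue
        values.append(unit_fn(labels[idx], scores[idx], False))
    if not values:
        raise MetricError("no units to evaluate")
    return float(np.mean(values))


def auc_roc(
    truth: AnnotationTable,
    pred: PredictionSet,
    structuring: str = "US",
    ties: str = "step",
) -> float:
    """AUC-ROC of the prediction list, pooled or per gene / per term.

    ``ties="step"`` (default) integrates the step curve over distinct
    scores; ``ties="midrank"`` is the Mann–Whitney estimator (identical
    when scores are distinct).
    """
    if ties == "step":
        fn = lambda y, s, strict: _roc_step(y, s, strict)
    elif ties == "midrank":
        fn = lambda y, s, strict: _auc_midrank(y, s)
    else:
        raise ValueError(f"unknown tie policy: {ties}")
    return _grouped_auc(truth, pred, structuring, fn)


def auc_pr(
    truth: AnnotationTable,
    pred: PredictionSet,
    structuring: str = "US",
    zero_when_constant: bool = True,
) -> float:
    """AUC-PR by step-wise summation; see :func:`_pr_step`."""
    return _grouped_auc(
        truth,
        pred,
        structuring,
        lambda y, s, strict: _pr_step(y, s, zero_when_constant, strict),
    )


# ---------------------------------------------------------------------------
# Semantic similarity metrics
# ---------------------------------------------------------------------------

def pairwise_similarity(
    graph: OntologyGraph,
    ic_table: ICTable,
    measure: str,
    t1: str,
    t2: str,
    ic_variant: str = "ic",
) -> float:
    """Pairwise term similarity: Resnik, Lin or ancestor-Jaccard.

    Resnik is the IC of the most informative common ancestor (MICA); Lin
    normalises it by the mean IC of the two terms; AJacc is the Jaccard
    similarity of the two ancestor closures.
    """
    if measure == "ajacc":
        return graph.term_jaccard(t1, t2)
    w = ic_table.weights(ic_variant)
    common = graph.ancestors(t1) & graph.ancestors(t2)
    mica_ic = max((w.get(t, 0.0) for t in common), default=0.0)
    if measure == "resnik":
        return mica_ic
    if measure == "lin":
        denom = w.get(graph.canonical(t1), 0.0) + w.get(graph.canonical(t2), 0.0)
        return 2.0 * mica_ic / denom if denom > 0 else 0.0
    raise ValueError(f"unknown similarity measure: {measure}")


def summarize_matrix(m: np.ndarray, method: str) -> float:
    """Collapse a predicted × correct similarity matrix to one score.

    A: mean of the matrix; B: mean of column maxima (best hit per correct
    term); C: mean of row maxima (best hit per predicted term); D: (B+C)/2;
    E: min(B, C); F: mean of the concatenated row and column maxima.
    """
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        raise ValueError("empty similarity matrix")
    if method == "A":
        return float(m.mean())
    col_max = m.max(axis=0)  # best hit per correct term
    row_max = m.max(axis=1)  # best hit per predicted term
    b, c = float(col_max.mean()), float(row_max.mean())
    if method == "B":
        return b
    if method == "C":
        return c
    if method == "D":
        return (b + c) / 2
    if method == "E":
        return min(b, c)
    if method == "F":
        return float((row_max.sum() + col_max.sum()) / (len(row_max) + len(col_max)))
    raise ValueError(f"unknown summation method: {method}")


def semantic_metric(
    truth: AnnotationTable,
    pred: PredictionSet,
    graph: OntologyGraph,
    ic_table: ICTable,
    measure: str,
    method: str,
    ic_variant: str = "ic",
) -> float:
    """Semantic-similarity metric: summation rule ``method`` over measure.

    Operates on direct (unpropagated) annotations.  For each threshold over
    the descending distinct prediction scores, each gene's similarity matrix
    between its predicted terms at that threshold and its correct terms is
    summarised with ``method``; gene scores are averaged (genes with no
    prediction above the threshold contribute 0) and the maximum over
    thresholds is returned.
    """
    if pred.propagated:
        raise MetricError("semantic metrics require unpropagated predictions")
    truth_sets = {g: sorted(ts) for g, ts in truth.terms_by_gene().items()}
    genes = sorted(truth_sets)
    if not genes:
        raise MetricError("empty truth set")

    sim_cache: dict[tuple[str, str], float] = {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        v = sim_cache.get(key)
        if v is None:
            v = pairwise_similarity(graph, ic_table, measure, a, b, ic_variant)
            sim_cache[key] = v
        return v

    # per-gene predictions sorted by descending score
    by_gene: dict[str, list[tuple[float, str]]] = {g: [] for g in genes}
    for g, t, sc in zip(pred.df["gene"], pred.df["term"], pred.df["score"]):
        if g in by_gene:
            by_gene[g].append((float(sc), t))
    for rows in by_gene.values():
        rows.sort(key=lambda r: (-r[0], r[1]))

    n_corr = {g: len(truth_sets[g]) for g in genes}
    col_max = {g: np.zeros(n_corr[g]) for g in genes}
    row_sum = {g: 0.0 for g in genes}    # sum of row maxima
    total = {g: 0.0 for g in genes}      # sum of all matrix entries
    n_pred = {g: 0 for g in genes}
    ptr = {g: 0 for g in genes}

    thresholds = np.unique(pred.df["score"].to_numpy(dtype=float))[::-1]
    best = 0.0
    for th in thresholds:
        for g in genes:
            rows = by_gene[g]
            i = ptr[g]
            while i < len(rows) and rows[i][0] >= th:
                _, t_pred = rows[i]
                sims = np.array([sim(t_pred, c) for c in truth_sets[g]])
                np.maximum(col_max[g], sims, out=col_max[g])
                row_sum[g] += float(sims.max())
                total[g] += float(sims.sum())
                n_pred[g] += 1
                i += 1
            ptr[g] = i
        gene_scores = []
        for g in genes:
            k = n_pred[g]
            if k == 0:
                gene_scores.append(0.0)
                continue
            if method == "A":
                gene_scores.append(total[g] / (k * n_corr[g]))
                continue
            b = float(col_max[g].mean())
            c = row_sum[g] / k
            if method == "B":
                gene_scores.append(b)
            elif method == "C":
                gene_scores.append(c)
            elif method == "D":
                gene_scores.append((b + c) / 2)
            elif method == "E":
                gene_scores.append(min(b, c))
            elif method == "F":
                gene_scores.append(
                    (row_sum[g] + float(col_max[g].sum())) / (k + n_corr[g])
                )
            else:
                raise ValueError(f"unknown summation method: {method}")
        best = max(best, float(np.mean(gene_scores)))
    return best


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

def score_metric(
    spec: MetricSpec,
    graph: OntologyGraph,
    truth_direct: AnnotationTable,
    truth_propagated: AnnotationTable,
    pred: PredictionSet,
    ic_table: ICTable | None = None,
    zero_when_constant: bool = True,
) -> float:
    """Score one prediction set with one registry metric.

    Handles per-family input conventions: propagates the prediction set for
    group/rank metrics, routes direct annotations to semantic metrics, and
    returns every score oriented higher-is-better (S_min arrives
    sign-flipped from :func:`smin`).
    """
    if spec.family == "semantic":
        if pred.propagated:
            raise MetricError(f"{spec.name} needs an unpropagated prediction set")
        return semantic_metric(
            truth_direct, pred, graph, ic_table, spec.measure, spec.summation,
            ic_variant=spec.ic_variant,
        )
    pred_prop = pred if pred.propagated else propagate_predictions(graph, pred)
    if spec.family == "fmax":
        return fmax(truth_propagated, pred_prop)
    if spec.family == "jaccard":
        return jaccard_metric(truth_propagated, pred_prop, spec.structuring)
    if spec.family == "simgic":
        return simgic(
            truth_propagated, pred_prop, ic_table,
            structuring=spec.structuring, ic_variant=spec.ic_variant,
        )
    if spec.family == "smin":
        return smin(
            truth_propagated, pred_prop, ic_table,
            variant=spec.measure, ic_variant=spec.ic_variant,
        )
    if spec.family == "auc_roc":
        return auc_roc(truth_propagated, pred_prop, spec.structuring)
    if spec.family == "auc_pr":
        return auc_pr(
            truth_propagated, pred_prop, spec.structuring,
            zero_when_constant=zero_when_constant,
        )
    raise ValueError(f"unknown metric family: {spec.family}")
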
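import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adsbench.metrics import (
    MetricError,
    auc_pr,
    auc_roc,
    confusion_counts,
    fmax,
    jaccard_metric,
    metric_registry,
    simgic,
    smin,
)
from adsbench.ontology import ICTable

from .conftest import pred_set, truth_table


def _roc_instance(rng, n=20):
    """Random tie-free instance: labels + distinct scores, both classes."""
    while True:
        labels = rng.random(n) < 0.4
        if labels.any() and not labels.all():
            break
    scores = rng.permutation(n).astype(float)  # distinct
    terms = [f"T{i}" for i in range(n)]
    truth = truth_table([("g", t) for t, y in zip(terms, labels) if y])
    pred = pred_set([("g", t, s) for t, s in zip(terms, scores)])
    return truth, pred, labels, scores


def brute_force_auc(labels, scores):
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_prediction(self):
        truth = truth_table([("g", "A"), ("g", "B")])
        pred = pred_set([("g", "A", 1.0), ("g", "B", 1.0)])
        tp, fp, fn, tn = confusion_counts(truth, pred, 0.5)
        assert (tp, fp, fn) == (2, 0, 0)

    def test_single_swap_bookkeeping(self):
        """One label swap between two genes: +1 FP and +1 FN per gene."""
        truth = truth_table([("g1", "A"), ("g2", "B")])
        swapped = pred_set([("g1", "B", 1.0), ("g2", "A", 1.0)])
        per_gene = confusion_counts(truth, swapped, 0.5, scope="per_gene")
        assert per_gene["g1"] == (0, 1, 1)
        assert per_gene["g2"] == (0, 1, 1)

    def test_threshold_above_all_scores(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "A", 0.3)])
        tp, fp, fn, tn = confusion_counts(truth, pred, 0.9)
        assert (tp, fp, fn) == (0, 0, 1)


class TestFmax:
    def test_perfect_prediction(self):
        truth = truth_table([("g1", "A"), ("g1", "B"), ("g2", "A")])
        pred = pred_set(
            [("g1", "A", 1.0), ("g1", "B", 1.0), ("g2", "A", 1.0)]
        )
        assert fmax(truth, pred) == pytest.approx(1.0)

    def test_half_recall_closed_form(self):
        # one gene, truth {A,B}, predicted {A}: p=1, r=1/2, F=2/3
        truth = truth_table([("g", "A"), ("g", "B")])
        pred = pred_set([("g", "A", 1.0)])
        assert fmax(truth, pred) == pytest.approx(2 / 3, abs=1e-12)

    def test_disjoint_sets_zero(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "B", 1.0)])
        assert fmax(truth, pred) == 0.0

    def test_no_predictions_zero(self):
        import pandas as pd

        from adsbench.annotations import PredictionSet

        truth = truth_table([("g", "A")])
        empty = PredictionSet(
            pd.DataFrame(columns=["gene", "term", "score"])
        )
        empty.propagated = True
        assert fmax(truth, empty) == 0.0

    def test_requires_propagated(self):
        truth = truth_table([("g", "A")], propagated=False)
        pred = pred_set([("g", "A", 1.0)])
        with pytest.raises(MetricError):
            fmax(truth, pred)


class TestSmin:
    def test_perfect_is_zero(self):
        truth = truth_table([("g", "A"), ("g", "B")])
        pred = pred_set([("g", "A", 1.0), ("g", "B", 1.0)])
        ic = ICTable.uniform(["A", "B"])
        assert smin(truth, pred, ic, "1") == pytest.approx(0.0)

    @pytest.mark.parametrize("variant", ["1", "2"])
    def test_closed_form_sqrt_two(self, variant):
        # truth {A,B}, pred {A,C}, unit IC: ru=1, mi=1 -> -sqrt(2)
        truth = truth_table([("g", "A"), ("g", "B")])
        pred = pred_set([("g", "A", 1.0), ("g", "C", 1.0)])
        ic = ICTable.uniform(["A", "B", "C"])
        assert smin(truth, pred, ic, variant) == pytest.approx(
            -math.sqrt(2), abs=1e-12
        )

    def test_variants_agree_for_single_gene(self, rng):
        terms = [f"T{i}" for i in range(12)]
        truth = truth_table([("g", t) for t in terms[:6]])
        pred = pred_set(
            [("g", t, float(s)) for t, s in zip(terms[3:], rng.random(9))]
        )
        ic = ICTable.uniform(terms)
        assert smin(truth, pred, ic, "1") == pytest.approx(
            smin(truth, pred, ic, "2")
        )

    def test_missing_ic_names_term(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "Zmissing", 1.0)])
        ic = ICTable.uniform(["A"])
        with pytest.raises(MetricError, match="Zmissing"):
            smin(truth, pred, ic, "1")


class TestSimgicAndJaccard:
    def test_perfect_is_one(self):
        truth = truth_table([("g", "A"), ("g", "B")])
        pred = pred_set([("g", "A", 1.0), ("g", "B", 1.0)])
        ic = ICTable.uniform(["A", "B"])
        assert simgic(truth, pred, ic) == pytest.approx(1.0)

    def test_unit_weights_closed_form(self):
        # {A,B} vs {B,C}: |∩|/|∪| = 1/3
        truth = truth_table([("g", "B"), ("g", "C")])
        pred = pred_set([("g", "A", 1.0), ("g", "B", 1.0)])
        ic = ICTable.uniform(["A", "B", "C"])
        assert simgic(truth, pred, ic) == pytest.approx(1 / 3, abs=1e-12)

    def test_weighted_closed_form(self):
        # ic(A)=2, ic(B)=ic(C)=1: 1 / 4
        truth = truth_table([("g", "B"), ("g", "C")])
        pred = pred_set([("g", "A", 1.0), ("g", "B", 1.0)])
        ic = ICTable(
            freq={"A": 1, "B": 1, "C": 1}, ic={"A": 2.0, "B": 1.0, "C": 1.0}
        )
        assert simgic(truth, pred, ic) == pytest.approx(1 / 4, abs=1e-12)

    def test_jaccard_equals_simgic_with_unit_ic(self, rng):
        for _ in range(20):
            terms = [f"T{i}" for i in range(10)]
            t_rows = [("g1", t) for t in terms[:5]] + [("g2", t) for t in terms[2:7]]
            p_rows = [
                (g, t, float(s))
                for (g, t), s in zip(
                    [("g1", t) for t in terms[3:]] + [("g2", t) for t in terms[:4]],
                    rng.random(11),
                )
            ]
            truth, pred = truth_table(t_rows), pred_set(p_rows)
            ic = ICTable.uniform(terms)
            for structuring in ("GC", "US"):
                assert jaccard_metric(truth, pred, structuring) == pytest.approx(
                    simgic(truth, pred, ic, structuring)
                )

    def test_disjoint_sets_zero(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "B", 1.0)])
        ic = ICTable.uniform(["A", "B"])
        assert simgic(truth, pred, ic) == 0.0

    def test_high_scoring_false_leaf_never_helps(self, rng):
        """Monotone penalty: adding a high-score FP prediction cannot
        increase SimGIC, Jaccard or flipped S_min."""
        terms = [f"T{i}" for i in range(10)]
        truth = truth_table([("g", t) for t in terms[:5]])
        base_rows = [("g", t, 0.5) for t in terms[:5]]
        ic = ICTable.uniform(terms + ["FPLEAF"])
        base = pred_set(base_rows)
        worse = pred_set(base_rows + [("g", "FPLEAF", 9.9)])
        assert simgic(truth, worse, ic) <= simgic(truth, base, ic)
        assert jaccard_metric(truth, worse) <= jaccard_metric(truth, base)
        assert smin(truth, worse, ic, "1") <= smin(truth, base, ic, "1")


class TestAucRoc:
    def test_perfect_separation(self):
        truth = truth_table([("g", "A"), ("g", "B")])
        pred = pred_set([("g", "A", 0.9), ("g", "B", 0.8), ("g", "C", 0.7)])
        assert auc_roc(truth, pred, "US") == pytest.approx(1.0)

    def test_interleaved_concordance(self):
        # positives at 0.9 and 0.6, negative at 0.8: 1 of 2 pairs concordant
        truth = truth_table([("g", "A"), ("g", "B")])
        pred = pred_set([("g", "A", 0.9), ("g", "B", 0.6), ("g", "C", 0.8)])
        assert auc_roc(truth, pred, "US") == pytest.approx(0.5)

    def test_matches_brute_force_mann_whitney(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            truth, pred, labels, scores = _roc_instance(rng)
            expected = brute_force_auc(labels, scores)
            assert auc_roc(truth, pred, "US") == pytest.approx(expected)
            assert auc_roc(truth, pred, "US", ties="midrank") == pytest.approx(
                expected
            )

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(60):
            truth, pred, *_ = _roc_instance(rng, n=40)
            vals.append(auc_roc(truth, pred, "US"))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_constant_scores_collapse_to_single_step_point(self):
        """A fully tied list is one ROC point whose step area is 1 —
        the failure mode that lets uninformative decoys saturate US AUC."""
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "A", 1.0), ("g", "B", 1.0), ("g", "C", 1.0)])
        assert auc_roc(truth, pred, "US") == pytest.approx(1.0)
        assert auc_roc(truth, pred, "US", ties="midrank") == pytest.approx(0.5)

    def test_single_class_us_raises(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "A", 1.0)])
        with pytest.raises(MetricError):
            auc_roc(truth, pred, "US")

    def test_tc_unpredicted_truth_terms_score_zero(self):
        truth = truth_table([("g1", "A"), ("g1", "B"), ("g2", "A")])
        pred = pred_set([("g1", "A", 0.9), ("g2", "A", 0.8), ("g1", "C", 0.1)])
        # term A: both genes predicted & positive -> 1; term B: unpredicted -> 0
        assert auc_roc(truth, pred, "TC") == pytest.approx(0.5)


class TestAucPr:
    def test_perfect_ranking(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "A", 0.9), ("g", "B", 0.8), ("g", "C", 0.7)])
        assert auc_pr(truth, pred, "US") == pytest.approx(1.0)

    def test_top_positive_step_area(self):
        # single positive at the top: PR point (r=1, p=1), area 1
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "A", 0.9), ("g", "B", 0.8), ("g", "C", 0.7)])
        assert auc_pr(truth, pred) == pytest.approx(1.0)

    def test_constant_scores_zero_or_prevalence(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "A", 1.0), ("g", "B", 1.0)])
        assert auc_pr(truth, pred, zero_when_constant=True) == 0.0
        assert auc_pr(truth, pred, zero_when_constant=False) == pytest.approx(0.5)

    def test_matches_sklearn_average_precision(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        for _ in range(50):
            truth, pred, labels, scores = _roc_instance(rng)
            expected = sk.average_precision_score(labels, scores)
            assert auc_pr(truth, pred, "US") == pytest.approx(expected)

    def test_no_positives_us_raises(self):
        truth = truth_table([("g", "A")])
        pred = pred_set([("g", "B", 1.0), ("g", "C", 0.5)])
        with pytest.raises(MetricError):
            auc_pr(truth, pred, "US")


class TestRegistry:
    def test_expected_entries_present(self):
        names = {s.name for s in metric_registry()}
        assert "TC AUC-PR" in names
        assert "ic2 SimGIC2" in names
        assert "Fmax" in names
        assert "Lin E" in names

    def test_semantic_entries_never_propagate(self):
        for spec in metric_registry():
            if spec.family == "semantic":
                assert spec.propagate_predictions is False

    def test_smin_oriented_lower_better(self):
        smins = [s for s in metric_registry() if s.family == "smin"]
        assert smins and all(s.orientation == "lower_better" for s in smins)
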
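import numpy as np
import pandas as pd
import pytest

from adsbench.annotations import AnnotationTable, PredictionSet
from adsbench.ontology import OntologyGraph
from adsbench.synthetic import SynthConfig, make_dag, make_truth


@pytest.fixture
def chain_graph():
    """A <- B <- C <- D (A is the root)."""
    return OntologyGraph({"B": {"A"}, "C": {"B"}, "D": {"C"}})


@pytest.fixture
def diamond_graph():
    """A root; B, C children of A; D child of both B and C."""
    return OntologyGraph({"B": {"A"}, "C": {"A"}, "D": {"B", "C"}})


@pytest.fixture(scope="session")
def small_synth():
    """A 300-term / 60-gene synthetic ontology + truth set."""
    cfg = SynthConfig(n_terms=300, n_genes=60, seed=3)
    graph = make_dag(cfg)
    truth = make_truth(graph, cfg)
    return graph, truth


def truth_table(rows, propagated=True):
    """Build a (propagated) truth table directly from (gene, term) rows."""
    t = AnnotationTable(pd.DataFrame(rows, columns=["gene", "term"]))
    t.propagated = propagated
    return t


def pred_set(rows, propagated=True):
    """Build a prediction set directly from (gene, term, score) rows."""
    p = PredictionSet(pd.DataFrame(rows, columns=["gene", "term", "score"]))
    p.propagated = propagated
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
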
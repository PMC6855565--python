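"""Ontology DAG handling.

The Gene Ontology (and any GO-like ontology) is a rooted directed acyclic
graph in which child terms specialise their parents: a gene annotated to a
term is implicitly annotated to every ancestor of that term.  This module
parses OBO files, serves ancestor closures, term–term ancestor-Jaccard
similarity, semantic neighbourhoods (the *k* nearest proper ancestors of a
term) and annotation-frequency-derived information-content weights.

Two information contents are provided per term:

``ic``
    marginal information content, ``-log2 f(t)`` where ``f(t)`` is the
    fraction of genes annotated (after ancestor propagation) to ``t``;
``ic2``
    information accretion, ``-log2( f(t) / min_p f(p) )`` over the direct
    parents ``p`` — the information gained by ``t`` beyond its parents.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "OntologyError",
    "OntologyGraph",
    "ICTable",
    "load_obo",
    "write_obo",
    "term_frequencies",
    "information_content",
]


class OntologyError(ValueError):
    """Raised for malformed or cyclic ontologies and unknown terms."""


class OntologyGraph:
    """A rooted DAG of terms with cached ancestor closures.

    Parameters
    ----------
    parents:
        Mapping term -> iterable of direct parent term IDs.  Terms that only
        appear as parents are added automatically.
    alt_id_map:
        Mapping of alternate (merged) IDs to canonical term IDs.
    names:
        Optional human-readable term names (kept for OBO round-trips).
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        alt_id_map: Mapping[str, str] | None = None,
        names: Mapping[str, str] | None = None,
    ) -> None:
        self.parents: dict[str, frozenset[str]] = {}
        terms: set[str] = set()
        for term, ps in parents.items():
            ps = frozenset(ps)
            self.parents[term] = ps
            terms.add(term)
            terms.update(ps)
        for t in terms:
            self.parents.setdefault(t, frozenset())
        self.terms: frozenset[str] = frozenset(terms)
        self.alt_id_map: dict[str, str] = dict(alt_id_map or {})
        self.names: dict[str, str] = dict(names or {})
        for alt, canon in self.alt_id_map.items():
            if canon not in self.terms:
                raise OntologyError(f"alt_id {alt} maps to unknown term {canon}")

        self.children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                self.children[p].add(child)
        self.roots: frozenset[str] = frozenset(
            t for t in self.terms if not self.parents[t]
        )
        if not self.roots and self.terms:
            raise OntologyError("ontology has no root term (cyclic?)")
        self._validate_acyclic()
        self._closures: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("parent edges contain a directed cycle")

    # -- queries --------------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self.alt_id_map

    def __len__(self) -> int:
        return len(self.terms)

    def canonical(self, term: str) -> str:
        """Map an alternate ID to its canonical term ID."""
        if term in self.terms:
            return term
        if term in self.alt_id_map:
            return self.alt_id_map[term]
        raise KeyError(f"unknown term: {term}")

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of ``term``, including the term itself."""
        term = self.canonical(term)
        cached = self._closures.get(term)
        if cached is not None:
            return cached
        closure = {term}
        for p in self.parents[term]:
            closure.update(self.ancestors(p))
        result = frozenset(closure)
        self._closures[term] = result
        return result

    def term_jaccard(self, t1: str, t2: str) -> float:
        """Jaccard similarity of the two terms' ancestor closures."""
        a, b = self.ancestors(t1), self.ancestors(t2)
        return len(a & b) / len(a | b)

    def parent_distances(self, term: str) -> dict[str, int]:
        """Shortest parent-path distance from ``term`` to each proper ancestor."""
        term = self.canonical(term)
        dist: dict[str, int] = {}
        queue: deque[tuple[str, int]] = deque([(term, 0)])
        while queue:
            t, d = queue.popleft()
            for p in self.parents[t]:
                if p not in dist or d + 1 < dist[p]:
                    dist[p] = d + 1
                    queue.append((p, d + 1))
        return dist

    def k_nearest_parents(self, term: str, k: int) -> list[str]:
        """The ≤ k proper ancestors closest to ``term``.

        Ordered by shortest parent-path distance, ties broken by term ID;
        ontology roots are excluded (they carry no information).  A root term
        has no eligible neighbours.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        dist = self.parent_distances(term)
        eligible = sorted(
            (d, t) for t, d in dist.items() if t not in self.roots
        )
        return [t for _, t in eligible[:k]]

    def non_root_terms(self) -> list[str]:
        """Sorted list of terms excluding roots (sampling universe)."""
        return sorted(self.terms - self.roots)


# ---------------------------------------------------------------------------
# OBO I/O
# ---------------------------------------------------------------------------

def load_obo(path, include_part_of: bool = True) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are dropped; ``is_a`` edges (and ``part_of`` when
    ``include_part_of``) are retained; alternate IDs are mapped to their
    canonical terms.
    """
    try:
        raw = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - obonet error classes vary
        raise OntologyError(f"failed to parse OBO file {path!r}: {exc}") from exc

    keep = {"is_a"}
    if include_part_of:
        keep.add("part_of")

    parents: dict[str, set[str]] = {t: set() for t in raw.nodes}
    for child, parent, rel in raw.edges(keys=True):
        if rel in keep and parent in parents:
            parents[child].add(parent)
    alt_id_map = {}
    names = {}
    for term, data in raw.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_id_map[alt] = term
        if "name" in data:
            names[term] = data["name"]
    return OntologyGraph(parents, alt_id_map=alt_id_map, names=names)


def write_obo(graph: OntologyGraph, path) -> None:
    """Write a minimal OBO 1.2 rendering of the graph (is_a edges only).

    Covers the subset of OBO that :func:`load_obo` reads back; sufficient for
    round-tripping synthetic ontologies.
    """
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: adsbench-synthetic\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {graph.names.get(term, term)}\n")
            for parent in sorted(graph.parents[term]):
                fh.write(f"is_a: {parent}\n")


# ---------------------------------------------------------------------------
# Term frequencies and information content
# ---------------------------------------------------------------------------

@dataclass
class ICTable:
    """Per-term annotation frequency and information-content weights."""

    freq: dict[str, float]
    ic: dict[str, float] = field(default_factory=dict)
    ic2: dict[str, float] = field(default_factory=dict)
    n_genes: int = 0

    @property
    def floor(self) -> float:
        """Frequency floor for unannotated terms: 1 / (2 * n_genes)."""
        return 1.0 / (2 * self.n_genes) if self.n_genes else 1e-9

    def weights(self, variant: str) -> dict[str, float]:
        if variant == "ic":
            table = self.ic
        elif variant == "ic2":
            table = self.ic2
        else:
            raise ValueError(f"unknown IC variant: {variant}")
        if not table:
            raise ValueError(f"IC variant {variant!r} not computed yet")
        return table

    @classmethod
    def uniform(cls, terms: Iterable[str]) -> "ICTable":
        """Unit weights (turns SimGIC into the plain Jaccard metric)."""
        ones = {t: 1.0 for t in terms}
        return cls(freq=dict.fromkeys(ones, 1.0), ic=dict(ones), ic2=dict(ones))

    def to_frame(self) -> pd.DataFrame:
        terms = sorted(self.freq)
        return pd.DataFrame(
            {
                "term": terms,
                "freq": [self.freq[t] for t in terms],
                "ic": [self.ic.get(t, float("nan")) for t in terms],
                "ic2": [self.ic2.get(t, float("nan")) for t in terms],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ICTable":
        df = pd.read_csv(path, sep="\t")
        table = cls(freq=dict(zip(df["term"], df["freq"])))
        if df["ic"].notna().any():
            table.ic = dict(zip(df["term"], df["ic"]))
        if df["ic2"].notna().any():
            table.ic2 = dict(zip(df["term"], df["ic2"]))
        return table


def term_frequencies(graph: OntologyGraph, annotations) -> ICTable:
    """Relative annotation frequency per term after ancestor propagation.

    ``freq(t)`` = (# distinct genes annotated to ``t`` or any descendant) /
    (# distinct genes).  Terms never annotated get frequency 0; roots that
    every annotated gene reaches get frequency 1.
    """
    df = annotations.df
    if df.empty:
        raise ValueError("annotation table is empty")
    gene_counts: dict[str, set[str]] = {t: set() for t in graph.terms}
    for gene, term in zip(df["gene"], df["term"]):
        for anc in graph.ancestors(term):
            gene_counts[anc].add(gene)
    n_genes = df["gene"].nunique()
    freq = {t: len(genes) / n_genes for t, genes in gene_counts.items()}
    return ICTable(freq=freq, n_genes=n_genes)


def information_content(
    graph: OntologyGraph, table: ICTable, variant: str = "both"
) -> ICTable:
    """Fill the ``ic`` and/or ``ic2`` columns of an :class:`ICTable`.

    Zero frequencies are clamped to the table's floor so unseen terms get a
    large finite weight instead of infinity.
    """
    floor = table.floor
    f = {t: max(v, floor) for t, v in table.freq.items()}
    if variant in ("ic", "both"):
        table.ic = {t: -math.log2(v) for t, v in f.items()}
    if variant in ("ic2", "both"):
        ic2 = {}
        for t in table.freq:
            ps = graph.parents.get(t, frozenset())
            if not ps:
                ic2[t] = -math.log2(f[t])  # roots: no parent to condition on
            else:
                parent_f = min(f[p] for p in ps)
                ic2[t] = max(0.0, -math.log2(f[t] / parent_f))
        table.ic2 = ic2
    if variant not in ("ic", "ic2", "both"):
        raise ValueError(f"unknown IC variant: {variant}")
    return table
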
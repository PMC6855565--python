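"""Truth sets and prediction sets.

A *truth set* is a two-column table of (gene, term) annotations; a
*prediction set* adds a real-valued classifier score per row plus an origin
label used by the dilution machinery (``positive`` rows descend from the
truth set, ``negative`` rows are the injected low-score decoys, ``fp`` rows
belong to false-positive decoy sets).

Both tables can be *propagated*: closed upward under the ontology's ancestor
relation.  Truth propagation simply adds the missing (gene, ancestor) rows;
prediction propagation gives each ancestor the maximum score over its
predicted descendants, so a term counts as predicted at threshold ``th``
exactly when one of its descendants (or itself) is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .ontology import OntologyGraph

__all__ = [
    "AnnotationTable",
    "PredictionSet",
    "FormatError",
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
    "propagate_truth",
    "propagate_predictions",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed annotation / prediction files."""


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(list(df.columns[:2]), kind="mergesort", ignore_index=True)


@dataclass
class AnnotationTable:
    """A (gene, term) truth table."""

    df: pd.DataFrame
    propagated: bool = False

    def __post_init__(self) -> None:
        if not {"gene", "term"}.issubset(self.df.columns):
            raise FormatError("annotation table needs 'gene' and 'term' columns")
        self.df = _sorted(self.df.drop_duplicates(subset=["gene", "term"]))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def terms_by_gene(self) -> dict[str, set[str]]:
        return {g: set(sub) for g, sub in self.df.groupby("gene")["term"]}

    def copy(self) -> "AnnotationTable":
        return AnnotationTable(self.df.copy(), propagated=self.propagated)


@dataclass
class PredictionSet:
    """A (gene, term, score) prediction table with per-row origin labels."""

    df: pd.DataFrame
    propagated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not {"gene", "term", "score"}.issubset(self.df.columns):
            raise FormatError(
                "prediction table needs 'gene', 'term' and 'score' columns"
            )
        if "origin" not in self.df.columns:
            self.df = self.df.assign(origin="positive")
        # one row per (gene, term): keep the maximum score
        df = self.df.sort_values(
            ["gene", "term", "score"], kind="mergesort", ignore_index=True
        )
        self.df = df.drop_duplicates(subset=["gene", "term"], keep="last").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def copy(self) -> "PredictionSet":
        return PredictionSet(
            self.df.copy(), propagated=self.propagated, meta=dict(self.meta)
        )


# ---------------------------------------------------------------------------
# I/O (tab-delimited, gzip transparent via pandas)
# ---------------------------------------------------------------------------

def _read_tsv(path, n_cols: int, names: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != n_cols:
        # tolerate a single header line
        first = df.iloc[0].tolist() if len(df) else []
        raise FormatError(
            f"{path}: expected {n_cols} tab-separated columns, got {df.shape[1]} "
            f"(first row: {first})"
        )
    df.columns = names
    if list(df.iloc[0])[:2] == names[:2]:  # optional header row
        df = df.iloc[1:].reset_index(drop=True)
    return df


def _map_terms(df: pd.DataFrame, graph: OntologyGraph | None, path) -> pd.DataFrame:
    if graph is None:
        return df
    known = df["term"].map(lambda t: t in graph)
    dropped = int((~known).sum())
    if dropped:
        log.warning("%s: dropped %d rows with unknown terms", path, dropped)
    df = df[known].reset_index(drop=True)
    if df.empty:
        raise FormatError(f"{path}: no rows left after unknown-term filtering")
    return df.assign(term=df["term"].map(graph.canonical))


def read_annotations(path, graph: OntologyGraph | None = None) -> AnnotationTable:
    """Read a 2-column (gene, term) TSV; map alt-IDs, drop unknown terms."""
    df = _read_tsv(path, 2, ["gene", "term"])
    return AnnotationTable(_map_terms(df, graph, path))


def write_annotations(table: AnnotationTable, path) -> None:
    table.df[["gene", "term"]].to_csv(path, sep="\t", index=False, header=False)


def read_predictions(path, graph: OntologyGraph | None = None) -> PredictionSet:
    """Read a 3-column (gene, term, score) TSV; duplicates keep the max score."""
    df = _read_tsv(path, 3, ["gene", "term", "score"])
    df = _map_terms(df, graph, path)
    df = df.assign(score=df["score"].astype(float))
    return PredictionSet(df)


def write_predictions(pred: PredictionSet, path) -> None:
    df = pred.df.sort_values(["gene", "term"], kind="mergesort")
    df[["gene", "term", "score"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# Ancestor propagation
# ---------------------------------------------------------------------------

def propagate_truth(graph: OntologyGraph, table: AnnotationTable) -> AnnotationTable:
    """Close a truth table upward under the ancestor relation (idempotent)."""
    rows: set[tuple[str, str]] = set()
    for gene, term in zip(table.df["gene"], table.df["term"]):
        for anc in graph.ancestors(term):
            rows.add((gene, anc))
    df = pd.DataFrame(sorted(rows), columns=["gene", "term"])
    return AnnotationTable(df, propagated=True)


def propagate_predictions(graph: OntologyGraph, pred: PredictionSet) -> PredictionSet:
    """Extend predictions to ancestors with score = max over descendants.

    Origin labels are inherited from the descendant row that supplied the
    maximum score.  Already-propagated sets are returned unchanged (a second
    application is a no-op by the max rule).
    """
    best: dict[tuple[str, str], tuple[float, str]] = {}
    df = pred.df
    for gene, term, score, origin in zip(
        df["gene"], df["term"], df["score"], df["origin"]
    ):
        for anc in graph.ancestors(term):
            key = (gene, anc)
            cur = best.get(key)
            if cur is None or score > cur[0]:
                best[key] = (score, origin)
    out = pd.DataFrame(
        [(g, t, s, o) for (g, t), (s, o) in best.items()],
        columns=["gene", "term", "score", "origin"],
    )
    return PredictionSet(_sorted(out), propagated=True, meta=dict(pred.meta))
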
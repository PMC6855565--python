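"""GO-like synthetic ontologies and truth sets.

The generator emulates the structural features of real GO annotation data
that the dilution machinery depends on: a rooted DAG in which terms can have
multiple parents, strongly skewed class sizes (a few huge general terms,
many tiny specific ones) and a right-skewed number of annotations per gene,
biased towards specific (deep) terms.  Genes are opaque identifiers; no
sequences are involved.

Acyclicity is guaranteed by construction: terms are organised into levels
below the root and each term draws its parents from the level directly
above, so the DAG is simultaneously broad (many top-level subtrees, as in
GO) and deep (default 8 levels), with occasional multiple parentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationTable
from .ontology import OntologyGraph

__all__ = ["SynthConfig", "make_dag", "make_truth"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic ontology/truth generator.

    Defaults produce a 500-term DAG (depth well beyond 5) annotated over 100
    genes — large enough for the permutation noise model to find acceptable
    swaps at every signal level, small enough for interactive use.
    """

    n_terms: int = 500
    n_top: int = 30                  # terms attached directly under the root
    n_levels: int = 10               # depth of the layered DAG below the root
    max_parents: int = 3
    multi_parent_prob: float = 0.1   # chance of each extra parent beyond the first
    depth_bias: float = 0.0          # level-size weight ~ level**bias (>0: deeper)
    n_genes: int = 100
    ann_log_mean: float = 1.6        # lognormal parameters of annotations/gene
    ann_log_sd: float = 0.6
    leaf_bias: float = 1.0           # term sampling weight ~ closure_size**bias
    min_ann_depth: int = 6           # direct annotations need > this closure size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 10:
            raise ValueError("n_terms must be >= 10")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def make_dag(cfg: SynthConfig) -> OntologyGraph:
    """Generate a rooted DAG with GO-like multiple parentage."""
    rng = np.random.default_rng(cfg.seed)
    root = _term_id(0)
    parents: dict[str, set[str]] = {root: set()}
    n_top = min(cfg.n_top, cfg.n_terms - 1)
    levels: list[list[str]] = [[root], [_term_id(i) for i in range(1, 1 + n_top)]]
    for t in levels[1]:
        parents[t] = {root}

    remaining = cfg.n_terms - 1 - n_top
    n_lev = min(max(2, cfg.n_levels) - 1, remaining)
    if n_lev <= 0:
        return OntologyGraph(parents)
    w = np.arange(2, n_lev + 2, dtype=float) ** cfg.depth_bias
    extra = remaining - n_lev
    add = np.floor(extra * w / w.sum()).astype(int)
    sizes = 1 + add  # every level keeps at least one term
    sizes[-1] += extra - add.sum()  # rounding drift to the deepest level

    i = 1 + n_top
    children: dict[str, list[str]] = {t: [] for t in parents}
    children[root] = list(levels[1])
    for size in sizes:
        level: list[str] = []
        above = levels[-1]
        # balanced parent assignment: cycle through the level above in a
        # shuffled order so every lineage keeps descendants (no branch
        # extinction; keeps distinct subtrees semantically separated)
        slots = np.tile(np.arange(len(above)), math.ceil(size / len(above)))
        rng.shuffle(slots)
        for j in range(size):
            term = _term_id(i)
            i += 1
            first = above[int(slots[j])]
            chosen = {first}
            # extra parents come from the first parent's siblings: multiple
            # parentage in GO links semantically close terms, so the child's
            # ancestor closure grows by ~1 term per extra parent, not by a
            # whole second lineage
            n_extra = rng.binomial(cfg.max_parents - 1, cfg.multi_parent_prob)
            if n_extra:
                siblings = sorted(
                    {
                        s
                        for gp in parents[first]
                        for s in children.get(gp, ())
                        if s != first
                    }
                )
                if siblings:
                    picks = rng.choice(
                        len(siblings), size=min(n_extra, len(siblings)),
                        replace=False,
                    )
                    chosen.update(siblings[j] for j in picks)
            parents[term] = chosen
            children[term] = []
            for p in chosen:
                children[p].append(term)
            level.append(term)
        levels.append(level)
    return OntologyGraph(parents)


def make_truth(graph: OntologyGraph, cfg: SynthConfig) -> AnnotationTable:
    """Sample a direct (unpropagated) truth set over ``cfg.n_genes`` genes.

    Annotation counts per gene follow a lognormal (right-skewed); terms are
    drawn without replacement with probability proportional to the size of
    their ancestor closure raised to ``leaf_bias``, which concentrates direct
    annotations on specific terms, as in curated GO data.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    terms = graph.non_root_terms()
    sizes = np.array([len(graph.ancestors(t)) for t in terms], dtype=float)
    weights = sizes**cfg.leaf_bias
    # curated annotations sit on specific terms, not just under the root
    deep = sizes > cfg.min_ann_depth
    if deep.sum() >= 10:
        weights = weights * deep
    weights /= weights.sum()

    rows: list[tuple[str, str]] = []
    width = len(str(cfg.n_genes))
    for g in range(cfg.n_genes):
        gene = f"G{g + 1:0{width}d}"
        n_ann = max(1, int(round(rng.lognormal(cfg.ann_log_mean, cfg.ann_log_sd))))
        n_ann = min(n_ann, len(terms))
        chosen = rng.choice(len(terms), size=n_ann, replace=False, p=weights)
        rows.extend((gene, terms[j]) for j in sorted(chosen))
    return AnnotationTable(pd.DataFrame(rows, columns=["gene", "term"]))
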
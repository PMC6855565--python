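"""Artificial dilution series and false-positive decoy sets.

An *artificial prediction set* (AP set) imitates the output of a GO
classifier at a controlled signal level.  It is built from a truth set in
four steps:

1. **Signal model — shifting to semantic neighbours.**  A uniform random
   number of rows have their term replaced by one of its *k* nearest proper
   ancestors, imitating classifiers that predict a nearby, more general
   term.
2. **Noise model — permutation.**  Term labels are swapped between genes
   until a fraction ``epsilon = 1 - signal`` of rows carry a wrong label.  A
   swap is accepted only when each incoming term is semantically far
   (ancestor-Jaccard below ``th_noise``) from everything annotated to the
   recipient gene, so the injected errors are unambiguous.  Swapping keeps
   the term multiset and the per-gene annotation counts invariant.
3. **Negative set.**  Every gene receives a fixed number of random far-away
   terms.
4. **Scores.**  Positive rows draw scores from N(pos_mean, pos_sd), negative
   rows from N(neg_mean, neg_sd); the sets are merged.  Negative-set errors
   are separable by score threshold; permutation errors are not.

Repeating this over a descending signal range with several replicates per
level yields the dilution series.  False-positive decoy sets (naive /
small / random term lists shared by all genes) provide predictions with no
gene-specific information at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationTable, PredictionSet
from .ontology import ICTable, OntologyGraph

__all__ = [
    "ADSConfig",
    "ADSSeries",
    "InfeasibleNoiseError",
    "shift_to_neighbours",
    "permute_noise",
    "make_negative_set",
    "assign_scores",
    "make_ap_set",
    "make_series",
    "make_fp_set",
]

DEFAULT_SIGNAL_RANGE = tuple(round(1.0 - 0.1 * i, 1) for i in range(11))


class InfeasibleNoiseError(RuntimeError):
    """Raised when the requested noise level cannot be realised."""


@dataclass
class ADSConfig:
    """Parameters of the dilution series generator (paper defaults)."""

    signal_range: tuple[float, ...] = DEFAULT_SIGNAL_RANGE
    replicates: int = 3
    k: int = 3
    th_noise: float = 0.2
    neg_per_gene: int = 4
    pos_score_mean: float = 1.0
    pos_score_sd: float = 0.5
    neg_score_mean: float = -1.0
    neg_score_sd: float = 0.5
    sigmoid_scores: bool = False
    master_seed: int = 0
    max_attempts_factor: int = 1000

    def __post_init__(self) -> None:
        sr = tuple(float(s) for s in self.signal_range)
        if any(not 0.0 <= s <= 1.0 for s in sr):
            raise ValueError("signal levels must lie in [0, 1]")
        if any(nxt >= prev for nxt, prev in zip(sr[1:], sr)):
            raise ValueError("signal_range must be strictly descending")
        self.signal_range = sr
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.th_noise < 1.0:
            raise ValueError("th_noise must be in (0, 1)")


@dataclass
class ADSSeries:
    """Grid of AP sets indexed by (replicate i, signal index j)."""

    ap_sets: dict[tuple[int, int], PredictionSet]
    signal_levels: tuple[float, ...]
    provenance: pd.DataFrame  # replicate, signal, child_seed, realised_noise

    @property
    def n_replicates(self) -> int:
        return 1 + max(i for i, _ in self.ap_sets)

    def __len__(self) -> int:
        return len(self.ap_sets)


# ---------------------------------------------------------------------------
# Step 1a: shifting to semantic neighbours
# ---------------------------------------------------------------------------

def shift_to_neighbours(
    graph: OntologyGraph, table: AnnotationTable, k: int, rng: np.random.Generator
) -> AnnotationTable:
    """Replace a uniform-random number of terms by nearby ancestors.

    ``N_shift ~ U{0..|P|}`` rows are chosen without replacement; each chosen
    row's term is replaced by a uniform draw from its ≤ k nearest non-root
    ancestors.  Rows whose term has no eligible neighbour stay unchanged;
    duplicate rows created by shifting are collapsed.
    """
    genes = list(table.df["gene"])
    terms = list(table.df["term"])
    n = len(terms)
    n_shift = int(rng.integers(0, n + 1))
    chosen = rng.choice(n, size=n_shift, replace=False) if n_shift else []
    neighbour_cache: dict[str, list[str]] = {}
    for idx in chosen:
        t = terms[idx]
        nbrs = neighbour_cache.get(t)
        if nbrs is None:
            nbrs = graph.k_nearest_parents(t, k)
            neighbour_cache[t] = nbrs
        if nbrs:
            terms[idx] = nbrs[int(rng.integers(len(nbrs)))]
    df = pd.DataFrame({"gene": genes, "term": terms})
    return AnnotationTable(df)


# ---------------------------------------------------------------------------
# Step 1b: permutation noise
# ---------------------------------------------------------------------------

def permute_noise(
    graph: OntologyGraph,
    table: AnnotationTable,
    epsilon: float,
    th_noise: float,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> tuple[AnnotationTable, float]:
    """Swap term labels between genes until ``epsilon·|P|`` rows are noise.

    A candidate swap picks two unpermuted rows of different genes carrying
    different terms; it is accepted iff each incoming term (a) has
    ancestor-Jaccard < ``th_noise`` against *every* pre-permutation term of
    the recipient gene — its signal terms, so the injected error is
    unambiguously wrong — and (b) does not duplicate a term the recipient
    currently carries.  Accepted swaps mark both rows as permuted; rows take
    part in at most one swap, which keeps the realised-noise accounting
    exact and leaves the term multiset and per-gene row counts invariant.

    At moderate noise levels pairs are drawn at random.  When most rows must
    be permuted, greedy random pairing strands rows whose feasible partners
    were consumed, so a maximum-cardinality matching of the compatibility
    graph (blossom algorithm) is computed instead and its pairs applied in
    random order until the target is met.  All randomness flows through
    ``rng``.

    Returns the permuted table (with a boolean ``permuted`` column) and the
    realised noise fraction.  A shortfall of up to two rows (an odd target,
    or an unswappable final pair) is tolerated; beyond that an
    :class:`InfeasibleNoiseError` is raised.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    genes = list(table.df["gene"])
    terms = list(table.df["term"])
    n = len(terms)
    if n == 0:
        raise ValueError("cannot permute an empty table")
    target = math.ceil(epsilon * n)
    permuted = np.zeros(n, dtype=bool)

    if target > 0:
        if max_attempts is None:
            max_attempts = 50 * n
        base: dict[str, frozenset[str]] = {}
        grouped: dict[str, set[str]] = {}
        for g, t in zip(genes, terms):
            grouped.setdefault(g, set()).add(t)
        base = {g: frozenset(ts) for g, ts in grouped.items()}  # signal terms
        current = {g: set(ts) for g, ts in grouped.items()}
        jac = graph.term_jaccard
        give_cache: dict[tuple[str, str], bool] = {}

        def can_give(term: str, gene: str) -> bool:
            key = (term, gene)
            ok = give_cache.get(key)
            if ok is None:
                ok = all(jac(term, t) < th_noise for t in base[gene])
                give_cache[key] = ok
            return ok

        def compatible(a: int, b: int) -> bool:
            gene_a, t_a = genes[a], terms[a]
            gene_b, t_b = genes[b], terms[b]
            if gene_a == gene_b or t_a == t_b:
                return False
            if t_a in current[gene_b] or t_b in current[gene_a]:
                return False
            return can_give(t_a, gene_b) and can_give(t_b, gene_a)

        pool = list(range(n))
        in_pool = np.ones(n, dtype=bool)
        n_permuted = 0

        applied_pairs: list[tuple[int, int]] = []

        def do_swap(a: int, b: int) -> None:
            nonlocal n_permuted
            current[genes[a]].discard(terms[a])
            current[genes[b]].discard(terms[b])
            current[genes[a]].add(terms[b])
            current[genes[b]].add(terms[a])
            terms[a], terms[b] = terms[b], terms[a]
            permuted[a] = permuted[b] = True
            in_pool[a] = in_pool[b] = False
            applied_pairs.append((a, b))
            n_permuted += 2

        def undo_swap(a: int, b: int) -> None:
            nonlocal n_permuted
            current[genes[a]].discard(terms[a])
            current[genes[b]].discard(terms[b])
            current[genes[a]].add(terms[b])
            current[genes[b]].add(terms[a])
            terms[a], terms[b] = terms[b], terms[a]
            permuted[a] = permuted[b] = False
            in_pool[a] = in_pool[b] = True
            n_permuted -= 2

        def matching_round() -> bool:
            """One maximum-matching pass over the unpermuted rows."""
            import networkx as nx

            remaining = sorted(i for i in pool if in_pool[i])
            if len(remaining) < 2:
                return False
            rng.shuffle(remaining)  # node order steers blossom to a different matching
            g_match = nx.Graph()
            g_match.add_nodes_from(remaining)
            for x in range(len(remaining)):
                for yy in range(x + 1, len(remaining)):
                    if compatible(remaining[x], remaining[yy]):
                        g_match.add_edge(remaining[x], remaining[yy])
            matching = nx.max_weight_matching(g_match, maxcardinality=True)
            pairs = sorted((min(p), max(p)) for p in matching)
            rng.shuffle(pairs)
            applied = False
            for a, b in pairs:
                if n_permuted >= target:
                    break
                if in_pool[a] and in_pool[b] and compatible(a, b):
                    do_swap(a, b)
                    applied = True
            return applied

        if target < 0.6 * n:
            # phase 1: uniform random pair proposals
            attempts = 0
            while (
                n_permuted < target and len(pool) >= 2 and attempts < max_attempts
            ):
                attempts += 1
                ia, ib = rng.choice(len(pool), size=2, replace=False)
                a, b = pool[ia], pool[ib]
                if not compatible(a, b):
                    continue
                do_swap(a, b)
                for i in sorted((ia, ib), reverse=True):
                    pool[i] = pool[-1]
                    pool.pop()

        # matching phase: exact maximum matchings until the target is met.
        # Applying matched pairs sequentially can strand rows through
        # duplicate-term collisions (two pairs sending the same term to one
        # gene); a different random application order usually avoids the
        # cascade, so retry from a snapshot a few times before giving up.
        def take_state():
            return (
                list(terms),
                permuted.copy(),
                in_pool.copy(),
                {g: set(ts) for g, ts in current.items()},
                n_permuted,
                list(applied_pairs),
            )

        def restore_state(state):
            nonlocal current, n_permuted
            terms[:] = list(state[0])
            permuted[:] = state[1].copy()
            in_pool[:] = state[2].copy()
            current = {g: set(ts) for g, ts in state[3].items()}
            n_permuted = state[4]
            applied_pairs[:] = list(state[5])

        snapshot = take_state()
        best = None
        for _ in range(8):
            kick_budget = 40
            while n_permuted < target:
                if not matching_round():
                    # local repair: undo a random applied swap and re-match;
                    # breaks duplicate-collision deadlocks among the last rows
                    kicked = False
                    while kick_budget > 0 and applied_pairs:
                        kick_budget -= 1
                        idx = int(rng.integers(len(applied_pairs)))
                        a, b = applied_pairs.pop(idx)
                        undo_swap(a, b)
                        if matching_round():
                            kicked = True
                            break
                    if not kicked:
                        break
            if target - n_permuted <= 2:
                break
            if best is None or n_permuted > best[4]:
                best = take_state()
            restore_state(snapshot)
        if target - n_permuted > 2 and best is not None:
            restore_state(best)

        if target - n_permuted > 2:  # beyond the ±2/|P| slack
            raise InfeasibleNoiseError(
                f"requested {target} permuted rows, achieved {n_permuted} "
                f"({n} rows, th_noise={th_noise})"
            )

    df = pd.DataFrame({"gene": genes, "term": terms, "permuted": permuted})
    realised = float(permuted.sum()) / n
    return AnnotationTable(df), realised


# ---------------------------------------------------------------------------
# Step 2: negative set
# ---------------------------------------------------------------------------

def make_negative_set(
    graph: OntologyGraph,
    truth: AnnotationTable,
    cfg: ADSConfig,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> PredictionSet:
    """Assign every gene ``neg_per_gene`` random far-away terms (score NaN).

    Terms are drawn uniformly from the non-root ontology terms and accepted
    iff their ancestor-Jaccard against every true term of the gene stays
    below ``th_noise`` and the term was not already drawn for that gene.
    """
    terms_pool = graph.non_root_terms()
    by_gene = truth.terms_by_gene()
    if max_attempts is None:
        max_attempts = cfg.max_attempts_factor * max(1, cfg.neg_per_gene)
    rows: list[tuple[str, str]] = []
    jac = graph.term_jaccard
    for gene in truth.genes:
        true_terms = by_gene[gene]
        chosen: set[str] = set()
        attempts = 0
        while len(chosen) < cfg.neg_per_gene:
            if attempts >= max_attempts:
                raise InfeasibleNoiseError(
                    f"could not find {cfg.neg_per_gene} negative terms for "
                    f"{gene} within {max_attempts} attempts "
                    "(ontology too small or shallow?)"
                )
            attempts += 1
            t_r = terms_pool[int(rng.integers(len(terms_pool)))]
            if t_r in chosen:
                continue
            if any(jac(t_r, t) >= cfg.th_noise for t in true_terms):
                continue
            chosen.add(t_r)
        rows.extend((gene, t) for t in sorted(chosen))
    df = pd.DataFrame(rows, columns=["gene", "term"])
    df["score"] = np.nan
    df["origin"] = "negative"
    return PredictionSet(df)


# ---------------------------------------------------------------------------
# Step 3: scores and merge
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def assign_scores(
    positive: AnnotationTable | PredictionSet,
    negative: PredictionSet | None,
    cfg: ADSConfig,
    rng: np.random.Generator,
) -> PredictionSet:
    """Draw prediction scores and merge the positive and negative sets.

    Positive rows get ``sc ~ N(pos_score_mean, pos_score_sd)``, negative
    rows ``sc ~ N(neg_score_mean, neg_score_sd)``; optional sigmoid squashes
    all scores into (0, 1).  Origin labels (and the ``permuted`` flag, when
    present) are retained.
    """
    pos_df = positive.df.copy()
    pos_df["score"] = rng.normal(
        cfg.pos_score_mean, cfg.pos_score_sd, size=len(pos_df)
    )
    if "origin" not in pos_df.columns:
        pos_df["origin"] = "positive"
    frames = [pos_df]
    if negative is not None and len(negative):
        neg_df = negative.df.copy()
        neg_df["score"] = rng.normal(
            cfg.neg_score_mean, cfg.neg_score_sd, size=len(neg_df)
        )
        frames.append(neg_df)
    df = pd.concat(frames, ignore_index=True)
    if "permuted" in df.columns:
        flags = df["permuted"].to_numpy(dtype=object)
        df["permuted"] = np.array(
            [bool(v) if v == v else False for v in flags], dtype=bool
        )
    if cfg.sigmoid_scores:
        df["score"] = _sigmoid(df["score"].to_numpy())
    return PredictionSet(df)


# ---------------------------------------------------------------------------
# Steps 1-3 pipeline and the series loop
# ---------------------------------------------------------------------------

def make_ap_set(
    graph: OntologyGraph,
    truth: AnnotationTable,
    signal: float,
    cfg: ADSConfig,
    child_seed: int,
) -> PredictionSet:
    """Build one AP set at the given signal level (deterministic per seed).

    ``meta`` records the child seed, the requested signal, the realised
    noise fraction and the post-shift pre-permutation table (needed to audit
    the noise constraint).
    """
    if not 0.0 <= signal <= 1.0:
        raise ValueError("signal must lie in [0, 1]")
    rng = np.random.default_rng(child_seed)
    shifted = shift_to_neighbours(graph, truth.copy(), cfg.k, rng)
    noisy, realised = permute_noise(
        graph,
        shifted,
        1.0 - signal,
        cfg.th_noise,
        rng,
        max_attempts=cfg.max_attempts_factor * max(1, len(shifted)),
    )
    negative = make_negative_set(graph, truth, cfg, rng)
    ap = assign_scores(noisy, negative, cfg, rng)
    ap.meta.update(
        child_seed=int(child_seed),
        signal=float(signal),
        realised_noise=realised,
        shifted=shifted,
    )
    return ap


def child_seed(master_seed: int, i: int, j: int) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(i, j))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def make_series(
    graph: OntologyGraph, truth: AnnotationTable, cfg: ADSConfig
) -> ADSSeries:
    """Generate the full N × |SR| dilution series."""
    ap_sets: dict[tuple[int, int], PredictionSet] = {}
    records = []
    for i in range(cfg.replicates):
        for j, signal in enumerate(cfg.signal_range):
            seed = child_seed(cfg.master_seed, i, j)
            ap = make_ap_set(graph, truth, signal, cfg, seed)
            ap_sets[(i, j)] = ap
            records.append(
                {
                    "replicate": i,
                    "signal": signal,
                    "child_seed": seed,
                    "realised_noise": ap.meta["realised_noise"],
                }
            )
    return ADSSeries(
        ap_sets=ap_sets,
        signal_levels=cfg.signal_range,
        provenance=pd.DataFrame.from_records(records),
    )


# ---------------------------------------------------------------------------
# False-positive decoy sets
# ---------------------------------------------------------------------------

def make_fp_set(
    graph: OntologyGraph,
    genes: list[str],
    freq: ICTable,
    kind: str,
    n_terms: int = 800,
    rng: np.random.Generator | None = None,
    score_mode: str | None = None,
) -> PredictionSet:
    """Build a decoy prediction set with one shared term list for all genes.

    ``naive``: the ``n_terms`` most frequent terms; ``small``: the least
    frequent (the *all positive* construction — many deep terms); ``random``:
    one shared uniform sample without replacement.  By default the naive set
    is scored by term frequency (the naive-predictor convention) and the
    small/random sets by a constant 1.0 (pure uninformative confidence);
    pass ``score_mode`` ("freq" or "constant") to override.
    """
    if score_mode is None:
        score_mode = "freq" if kind == "naive" else "constant"
    pool = graph.non_root_terms()
    if len(pool) < n_terms:
        raise ValueError(
            f"ontology has {len(pool)} non-root terms, need {n_terms}"
        )
    if kind == "naive":
        ranked = sorted(pool, key=lambda t: (-freq.freq.get(t, 0.0), t))
        terms = ranked[:n_terms]
    elif kind == "small":
        ranked = sorted(pool, key=lambda t: (freq.freq.get(t, 0.0), t))
        terms = ranked[:n_terms]
    elif kind == "random":
        if rng is None:
            raise ValueError("kind='random' requires an rng")
        idx = rng.choice(len(pool), size=n_terms, replace=False)
        terms = [pool[i] for i in sorted(idx)]
    else:
        raise ValueError(f"unknown FP set kind: {kind}")

    if score_mode == "freq":
        floor = freq.floor
        scores = {t: max(freq.freq.get(t, 0.0), floor) for t in terms}
    elif score_mode == "constant":
        scores = dict.fromkeys(terms, 1.0)
    else:
        raise ValueError(f"unknown score_mode: {score_mode}")

    rows = [(g, t, scores[t]) for g in sorted(genes) for t in terms]
    df = pd.DataFrame(rows, columns=["gene", "term", "score"])
    df["origin"] = "fp"
    return PredictionSet(df, meta={"kind": kind, "n_terms": n_terms})
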
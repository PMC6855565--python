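# Methods

This note records the models implemented in `adsbench`, the parameter
choices that matter, and the numerical conventions a user should know
before trusting — or extending — the results.

## The dilution model

An AP set at signal level *s* is produced from a direct (unpropagated)
truth table in four stages, all driven by one `numpy` Generator seeded per
(replicate, signal) cell from the master seed:

1. **Shift to semantic neighbours.** `N_shift ~ U{0..|P|}` rows are drawn
   without replacement and each selected row's term is replaced by a
   uniform draw from its ≤ *k* nearest proper ancestors (BFS distance over
   parent edges, ties broken by term ID, ontology roots excluded; default
   *k* = 3). Rows whose term has no eligible ancestor are left unchanged;
   duplicates created by shifting collapse. Because `N_shift` is drawn per
   AP set, replicates at the same signal level differ in how much they are
   generalised — variation a metric should tolerate.
2. **Permutation noise.** Term labels are swapped between rows of
   different genes until `ceil((1 − s)·|P|)` rows are permuted. A swap is
   accepted only if each incoming term has ancestor-Jaccard < `th_noise`
   (default 0.2) against **every pre-permutation term of the recipient
   gene** and does not duplicate a term the gene currently carries. The
   guard is the gene's *signal* term set: noise must be unambiguously far
   from the truth, but two noise terms may be close to each other — that
   proximity does not blur the signal, and forbidding it makes near-total
   noise infeasible on small ontologies. Each row participates in at most
   one swap, so the realised noise fraction is exact bookkeeping; the term
   multiset and the per-gene annotation counts are invariant, keeping
   class sizes and annotation depth constant across signal levels.
3. **Negative set.** Every gene receives `neg_per_gene` (default 4)
   uniformly sampled non-root terms, accepted under the same
   ancestor-Jaccard guard against the gene's true terms.
4. **Scores and merge.** Positive rows draw scores from
   N(`pos_score_mean`=1, `pos_score_sd`=0.5), negative rows from
   N(−1, 0.5); an optional sigmoid maps scores into (0, 1). The union is
   the AP set; origin labels and permutation flags are kept for auditing.

### Finding swaps at high noise levels

Uniform random pair proposals find valid swaps quickly up to moderate
noise, but near signal 0 they strand rows whose few compatible partners
were consumed earlier. The permutation therefore switches strategy when
more than 60 % of rows must be permuted: it builds the full
swap-compatibility graph and applies a maximum-cardinality matching
(blossom algorithm, `networkx`), in a random order, re-matching the
remainder, with snapshot retries and single-swap undo "kicks" to break the
rare deadlocks caused by two matched pairs delivering the same term to one
gene. A shortfall of up to two rows (odd targets, an unswappable final
pair) is tolerated — within the ±2/|P| accounting granularity — and
anything worse raises an explicit infeasibility error rather than silently
under-noising. On the default synthetic data (below), signal 0 completes
for 30/30 generator seeds.

## False-positive decoy sets

Three shared-term-list decoys per run: *naive* = the `n_terms` most
frequent terms with score = term frequency (the CAFA naive predictor);
*small* (all-positive) = the `n_terms` least frequent terms; *random* =
one random sample. Small and random sets carry a constant score of 1.0 —
maximal, uniform confidence with zero information. `n_terms` defaults to
800; on the 500-term synthetic ontology the shipped study uses 60, which
matches the decoy-to-annotated-terms ratio of the 800-term sets used on
real data (≈ 12 %). Term frequencies default to the truth set itself after
ancestor propagation; an external frequency table can be supplied.

## Metrics: conventions that matter

* **Propagation.** Group and rank metrics consume ancestor-propagated
  truth and predictions; a predicted term propagates its score to
  ancestors by maximum, so a term counts as predicted at threshold τ iff
  any of its descendants (or itself) does. Semantic metrics consume the
  direct annotations — the similarity measure already encodes the
  hierarchy — and refuse propagated input.
* **Threshold sweep.** All thresholded metrics sweep every distinct
  prediction score descending and report the best value (S_min: the
  minimum, returned sign-flipped so every metric is higher-is-better).
* **AUC-ROC / AUC-PR** are computed on the explicit prediction list:
  candidate points are the predicted (gene, term) pairs, labelled by
  membership in the propagated truth, and the area is accumulated
  step-wise over distinct scores. GC averages per-gene areas over the
  truth genes, TC per-term areas over the propagated truth terms; a unit
  with no predictions scores 0, a unit whose predictions are all correct
  scores 1. Two deliberate consequences: (a) a fully tied score list
  collapses to one curve point whose step-ROC area is 1 — this is the
  mechanism by which constant-score decoys saturate US/GC AUC-ROC, and the
  benchmark is designed to expose it; (b) for AUC-PR the same collapse
  yields the class prevalence, unless `zero_when_constant` (default on)
  maps it to 0, the recommended correction for uninformative constant
  predictors. A Mann–Whitney midrank estimator (`ties="midrank"`) is
  available and coincides with the step area whenever scores are distinct.
* **F_max** follows the CAFA convention: precision averaged over genes
  with at least one prediction above threshold, recall over all truth
  genes.
* **Information content.** `ic(t) = −log2 f(t)` with `f(t)` the fraction
  of genes annotated to `t` after propagation; `ic2(t) = −log2(f(t) /
  min_p f(p))` over direct parents (information accretion). Zero
  frequencies are clamped to `1/(2·n_genes)` so unseen terms get a large
  finite weight. Both variants feed SimGIC/SimGIC2 and S_min1/S_min2.
* **Semantic summation.** Per gene and threshold, the matrix of pairwise
  similarities between predicted and correct terms is collapsed by one of
  A (matrix mean), B (column-maxima mean), C (row-maxima mean), D =
  (B+C)/2, E = min(B, C), F (mean of concatenated row and column maxima);
  gene scores are averaged (empty predictions contribute 0) and the best
  threshold is reported. Resnik is used unnormalised — RC is rank-based
  and FPS compares within a metric, so its scale is immaterial.

## Meta-evaluation

RC pools all N·|SR| output cells and Spearman-correlates them against
their signal levels (Kendall available); with several replicates per
level the tied signal ranks cap the attainable value just below 1.
Constant outputs give RC = 0 with a warning. FPS interpolates the
horizontal FP-set score against the piecewise-linear curve of per-level
medians and reports the *largest* crossing — the worst case — clipped to
[0, 1]; scores above the top-signal median map to 1, below all medians to
0. Failed metric evaluations mark cells missing; more than 10 % missing
aborts the metric.

## Synthetic data generator

The generator emulates the structural features the dilution model needs
from real GO data, at desk scale (defaults: 500 terms, 100 genes):

* **Ontology.** A layered DAG: one root, `n_top` = 30 top-level terms,
  then 9 further levels of roughly equal size. Parents are assigned by a
  shuffled round-robin over the level above, so every lineage keeps
  descendants (plain uniform attachment is a critical-branching process
  whose lineage extinction concentrates all deep terms into a handful of
  subtrees, making every term pair semantically close). Extra parents
  (probability 0.1, up to `max_parents` = 3) are drawn from the first
  parent's siblings — multiple parentage in GO links semantically close
  terms — which keeps ancestor closures compact. The resulting random
  annotated-term pair has ancestor-Jaccard ≥ 0.2 with probability ≈ 0.02,
  the scale-relative sparsity that makes the 0.2 noise guard workable.
* **Truth sets.** Annotation counts per gene are lognormal (median ≈ 5,
  right-skewed); terms are drawn without replacement with weight
  proportional to closure size (`leaf_bias` = 1) among terms with more
  than `min_ann_depth` = 6 ancestors, mimicking curated annotations that
  sit on specific terms. Propagated class sizes come out right-skewed
  (few huge general classes, many tiny ones).

What the generator does **not** emulate: real GO term semantics and
namespace structure, evidence codes, inter-gene annotation correlation
(gene families), and the sheer scale of GO (44k terms). Consequently,
absolute RC/FPS values on synthetic data are not comparable to values on
real data — only the qualitative ordering of metrics is, and the shipped
study sizes (500 terms / 100 genes / 3 replicates / 11 signal levels,
decoys at 12 % of terms) were chosen so that one full evaluation runs in
about a minute on one CPU.

## Degenerate inputs and numerical conventions

Empty prediction sets score 0 on every [0, 1] metric; SimGIC returns 0
when the IC mass of the union is 0; Lin returns 0 when both terms have
zero IC; per-unit AUC handles single-class units as described above while
the pooled (US) form raises. Duplicate prediction rows keep the maximum
score. All tie-breaks (neighbour ordering, FP-set term ranking,
frequency ties) are lexicographic on term ID, making every output
reproducible byte-for-byte from the master seed.

## Known limitations

* The permutation matcher's fallback is stochastic; at extreme noise on
  very small or very dense ontologies it may verify that no valid swap
  set exists and raise — by design, instead of shipping an AP set with
  less noise than labelled.
* The 37-variant battery of the wider literature is represented here by
  35 registry entries; further IC-variant crosses can be added to the
  registry in one line each.
* GC AUC variants on desk-scale data show compressed dynamic range
  (ancestor overlap keeps per-gene ROC high at zero signal); rankings
  remain interpretable, absolute values are ontology-size dependent.
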
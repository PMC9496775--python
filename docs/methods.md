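# Methods

## Problem setting

A corpus of N labeled documents (classes PASC and non-PASC) is analyzed by
two unsupervised topic models; the discovered topics are then mapped onto
the two classes by majority and the mapping is scored as a classifier.
The package's claims are therefore about (i) the correctness of each
inference algorithm, established against exact small-case oracles and a
reference implementation, and (ii) the behavior of the full pipeline under
controlled synthetic study conditions, established by recovery and accuracy
experiments with known ground truth.

## LDA track

### Model and inference

Standard LDA: θ_d ~ Dir(α) (symmetric, default α = 1/k), topic-word rows
φ_t ~ Dir(η) (default η = 0.01), tokens drawn topic-then-word. Inference is
collapsed Gibbs sampling over the token-level assignments z with the usual
conditional p(z_i = t | z_−i, w) ∝ (n_dt + α)(n_tw + η)/(n_t + Vη). The
default chain length is 1000 full sweeps; estimates use the final count
state (no burn-in separation, no averaging across sweeps). This is a
deliberate simplification: on the corpus sizes this package targets
(hundreds of documents, tens of thousands of tokens) chains mix within a
few hundred sweeps, and final-state estimates keep the seed → output map
bit-reproducible. Variational inference is intentionally not offered; Gibbs
admits exact posterior checks by enumeration on tiny documents, which the
test suite exercises directly (a 3-token document, k = 2, V = 4, all 2³
assignments enumerated; chain frequencies agree within 3 batch-means
standard errors).

Token order within the sampler is fixed (document by document, word index
ascending, repeats adjacent) and each sweep consumes a fresh block of
uniforms from a seeded `numpy` Generator, so identical seed and input give
bit-identical z, φ, θ. The inner sweep is a numba kernel.

Document-topic mixtures for evaluation always come from the training
corpus; held-out inference is deliberately unsupported (`transform` on
anything but the training matrix raises).

### Model-quality scores

*Log perplexity* is the per-word log₂ training likelihood
(1/T)·Σ_d Σ_w count·log₂(θ_d · φ_{·,w}); more negative is worse. Training
rather than held-out likelihood matches the single-corpus usage of the
pipeline.

*Coherence* is UMass intrinsic coherence: per topic, with top words ranked
by φ, mean over ordered pairs of log((D(w_i, w_j) + 1)/D(w_i)) where D
counts document (co-)occurrences and the conditioning word is the
higher-ranked one. Words that never occur in the corpus (reachable only
through smoothing) are skipped. Other coherence variants (c_v, NPMI) are
out of scope; absolute coherence values are therefore not comparable
across packages, only across k within one corpus.

*Choice of k*: maximize coherence over the grid (default {3, 5, 7, 10});
among candidates within 0.01 coherence of the best, prefer the log
perplexity closest to 0, then the smaller k. The 0.01 band codifies an
informal "best trade-off" rule; it is configurable.

## Clustering track

### Embedding and reduction

The default embedder is L2-normalized TF-IDF over the corpus vocabulary
(scikit-learn's vectorizer on pre-tokenized streams): deterministic,
offline, and adequate for corpora whose classes differ in vocabulary use.
It does **not** model word order, synonymy or cross-lingual semantics — a
pre-trained sentence transformer does, and can be plugged in through the
embedder registry without touching the pipeline. Results obtained with the
default embedder are therefore not expected to match any particular
transformer-based run cluster for cluster; the pipeline's logic, not the
embedding geometry, is what the package pins down.

Reduction defaults to PCA to 5 components (full SVD; scikit-learn's
deterministic sign convention). UMAP is pluggable through the reducer
registry but is not a default because its stochastic optimization breaks
desk-scale determinism.

### HDBSCAN

Implemented in-package from primitives: core distance = distance to the
min_samples-th nearest neighbor (the point itself counting as its first
neighbor, the reference convention); mutual reachability
d_mr(a,b) = max(core_a, core_b, d(a,b)); exact O(n²) Prim MST over the
dense mutual-reachability graph; single-linkage dendrogram via union-find
over ascending MST edges; condensed tree pruning components smaller than
min_cluster_size (λ = 1/distance; a point "falls out" at the λ where its
link breaks); cluster stability Σ (λ_leave − λ_birth); excess-of-mass
selection with the root never eligible. Flat labels renumber clusters
1..C by decreasing size (ties: lowest member index) with noise −1, and
membership strengths are λ_point/λ_max within each selected cluster (0 for
noise). Defaults: min_cluster_size = 10, min_samples = min_cluster_size,
Euclidean metric on the reduced vectors.

Correctness is established against scikit-learn's independent HDBSCAN on
20 seeded blob-plus-outlier point sets (adjusted Rand index exactly 1.0,
identical noise sets) and the MST against exhaustive minimization for
n ≤ 8. Degenerate inputs: fewer points than min_cluster_size → all noise
with a warning; coincident points (zero distance) are handled by capping
λ at 10¹².

### Cluster keywords

Class-based TF-IDF on per-cluster concatenations:
W(t,c) = tf(t,c)·log(1 + A/tf(t)), A = mean token count per cluster. The
noise cluster is excluded from A, from tf(t) and from the keyword tables
(it still appears in all per-class distribution reports). Zero-weight
terms are dropped; ties break lexicographically.

## Evaluation

Positive topic = non-noise topic with the most PASC documents; Negative =
most non-PASC; ties to the lower topic id; if one topic wins both, the
Positive claim prevails and Negative falls to the best remaining topic.
Accuracy = (TP + TN)/N with N the full corpus — documents in other topics
and in topic −1 are counted in the denominator but credited to neither
class. The grouped fraction of a class is max_topic(count)/class_total over
non-noise topics. Percentages are printed half-up to two decimals; the
underlying fractions are kept exact (integer arithmetic until the final
division).

## Synthetic study conditions

The generator runs the LDA generative process forward with:

| parameter | default | rationale |
|---|---|---|
| class sizes | 73 PASC / 114 non-PASC | the emulated collection's sizes |
| mean lengths | 205 / 345 words | the emulated per-class means |
| length law | 21 + Poisson(mean − 21) | only means are emulated; 21 = shortest observed document |
| k_true | 3 | symptom / clinical / generic themes |
| class priors | PASC (4.0, 0.5, 0.5); non-PASC (0.5, 4.0, 1.0) | concentrates PASC mass on the symptom topic and non-PASC on the clinical topic, yielding majority-topic accuracy in the observed 0.86–0.92 band; a design choice, not a measured quantity |
| vocabulary | 3 blocks: 10 symptom + 40 tail, 10 clinical + 40 tail, 20 generic + 100 tail | named heads are the domain words; tails make lemma frequencies Zipfian |
| topic-word law | φ_t ~ Dir(0.05 + separation·zipf weights on own block) | separation (default 5.0) scales how block-disjoint topics are |

The Zipf weighting (1/rank within each block, normalized to mean 1) is
load-bearing: with a flat small vocabulary every word occurs in nearly
every document, document co-occurrence saturates, and UMass coherence
cannot distinguish topic counts. With Zipfian heads and tails, over-split
topics surface rare tail words with poor co-occurrence and the generative
k wins the coherence sweep by majority over seeds — the qualitative
behavior real corpora show.

What the generator does **not** emulate: Italian surface forms and
morphology (tokens are pre-lemmatized lowercase strings, so the identity
lemmatizer is exact), grammar and word order (irrelevant to both tracks),
burstiness beyond the Dirichlet-multinomial, the true length distribution
beyond its mean and floor, and any generative mechanism for the noise
cluster. Passing tests therefore certify algorithmic correctness and
pipeline behavior under Dirichlet-multinomial conditions — not performance
on scraped blog text, whose preprocessing (stopword expansion,
lemmatization quality) materially affects results.

## Preprocessing

Cleaning order is fixed: lowercase → URL removal → punctuation and special
characters to spaces (underscores survive, keeping compound tokens whole)
→ separator collapse → optional digits-only token removal. The order makes
the map idempotent. Stopword lists are plain-text files (one token per
line, `#` comments); a default Italian function-word list and a small
expansion list ship with the package, and the expansion list is explicitly
a curated substitute for unpublished original lists — results that depend
on stopword choice are not bit-reproducible across lists. Lemmatization is
a pluggable token→lemma mapping, identity by default. Vocabulary indices
follow first-occurrence order; min_df = 1 and max_df = 1.0 by default (no
dictionary filtering).

## Numerical and reporting conventions

* Ties break to the lowest index / lexicographically smallest everywhere
  (dominant topic, keyword ranks, topic-to-class mapping, frequency
  tables), making every ranking deterministic.
* One global seed is split into fixed per-stage seeds (SeedSequence with a
  fixed stage table), so enabling or disabling one track never perturbs
  the other; identical config + seed ⇒ byte-identical metrics JSON.
* Problem sizes used by the shipped experiments: the default 187-document
  corpus for recovery and end-to-end checks; 300-sweep chains for the
  k-sweep (whose scores stabilize early) and 800–1000 sweeps for fitted
  models; 21 000 sweeps for the tiny-document posterior check. These sizes
  were chosen as the smallest at which the respective statistics are
  stable.
* The worked-example percentages 86.10 and 91.97/91.98: both tracks'
  published tables are reproduced exactly as fractions (161/187, 172/187);
  the second fraction prints as 91.98 under this package's half-up
  rounding because 172/187 = 91.9786 % (a truncating convention prints
  91.97).

## Known limitations

* Held-out perplexity and held-out topic inference are unimplemented.
* UMass is the only coherence measure; its absolute scale is
  corpus-dependent.
* The clustering track's noise rate on default synthetic conditions varies
  noticeably across corpus seeds (roughly 2–35 of 187 documents), moving
  its accuracy accordingly; this is inherent to density clustering at
  these sample sizes and is reported, not suppressed.
* HDBSCAN is O(n²) memory and time; adequate for narrative-medicine
  corpora (hundreds of documents), not for large collections.
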
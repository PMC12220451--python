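# Methods

## The model

`repowalk` treats ingredient–disease repositioning as supervised link
prediction on a typed heterogeneous network with four node classes
(herb, ingredient, target, disease) and seven relations (six curated
relations plus a target–target PPI layer). The premise is structural:
an ingredient and a disease that share a neighbourhood of targets,
herbs and intermediate diseases are likely to be therapeutically
related, even when no direct edge is recorded.

### Graph construction

The graph is undirected and simple. The sources never state edge
directionality, and both downstream consumers — random walks and
shortest-path distances — are orientation-free, so undirectedness is
forced. Duplicate edges (including reversed duplicates) collapse to
one, keeping the first relation tag and the maximum weight; self-loops
are dropped with a warning (they are meaningless for walks and
distances). A node id carries exactly one type; the same string
appearing as, say, both ingredient and disease is a hard error because
feature matrices are indexed by id alone. PPI records are kept when
`combined_score ≥ 700` (inclusive); the reader accepts space- or
tab-delimited STRING files and auto-detects a header by a non-integer
third field. Edge weights default to 1; weighted input is accepted and
enters the walk bias `π_vx = α·w_vx`, but no default data source
assigns non-unit weights.

### Walks and embedding

Walk transitions follow the second-order biased rule: from state
(*t*, *v*), neighbour *x* of *v* receives unnormalised weight
`α_pq(t,x)·w_vx` with α = 1/p if x = t, 1 if x is a neighbour of t,
1/q otherwise. Defaults: `dimensions 64, walk_length 50, num_walks 10,
window 10, p 0.5, q 2` — the published operating point for this model
family; p < 1 and q > 1 keep walks local, which suits densely
clustered herb–disease neighbourhoods. The first step of a walk has no
predecessor and is sampled uniformly over neighbours (the standard
convention). Walks run on the full heterogeneous graph; node types do
not constrain transitions. Isolated nodes yield length-1 walks.

Embeddings come from skip-gram with negative sampling, implemented
in-package as a numba-compiled **sequential** SGD loop with exact
word2vec semantics: dynamic window (half-width uniform on 1..window
per center occurrence per epoch), 5 negatives from the unigram^0.75
distribution, learning rate decaying linearly from 0.025 to 1e-4 over
all scheduled pairs, 5 epochs. Sequential updates matter: on walk
corpora the vocabulary is tiny relative to the pair stream, so any
mini-batch scheme aggregates hundreds of stale-gradient contributions
per vocabulary row per batch — we observed divergence when summing
them and loss of all structure when averaging them. Training is
single-threaded and bit-reproducible under a fixed seed; parallel
(hogwild-style) training would be faster but nondeterministic, and the
corpora here are desk-scale.

Four topology attributes are concatenated raw onto the embedding
(68 dims at defaults): degree, local clustering coefficient, closeness
centrality, PageRank (damping 0.85, tolerance 1e-12). Closeness on
disconnected graphs uses the Wasserman–Faust convention (per-node
value over its reachable set, scaled by relative reachable size), so
isolated nodes get 0. Attributes are left unscaled because the
downstream tree ensemble is scale-invariant; `fuse_features`
has an optional min-max switch for scale-sensitive classifiers.

### Link prediction

Every ingredient–disease edge is a positive; negatives are drawn
uniformly without replacement from non-edge ingredient×disease pairs
at `negative_ratio` per positive (default 10, `"all"` available). The
ratio is the main knob affecting AUPR: adding negatives dilutes the
positive class and lowers precision at any threshold while leaving
AUC roughly unchanged. Requests exceeding the available non-edges are
capped with a warning — at desk scale the default ratio routinely
exhausts the pool, making the dataset effectively "all non-edges".

Pairs are fused by the Hadamard product and split 8:2, stratified by
label so the minority class stays present in the test set (falling
back, with a warning, when a class has fewer than two members). The
classifier is a random forest: 100 trees, unlimited depth, √d features
per split, single-threaded for determinism. Scores are positive-class
probabilities; `predicted_label` thresholds them at 0.5. Under heavy
imbalance the forest's probabilities are conservative, so recall at
0.5 is low even when ranking quality (AUC) is high — the ranked list,
not the thresholded call, is the repositioning output. Disease
rankings sort by score descending with ties broken lexicographically
by disease id for reproducibility.

**Leakage control.** By default the embedding is retrained on the
network with the test-split positives removed, so no test edge can
leak into the features it is judged on. A `full_graph_embedding` flag
restores the cheaper convention of embedding the complete graph once;
the run log records the mode prominently because it changes results.

**Metrics.** AUC is the rank-based ROC area (ties count 1/2). AUPR is
average precision with step-wise interpolation — interpolation
conventions differ between tools, so this one is fixed and
cross-checked in the tests against a from-scratch implementation.
Accuracy, precision, recall and F1 are computed for the positive class
at the decision threshold.

### Network separation

For gene sets A and B on the PPI,
`S_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2`, where ⟨d_AB⟩ averages, over
members of both sets, each node's shortest-path distance to the
closest member of the other set (0 for shared members), and ⟨d_AA⟩,
⟨d_BB⟩ average each member's distance to the closest *other* member
of its own set. Genes absent from the PPI or with no finite distance
are dropped from the means and reported, rather than poisoning the
mean with infinities. Within-set means are undefined for singleton
sets (`set_distances` raises); the cross-set mean alone is available
via `cross_set_distance`. Negative S_AB indicates topologically
overlapping modules. No permutation z-score is attached: the score is
reported raw, as a descriptive statistic.

## The synthetic benchmark

The generator is a latent-module (stochastic block) model: each node
joins one of `k_modules` uniformly; within-module pairs connect with
probability `p_in`, cross-module with `p_out`, for the five background
relations; ingredient–disease positives are planted on same-module
pairs at rate `p_in`; PPI scores are drawn from [800, 1000] within
modules and [0, 400] across, so the standard 700 filter separates
signal from noise by construction. Block structure is the right null
model here because it *is* the repositioning premise — ingredients and
diseases sharing a target neighbourhood are the linked ones — and
`p_in/p_out` is a single interpretable effect-size dial.

Defaults: 10 herbs / 40 ingredients / 120 targets / 30 diseases,
k = 4, p_in = 0.4, p_out = 0.01 — chosen as the package's desk-scale
operating point: large enough for stable recovery (held-out AUC
0.88–0.94 across seeds, tested ≥ 0.8 over five seeds), small enough
that a full pipeline run takes seconds. An optional `holdout` fraction
withholds 20% of planted positives from the emitted files to support
evaluation against an external positive set.

What the generator does **not** emulate: real degree distributions
(ETCM-like networks are heavy-tailed; blocks are homogeneous),
database-scale node counts, cross-database identifier noise, or
biased/correlated negative annotations. Passing tests therefore show
the pipeline recovers planted block structure under clean conditions —
they bound implementation correctness, not real-data performance. One
consequence worth knowing: the filtered synthetic PPI is exactly the
within-module graph and is therefore disconnected across modules, so
cross-module separation scores must be computed on the unfiltered PPI
(as the acceptance script does).

## Numerical and design notes

- **Seeding.** A single run seed fans out as `stage_seed = seed +
  stage index` (negatives 1, split 2, walks/skip-gram 3, forest 4), so
  stages can be re-run in isolation. All samplers are numpy
  `default_rng`; runs are byte-identical for identical config + seed.
- **Walk sampling** memoises the transition CDF per directed edge
  (prev, curr) — states recur many times per corpus, making corpus
  generation near-linear in steps.
- **Skip-gram scatter** and arithmetic are float32; returned
  embeddings are float64. Sigmoid saturates at |x| > 8.
- **Degenerate inputs.** Empty networks, all-length-1 walk corpora,
  single-class training sets, one-class evaluation records, empty or
  singleton gene sets, and exhausted negative pools all raise typed
  errors (or warn and cap, where the spec of the operation is a
  best-effort one).
- **Open choices resolved.** Negative sampling, decision threshold
  (0.5), stratification, RF hyperparameters and the AUPR convention
  are not pinned by the workflow this package systematises; each is a
  documented default in config rather than a hidden constant.

## Known limitations

- The embedding trainer is single-threaded by design; very large
  corpora would need hogwild parallelism at the cost of determinism.
- `build_pair_dataset` enumerates the ingredient×disease non-edge pool
  in memory — fine to ~10⁷ pairs, not beyond.
- Identifier matching is exact-string (optional upper-casing for gene
  sets); no ontology or cross-database id mapping.
- The thresholded metrics inherit the forest's conservative
  probability calibration under imbalance; users who need calibrated
  hard calls should tune the threshold on validation data.
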
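# Methods

## The resampling model

Let `G_o` be a simple undirected graph with `n` nodes. A *subsample* is a
uniform without-replacement draw of `max(1, floor(f * n))` nodes together
with its induced subgraph, for a fraction `f` in (0, 1]. For an ordered set
of statistics **S**, the package builds three resampling distributions as
`B x |S|` matrices:

* `F_o` — statistics of `B_o` subsamples of the observed network;
* `F_c` — statistics of one subsample from each of `B_M` *independent*
  draws from a candidate model `M_c`, each draw grown to the same `n` as
  `G_o`;
* `F_1` — statistics of `B_M` subsamples of a *single* model draw.

`F_c` rather than `F_1` is the default model-side object because single
draws from mechanistic models can be unstable (see the stability study
below); `F_1` exists for diagnostics. Observed and model sides always use
the same fraction, so both carry the same degree of missingness — this
comparability is the heart of the method. Subsampling the observed network
does not alter the dependence structure that formed it, unlike simulating
from a fitted model, which imposes the fitted model's dependence.

### Choice of the subsample fraction

`fraction_diagnostic` estimates E[KS(F_1, F_c)] per statistic over a grid
of fractions: where it is small, one model draw already behaves like many,
so the fraction retains model features without over-committing to a single
realisation. The package default is `fraction = 0.3` (keep the subsampled
portion low); the selection-study harness uses 0.8 of 100 nodes, matching
the study it replicates. At `fraction = 1` the observed-side distribution
collapses to a point mass and the method degenerates.

## Statistics

Registered under string identifiers; all are label-invariant:

* `avg_clustering` — mean over nodes of (edges among neighbours)/C(deg, 2);
  nodes with degree < 2 contribute 0 (this convention makes a star 0 and
  any complete graph 1).
* `triangles` — global triangle count.
* `assortativity` — Pearson correlation of endpoint degrees with both edge
  orientations included. Undefined (NaN) when endpoint degrees have zero
  variance (regular graphs) or the subsample has no edges; rows containing
  undefined values are *dropped and counted*, never imputed, since imputing
  a constant would distort the distribution.
* `deg_q25`/`deg_q50`/`deg_q75` — degree-sequence quantiles with numpy's
  linear interpolation. The convention is arbitrary but fixed: only
  consistency between training and test features matters for selection.

Users can register additional statistics; a `from_adjacency` fast path may
be supplied for use inside the resampling loops.

## Distances

* **KS**: `sup_t |ECDF_x(t) - ECDF_y(t)|` evaluated on the pooled sample
  with right-continuous ECDFs — exact under ties, valid for discrete data
  such as triangle counts. Used descriptively (no p-values: subsample rows
  are dependent).
* **KL**: both samples histogrammed on shared Freedman–Diaconis bins from
  the pooled sample; `1/(2(n_x + n_y))` mass is added per bin before
  normalising so empty bins never give infinities. `smoothing=0` recovers
  the raw plug-in estimate.
* Multivariate comparison across all of **S** jointly is an extension
  point only (`joint_distance` takes any callable on the two raw
  matrices); no specific multidimensional generalisation is shipped.

## Procedures

**Goodness of fit** builds `F_o` once and one `F_c` per candidate, then
reports per-statistic distances and the induced orderings. Orderings are
deliberately reported per statistic and never collapsed — different
statistics can disagree about which model fits best, and that disagreement
is informative. Candidate RNG substreams are derived from a digest of the
model spec, not its list position, so reports are exactly invariant to
candidate order.

**Model selection** trains a classifier on `B_M` labelled rows per
candidate (independent-draw mode), classifies each of the `B_o` observed
subsamples, and selects by plurality; the winning proportion is the
confidence. The binary score-threshold rule (score 0.5) generalises to
per-subsample predicted labels plus plurality for 3+ candidates. Ties are
broken toward the lowest candidate index and flagged. Reference learners:
nu-SVC (nu = 0.5, RBF kernel, standardised inputs), random forest (1000
trees, minimum terminal node size 1), k-NN (k = 10), and a stacked
ensemble of the three with a logistic meta-learner fitted by 5-fold
cross-validation — a cross-validated-weighting reading of the ensemble
role, chosen over discrete winner-takes-all selection because it degrades
more gracefully when base learners are comparable. Any
sklearn-style estimator can be substituted. `ModelSelector` follows the
scikit-learn estimator contract and also accepts plain feature matrices.

**Multi-network comparison** builds one observed-side distribution per
network and reports the per-statistic (and mean-aggregated) pairwise
distance matrices; with KS the matrices are symmetric.

## Simulators

All generators grow a boolean adjacency matrix and are bit-reproducible
from an integer seed or `numpy.random.Generator`.

* **ER growth** (`p`): each new node links to every existing node
  independently with probability `p`. Seeded with K1 this is exactly
  G(n, p); mean edge count `C(k,2) + (C(n,2) - C(k,2)) p` from a seed K_k.
* **DMC** (`q_mod`, `q_con`): duplicate a uniform node's neighbourhood;
  for each neighbour, remove one of the two parallel-role edges (chosen
  uniformly) with probability `q_mod`; link original and copy with
  probability `q_con`. With `q_mod = 1, q_con = 0` the edge count is
  conserved exactly at every step. Duplicating an isolated node has an
  empty divergence loop; only the `q_con` coin applies.
* **DMR** (`q_del`, `q_new`): each copied edge is deleted independently
  with probability `q_del`; each node present at step start then links to
  the new node with probability `q_new / n(t)` (`q_new` is an *expected
  edge count per step* and may exceed 1, as in published fits; a success on
  an already-copied pair changes nothing). With `remove_singletons`, a new
  node finishing the step with degree 0 is discarded and the step does not
  count; a cap of `100 n` attempted steps turns the non-terminating
  configuration (`q_del` near 1, `q_new` near 0) into an error.
* **Triangle closure** (`p0`, `p1`, `p_delta`, target `m`): propose
  uniform non-adjacent pairs; accept with `p0` when no triangle would be
  closed, else `p0 + p1 + (t - 1) p_delta` for `t` triangles closed,
  clamped to [0, 1]. With `p1 = p_delta = 0` acceptance is state-independent
  and the result is exactly uniform G(n, m). A cap of `1000 m` probability
  rejections surfaces degenerate parameterisations instead of hanging.

Seed constructors: complete graphs K_k; a 50-node two-clique composite
(intact K7 and K10, each of the 70 cross-clique pairs linked independently
with probability 0.67, 33 pendant nodes anchored uniformly among the 17
clique nodes — the minimal reading of an under-specified published
construction, expected edge count 145.9); and an inverse-geometric seed
(i.i.d. standard-normal coordinates in R^d, edge when pairwise distance
*exceeds* R — implemented exactly as its source states even though it
inverts the usual geometric-graph convention; `connect_within=True`
restores the conventional rule). Per-pair edge probability at d = 2,
R = 1.5 is `exp(-R^2/4) ≈ 0.570`.

## Randomness and reproducibility

Every resampling matrix derives one `SeedSequence` substream per row from
`(scheme.seed, row index)`: rows are independent, results are identical
whether rows are evaluated serially or in parallel, and fixed seeds give
bit-identical matrices, graphs and CLI outputs. Subsample index sets are
sorted so that equal node sets give bitwise-equal statistic rows
(summation order is fixed).

## Study harnesses and problem sizes

*Selection study*: model 1 and model 2 are triangle-closure models with
`p0 = 0.3`, `p1 = 0.1` and `p_delta = 0` vs `p_delta` in
{0.05, 0.03, 0.01, 0.005}, on 100-node networks with m in
{100, 500, 1000, 2000}; training uses one 80-node subsample from each of
10000 draws per model and testing 1000 networks per model with 100
subsamples each. The harness exposes a `scale` factor applied to the draw
counts; the package default of 0.1 (1000 training draws, 100 test networks
per model) runs every cell in about a minute while leaving the estimated
proportions unchanged up to binomial noise — scaling changes Monte-Carlo
error, not the estimand. Accuracy in separable cells (large `p_delta`,
dense graphs) approaches 1; near-null cells sit at 0.5 and their
confidence histograms centre on 0.5.

*Stability study*: replicate networks are grown per (model, n, seed size)
and the replicate-to-replicate variability of the degree distribution is
summarised as the mean pairwise total-variation distance between empirical
degree distributions. The scalar summary is this package's proxy for what
is usually assessed visually as the width of the band of overlaid degree
distributions, and it reproduces the qualitative finding: DMC/DMR
variability falls sharply as the complete-graph seed grows from 5 to 50
nodes, while ER growth is insensitive to seed size. Defaults mirror the
full design (50 replicates; n in {1000, …, 10000}; seeds K5–K100); tests
and the acceptance script run 25 replicates at n = 1000.

## What the synthetic data does and does not show

All test inputs are produced by the package's own simulators, so passing
tests demonstrate internal consistency of the framework and faithful
implementation of the models — not fit to any real interaction network.
Real PPI data differ in ways the simulators do not emulate (sampling/assay
bias, false positive and negative interactions, database versioning), so
the goodness-of-fit workflow is exercised end-to-end on a synthetic
stand-in network of ~5100 nodes drawn from a literature-style DMR
parameterisation, and conclusions about real data require the real edge
list as input (any curated set exported as a two-column edge list works).

## Numerical choices and degenerate inputs

* Subsample size `max(1, floor(f n))` — never empty, no rounding surprise.
* LCC ties broken toward the component containing the lexicographically
  smallest node label.
* KS is computed over pooled points exactly; KL smoothing as above.
* Plurality ties flagged and broken toward the lowest candidate index.
* Rows with undefined statistics dropped with a logged and reported count;
  a distribution can legitimately end up empty (e.g. assortativity on
  complete-graph subsamples), which downstream procedures flag.
* Edge-list files cannot express isolated nodes; a `%ISOLATED` sidecar
  section preserves them through round trips.

## Known limitations

* Only uniform node subsampling is implemented (snowball/edge designs are
  out of scope), though any scheme applied identically to both sides would
  be methodologically valid.
* KS/KL are univariate; joint comparison across statistics is a hook, not
  a feature.
* Confidence is descriptive, not a calibrated probability; no hypothesis
  tests are attached to the distances.
* DMC networks densify quickly for small `q_mod`; memory is O(n^2) (dense
  adjacency), fine up to tens of thousands of nodes but not for
  million-node graphs.
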
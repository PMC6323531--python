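# Methods

## Model and assumptions

The method segments an 8-bit grayscale image by clustering its gray
levels, not its pixels' coordinates: pixels are the data points, the
distance between two pixels is |g − g′| of their gray levels, and all
computation reduces to the 256-bin histogram. The underlying assumption
is that tissue classes occupy distinct gray ranges, so a good partition
of the gray axis is a good partition of the image. No spatial
regularity is modeled; tissue classes that overlap in gray cannot be
separated by this method.

The gray domain is fixed at 0..255. Deeper inputs must be explicitly
min-max rescaled (`rescale=True` / `--rescale`); color inputs are
reduced by ITU-R BT.601 luma with round-half-up, so the conversion is
deterministic. DICOM windowing is deliberately left to the caller: there
is no principled default window, so none is guessed.

## Density-peaks clustering on the histogram

For every present gray level, with cut-off distance d_c:

* rho(g) = sum over levels g′ with |g − g′| < d_c of counts[g′]. The
  inequality is strict (the neighborhood indicator is 1 only for
  negative arguments), so d_c = 1 degenerates to rho = counts. Density
  is frequency-weighted — an unweighted per-level count would discard
  the histogram ordinate entirely. The pixel's own level is included;
  this shifts every rho by the same self-count and never changes any
  ranking.
* Ties in rho are totally ordered by (rho desc, counts desc, gray asc).
  Any fixed total order would do; this one prefers the better-populated
  level and is deterministic.
* delta(g) = min distance to a strictly higher-ranked level, with the
  nearest-neighbor tie resolved toward the lower gray. The top-ranked
  level takes the **maximum** distance to any other level — the
  original density-peaks convention — so the global density peak gets
  the large gamma it needs to be selectable as a center. For a
  single-level histogram delta := 1 so gamma stays defined; such images
  yield a single-cluster result.
* gamma = rho · delta; the k largest (ties: larger rho, then lower
  gray) are the centers, k silently clamped to the number of present
  levels (recorded as `effective_k`). Label propagation visits levels
  from the densest down; each non-center inherits its nearest
  higher-ranked level's label, which is always already assigned.

Because gray distances are integers and the density test is strict,
only ceil(d_c) matters: all d_c in (n−1, n] produce identical
clusterings. The integer lattice d_c ∈ {1..10}, k ∈ {2..40} therefore
covers the whole continuous search box, which is what makes the
390-cell exhaustive grid an exact upper bound for the stochastic
optimizers, and what lets fitness evaluations be memoized per
(ceil(d_c), k) cell.

## Fitness and evaluation metric

The optimizer maximizes the Shannon entropy, in bits, of the segmented
image's cluster-frequency distribution (0·log 0 := 0). Base 2 and the
standard negative sign are used; H ≤ log2(effective_k) with equality
iff clusters are equally populated, and a deterministic coarsening of
levels into clusters can never exceed the raw histogram's entropy.

SEC orders clusters by mean gray and sums, over adjacent pairs with
sizes N, M and means U1, U2, the two-class between-class variance
N/(N+M)(U1−U)² + M/(N+M)(U2−U)² with U the pooled mean — algebraically
NM/(N+M)²(U1−U2)². "Adjacent" means adjacent in mean-gray order;
spatial adjacency is not defined for a histogram clustering. A
single-cluster segmentation has SEC := 0.

## Fruit-fly optimizer

The swarm lives directly in the two-dimensional decision space: a
position's first coordinate carries d_c, its second carries k, matching
the method's identification of the two decision variables with the
swarm's X and Y axes. Decoding clamps d_c into [1, 10] and k, rounded
half-up, into [2, 40]; clamping means proposals beyond a bound land on
it, so the box edges are reachable. Each generation every fly proposes
anchor + U(step_low, step_high) per coordinate (defaults −5, 5 — the
random step that replaces classic FOA's fixed step), proposals are
scored, and the anchor relocates to the generation's best proposal only
if it improves the best smell found so far (elitism), so the
convergence trace is non-decreasing. Defaults are population 10 and 10
generations (100 fitness evaluations per run). The anchor initializes
uniformly inside the search box. The classic FOA scoring transform
S = 1/sqrt(X² + Y²) is exposed as `smell_concentration` for reference;
it is not used in the search, where positions are parameters
themselves — with ±5 steps, the reciprocal transform can essentially
never produce S above ~2, which would confine k to its lower bound and
make the search inoperative.

All randomness flows from one seeded `numpy` generator per run; a fixed
seed reproduces positions, traces and reports bit for bit.

## Baselines

* **Grid search** enumerates all 390 lattice cells in fixed order; ties
  at the maximum resolve to the lexicographically smallest (d_c, k).
* **Weighted 1-D k-means** (scikit-learn) runs Lloyd's algorithm on the
  present gray levels weighted by their counts, seeded k-means++ init,
  clusters relabeled in ascending-centroid order; default k = 7.
* **Genetic algorithm** (population 10, 20 generations = 200
  evaluations): tournament selection of size 2, BLX-0.5 blend crossover
  at rate 0.9, per-gene mutation at rate 0.1 that resets the gene
  uniformly, half the time snapped to a box boundary
  (Michalewicz-style), elitism of 1, children clipped to the box. Blend
  crossover and boundary mutation are load-bearing: a maximum-entropy
  objective leans on the upper k bound (H ≤ log2 k), and a purely
  interpolative crossover cannot reach a boundary optimum reliably.

## Synthetic phantoms

A phantom is a background gray plus ellipse/rectangle regions at
distinct base grays (later regions overwrite earlier), with additive
Gaussian noise rounded half-up and clipped to 0..255, and a pixel-exact
truth labeling. The standard suite holds five 64×64 phantoms with 2–4
tissue classes, base grays at least 60 apart, and noise sigma in
{0, 3, 5} gray units — separations and noise chosen so that classes are
distinct in gray but levels overlap enough to exercise the clustering.
What phantoms emulate: the piecewise-near-constant gray structure of
brain CT/MRI slices (lesion/edema regions on a darker background).
What they do not: Rician MRI noise statistics, bias fields, partial
volume effects, or anatomical texture. Tests passing on phantoms
therefore certify the algorithmic contracts (optimality, recovery,
determinism), not clinical segmentation quality.

Scoring against truth: `match_and_score` uses one-to-one Hungarian
matching on the confusion matrix and suits comparisons at equal class
counts; `merge_and_score` first merges each predicted cluster onto the
truth class it overlaps most, which is the right notion when the
entropy-maximal segmentation is deliberately finer (tens of gray bands)
than the handful of truth classes.

## Numerical choices and degenerate inputs

* Round-half-up (`floor(x + 0.5)`) everywhere a real becomes a gray
  value or a k, for platform-independent determinism.
* Argmax ties in the optimizers go to the lowest index; grid-search
  ties to the smallest (d_c, k).
* A constant image yields one level, one cluster, entropy 0, SEC 0, for
  every method.
* Fitness values must be finite; a NaN/inf fitness raises immediately.
* k-means requires 2 ≤ k ≤ number of present levels; the pipeline
  clamps its default k to the level count.
* JSON reports serialize with sorted keys and contain no timestamps, so
  equal seeds give byte-identical files.

## Problem sizes used in tests

The test suite and acceptance script use the 64×64 suite phantoms,
20 optimizer seeds per phantom, 200 random histograms (≤ 20 levels,
≤ 10⁴ pixels) for the brute-force cross-check, and a 30-generation
swarm for the smooth quadratic recovery check; the full run completes
in well under a minute on one core.

## Known limitations

Gray-overlapping tissues are not separable; no spatial prior; no 3-D
volumes; the maximum-entropy objective prefers the finest admissible
clustering (k at its upper bound) whenever noise spreads the histogram,
so a semantically small class count must be imposed afterwards (e.g. by
merging clusters against an atlas or prior), as the recovery tests do
with majority merging.
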
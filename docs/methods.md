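# Methods

## Scope

The package implements a complete functional-layout analysis for
labeled voxel time series: prewhitening, correlation pooling, UPGMA
clustering, serial-order regression, and permutation tests of compact
component placement. Raw resting-state fMRI for the 52-area cortical
parcellation is not publicly deposited, so a synthetic generator with
known ground truth provides the data; the packaged atlas (52 areas,
mean Talairach coordinates and volumes over 18 adults) is real.

## Synthetic data model

Each subject's data are built in three layers.

**Latent area signals.** At every time point the 52 areas receive a
joint Gaussian draw with correlation matrix

    C(a, b) = exp(-lambda * d_fold(a, b)) * gamma^[cross-hemisphere]
    C(a, b) <- C(a, b) + beta * (1 - C(a, b))   for homotopic pairs,

where `d_fold` is the Euclidean distance between areas on
hemisphere-folded coordinates (|LR|, PA, IS), `lambda` is the distance
decay (default 0.05 / mm), `gamma` the contralateral attenuation
(default 0.7), and `beta` the homotopic boost (default 0.3). Folding
plus a uniform attenuation makes the two hemispheres' connectivity
profiles mirror images of each other — the property of real cortex that
makes homotopic areas cluster as left/right doublets — while still
producing the empirical ordering of coupling strength: within-area >
homotopic > ipsilateral > contralateral. A bilateral (unfolded)
exponential kernel was evaluated and rejected: it renders left and
right profiles maximally dissimilar, so homotopic doublets and the
anterior→posterior leaf order are unrecoverable by profile-distance
clustering at any parameter setting, and it admits almost no homotopic
boost before losing positive semi-definiteness.

The defaults are checked to give a positive-definite C on the packaged
atlas (smallest eigenvalue ≈ 0.06). Invalid combinations raise with a
parameter suggestion; an opt-in nearest-correlation repair (Higham
alternating projections) exists for deliberately extreme settings and
is reported by `ground_truth_correlation`, which returns the exact
matrix the simulator samples from.

**Voxels.** Each of the (by default) 10 voxels of an area mixes the
area signal with weight 0.9 and idiosyncratic N(0, 0.35²) noise, giving
within-area voxel coupling ≈ 0.87, above the homotopic tier.
A volume-proportional voxel allocation is available but uniform counts
are the default (test speed; the analysis never weights by voxel
count).

**Coloring.** The white voxel mixture is ARMA-filtered (defaults AR
0.4, MA 0.3), summed with a subject-specific drift slope ~ N(0, 0.05²)
per step, integrated once (cumulative sum), and offset by a baseline of
1000 — i.e. an ARIMA(1, 1, 1)-with-drift process on a positive level,
so ARIMA(p, 1, q) prewhitening is well specified and the 5%
coefficient-of-variation voxel filter operates on realistic levels.
Default series length is 203 volumes, 18 subjects.

What the generator does **not** emulate: volumetric images (no spatial
smoothing or partial-volume effects), physiological noise (cardiac or
respiratory), inter-subject anatomical variability, or heavy-tailed
artifacts. Passing tests therefore show that the analysis chain
recovers the statistical structure it assumes; they cannot certify
behavior under real-scanner artifacts.

## Prewhitening

Trim (3 initial volumes), CV filter (sd/mean ≤ 0.05; non-positive-mean
voxels excluded with an explicit reason), then an ARIMA(15, 1, 1) fit
per voxel. Two estimation criteria are exposed and recorded in output
metadata: full Gaussian MLE via the Kalman filter (`"statespace"`, the
function default) and the regression-based Hannan–Rissanen estimator
with residuals from Kalman-filtering the fixed parameters
(`"hannan_rissanen"`, roughly 13× faster and what the packaged pipeline
configuration uses; at ~200 observations the innovations it produces
pass the whiteness checks at the same rates). With d ≥ 1 a drift term
is included by default so innovations are mean-zero under linear
trends; `trend="n"` disables it, under which a (0, 1, 0) "fit" returns
exactly the first differences. Non-converged fits fall back to
(5, 1, 1) then (1, 1, 1); a voxel failing all three is excluded and
logged, and the result records the order actually used. The first `d`
residuals (diffuse initialization) are dropped, so a 203-volume voxel
yields 199 innovations. Ljung–Box uses 20 lags by default with no
degrees-of-freedom correction for fitted parameters (a `model_df`
switch exists).

## Proximity and clustering conventions

Voxel-pair Pearson correlations are clipped at |r| = 1 − 1e−7 before
the Fisher transform so degenerate perfect pairs stay finite.
Within-area pooling uses unordered distinct voxel pairs (no
self-pairs); cross-area pooling uses all |A|·|B| pairs. The +2 constant
is added per subject before averaging; adding it after is algebraically
identical and kept as an option with an equivalence test. The diagonal
stores the within-area pooled correlation + 2 but is excluded from
clustering features.

Profile distance between areas a and b is the squared Euclidean
distance between their proximity rows over the columns k ∉ {a, b}: the
two self-columns are removed so an area's own within-area proximity
does not dominate. UPGMA is implemented in-package with an explicit
deterministic tie-break (smallest lexicographic pair of cluster ids);
scipy's average linkage and a brute-force recomputation of all
cross-pair means serve as independent oracles in the tests. Merge
heights are reported raw (squared-distance units); Newick export uses
height/2 as node age, giving an ultrametric tree.

A dendrogram determines its leaf order only up to a flip at every
internal node, so the serial order is a convention and three policies
are provided: `index` (subtree containing the smaller original label
index first — the default of `leaf_order`), `height` (tighter subtree
first), and `seriate` (optimal leaf ordering: flips chosen to minimize
the total distance between adjacent leaves). The pipeline uses
`seriate`, which is the only policy whose order reflects the spatial
gradient rather than label bookkeeping; its global direction is fixed
by an orientation vector (the pipeline passes PA coordinates, putting
the anterior end at rank 1, mirroring how a published dendrogram is
read top-down). Serial order is 1 at the top; this convention is
recorded in the regression artifact.

## Regression and compactness conventions

The layout regression enters LR **signed** (a near-zero LR coefficient
is the signature of homotopic doublets); t statistics use the residual
degrees of freedom (n − 4 = 48 for the full atlas). The bilateral
compactness analysis **rectifies** LR (|LR|) so homotopic doublets are
spatial neighbors; per-hemisphere analyses (M = 25) keep LR signed and
re-cluster from the hemisphere-only proximity submatrix rather than
pruning the bilateral tree.

Permutations are uniform over all orderings, identity included; the
identity produces a tie, not a violation, under the strict inequality
`D̄_perm < D̄_tree`. Window starts for the subset analyses are drawn
uniformly with replacement over the full inclusive range
0 … n − L. Because the compactness ratio is positive, window values are
averaged on the natural-log scale and exponentiated (geometric mean).
Randomness uses one root seed with `SeedSequence`-spawned child streams
per test and per window, so any window's result is independent of
execution order, and a full-length window reproduces the whole-set
adjacency test exactly. Degenerate sequences (all coordinates
identical, observed mean distance 0) raise rather than return an
infinite index.

## Problem sizes and observed behavior

The test suite and the acceptance script run the chain at 6 subjects ×
52 areas × 10 voxels × 203 volumes (3 120 ARIMA fits, ~1 minute with
the Hannan–Rissanen path) — a scale-down of the 18-subject study
condition chosen to keep a full run in minutes; the generator's default
remains 18 subjects. At the scaled-down size the recovered tree shows
zero adjacency violations at N = 1000 (bilateral and per hemisphere),
> 95% Ljung–Box whiteness, and a dominant negative PA coefficient. The
size-law and metamodule postulates are asserted on the model's compact
layout (the tree of the noise-free latent proximity): geometric-mean c
rises strictly over L ∈ {12, 20, 30, 40, 51} and metamodule violations
are exactly zero over 5 × 10⁶ window-permutations. On noisy recovered
trees the metamodule count is near zero but not guaranteed zero (of
order 10⁻⁶ per window-permutation at these data volumes); the
acceptance script reports both. Per-hemisphere windows at L = 10 can
show small violation counts even noise-free — within one hemisphere
there are no homotopic doublets anchoring small windows.

## Known limitations

* The ARIMA order (15, 1, 1) is taken as given; no order selection is
  performed (the `order` argument accepts alternatives).
* Zero-lag Pearson correlation only — no lagged, partial, or spectral
  connectivity.
* UPGMA is the only tested linkage; the compactness machinery is
  agnostic to how the order was produced.
* Synthetic realism is limited to the statistical features listed
  above; conclusions about real scanner data require real data.
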
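# Methods

## Maps, grids and geometry

A `DensityMap` stores node-sampled scalar values with full crystallographic
geometry: the unit-cell orthogonalization matrix, the per-axis sampling of
the full cell, and a Cartesian origin assembled from the MRC ORIGIN record
plus start-index offsets, covering both the cryoEM and the CCP4 origin
conventions. Axis order is normalized to (x, y, z) on read, so all six
storage permutations of the same physical map produce identical arrays.
Interpolation happens in fractional (index) coordinates through the inverse
step matrix, which makes resampling correct for non-orthorhombic cells;
trilinear interpolation is used, which reproduces constant and linear
fields exactly. The interpolation order is a package choice — nothing in
the problem fixes it — and trilinear is the cheapest scheme that preserves
the degree-1 exactness the tests rely on.

`VoxelGrid` is the axis-aligned 0.2 Å product of resampling: voxel `i`
spans `[origin + i·s, origin + (i+1)·s)` and its center, `origin +
(i+0.5)·s`, is the coordinate a point cloud inherits. Fixing the half-open
convention removes a recurring off-by-half ambiguity between node- and
cell-centered interpretations.

## Thresholding

The X-ray cutoff is `k·σ` with `k = 2.8` and σ the population standard
deviation of all map voxels — the standard crystallographic convention.

CryoEM maps get the three-step normalization:

1. **Zero-inflation trimming.** Median and SD are computed over *all*
   voxels of the map (the spike is exactly what anchors the median); values
   within ±0.5 SD of the median are dropped, both tails kept. A single
   pass is performed — iterating the trim would change the statistics it
   depends on and has no empirical motivation.
2. **Quantile thresholding.** The cutoff is the empirical q-quantile
   (linear interpolation between order statistics, matching the sort-based
   oracle) of the surviving sample, with `q = Φ(2.8) ≈ 0.9974449` computed
   from the normal CDF at machine precision rather than hard-coded to four
   digits. On a Gaussian map this reproduces the X-ray 2.8σ cutoff; on a
   trimmed zero-inflated map it is strictly higher than the raw quantile,
   which is the entire point of the trim.
3. **Value calibration.** After zeroing sub-threshold voxels, values are
   rescaled multiplicatively so the lowest nonzero value equals the
   calibration-table target for the map's resolution. The table uses
   0.1 Å bins with nearest-bin lookup and edge clamping; the shipped table
   is synthetic (monotone targets decaying with the resolution bin) since
   real targets require the full X-ray blob corpus.

Every statistic in the chain is scale-equivariant, so the selected voxel
set and the calibrated output are invariant to a global rescaling of the
input map — a property the tests assert over three orders of magnitude.
The quantile is computed map-wide, not within a ligand box, mirroring how
the histogram is analyzed in practice.

## Blob extraction and filters

Connected components run on the nonzero voxels at 6/18/26 connectivity
(default 26, the most permissive: thin diagonal density bridges at 0.2 Å
sampling should not split a ligand). Volume is `nonzero count × 0.008 Å³`.
Filter inequalities follow their printed form exactly — in particular the
RSZD criterion is inclusive (`≥ 6.0` rejects) while the cryoEM volume
criterion is strict (`> 2.14 Å³` keeps) and the Q-score bound is inclusive
(`≥ 0.6` keeps). Blob-to-ligand assignment uses a 2.0 Å atom-to-voxel
radius, roughly a covalent bond length plus half a voxel diagonal.

## Point sampling

`partition_meta_voxels` starts at divisor N = 1 and increments while the
occupied-block count at the next N stays within `max_p`, returning the last
admissible N — the literal iterative rule, kept even though occupancy can
be non-monotonic in N for sparse masks. Block shape is `ceil(dim/N)` per
axis (zero padding). Uniform-max keeps the highest-density voxel per
occupied block with ties broken toward the lowest (z, y, x) index, making
it fully deterministic and permutation-invariant. Surface sampling defines
the shell by 6-connectivity to zero (or out-of-bounds) neighbors — the
strictest notion of "outer shell". Clustering sampling runs seeded
k-means++ (k = max_p, ≤ 50 iterations) on coordinates; each centroid
carries the density of its nearest original point so values stay on the
original scale, mirroring the uniform strategy's contract.

## Classifiers

Both architectures sit on a small in-repo reverse-mode autodiff core
(`models/autodiff.py`): numpy tensors, broadcasted arithmetic, matmul,
reductions with max/segment-max, gather/scatter, log-softmax, and
topological backpropagation. It is deliberately minimal and deterministic.

**Rotation-invariant stack (`riconvpp`).** The network never sees raw
coordinates. Each point gets 11 informative rotation-invariant features:
its density, distance to the centroid, neighborhood distance statistics
(mean/max/SD), the sorted eigenvalues of the neighborhood covariance, the
|cosine| between the local reference axis (smallest-eigenvalue eigenvector,
sign-disambiguated toward the centroid) and the centroid direction, the
mean cosine of neighbor offsets against the centroid direction, and the
mean neighbor density. Neighborhoods are the k = 16 nearest points
*inclusive of distance ties* (every point within the k-th neighbor distance
plus 1e-9), so the neighborhood is a purely metric object — unchanged by
reordering and by rotation even on regular-grid clouds where ties are
exact. Five convolution layers (shared linear map → normalization → ReLU →
neighborhood max-aggregation) are followed by a global max pool and two
fully connected layers with softmax. Because per-point normalization
removes absolute scale, seven unnormalized global invariants (log point
count, max/RMS/mean centroid distance, density mean/SD, mean neighbor
distance) are concatenated into the head input.

**Sparse-voxel pyramid (`minkloc`).** The cloud is quantized onto an
integer lattice (default step 0.2 Å — one canonical voxel — with density as
the single feature; duplicate points reduce by max). Three bottom-up
kernel-3 stride-2 sparse convolution blocks (each with normalization, ReLU
and Efficient Channel Attention, kernel 3) build a feature pyramid with
channels (32, 64, 128); a top-down pathway adds stride-2 transposed
convolutions of the coarser levels onto 1×1-convolved lateral maps; the
merged finest level is aggregated by NetVLAD (32 clusters: soft-assigned
residuals to learnable centers, intra- plus global L2 normalization) and
classified by a linear softmax head. Coordinates enter only relative to
the cloud, so predictions are translation-invariant. By default the cloud
is first rotated into its density-weighted principal-axis frame
(eigenvectors by descending eigenvalue, signs fixed by third-moment
non-negativity, right-handed). This canonicalization commutes with
permutation and translation and drastically reduces the orientation
variance the lattice otherwise injects — without it the architecture needs
far more data than a desk-scale experiment provides to generalize across
random rotations. It can be disabled via `canonicalize_orientation=False`.

Both heads are zero-initialized, so an untrained model scores every group
uniformly and the ranking degenerates to group-id order — a documented,
testable state. Ranking ties always break toward the smaller group id.

**Normalization layers.** The per-layer normalization uses the statistics
of the current cloud (instance-style) in training and inference alike.
With a batch size of one cloud, running-average statistics would make
inference depend on training history and systematically mismatch the
per-cloud statistics seen during training; per-cloud moments are
deterministic, permutation-invariant and rotation-invariant.

**Training.** Cross-entropy with Adam, gradient accumulation over a
configurable number of single-cloud examples (default 8), optional class
rebalancing (oversampling duplicates minority examples up to the majority
count within each epoch; undersampling caps all classes at the minority
count), a stratified validation split (default 25% of the input), and a
per-epoch history of loss and validation accuracy. One seed drives the
split, the balancing, and the visit order. An optional
`early_stop_accuracy` halts training once validation accuracy reaches a
target.

## Evaluation

Splits assign whole deposits: the holdout split walks deposits in seeded
random order and places each on the side that minimizes the squared
deviation of per-group counts from the target fractions (70% train pool,
of which 25% becomes validation); in divisible cases this greedy rule is
exact. The k-fold plan wraps scikit-learn's `StratifiedGroupKFold`
(deposit = group, ligand group = stratum) and re-validates that no deposit
spans folds. A group living entirely inside one deposit cannot be split
and triggers a warning.

Metric conventions: the rank of the correct class is
`1 + #{strictly better} + #{ties with smaller id}`; accuracy uses argmax
with the same smallest-id tie rule; the Brier score is the squared error
of the correct-class probability, `mean((1 − p_true)²)`, with the
sum-over-classes multiclass variant available behind
`brier_multiclass=True`; macro recall averages per-class recall over the
classes present in the truth set — empty classes are excluded rather than
counted as zero, which avoids penalizing folds that lack rare classes.

## Synthetic data

`render_pseudo_ligand` sums isotropic Gaussian atoms with
`σ_atom = 0.425 × resolution` (FWHM ≈ nominal resolution) on the 0.2 Å
grid, padded 3σ beyond the atom bounding box so each atom's integral is
accurate to better than 2%; optional seeded Gaussian noise, negatives
clipped. `make_zero_inflated_map` draws a normal background, zeroes a
seeded random `mask_fraction` of voxels exactly (the spike), then adds
noiseless blobs at recorded offsets; each blob's ground-truth mask marks
voxels at ≥ 50% of its peak. The half-maximum level was chosen because it
is the level a quantile threshold near 3 background SDs can plausibly
recover at moderate signal-to-noise; a much lower mask level (e.g. 1% of
peak) would require SNR in the hundreds for high overlap and would measure
the Gaussian tail rather than the blob. `make_shape_dataset` builds
labeled clouds from five atom templates (line, ring, tetrahedron, T-shape,
helix) with per-atom Gaussian point scatter, density decaying with offset,
random rigid rotations and translations — a stand-in for the 219-group
ligand corpus whose classes are separable by construction (a
nearest-centroid oracle on invariant moments reaches ≥ 95%).

What the generators do *not* emulate: position-dependent resolution,
sharpening/B-factor effects, model-phase bias, chemically realistic
geometry, or class imbalance. Tests passing on them certify the pipeline's
algebra and contracts, not real-data accuracy.

## Problem sizes and numerical choices

The test suite and the demo harness run at desk scale, chosen as the
smallest sizes at which each property is meaningfully exercised: recovery
maps of 128³–160³ voxels with two 2-atom blobs at SNR 5–8; training smoke
tests on 5 classes × 200 clouds (≈ 50–70 points each) with early stopping
at 90% validation accuracy; invariance checks over 20 random rotations of
10 random clouds; leakage checks over 1000 random split configurations.
Quantile agreement with the sort oracle is asserted to 1e-12; trilinear
exactness on degree-≤1 fields to 1e-9; rotation-invariance drift to 1e-3
(measured drift is at float-epsilon level); permutation drift to 1e-5.

## Known limitations

* The calibration table shipped for tests is synthetic; real use requires
  deriving targets from an X-ray blob corpus.
* The numpy networks are CPU-bound and desk-scale; they implement the
  architectures' defining structure, not their published widths or
  training scale, and make no claim of matching published accuracies.
* Orientation canonicalization for the sparse-voxel model is a
  quasi-invariance: clouds with degenerate principal axes or near-zero
  third moments can flip frames.
* The greedy holdout split is near-exact for many small deposits but can
  drift beyond ±5 percentage points for adversarial deposit compositions
  (few, large, mixed-group deposits).
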
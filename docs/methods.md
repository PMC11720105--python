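# Methods

## Problem and model

The package estimates the rigid rotation that maps a CT-acquired skull
posture onto the natural head position (NHP). The input is a skull surface;
the output is a proper rotation `R ∈ SO(3)`. The regressor operates on a
fixed-size point-cloud representation of the surface, which removes any
dependence on mesh connectivity or resolution.

The network is a two-stage set-abstraction architecture. Each stage
subsamples the cloud with farthest point sampling (greedy, deterministic:
the first centroid is index 0 and ties break to the lowest index), groups
neighbours within a radius (inclusive bound; groups are truncated to the
nearest `max_group_size` members or padded by repeating the centroid, so
tensors stay rectangular), and applies a density-corrected point
convolution: the features of each group member are divided by an estimate of
the local point density, multiplied by a learnable function of the member's
offset from the centroid (a two-layer MLP producing a weight vector), summed
as outer products over the group, and linearly projected to the stage's
output width with a rectifier. A global max pool over the surviving
centroids produces an order-invariant descriptor, and a fully connected head
outputs 9 numbers, reshaped row-major to a 3×3 matrix.

The raw matrix is *not* orthogonalized during training; the loss compares it
elementwise to the ground-truth rotation. At inference the raw output is
projected to the Frobenius-nearest proper rotation via SVD with a
determinant correction, `R = U·diag(1,1,det(UVᵀ))·Vᵀ`, which guarantees
`det R = +1` even for degenerate raw outputs where plain `UVᵀ` would be a
reflection.

### Density estimate

The density `ρ(p_j)` is a fixed Gaussian kernel-density estimate over the
input cloud (bandwidth expressed as a fraction of the unit-sphere scale,
default 0.1), normalized by its mean over the cloud. The normalization makes
`1/ρ` an O(1) *relative* density correction; without it the raw KDE values
are tiny and the corrected features become numerically ill-conditioned. The
estimate is floored at 1e-8. A learned density network would also fit the
formulation, but a fixed KDE keeps the correction interpretable and the
parameter count stable.

### Second-stage features

The second block's input features are the first block's outputs concatenated
with the centroid coordinates. The pooled descriptor then carries explicit
position information, which measurably improves orientation recovery; with
coordinates only entering through relative offsets, the trained model was
markedly slower to generalize.

## Euler convention

Roll/pitch/yaw are degrees about the anatomical axes +x (anterior), +y
(left), +z (superior), composed as `R = R_z(yaw)·R_y(pitch)·R_x(roll)`
(extrinsic x-y-z). Pitch lies in [−90°, 90°]; roll and yaw in (−180°, 180°].
At gimbal lock (|pitch| = 90° within 1e-7) roll is set to 0 and yaw absorbs
the in-plane freedom. The convention is a package contract — reported angles
are only meaningful relative to it — and round-trips are exact to 1e-9°
away from the lock.

## Losses

Wing loss, elementwise on the 9 matrix elements with mean reduction:
logarithmic for residuals below ω, linear above, joined continuously by
`C = ω − ω·ln(1 + ω/ε)`. Defaults ω = 10, ε = 3; the hyperparameter grid
ω ∈ {5, 10} × ε ∈ {0.5, 1, 2, 3, 4} is exposed. The value is continuous at
the branch point but the derivative is not (inner slope ω/(ε+ω) vs. outer
slope 1) — inherent to the definition, and irrelevant in matrix regression
where residuals never reach ω = 10 (entries differ by at most 2). Mean
rather than sum reduction keeps ω and ε scale-free in the matrix size.
Baselines: elementwise MAE, MSE and Huber (default delta 1.0).

## Synthetic cohort

Clinical NHP data is IRB-restricted, so the package generates skull proxies:
star-shaped closed surfaces over a subdivided icosphere whose radial profile
is a superellipsoid (the vault; semiaxes 90/70/80 mm, exponent 1.25), plus a
smooth anterior-inferior bulge (the jaw) and one small lateral bump (8 mm)
that breaks left–right symmetry. The bump guarantees the surface has no
rotational self-symmetry, so the ground-truth orientation is identifiable.
The construction is watertight by design (Euler characteristic 2 for every
parameter choice), which a boolean union of separate solids would not
robustly give.

Per subject, shape lengths are rescaled by a uniform ±10% relative spread,
and an acquisition misalignment is drawn per axis from a truncated normal
(SD 5°, hard bound ±15°) — a plausible magnitude for head deviation in a CT
headrest, stated as a modelling assumption; no empirical distribution of
clinical misalignments is available to calibrate against. The acquired mesh
is the canonical mesh rotated by the misalignment about its vertex centroid;
the stored ground truth is the inverse rotation, i.e. the NHP-restoring
correction the network must predict. Generation is bit-reproducible from the
cohort seed.

What the proxies do **not** emulate: anatomical detail (teeth, orbits,
mandibular condyles), CT noise and metal artifacts, intensity textures, and
inter-patient variability beyond smooth size/shape scaling. Passing the
synthetic parameter-recovery study therefore shows the pipeline is correct
and trainable — not that its clinical accuracy matches any particular
reported figure.

## Preprocessing

Global thresholding uses the inclusive rule (voxel ≥ T is bone); the default
T = 300 HU is a conventional bone threshold, configurable because the
appropriate value is scanner- and protocol-dependent. Marching cubes runs at
level 0.5 on the padded binary mask; only the largest connected component
(by area) is kept, standing in for the manual cleanup clinical tools
require. A volume-preserving Taubin smoothing pass (10 iterations) removes
the staircase artifact of binary marching cubes, which otherwise inflates
surface area by about 8%. Surface sampling is area-weighted with uniform
barycentric placement, seeded. Normalization subtracts the cloud centroid
and divides by the maximum point norm, recording both for inversion; it is
idempotent to 1e-12. STL I/O (binary and ASCII read, binary write) merges
duplicate vertices within 1e-6 mm since STL stores an unindexed triangle
soup.

## Augmentation

Each training subject is expanded `factor` times (default 30) by rescaling
its ground-truth angles per axis with factors drawn from [0.5, 1.5].
Factors come in antithetic pairs (s, 2−s), so each subject's augmented mean
angle equals the original *exactly* — a plain uniform draw preserves the
mean only in expectation. The acquired mesh of each augmented sample is
re-rendered from the canonical mesh, so the ground-truth round-trip
invariant holds for augmented data too. Originals are replaced by their
augmentations by default (90 → 2700). A zero original angle stays zero under
relative scaling; this degeneracy is inherent to the scheme.

## Training protocol and profiles

The full-scale profile mirrors the reference protocol: 2048 points,
SAB widths 128/512, head 512→256→9 (1,476,905 learnable parameters —
within the intended ≈1.46 M), Adam at 1e-4 halved every 50 epochs, 500
epochs, batch size 1, Wing loss. Batch size 1 is also why the network uses
no batch normalization. Full-scale training is a GPU-class job.

The desk profile is the package's CPU-scale study: SAB widths 32/128 with
weight-net width 8, head 128→64→9, 512 points, 15 epochs over the 30×
augmented training split, Adam at 1e-3 halved every 6 epochs. With 30×
augmentation each epoch already covers the data densely, so few epochs and a
proportionally larger learning rate are appropriate. The scaled-down
parameter-recovery study uses 120 training and 40 test subjects and runs in
a few minutes on one CPU; the trained model's median test rotation error is
compared against the identity baseline (predicting "no correction"), which
it must at least halve.

Per-sample clouds are sampled once (seeded) and their geometric structure is
cached across epochs; per-epoch resampling is available but off by default
so runs are exactly reproducible from a single seed. The final-epoch
checkpoint is used for evaluation; no early stopping.

## Numerical choices and degenerate inputs

- `arccos` arguments in the rotation error are clamped to [−1, 1].
- SVD projection of a rank-deficient matrix with two equal smallest singular
  values and negative determinant has an ambiguous nearest rotation; the
  implementation resolves it deterministically through NumPy's SVD column
  order.
- All-coincident point clouds (zero scale), empty segmentations, zero-area
  meshes, malformed STL files, non-rotation matrices and length-mismatched
  angle lists raise typed errors.
- Paired t-tests with zero-variance differences: identical error lists give
  t = 0, p = 1; constant nonzero differences are flagged degenerate rather
  than returning an infinite statistic.
- Training aborts with a diagnostic if the loss becomes non-finite.

## Known limitations

- The backbone runs on a single CPU core in NumPy; full-scale (2048-point,
  500-epoch) training is impractical without an accelerator. The
  architecture and protocol are nevertheless implemented at full scale and
  parameter-counted.
- The regressor assumes the input surface is a skull-like closed shape
  occupying most of its unit sphere; it is untested on partial surfaces.
- Synthetic-cohort results quantify pipeline correctness, not clinical
  accuracy (see the synthetic-cohort section).
- The anatomical axis assignment of roll/pitch/yaw is a convention; only
  internal consistency is verifiable.
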
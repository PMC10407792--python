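# Methods

This note records the models, parameter choices and numerical conventions
behind `soyphen`, and what validation on synthetic scenes does and does
not establish.

## Measurement model

A dense SfM-MVS reconstruction of a pot-grown plant is treated as a point
set known up to a similarity transform plus additive isotropic Gaussian
sensor noise and sparse background clutter. Two anchors fix the transform:

* **Scale.** A reference object of known physical size must appear in the
  scene; we use the pot. The calibration factor is
  `alpha = real_length_cm / measured_length_raw` and multiplies every
  coordinate (`unit` flips from `raw` to `cm`; a second application is an
  error). On synthetic scenes the pot wall is found by its RGB range and
  its diameter estimated as **twice the median radial distance** of the
  pot points from their horizontal centroid. A max-extent estimate (the
  obvious alternative) is biased upward by the noise tails — about +0.3%
  at sigma = 0.05 cm on a 27 cm pot — while the median-radius estimate is
  unbiased for a circular footprint; on real scans the reference length
  can instead be supplied as a picked point pair (`soyphen calibrate
  --ref-points`).
* **Orientation.** The dominant RANSAC plane is the ground. Its normal is
  oriented toward the cloud centroid (plant above ground), rotated onto
  +z by the axis–angle Rodrigues matrix, and the ground inliers' mean is
  translated to z = 0. Antiparallel normal pairs (undefined rotation
  axis) rotate 180° about the coordinate axis least aligned with the
  normal, orthogonalised — a deterministic completion of the degenerate
  case. RANSAC ground threshold: 0.004 × scene bounding-box diagonal
  (scale-free, since it runs before calibration).

## Preprocessing

* **Voxel downsampling** keeps, per occupied voxel, the original point
  nearest the voxel centroid (ties: lowest index). The grid is anchored
  at the cloud's minimum corner so results do not depend on global
  translation; an explicit `origin` argument pins the grid when exact
  idempotence across reruns matters. Working resolution after
  calibration: 0.12 cm. This sets the effective sampling pitch of every
  later measurement; boundary-sensitive quantities (projected area)
  degrade roughly linearly with it.
* **Statistical outlier removal**: point *i* is removed when its mean
  distance to its k nearest neighbours exceeds the cloud mean by more
  than `n_sigma` population standard deviations (k = 8,
  n_sigma = 3.5). Clutter sits many tens of sigma out, so the cut is
  insensitive to `n_sigma` for its intended targets; tighter cuts
  (2–2.5 sigma) measurably erode leaf boundaries (−3% projected area per
  pass) and are avoided.
* The **low-pass local-plane filter** (fit a total-least-squares plane to
  the neighbours within a radius, drop points whose orthogonal residual
  exceeds `max_error` × the local RMS; defaults radius 0.098264,
  max_error 2) and the **Gaussian neighbourhood smoother** are available
  in the library and CLI but are not part of the default pipeline, whose
  synthetic inputs do not need them.

## Segmentation

* **Stem**: RANSAC cylinder from two-point samples with PCA normals
  (k = 10 neighbourhoods). Surface normals on a thin noisy stalk
  (sigma/radius ≈ 0.17) are unreliable, so when an axis hint is available
  — vertical, after ground alignment, within 30° — each sample also
  yields a hint-constrained candidate whose axis is the hint and whose
  center/radius come from the horizontal projection. Consensus counting
  uses `|distance to axis − r| ≤ 0.15 cm`; the winner is refined by
  bounded nonlinear least squares (radius clamped to [0.05, 1] cm) on a
  2×-threshold band, iterating until the band stabilises, and the
  refinement is discarded if it loses consensus. The stem split claims
  the cylinder inliers plus everything within `radius + margin`
  (margin 0.3 cm) of the axis segment; leaf points within a further
  0.6 cm junction band are cleaned by a local outlier pass so petiole
  stubs do not bridge leaves.
* **Leaves**: connected components of the ε-graph with
  ε = 3 × median nearest-neighbour distance (scale-adaptive; no fixed
  value exists for the clustering tolerance), minimum cluster size 60.
  This presumes a spatial gap between leaves, which the synthetic
  generator enforces by construction (clearance 1.2 cm) and which holds
  for well-spaced pot plants but not for overlapping canopies.

## Trait extraction (LPM)

All lengths cm, areas cm², volumes cm³, angles degrees.

* **Plant height** = max z − ground z. **Plant box volume**: the
  horizontal principal direction is rotated to x (z kept vertical), then
  the axis-aligned box is measured — orientation on the turntable cannot
  affect it. Leaf boxes use the full 3D PCA rotation.
* **Leaf length** is the Euclidean chord between the two farthest points
  (convex-hull accelerated exact search; base = the lower endpoint). An
  optional geodesic reading (shortest path over the k-NN graph) is not
  implemented; the chord is the measure validated here. **Width** is the
  extent along the in-plane direction orthogonal to the base–tip axis,
  inside the total-least-squares leaf plane.
* **Trimmed extremes.** Width and the projected length/width are extents
  of noisy coordinates; the raw max−min statistic is inflated by the
  extreme order statistics (≈ 2–3 sigma per side: +3.2% mean, +7.3%
  worst-case on narrow leaves at sigma = 0.05 cm). Extents therefore drop
  the 2 outermost points per side when n ≥ 20 (+0.6% mean, +2.4% worst
  under the same conditions); smaller sets use the exact extent.
* **Projected area**: drop z, triangulate the footprint greedily — edges
  sorted by length, inserted unless they cross an accepted edge, cutoff
  at 4 × the 95th-percentile nearest-neighbour spacing — and sum Heron
  areas per empty 3-clique (cliques containing another vertex are
  rejected, so triangles never overlap). The q95-based cutoff, rather
  than the median, keeps coverage stable across sampling regularity:
  Poisson scatters need ≈ 8× the median spacing at the boundary, while
  near-regular voxel-thinned sets need ≈ 4×. The estimate is an *inner*
  approximation (it cannot extend beyond the sampled hull) and carries a
  −1 to −4% bias that shrinks with sampling density. The insertion loop
  is numba-compiled when numba is importable, with an identical
  pure-numpy fallback (parity is tested).
* **Shell volume** = occupied voxels × cell³ at cell = 0.2 cm (chosen
  above the 0.12 cm sampling pitch so occupancy saturates). It is a
  resolution-dependent surface-shell measure, not an enclosed volume — a
  lamina has no watertight interior — and is only comparable across
  clouds measured at the same cell size and density. Optional Gaussian
  pre-denoising is off by default: it contracts open surfaces by roughly
  sigma per boundary and the pipeline's leaves are already clean.
* **Tilt**: RANSAC plane on the leaf (threshold 0.5 cm — generous enough
  that a gently curved blade keeps all its points as inliers and the
  refined plane matches the total-least-squares plane), normal resolved
  to the upward hemisphere; tilt = arccos |n_z| ∈ [0°, 90°], azimuth from
  the horizontal component of the downhill direction. The fitted plane
  and RMSE are exposed alongside the angles.

## Classification

Cultivar labels are encoded 1..C and *regressed* (hard labels by rounding
and clipping), which is what makes training/test correlation (Rc/Rp) and
RMSEC/RMSEP well defined. Features are standardised with training-set
statistics inside `fit` — GRNN and RBF kernels are scale-sensitive.

* **GRNN**: kernel-weighted mean of stored training targets,
  `w_i = exp(−‖q−x_i‖²/2s²)`; predictions are convex combinations of
  training labels. The spread `s` is chosen by leave-one-out grid search
  (25 log-spaced points in [0.05, 5]) — deterministic and standard where
  no bandwidth is prescribed. Total underflow falls back to the nearest
  neighbour.
* **LS-SVM**: dual system `[[0, 1ᵀ],[1, K + I/γ]]·[b; α] = [0; y]` solved
  directly (residual asserted ≤ 1e-8); one-vs-rest argmax for hard
  multiclass labels; γ = 10, RBF width 1 on standardised features.
* **BP**: one sigmoid hidden layer, linear output, full-batch gradient
  descent on MSE; seed-deterministic init; the analytic gradient is
  verified against central finite differences. Divergence (loss > 1e6)
  aborts with advice to lower the learning rate.
* **Split**: stratified, seed-deterministic 80/20 by class.

## Synthetic scenes and ground truth

A scene = dark ground disk, terracotta pot (diameter 27 cm, height 21 cm,
the metric reference), soil disk, vertical stem (radius 0.3 cm), and N
elliptical leaflets bent parabolically along their main axis, tilted,
azimuthally distributed with a golden-angle offset and a minimum
clearance of 1.2 cm enforced by rejection. Plant surfaces are sampled at
100 points/cm² (dense phone-video reconstructions resolve leaves at least
this finely), background surfaces more sparsely; isotropic Gaussian noise
sigma = 0.05 cm; 250 dark clutter points. The scene is handed out in raw
units: a hidden scale uniform in [0.5, 2], a rigid tilt of up to 20° and
a random translation exercise calibration and alignment nontrivially.

Truth values are computed from the continuous surface: projected area by
quadrature of the projection Jacobian over the ellipse, extents and box
volumes from a dense noiseless grid, shell volume from a 640×640 surface
grid (dense enough to saturate cell occupancy), tilt from the symmetry of
the parabolic bend (the best-fit plane of a symmetrically bent patch has
the nominal tilt). The trait dataset for classification draws the six
leaf features from class-shifted lognormals (linear-dimension multipliers
0.8 / 1.0 / 1.25, log-sd 0.1, tilt unshifted), giving ≥ 3-sd adjacent-class
separation on the volumetric traits — a small/medium/large cultivar
contrast; shape 3 × 149 = 447 × 6.

**What passing tests show — and don't.** Synthetic scenes have single
elliptical laminae with guaranteed gaps, exactly one ground plane, a
perfectly cylindrical stalk, and isotropic noise. Real reconstructions
have compound trifoliate leaves that may touch, petioles, reconstruction
artefacts (non-isotropic noise, missing patches, color bleeding) and an
uncertain reference measurement. Recovery within a few percent here
validates the measurement chain's correctness, not its field accuracy.

## Problem sizes and determinism

Validation uses 20 seeded scenes (≈ 70–110k raw points each) for trait
recovery and 15 size-varying scenes in the acceptance script — large
enough for stable error statistics while keeping a full run in minutes on
one core. Every stochastic step (RANSAC sampling, scene synthesis,
splits, BP init) takes an explicit integer seed; a pipeline run is a pure
function of (cloud, config), and reruns produce byte-identical trait
tables.

## Known limitations

* Leaf projected area is an inner estimate with a density-dependent
  negative bias (≈ −2% at the default resolution).
* Per-leaf bounding-box volume of thin laminae is dominated by the noise
  thickness along the normal; treat it as a comparative, not absolute,
  trait at sigma ≳ the blade sag.
* Shell volume is resolution-bound (see above).
* Clustering cannot split touching leaves; leaf counts are only exact
  when the inter-leaf gap exceeds about twice the clustering tolerance.
* The classifiers are small-data shallow models; with strongly separated
  synthetic classes their metrics saturate near 1 and say nothing about
  harder real-world contrasts.
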
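# Methods

This note documents the models, algorithms, parameter choices and
known limitations of the package; everything quantitative stated here
is recomputed by the test suite or by `scripts/acceptance.py`.

## Coordinates and calibration

Voxel indices are 0-based and ordered (z, y, x); physical positions
are `index × voxel_size` in micrometres.  All geometry downstream of
preprocessing lives in isotropic micrometre space (default voxel
0.33 μm), which makes distances, volumes and directions unambiguous.
Time is in minutes (default frame interval 1 min; typical acquisitions
use 1–1.5 min).

## Preprocessing

1. **Isotropic resampling** — per frame and channel, trilinear
   interpolation to the target voxel.  The physical extent of each
   axis is preserved to within one output voxel; a stack already at
   the target is passed through bit-exactly.
2. **Photobleaching correction** — the specimen is assumed to carry a
   constant amount of fluorophore, so each frame is rescaled by
   `gain(t) = total(0) / total(t)` per channel.  Totals are computed
   over the whole frame after subtracting a fixed, configurable
   background level (default 0): no foreground mask exists yet at this
   stage, and a *per-frame* background estimate would be degenerate on
   flat frames.  The correction is idempotent, and it amplifies
   late-frame noise, which the subsequent smoothing absorbs.
3. **Denoising** — Gaussian smoothing (default σ = 0.5 μm; the scale
   is a free choice, kept well below the nucleus radius) followed by
   background removal with a separable box top-hat of half-width
   10 μm.  A box, rather than a rolling ball, keeps the operation
   separable and fast; at a half-width ≫ cell scale the difference is
   immaterial for these images.

## Nucleus segmentation (weighted-EM Gaussian mixture)

The number of nuclei `c` is fixed for the whole movie by the
first-frame annotation (2 polar + N border cells; polar cells get
labels 1–2, border cells 3..c, in file order).

Per frame:

* **Foreground** — the intensity threshold whose enclosed fluorescence
  mass is closest to a target held fixed from frame 0 (Otsu-seeded),
  so the total nuclear mass is conserved over time; components below
  1 μm³ are dropped and holes filled.  Threshold ties go to the
  smaller mask.
* **Boundary enhancement** — Laplacian sharpening
  `I − κ ∇²I` (κ = 1), clipped at 0, deepens valleys between touching
  nuclei without moving isolated peaks.
* **EM** — a `c`-component Gaussian mixture over the 3-D voxel
  positions, with each voxel weighted by `brightness^α` (α = 1).
  Brightness as a *weight* rather than a fourth feature dimension
  avoids mixing incommensurate units and makes the fitted means
  exactly the brightness-weighted geometric centers.  After every
  M-step a ridge of 10⁻³ μm² is added to the covariance diagonals to
  keep them positive-definite (the unpenalized ML problem is singular:
  a component can collapse onto bright voxels).  Stopping: relative
  log-likelihood change < 10⁻⁶ or 200 iterations.  Because the ridge
  is applied after the exact M-step, the likelihood is monotone only
  up to a perturbation of order ridge/σ² per iteration; the property
  test asserts monotonicity at 10⁻⁶ relative tolerance.
* **Labelling** — maximum-posterior assignment of masked voxels;
  posterior ties go to the lower label; an empty component is an
  error, never silently dropped.
* **Temporal coherence** — frame t initializes from frame t−1's fitted
  model; frame 0 from the annotation (isotropic 2 μm covariances,
  uniform weights).

## Tracking

Between consecutive frames the confidence
`S_ij = (overlap_ij + 1) / (distance_ij + ε)` (overlap in voxels,
distance in μm, ε = 0.33 μm — one voxel) rewards both proximity and
shared volume; the `+1` keeps fully disjoint pairs rankable by
distance, which is what recovers fast movers whose masks do not
overlap between frames.  The permutation maximizing the summed
confidence is found by the Hungarian algorithm on negated scores; ties
resolve to the lexicographically smallest permutation (fixed row by
row against the optimal total, so the result is deterministic).  The
assignment is verified against exhaustive permutation search on random
matrices up to c = 8.

Speeds are `|c(t+1) − c(t)| / Δt`; unit directions are undefined (NaN,
and excluded downstream) at zero displacement.

## Cell segmentation

* **Cluster mask** — cells neither gain nor lose mass during
  migration, so the mask is volume-constrained: the target volume is
  `N_border·V_border + 2·V_polar` (defaults 1,250 and 600 μm³; the
  border value is the midpoint of the observed 1,000–1,500 μm³ range,
  the polar value is a configuration default to be calibrated per
  dataset).  Candidate thresholds on the combined membrane+nuclei
  intensities are scanned from bright to dim; each candidate's largest
  connected component is hole-filled and the threshold minimizing
  |V − V_target| wins (this matches exhaustive search, which is
  property-tested).  The winning mask is then regularized by a ball
  closing at the membrane blur scale (2 μm) and re-filled: after
  z-decimation and resampling the membrane is dim where the cluster
  surface is perpendicular to z, and without the closing the mask
  loses its z-caps and the watershed leaks along them (on synthetic
  movies this single step moves the voxel-level TPR from ~0.83 to
  ~0.93).  Deviations beyond 10% of the target volume are logged.
* **Membrane enhancement** — the maximum response of an oriented
  filter bank: second-derivative-of-Gaussian "plate" kernels at
  σ = 0.66 μm whose normals sample the x–y, x–z and y–z planes every
  30° (18 orientations).  The directional second derivative is
  evaluated as `n̂ᵀHn̂` from the six Gaussian Hessian components,
  which equals convolution with the rotated kernel at a fraction of
  the cost and is exactly equivariant under 90° grid rotations.
* **Watershed** — priority flood of the enhanced image from the
  tracked nucleus labels, restricted to the cluster mask (ties to the
  lower label).  Labels partition the mask and each cell contains its
  nucleus.  Per-cell volume equality is deliberately *not* enforced.
* **Interfaces** — each cell is dilated by the full 3×3×3 element;
  overlap with a neighbour estimates the internal contact area,
  overlap with the mask complement the external (substrate) area,
  scaled by the in-plane voxel face (0.33² μm²).  The dilation makes
  the contact estimate asymmetric by at most a few percent, which the
  symmetry audit bounds at 5%.

## Coordination and modes

`P(t) = |Σ d̂_k|/K` and `M(t) = |Σ r̂_k × d̂_k|/K` over the K members
with defined directions (zero-displacement members reduce K rather
than contributing arbitrary directions); both are in [0, 1] by the
triangle inequality.  By default they are computed from nuclei;
cell-center variants are available.

The running/rotating classifier is one bivariate Gaussian per mode
over (P, M) with class-frequency priors; the decision boundary is the
equal-posterior locus and the posterior is always reported, because
real clusters form a continuum between the modes.  The published
boundary parameters are not available, so the package ships a default
trained on simulated direction fields (coherent cones for running,
jittered tangent fields for rotating, 400 samples per class, fixed
seed); users should refit on their own annotated frames when absolute
boundary placement matters.

The polar axis is the undirected line through the two polar-cell
centers; its per-step rotation angle is `arccos |â_t · â_{t+1}|`, with
a centered 5-point moving average (shrunken windows at the ends).

## Neighbour exchange

`g(t, s) = max_ij | D(t+s) − D(t) |_ij` over pairwise center-distance
matrices, for steps s = 1..max_step (default 10).  `g` is exactly
invariant under rigid motion of the whole cluster, so only genuine
topology changes light up.  Detection: connected components of
`{g > τ}` (τ = 30 voxels × 0.33 μm = 9.9 μm, about twice a nucleus
diameter) correspond one-to-one to events; within a component the
event onset and duration are read from the finest scale — the
single-step row `g(t, 1)` is quiet outside the exchange and active
throughout it.  This localization replaces naive 3×3 non-maximum
suppression, which degenerates on the plateau that every
event produces (all windows spanning the event see the same full
change).  A geometric caveat: for a 6-cell ring at these scales the
largest change a position swap can produce (~7.7 μm) is below τ, so
the detector is validated on 8-border-cell scenes (cluster sizes of
6–10 cells occur in this system), where diametric swaps produce
10–15 μm.

## Protrusions and morphodynamics

* **External protrusions** — `B \ opening(B, ball(r))` with
  `r = (3V̄/4π)^{1/3}` from the mean border-cell volume.  Opening and
  closing with large Euclidean balls are computed via distance
  transforms (identical to the structuring-element composition, which
  is property-tested, but without materializing ~40³ elements).  On a
  voxel grid the opening of even a smooth body leaves a sub-voxel
  residue film on its surface; residue lacking a 1-voxel-erodible core
  is discarded.  Protrusion direction is the normalized vector from
  the cluster-body mass center (the opened mask) to the protrusion
  mass center, undefined for symmetric residues; the owner is the
  modal cell label inside the protrusion (the assignment rule is a
  package choice; protrusions are cluster-level structures generated
  by individual border cells).
* **PA / CD / CS** — PA is the *signed* dot product of unit protrusion
  and cluster directions (so opposite protrusions score −1); CD
  correlates the magnitude of the summed unit protrusion directions
  with cluster speed; CS correlates protrusion volume with cluster
  speed.  All correlations are plain Pearson coefficients.
* **Deformation mapping** — assuming the sampling interval is short
  enough that surface motion is locally linear, surface voxels
  (6-connected boundary) of the new frame lying outside the old cell
  are positive samples with magnitude the distance to the nearest old
  surface voxel, and symmetrically for negative samples; a voxel can
  never be both.  The bidirectional nearest-surface scheme realizes
  the minimum-distance mapping without mesh correspondence.  MPD/MND
  are the maximum magnitudes, PDE/NDE the summed magnitudes.
* **Rotation association** — `R(t) = Σ r̂_k × v_k` from nucleus
  displacements and `Q(t) = Σ r̂_k × u_k` from each cell's summed
  positive deformation vectors.  A frame's angle is reported only when
  `|Q|` carries a coherent fraction (> 0.25) of the frame's total
  positive deformation energy: incoherent (radial) extensions cancel
  in the cross-product sum, and the EDT tie-breaking otherwise leaves
  a spurious residual direction.  The movie-level summary is the mean
  angle over valid frames and the Pearson correlation of |R| and |Q|.

## Synthetic movies

The generator emulates the real system rather than idealizing it:

* **Geometry** — 2 polar nuclei 3.6 μm apart at the center, N border
  nuclei (default 6) on a ring at 0.7 R in the plane containing the
  polar axis; cluster ball radius from the reference volumes
  (12.75 μm for 6 border cells).  Cells are the Voronoi partition of
  the ball seeded by the nuclei — label-exact and cheap, at the cost
  of unrealistically flat cell-cell faces.  Nucleus blobs are
  isotropic Gaussians (σ = 1.25 μm, diameter ≈ 5 μm); membranes are
  1-voxel shells on label boundaries and the cluster surface; the
  nurse channel is a Voronoi foam of jittered substrate seeds
  (18 μm spacing).
* **Motion** — schedules compose running (constant velocity), rotating
  (rigid rotation about an axis through the cluster center, optional
  drift) and chaotic (per-nucleus isotropic random steps with soft
  containment) segments.  Exchange events slide two cells over the
  cluster surface along one great circle in opposite senses, with a
  small radial separation at mid-arc (one passes outside the other);
  from the event end onward their cluster-frame positions are swapped.
  Protrusion events union a cylinder (owner's label) onto the cluster.
* **Degradation** — per-frame intensity decay `exp(−0.02 t)`, Poisson
  shot noise plus additive Gaussian noise (σ = 1.5 intensity units on
  amplitudes of 30–60 over a background of 2; the real movies are
  low-SNR but unquantified, so the level is a package choice), and
  z-decimation by 3 (z step 0.99 μm, the typical confocal motor step).
  Ground truth (labels, tracks, events, per-frame mode) is recorded
  pre-degradation and is bit-identical across noise settings.

What passing tests on these movies do *not* show: robustness to
spectral bleed-through, optical PSF anisotropy beyond coarse z
sampling, cell-shape irregularity beyond Voronoi faces, specimen
drift, or varying cell numbers.  The voxel-level segmentation accuracy
on synthetic movies (≈ 0.93) should therefore be read as an upper
bound relative to real data.

## Problem sizes and determinism

The evaluation scenarios use 20-frame movies for the
protrusion-alignment and rotation-association statistics and a
10-frame movie for the full-pipeline segmentation accuracy — large
enough for stable means over frames while keeping a full run of the
reproduction script in the minutes range on one CPU.  Every random
choice flows from a single seed; per-stage sub-seeds are derived by
hashing, so reruns are bit-identical.
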
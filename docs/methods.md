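# Methods

`ulm3d` implements a 3D ultrasound localization microscopy (ULM)
processing chain for volumetric ultrafast ultrasound of the brain
vasculature, together with a fully ground-truthed synthetic phantom that
stands in for an in vivo acquisition. This note describes the models, the
numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Processing model

The pipeline starts from beamformed, IQ-demodulated complex volume series
`(x, y, z, t)` on a regular grid. The default acquisition arithmetic
follows a transcranial mouse protocol: 16 tilted plane waves compounded at
a 12 kHz PRF give 750 volumes/s; a 10 MHz transmit at 1 MPa peak
rarefaction pressure corresponds to a mechanical index of
P/√f ≈ 0.32, reported as 0.3. Acquisition blocks hold 300 volumes,
processed in SVD sub-blocks of 150.

**Coordinates.** Axes are (x, y, z) with z the depth; all continuous
positions are in mm; voxel indices are 0-based; a voxel's world position
is its centre, `origin + (i + 0.5)·pitch`; binning is half-open on the
upper face. The pre-interpolation grid pitch is 0.197 × 0.197 × 0.0739 mm,
which two-fold interpolation brings to ≈0.1 × 0.1 × 0.04 mm.

**Clutter filtering.** Each sub-block is reshaped to a Casorati matrix
(voxels × time) and the leading `n_remove` (default 15) singular
components — static and slowly varying tissue — are removed. Because time
is the short axis, the temporal singular vectors are computed as
eigenvectors of the t × t Gram matrix `XᴴX` and the filter applied as the
projection `X(I − V_k V_kᴴ)`; this is algebraically identical to zeroing
the k largest singular values and about 30× faster than a tall economy
SVD at 64³ × 150. A trailing remainder shorter than half a sub-block is
merged into the previous one; a longer remainder is processed alone with
`n_remove` rescaled by its relative length. Note that refiltering a
filtered series is *not* a no-op in general — a second pass removes the
next k modes; the near-idempotence bound only holds when essentially all
removable energy sat in the first k modes (the clutter-dominated regime).

**Localization.** Per frame, the magnitude volume is upsampled two-fold
per axis with separable not-a-knot cubic splines (these reproduce the
original samples and any cubic polynomial exactly, boundaries included;
the refined grid is aligned so refined centre `2i` coincides with
original centre `i`). Regional maxima under 26-connectivity are detected
(an equal-valued plateau yields one candidate at its floored centroid);
each candidate's 11³ neighbourhood is scored by zero-normalized
cross-correlation against the anisotropic Gaussian PSF template
(σ = 0.4, 0.4, 0.17 mm) and accepted if the correlation exceeds 0.65 and
the magnitude exceeds −20 dB relative to the frame maximum. Duplicates of
one bubble (several noise-split maxima inside one kernel footprint) are
removed by greedy non-maximum suppression over a kernel-half box.

The sub-voxel centre comes from a linear least-squares fit of
`d + a(x−x₀)² + b(y−y₀)² + c(z−z₀)²` over a 3³ window, solved in the
expanded basis {1, x, y, z, x², y², z²}; fits with non-negative curvature,
a centre displaced more than one voxel, or a window crossing the border
are rejected. An explicit offset term `d` is included — without it the
fit is degenerate for any nonzero peak.

**Fit surface.** By default the paraboloid is fitted on the PSF
cross-correlation (matched-filter) surface of the interpolated volume, in
the vicinity of the maximal correlation, rather than on the raw
intensity. The reason is information, not convenience: with a 0.4 mm PSF
sampled at 0.1 mm, the quadratic signal across a 3³ window is ~1.5 % of
the peak, so at 20 dB image SNR a raw-intensity fit is noise-dominated
(~60 µm median error) no matter how it is regularized. The correlation
surface averages noise over the whole 11³ kernel, is unbiased for a
symmetric kernel, preserves shift-equivariance, and reaches ~7 µm median
error at 20 dB — close to the information-theoretic bound for a Gaussian
spot of this size. `DetectionConfig.fit_on = "intensity"` restores the
raw-intensity fit.

**Tracking.** Frame-to-frame linking solves the optimal one-to-one
assignment (Kuhn–Munkres) on squared Euclidean distance with a hard gate
of 0.13 mm (≈100 mm/s at 750 Hz). Since "minimum total cost over partial
matchings" is degenerate (the empty matching costs zero), the implemented
contract is: maximum cardinality subject to the gate, then minimum total
squared distance — obtained by giving gated-out pairs a large finite
penalty. Matched detections extend tracks, unmatched ones open tracks,
unextended tracks close; tracks shorter than 4 frames (~5 ms) are
discarded, and tracks never cross acquisition blocks (blocks are
separated by multi-second write gaps). Lagrangian velocities use forward
differences with a backward difference at the last sample.

**Motion correction.** Localization clouds pooled over groups of 20
blocks are registered to the first group by point-to-point ICP
(nearest-neighbour correspondences with a 0.1 mm rejection radius,
closed-form rigid update from the cross-covariance SVD, convergence when
the update moves points < 0.1 µm, 50 iterations max, clouds subsampled to
≤ 50 k points). Because cumulative drift over a long session can exceed
the correspondence radius, each group's ICP is warm-started from the
previous group's transform, so only the small group-to-group increment
must be discovered from correspondences. Non-convergence yields a warning
and the identity transform.

**Maps.** Tracks are resampled along arc length at 20 µm before
accumulation. Density counts one increment per distinct voxel traversal
per track (a slow bubble dwelling in a voxel does not inflate the count;
disable with `dedup_traversal=False` for pure-sample counting). Velocity
maps first average the chosen quantity (signed component or amplitude)
within each voxel per track, then across tracks, so every bubble passing
a voxel has equal weight; empty voxels are NaN, never zero.

**Quantification.** Density maps on a 20 µm isotropic grid are smoothed
with a σ = 40 µm Gaussian truncated to a 3³ kernel and thresholded at 1;
the binary mask is thinned to a 1-voxel medial skeleton, and the radius at
each centreline point is the Euclidean distance transform of the mask
minus half the finest pitch (the EDT measures to the nearest background
voxel *centre*, overshooting the boundary by about half a voxel). The
centreline velocity is read from the velocity-amplitude map (nearest
non-empty neighbour within one voxel as fallback) and taken as the profile
maximum V_max; the flow rate follows from Poiseuille flow,
Q = (V_max/2)·π·R². Flow–radius pairs per branch-free segment feed an OLS
regression of log₁₀ Q on log₁₀ R, whose slope is the generalized Murray
exponent. Spatial resolution is measured as the FWHM of a density profile
sampled every 10 µm with linear interpolation between samples. Region
statistics consume a supplied integer label volume plus a 3×4 affine from
ULM space to label space (atlas registration is an input, not estimated);
densities are counts of track points per region volume, and per-layer
arteriole/venule comparisons (classified by the sign of v_z: positive =
flowing down into the cortex) use Anderson–Darling normality checks and
unpaired two-sample t-tests at the track-point level (a per-track
aggregation flag exists because point-level tests inflate n).

Known upstream degeneracy: the 3D thinning in scikit-image annihilates a
tube whose axis lies exactly on a voxel corner (perfectly even-symmetric
cross-section). When thinning a non-empty mask returns nothing, the
skeleton is recomputed on a 2× nearest-neighbour upsampling and mapped
back — a tie-break for a measure-zero alignment that arbitrary vessel
orientations do not hit.

## The phantom

The generator replaces the in vivo acquisition with a scene whose every
quantity is known exactly.

* **Geometry.** A seeded binary tree whose child radii satisfy the
  generalized Murray law `r_pᵞ = Σ r_cᵞ` exactly (γ default 3, asymmetry
  ratio configurable); segment length is 10× radius; branch directions
  are drawn in a 35° cone around the parent axis, with retries inside a
  bounding box.
* **Flow.** The inlet flow splits ∝ rᵞ at each node (conserved to 1e-9);
  per segment V_max = 2Q/(πR²), the Poiseuille centreline velocity.
* **Transport.** Bubbles enter at the root at Poisson times; per segment
  traversal each bubble draws a radial offset uniform in cross-sectional
  area and moves at the constant local Poiseuille speed
  v(ρ) = V_max(1 − (ρ/R)²); at bifurcations the branch is chosen ∝ flow;
  positions and velocities are recorded at every frame. Tree randomness,
  Poisson arrivals, and path choices use separate seeded streams.
* **Rendering.** Each frame sums one anisotropic Gaussian echo per bubble
  (unit peak, random phase fixed per bubble, no shell dynamics), a static
  smooth complex clutter field (RMS 30 dB above the bubble peak by
  default, constant within a block — rank 1 in the Casorati sense, which
  makes the SVD filter's behaviour analytically predictable), complex
  white noise (−40 dB default), and a rigid drift translation
  accumulating between blocks at 20 µm/min. Rendering substreams are
  independent, so a bubble-only and a cluttered render of the same truth
  superpose exactly.

Default phantom conditions: 64³ voxels at 0.1 × 0.1 × 0.04 mm, 750
volumes/s, blocks of 150 frames, bubble speeds spanning roughly 2–50 mm/s
along the tree (off-axis bubbles slower still), clutter 30 dB above
bubbles. These sizes keep a full pipeline run in minutes on one CPU.

**What the phantom does not emulate:** acoustic propagation and skull
aberration, nonlinear bubble oscillation and shell dynamics, PSF
variation with depth, speckle statistics of real tissue, respiratory or
cardiac (non-rigid, fast) motion, and localization failures from
overlapping bubbles in dense clouds. Passing tests therefore demonstrate
the correctness of the processing chain on its stated model, not in vivo
image quality.

## Experiment sizing (evaluation module)

* Localization error: 500 isolated bubbles, 5 per frame ≥1.2 mm apart,
  SNR defined as bubble peak over total complex noise std (20 dB default).
* Flow recovery: one straight vessel (R = 0.1 mm, V_max = 50 mm/s),
  ~1000 bubbles — chosen so the outermost cross-section voxels average
  several traversals each; below that the binarized boundary has not
  converged and the radius (hence Q ∝ R²) is biased low.
* Murray exponent: depth-3 tree, root radius 0.15 mm, asymmetry 0.85 —
  sized so the deepest branches stay ≈3 voxels wide on the 20 µm grid —
  with ~3000 bubbles (~375 per leaf) by the same convergence argument.
  Residual seed-to-seed variability (~±0.3 around the true γ) comes from
  junction regions and near-touching branches corrupting per-segment
  radii; this mirrors the difficulty of skeleton-based quantification on
  real maps.
* Drift recovery: 15 groups × 60 s at 20 µm/min (280 µm total), 5000
  points per group with 3 µm localization jitter — a block group pools
  thousands of frames of localizations, and the ICP translation error
  scales like the nearest-neighbour spacing over √N.
* t-test calibration: 200 null repeats of two layers with identical
  speed distributions; the rejection count is compared with the 99 %
  binomial band around 5 %.

## Known limitations

* The intensity-threshold reference for detection is the per-frame
  maximum of the filtered volume; in a frame with no bubble this makes
  the −20 dB gate relative to noise and ghost residues, so empty frames
  can yield spurious detections (they form short or static tracks that
  the 4-frame filter and velocity maps largely ignore).
* Skeleton radii below ~2 voxels are unreliable (EDT quantization);
  vessels that small should be quantified on a finer map grid.
* The "smoothed density > 1" binarization makes the mask radius depend
  on the count amplitude: very high counts dilate the mask by roughly a
  voxel because even attenuated smoothing tails clear the threshold.
* ICP assumes quasi-rigid drift between block groups; it cannot correct
  motion within a block.
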
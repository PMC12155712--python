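# Methods

This note documents the models implemented in `octfuse`, the parameter
choices that matter, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Coordinate and sign conventions

Voxel indices are 0-based; x is the fast axis of an x-fast volume, y its
slow axis, z is depth increasing posteriorly.  Physical positions are in
micrometres at voxel centres; grids are stored `(nz, nslow, nfast)`.

Per-A-scan time is `t = volume start + b·T_B + a / f_A` with the B-scan
period `T_B = volume duration / B-scan count` (flyback folded in).  With
the default protocol (six 2.4 s volumes, 0.04 s inter-volume gap) the full
acquisition spans 6·2.4 + 5·0.04 = 14.6 s.  The instrument's flyback
timing is not separately modeled; folding it into `T_B` reproduces both
the per-volume and total durations, which is what the timestamp model is
for.

The motion model stores **eye displacement**.  During acquisition a beam
aimed at nominal position *n* records retinal content at *n + s(t)* where
*s* is the apparent content offset; since the retina moving by *d* shifts
apparent content by *s = −d*, correction places each A-scan at
*n − d(t)*.  `motion.model_from_trace` performs the negation when
converting simulator traces (which store *s*) into models, and recovery
tests compare `−model` with the trace.

## Simulator (`simkit`)

The phantom is a layered reflectivity field: thin Gaussian lines for ILM,
IS/OS and BrM (σ = 4 µm), an RPE band, dim fills for inner retina, outer
segments and choroid, all riding on a smooth random undulation field
(Gaussian-filtered white noise, default correlation length 600 µm,
amplitude 30 µm).  Soft drusen are spherical caps of sub-RPE material that
elevate RPE/IS-OS/ILM but not BrM.  Dot SDDs are dome-shaped deposits on
the anterior RPE surface; stage 1 deposits (20 µm) stay below the IS/OS,
stage 2 (55 µm) reach and locally elevate it, stage 3 (70 µm) additionally
reduce IS/OS reflectivity by 60 % above the deposit — the standard B-scan
staging criteria expressed geometrically.  Default SDD density in
generated scenes is ≈ 2.3 deposits/mm², the density implied by ≈ 80
deposits per 6 × 6 mm macular field in deposit-rich intermediate-AMD eyes.

Axial spacing defaults to 2 µm/voxel (the axial resolution is ~2.7 µm, so
sampling must be finer); transverse pitch is fov / A-scan count = 12 µm.

Eye motion: transverse drift is an integrated Gaussian random walk
(default 10 µm/√s per axis; 5 µm/√s axially) integrated at 1 ms and stored
as piecewise-linear knots; saccades follow a Poisson process (default
0.25 /s) with instantaneous 2D jumps, |N(60, 20)| µm in a uniform
direction.  The trace is continuous between saccades and right-continuous
at them.

Noise: multiplicative speckle `I·(1 + c(E−1))`, `E ~ Exp(1)` (c = 1 is
fully developed speckle; default 0.25), plus additive Gaussian detector
noise, plus an optional multiplicative illumination gain per A-scan that
is smooth along each B-scan.  Blinks set whole B-scan ranges to the
detector floor.

What the simulator does *not* emulate: beam-propagation optics, shadowing
and depth-dependent signal roll-off, vascular structure, torsional eye
motion, intra-A-scan (fringe-level) motion, and pathology beyond drusen
and dot SDDs.  Passing tests therefore demonstrate correctness of the
*algorithms* under controlled violations of their assumptions, not
clinical performance on real eyes; in particular real en face texture has
vessels, which help transverse registration but also create confounds the
phantom does not probe.

## Motion estimation

Displacement per volume is a uniform cubic B-spline over the acquisition
span, one coefficient per control period (default: 4/2/1 B-scan periods at
the three pyramid levels).  The objective is the mean squared difference
of log-compressed intensities (`log1p(I/0.05)`, which tames speckle's
heavy tail) between each volume's samples at corrected positions and a
trilinearly gridded *leave-one-out* reconstruction of the other volumes,
plus first- and second-difference penalties on the coefficients
(λ₁ = 10⁻⁴, λ₂ = 10⁻³ per µm², relative to the data term; saccades are
handled by the same continuous model, the weak curvature penalty merely
discourages speckle-chasing).  The defaults were calibrated on the
drift-recovery scenario (fixational-amplitude drift, speckled volumes) and
are recorded in `MotionOptions`, not hard-coded.

Minimization is alternating Gauss–Seidel over volumes — each volume's
spline is optimized by L-BFGS-B with analytic gradients against the
*current* reconstruction of the others, which is updated immediately.
(A Jacobi update, optimizing all volumes against stale references,
overshoots by a factor ~2 per pass and stalls.)  Optimization variables
are expressed in level-voxel units so the transverse and axial axes are
equally conditioned; the projected-gradient stopping rule is disabled and
the relative-objective tolerance is 10⁻⁶ scaled to typical cost
magnitudes.  Three spatial pyramid levels (×4, ×2, ×1 transverse, axial
capped at ×2) with fixed iteration caps; estimation crops the axial range
to the retina band (rows above 10 % of the peak mean-intensity profile,
padded) since the empty vitreous and deep choroid contain no signal.

The registration determines displacements only up to one global 3D
constant; the gauge is fixed by constraining the mean displacement over
all volumes and control points to zero per axis, and recovery tests remove
the same constant from the ground truth before measuring error.  A
fixed-definition cross-stage metric (between-volume intensity variance on
a coarse grid) is recorded after every pyramid level as
`diagnostics["stage_objectives"]`; it is non-increasing on all test
scenarios and the final value is reported as the objective.

Observability note: with orthogonal scan directions, axial displacement is
pinned by the sharp layer gradients to sub-micrometre accuracy, while
transverse accuracy is set by the transverse texture (deposits, drusen)
— a featureless phantom leaves smooth transverse components weakly
determined.  This is a property of the problem, not the optimizer.

## Illumination correction

Bias is modeled as a multiplicative gain per A-scan, smooth along each
B-scan: 8 control points per B-scan, linearly interpolated — the small
control count *is* the feature-preservation constraint, since per-A-scan
image structure cannot be represented by the curve.  Gains are estimated
in log space by linear least squares on the disagreement of per-A-scan
summaries (log mean column intensity) between volumes overlapping at the
same en face pixel, with first-difference coupling of adjacent B-scans'
curves (weight 40; this is what propagates fast-axis continuity across
the slow axis through the orthogonal volumes), a second-difference penalty
along the curve (weight 1), and a small ridge that pins the unobservable
common log level to zero.  Solved with LSMR.  High-frequency structure
couples only through the basis-boundary projection, about 5 % of its
amplitude in the worst case.

Brightness matching is separate: each volume's robust mean (top-decile
trimmed mean of above-noise voxels) is scaled up to the brightest
volume's, so all scale factors are ≥ 1.

## Surfaces, flattening, fusion

BrM is found per B-scan by dynamic programming with a slope constraint of
2 voxels per A-scan step: the path minimizes the above-threshold bright
mass remaining *below* it minus a brightness reward at the path (units of
intensity·voxels; the reward acts as an effective line width of 2 voxels).
This is the "posterior-most bright structure" criterion — nothing
reflective lies below BrM but choroid — and it is immune to the brighter
IS/OS and RPE edges that defeat a pure strongest-gradient rule.  The
integer path is refined to the membrane line's reflectivity peak with
sub-voxel parabolic interpolation.  The posterior RPE boundary is the last
strong bright-to-dark edge anterior to BrM, found by the same
posterior-mass construction on the thresholded gradient.  Columns whose
path has no reflective support (blinks, dropouts) are masked.

Per-volume surfaces are motion-corrected (transverse and axial) and
averaged bilinearly onto the nominal transverse grid; holes are filled
from the nearest valid position before flattening (averaging precedes hole
filling, so gaps never bias the mean).  Flattening shifts every A-scan
column by `target − BrM(x, y)` with the default target row at 75 % of the
axial extent; merging bins all samples with trilinear weights and keeps
the summed weights as per-voxel contribution counts (mean combination
maximizes the SNR gain; the background noise of a six-volume fusion drops
by ≈ 1/√6).  Transverse positions are never altered by flattening.

## En face slabs

A slab is the per-pixel mean of voxels whose centre depth lies in the
half-open interval [ref − upper, ref − lower) µm above the reference
surface, counting only voxels with contributions; "27 to 77 µm above BrM"
with thickness 50 µm is consistent with the half-open convention, which
also makes adjacent slabs partition exactly.  A voxel belongs to the slab
iff its centre is inside the interval — the same rule the brute-force test
oracle applies voxel by voxel.  For pRPE-referenced slabs the fused volume
carries the pRPE depth map in the flattened frame (target − (BrM − pRPE)),
so the projection re-references per column; sub-RPE druse material
disappears in that slab, which the pipeline also exploits to separate
drusen from deposits during detection (a candidate that vanishes above
pRPE is a druse, not an SDD).  Mean aggregation is used throughout.

## Tracking

Visits are registered rigidly: upsampled phase correlation for
translation, then a golden-section search over rotation (bounded at ±5°)
maximizing normalized cross-correlation; pure translation is preferred
when rotation does not genuinely raise the score, and a score floor of
0.35 raises an error for unregistrable pairs.  Deposits are detected by
Laplacian-of-Gaussian scale-space blobs (radii 25–125 µm) on the
background-subtracted, normalized slab with non-maximum suppression.

Change classification: each baseline deposit claims its nearest follow-up
deposit within the match radius (default 60 µm = 5 transverse voxels,
small against typical deposit spacing).  Two or more baseline deposits
sharing a target are each **fused**; a sole claimant is **stable**; a
baseline deposit with no target in radius is **regressed**; an unclaimed
follow-up deposit is **new**.  Each baseline member of a merged group
counts once under "fused" and new deposits join the tracked total, so
counts like 278 + 32 + 11 + 5 add up to the total tracked.  Percentages
are `100·count/total` rounded half-up to one decimal (`decimal`-based,
reproducing every printed value, e.g. 278/326 → 85.3).

Quadrants are fovea-centred (fovea defaults to the field centre, supplied
by config otherwise); smaller row coordinate is superior, and nasal is −x
for OD, +x for OS in the fundus orientation.  Ties break toward superior
and nasal.

## Problem sizes and determinism

Unit tests run on 64–128 A-scan fields; the full-scale motion checks use
a 200 × 200 × 256 phantom with four volumes, and the acceptance script
measures motion metrics at 120 × 120 × 256 with the same protocol scaling
(volume duration shortened in proportion to the A-scan count, keeping the
published protocol's flyback fraction).  These sizes are the package's desk-scale study
conditions; all statistical structure (pitch, rates, noise, deposit
density) is kept at the full-scale values.  Every random element is driven
by explicit seeds (`numpy.random.default_rng` / `SeedSequence`), and
pipeline reruns with identical config and seed are bit-reproducible
(content-hashed manifests).

## Known limitations

* Transverse motion accuracy depends on en face texture; eyes (or
  phantoms) without deposits, drusen or vessels leave smooth transverse
  drift components weakly observable.
* The gain model is per-A-scan multiplicative and band-limited along the
  fast axis; depth-dependent attenuation or roll-off is out of scope.
* The surface finder is designed for the BrM/pRPE geometry of these
  phantoms and intermediate-AMD anatomy; it is not a general layer
  segmenter and does not handle RPE atrophy or detachments.
* Detection separates drusen from deposits via the pRPE slab; co-located
  deposit-on-druse configurations can merge into one blob.
* "Stable" means present at both visits within the match radius — size
  change of a persisting deposit is not measured.
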
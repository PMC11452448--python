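# Methods

## Problem and model

A 3D Cartesian brain acquisition collects one k-space readout line per
time index `t`.  If the head moves rigidly during the scan, line `t`
samples the spectrum of the *moved* object.  For a rigid pose
`theta = (tau, phi)` (translations in mm; rotations in radians about
x, y, z, composed as `R = R_z R_y R_x` with the x-rotation first,
right-hand rule), the spectrum of the moved object is a phase ramp
times the rotated spectrum of the still object:

    F_theta u (k) = exp(-i k . tau) * F u (R_phi^{-1} k).

The acquisition model is `d_t = S_t F_theta_t u`: pose frozen within a
readout (a readout lasts milliseconds), one pose per line.  Because the
rotation acts on sample *coordinates*, a single NUFFT evaluation of the
image spectrum serves every pose; per-pose cost is interpolation only.

Reconstruction solves

    min_{u, theta_1..n_t}  sum_t 0.5 ||F_theta_t u - d_t||^2
    subject to             g_u(u) <= eps,

where `g_u` is structure-guided total variation built from a motion-free
reference contrast `v` of the same anatomy:

    g_u(u) = sum_x || (I - xi xi^H) grad u|_x ||,
    xi|_x  = grad v|_x / sqrt(||grad v|_x||^2 + eta^2).

Gradient components parallel to the reference's edges are free; only the
component orthogonal to shared anatomy is penalized.  With `xi = 0` this
is plain isotropic TV (the blind baseline).  The trajectory is
parameterized on a coarse temporal knot grid with linear interpolation,
an implicit temporal smoother; an optional quadratic temporal penalty
(`mu * sum_t 0.5 ||theta_{t+1} - theta_t||^2`, prox solved exactly via a
tridiagonal system) is available but off by default.

## Numerical building blocks

**NUFFT.** A gridding NUFFT (type 2 and its exact adjoint) with 2x
oversampling and an exponential-of-semicircle kernel; deapodization
factors are computed by Gauss-Legendre quadrature of the kernel
transform.  Width-8 kernels give ~1e-7 relative accuracy against the
naive Fourier sum; the solver uses width 6 (~2e-5) for speed.  The
adjoint is the exact adjoint of the discrete pipeline, so adjoint tests
pass at machine precision.  Wavevectors outside the Nyquist box — which
rotated Cartesian lines produce at the volume corners — are evaluated
modulo 2*pi; for even grid sizes the discrete Fourier sum is exactly
periodic, so this introduces no approximation and keeps simulation and
reconstruction self-consistent.

**Conventions.** Wavevectors are in radians/voxel on the centered grid
`k = 2 pi q / n`; the forward transform is the unnormalized Fourier sum
(`||A u||^2 = n_vox ||u||^2` when fully sampled, tested via Parseval);
the zero-filled reconstruction is `A^H d / n_vox`.  Rotation center is
the voxel `n // 2` per axis (the DFT grid origin).  Translations are
carried in mm and converted to voxels inside the operator, so pose
estimates keep physical units across scales.

**Derivatives.** The image gradient of the misfit is `A^H (A u - d)`.
Knot-parameter derivatives: translations analytically (phase-ramp
derivative), rotations by central finite differences of the predicted
samples with step 1e-4 rad, evaluating only the lines each knot
influences and batching all perturbed coordinates into one NUFFT
interpolation.  The same finite differences supply a per-parameter
Gauss-Newton curvature `sum |ds/dp|^2` used as the step metric.

**TV-ball projection.** Euclidean projection onto `{g_u(u) <= eps}` by
FISTA on the dual problem (prox of the (2,inf)-norm via projection of
the per-voxel norms onto an l1 ball); warm-started across solver
iterations; a final homogeneity rescale around the image mean guarantees
feasibility within 0.1%.  Verified against a lifted smooth-QP oracle on
1D signals to 1e-4.

## Solver

Two nested continuation loops, following the clinical-protocol recipe:

* **spatial scale** (default factors 4, 2, 1): data restricted to the
  central low-frequency k-space block; sample values are divided by
  `factor^3` (voxel-volume change of the unnormalized sum) so the data
  model stays exact at every scale; the image transfers between scales
  by Fourier zero-padding, the knots unchanged;
* **regularization strength**: `eps = alpha * g_u(u_corrupted)` with
  `alpha = 0.01, 0.1, 0.5, 0.8` and `u_corrupted` the zero-filled
  reconstruction at the current scale.

Within a stage, one alternation per iteration: an image
gradient-projection step (monotone backtracking line search from a
power-iteration step size; the approximate prox makes the textbook
sufficient-decrease bound inexact, so acceptance additionally requires
an actual misfit decrease), then a damped diagonal Gauss-Newton step on
the motion knots, trust-capped at one coarse voxel / 2 degrees per
iteration.  The stage misfit trace is non-increasing by construction.

Two empirical identifiability facts shape the outer loop.  First,
motion information lives in the *binding* regime of the constraint: the
single-channel undersampled model has more unknowns than samples, so
once `eps` is loose enough to admit an exact data fit the residual
carries no pose information.  Second, rotations need both sufficient
k-space radius (coarse grids below 16 voxels only constrain the
translational phase ramps) and an image with full-band structure to
lock onto.  Per scale the solver therefore (i) runs the two binding
("probe") alpha stages with image+translation updates, (ii) refines all
six pose parameters in dedicated Gauss-Newton passes against the
current full-band image, alternating with re-reconstruction at the
binding strength, and (iii) runs the loose ("bake") alpha stages with
motion frozen to produce the final image.

**Stepwise trajectory model (default).** Patients hold still between
discrete repositionings, and the knot trajectory of such motion is a
staircase.  After knot refinement at the finest scale, change points
are detected from the (median-filtered) knot differences (every gap
jumping by >= 0.5 voxel or 0.75 degrees is a candidate — spurious
candidates are cheap, missed ones poison both neighbors), and each held
pose is re-estimated by pooling all of its readout lines.  An
expectation-maximization-like loop alternates pooled Gauss-Newton pose
refinement with per-line reassignment near the boundaries (localizing
each change to the exact readout), a temporal majority-vote filter
(dwell prior), merging of pose clusters that agree within 0.5 voxel /
1 degree, and absorption of segments too small (< 24 lines) for a
reliable rotation estimate.  A final global sweep lets every line pick
its best-fitting pose — dissolving clusters stuck in spurious rotation
basins — and is kept only when it lowers the total misfit, since with
unreliable poses (e.g. a heavily degraded reference) a global reshuffle
can do harm.  Set `trajectory_model="knots"` for motion
that is genuinely continuous; the stepwise model cannot represent it
and would quantize it.

## Synthetic study conditions

The generators emulate a controlled volunteer session:

* **Phantom pair**: an outer head ellipsoid plus 8 inner ellipsoidal
  regions shared by both contrasts (identical edge sets; Dice of
  gradient-magnitude masks >= 0.9), with independent per-region
  intensities, a 10% smooth intensity modulation per contrast, 0.8-voxel
  Gaussian edge softening, and a smooth +-0.5 rad phase map on the
  target (phase is required for k-space reprocessing).  Default grid
  32^3 at 1 mm isotropic: large enough for three spatial scales and
  graded rotation sensitivity, small enough that the full study runs in
  minutes on one CPU.
* **Motion**: piecewise-constant pose trajectories with `n_moves`
  changes at uniformly spaced times, starting aligned.  Mode "walk"
  accumulates deltas with component magnitudes uniform in [0.3, 1] times
  the bound (deliberate repositioning, wandering head); mode "jump"
  places every held pose at a fixed 0.75 x bound component displacement
  with random signs, so corruption grows reproducibly with the number of
  moves — the mode used for motion-complexity comparisons (verified
  monotone across 12 seed families).  Complexity studies use bounds of
  2 voxels / 2 degrees (keeps the zero-filled baseline out of
  saturation); single-step recovery runs use 5 voxels / 5 degrees.
* **Sampling**: variable-density Gaussian phase-encode patterns (sigma
  a quarter of the grid, fully sampled elliptical center block of 8%
  radius) at acceleration 2, or regular 2x2 lattices plus center block.
  Randomized patterns default to a seeded pseudo-random temporal order
  (clinical randomized fills are pseudo-random; ordering also decides
  which poses the retained coarse-scale lines observe); regular
  patterns default to low-frequency-first.
* **Noise**: complex Gaussian at 1% of the RMS clean-sample magnitude
  (zero-filled image SNR around 30 dB, typical of clinical scans).  A
  DC-referenced noise level is much harsher than any clinical scan
  because the DC sample dwarfs the RMS sample.
* **Reference degradation**: hard k-space low-pass at the full Nyquist
  band (level 0), a quarter (level 1), or an eighth (level 2) per axis.

What passing these studies does *not* show about real data: phantoms
are piecewise-smooth ellipsoids without anatomical texture, coil
combination is assumed ideal (single virtual channel), motion is exactly
rigid and frozen within readouts, and the corrupted data are generated
by the same forward model the solver inverts (no model mismatch beyond
noise).  Performance on scanner data additionally depends on the
reconstruction used to produce coil-combined k-space.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `eta_rel` | 0.01 | guide damping, fraction of max reference gradient |
| `alpha_schedule` | 0.01, 0.1, 0.5, 0.8 | constraint continuation (fractions of corrupted TV) |
| `mu` | 0 | temporal penalty weight (knot grid already smooths) |
| `spatial_factors` | 4, 2, 1 | coarse-to-fine k-space restriction |
| `iters_per_stage` | 30 | PALM iterations per stage (the bundled studies use 8-10) |
| `knot_count` | 16 | coarse temporal knots |
| `refine_cycles` / `refine_iters` | 2 / 12 | pose-refinement passes per scale (studies use 16-20 iters) |
| NUFFT width | 8 operators / 6 solver | kernel taps per axis (accuracy vs speed) |
| rotation FD step | 1e-4 rad | central-difference step for rotation derivatives |

## Degenerate inputs and tie-breaks

Constant reference: the guide field degenerates to zero and guided TV
reduces to plain TV.  `eps = 0` with plain TV projects to the constant
mean image.  A trajectory with a single knot is constant in time.
Stepwise detection on motion-free data returns a single segment pooling
all lines.  Ties in the boundary reassignment go to the earlier
segment; the majority-vote filter keeps the current assignment on vote
ties.

## Known limitations

* Pose changes smaller than ~0.5 voxel / 0.75 degrees are below the
  stepwise detection threshold and are absorbed into neighboring poses
  (they are also below the clinically relevant artifact level at these
  resolutions).
* On unlucky seed/schedule combinations a line cluster can settle in a
  spurious rotation basin that the image reconstruction then colludes
  with (rotated sample coordinates fall into the undersampled
  nullspace and can be overfit almost freely).  A plausibility guard
  catches the flagrant cases: when any held pose exceeds 10 degrees or
  8 voxels, the estimated and the null trajectory are re-reconstructed
  from the same zero-filled start at binding strength, and the motion
  estimate is kept only if it explains the data at least twice as well
  — real motion wins this comparison by orders of magnitude, overfit
  rogues by fractions of a percent.  Sub-threshold rogue poses remain
  possible.
* Rotation estimates at a held pose carry a residual bias of a few
  tenths of a degree inherited from the image they were refined
  against; it shrinks with milder motion and more polish cycles but is
  not driven to zero.
* The multiscale grids require grid sizes divisible by the spatial
  factors; the reference grid must be an integer multiple of the
  reconstruction grid (or equal to it) at every scale.
* Non-rigid motion, within-readout motion, and multi-coil modeling are
  out of scope.
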
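# rigidmoco

Reference-guided retrospective rigid-motion correction for 3D Cartesian
brain MRI.

In a typical MR session several contrasts are acquired back to back.
When the patient moves during one of them, that scan is corrupted by
ghosting and blurring while earlier scans of the *same anatomy* are
clean.  `rigidmoco` removes rigid-motion artifacts from a corrupted
coil-combined k-space dataset by jointly estimating the image and the
per-readout rigid pose trajectory, using a motion-free contrast from
the same session as a structural prior — no navigators, markers, or
scanner modifications.

## Model

The spectrum of a rigidly moved object is a phase ramp times the
rotated spectrum of the still object,

    F_theta u (k) = exp(-i k . tau) * F u (R_phi^{-1} k),

so each readout line `d_t = S_t F_theta_t u` samples the perturbed
spectrum at the pose `theta_t = (tau_t, phi_t)` held during that line
(evaluated by a NUFFT, since rotations move Cartesian samples
off-grid).  Reconstruction solves

    min_{u, theta}  sum_t 1/2 || F_theta_t u - d_t ||^2
    s.t.            g_u(u) <= eps,

where `g_u` is **structure-guided total variation**: with
`xi = grad v / sqrt(||grad v||^2 + eta^2)` built from the motion-free
reference `v`, only the component of `grad u` orthogonal to the shared
anatomy is penalized, `g_u(u) = sum_x ||(I - xi xi^H) grad u|_x||`.
The solver alternates proximal image updates with Gauss-Newton pose
updates inside two continuation loops (spatial scale, and
`eps = alpha * g_u(u_corrupted)` with `alpha = 0.01, 0.1, 0.5, 0.8`),
and by default re-estimates the trajectory under a stepwise held-pose
model — patients hold still between discrete repositionings.
See `docs/methods.md` for the complete account.

## Worked example

```python
import numpy as np
from rigidmoco.synthetic import (PhantomSpec, make_phantom_pair,
                                 make_sampling_pattern,
                                 make_stepwise_trajectory,
                                 simulate_acquisition)
from rigidmoco.model import MotionCorrectionModel, MultiScaleSchedule
from rigidmoco.operators import RigidMotionOperator
from rigidmoco.metrics import psnr

# two contrasts of the same anatomy; the volunteer moves once mid-scan
truth, reference = make_phantom_pair(PhantomSpec(shape=(32, 32, 32),
                                                 n_blobs=8, seed=1))
pattern = make_sampling_pattern((32, 32, 32), "randomized",
                                acceleration=2, seed=1)
motion = make_stepwise_trajectory(pattern.n_t, n_moves=1,
                                  max_translation=5.0, max_rotation=5.0,
                                  seed=1, pose_mode="jump")
data = simulate_acquisition(truth, motion, pattern, seed=1)

corrupted = RigidMotionOperator(pattern).zero_filled(data)
model = MotionCorrectionModel(data=data, reference=reference,
                              schedule=MultiScaleSchedule(
                                  iters_per_stage=10, refine_iters=20))
result = model.fit()

print(f"corrupted PSNR {psnr(corrupted, truth):.2f} dB")
print(f"corrected PSNR {psnr(result.image, truth):.2f} dB")
step = result.fine_params()[-1] - result.fine_params()[0]
print("recovered step:", np.round(step[:3], 2), "mm,",
      np.round(np.rad2deg(step[3:]), 2), "deg")
```

Output:

```
corrupted PSNR 12.36 dB
corrected PSNR 42.49 dB
recovered step: [-3.73  3.82  3.79] mm, [ 4.55 -3.95 -4.14] deg
```

The zero-filled reconstruction of the corrupted data sits at 12 dB; the
jointly corrected image gains 30 dB.  The simulated repositioning has
components of ±3.75 voxels and ±3.75°; translations come back to a few
hundredths of a voxel, rotations to a few tenths of a degree at this
32³ grid (rotation accuracy grows with grid size — at 48³ the same
experiment recovers the step to 0.04°).  `result.summary()` prints the
continuation stages; `result.save_trajectory_csv(...)` and
`result.plot_motion(...)` export the estimated trajectory.

## Command line

```bash
rigidmoco simulate --scenario scenario.yaml --out sim/ --seed 1
rigidmoco correct  --data sim/kspace.h5 --reference sim/reference --out run/
rigidmoco evaluate run/corrected sim/ground_truth --out quality.json
rigidmoco plot-motion run/trajectory.csv --out motion.png
```

Volumes travel as magnitude/phase NIfTI pairs (the phase map is
required to reprocess reconstructions into k-space); k-space data use
an HDF5 container with datasets `/samples` (complex64, `n_t x n_r`) and
`/lines` (int32, `n_t x 2` centered phase-encode offsets) plus
attributes `grid_shape`, `readout_axis`, `spacing`, `noise_sigma`.

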
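"""Joint motion-correction / reconstruction model and its solver.

The estimation problem is

    min_{u, theta_1..n_t}  sum_t 0.5 ||F_theta_t u - d_t||^2
                           + mu * g_theta(theta)
    subject to             g_u(u) <= eps,

with ``g_u`` the (structure-guided) total variation and the motion
trajectory parameterized by a coarse temporal knot grid with linear
interpolation (an implicit temporal smoother).  The solver alternates
proximal-gradient updates over the image and the knot parameters (one
of each per iteration, image first), with backtracking line searches
that keep the misfit monotone, nested inside two continuation loops:

* spatial scale — the data are restricted to the central low-frequency
  k-space block at each downsampling factor, keeping the data model
  exact at every scale; the image transfers between scales by Fourier
  zero-padding, the knots transfer unchanged;
* regularization strength — ``eps = alpha * g_u(u_corrupted)`` with
  ``alpha`` swept over an increasing schedule (0.01, 0.1, 0.5, 0.8 by
  default), so heavily constrained problems are solved first.

Usage follows the model/results pattern::

    model = MotionCorrectionModel(data, reference)
    res = model.fit()
    res.summary()
    corrected = res.image
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
import numpy as np

from rigidmoco.geometry import ImageVolume, MotionTrajectory, interp_weights
from rigidmoco.operators import KSpaceData, RigidMotionOperator, SamplingPattern
from rigidmoco.regularizers import (RegularizerSpec, StructureGuide, build_guide,
                                    motion_penalty, motion_penalty_prox,
                                    project_tv_ball, tv_value)

__all__ = [
    "MultiScaleSchedule",
    "SolverState",
    "MotionCorrectionModel",
    "MotionCorrectionResults",
    "epsilon_from_alpha",
    "restrict_kspace",
    "upsample_volume",
    "palm_iteration",
]


@dataclass
class MultiScaleSchedule:
    """The two continuation axes plus solver bookkeeping parameters."""

    spatial_factors: tuple[int, ...] = (4, 2, 1)
    alpha_schedule: tuple[float, ...] | None = None  # None: take from RegularizerSpec
    iters_per_stage: int = 30
    knot_count: int = 16
    step_rule: str = "backtracking"  # "backtracking" | "fixed"
    refine_cycles: int = 2
    refine_iters: int = 12
    polish_alpha: float | None = None  # None: reuse the last probe alpha

    def __post_init__(self) -> None:
        factors = tuple(int(f) for f in self.spatial_factors)
        if not factors or factors[-1] != 1 or any(
                a <= b for a, b in zip(factors, factors[1:])):
            raise ValueError("spatial_factors must decrease and end at 1")
        self.spatial_factors = factors
        if self.iters_per_stage < 1 or self.knot_count < 1:
            raise ValueError("iters_per_stage and knot_count must be positive")
        if self.step_rule not in ("backtracking", "fixed"):
            raise ValueError(f"unknown step rule {self.step_rule!r}")


def epsilon_from_alpha(u_corrupted, guide: StructureGuide | None, alpha: float) -> float:
    """Constraint level ``eps = alpha * g_u(u_corrupted)``."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return float(alpha) * tv_value(u_corrupted, guide)


def restrict_kspace(data: KSpaceData, factor: int) -> tuple[KSpaceData, np.ndarray]:
    """Restrict data to the central low-frequency block at a downsampling factor.

    Returns the coarse-grid dataset and the original time fractions of
    the retained lines (needed to evaluate the knot interpolation on the
    coarse time axis).  Sample values are divided by ``factor**3`` (the
    voxel-volume change of the unnormalized Fourier sum), and the voxel
    spacing is multiplied by ``factor``, so pose parameters keep their
    physical units across scales.
    """
    if factor == 1:
        times = np.arange(data.pattern.n_t) / max(data.pattern.n_t - 1, 1)
        return data, times
    pat = data.pattern
    if any(n % factor for n in pat.grid_shape):
        raise ValueError(f"grid {pat.grid_shape} not divisible by factor {factor}")
    coarse_shape = tuple(n // factor for n in pat.grid_shape)

    pe_shape = pat.phase_encode_shape
    m1, m2 = pe_shape[0] // factor, pe_shape[1] // factor
    keep = ((pat.lines[:, 0] >= -(m1 // 2)) & (pat.lines[:, 0] < m1 - m1 // 2)
            & (pat.lines[:, 1] >= -(m2 // 2)) & (pat.lines[:, 1] < m2 - m2 // 2))
    t_idx = np.nonzero(keep)[0]

    n_r = pat.n_r
    m_r = n_r // factor
    lo = n_r // 2 - m_r // 2
    ro_slice = slice(lo, lo + m_r)

    coarse_pat = SamplingPattern(grid_shape=coarse_shape, readout_axis=pat.readout_axis,
                                 lines=pat.lines[keep])
    samples = data.samples[keep][:, ro_slice] / float(factor) ** 3
    coarse = KSpaceData(samples=samples, pattern=coarse_pat,
                        noise_sigma=data.noise_sigma / float(factor) ** 3,
                        spacing=data.spacing * factor)
    times = t_idx / max(pat.n_t - 1, 1)
    return coarse, times


def upsample_volume(u: np.ndarray, to_shape: tuple[int, int, int]) -> np.ndarray:
    """Fourier zero-padding upsampler preserving image amplitude."""
    from_shape = u.shape
    spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(u)))
    out = np.zeros(to_shape, dtype=np.complex128)
    sl = tuple(slice(N // 2 - n // 2, N // 2 - n // 2 + n)
               for n, N in zip(from_shape, to_shape))
    out[sl] = spec
    scale = np.prod(to_shape) / np.prod(from_shape)
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(out))) * scale


def _power_iteration_lipschitz(op: RigidMotionOperator, n_iter: int = 8,
                               seed: int = 0) -> float:
    """Estimate ``||A^H A||`` for the zero-motion operator by power iteration."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(op.shape) + 1j * rng.standard_normal(op.shape)
    x /= np.linalg.norm(x)
    zeros = np.zeros((op.pattern.n_t, 6))
    lam = 1.0
    for _ in range(n_iter):
        y = op.adjoint(op.forward(x, zeros), zeros)
        lam = float(np.linalg.norm(y))
        if lam == 0:
            return 1.0
        x = y / lam
    return lam


@dataclass
class SolverState:
    """Mutable working state of one continuation stage."""

    u: np.ndarray
    knots: np.ndarray  # (n_knots, 6): tau in mm, phi in radians
    eps: float
    t_u: float
    t_theta: float
    objective: float = np.inf
    trace: list[float] = field(default_factory=list)
    p_dual: np.ndarray | None = None


class _StageContext:
    """Operator, data and regularizer wiring at one spatial scale."""

    def __init__(self, op: RigidMotionOperator, data: KSpaceData,
                 guide: StructureGuide | None, interp_w: np.ndarray,
                 mu: float, estimate_motion: bool, backtracking: bool,
                 update_rotations: bool = True):
        self.op = op
        self.data = data
        self.guide = guide
        self.interp_w = interp_w
        self.mu = mu
        self.estimate_motion = estimate_motion
        self.backtracking = backtracking
        self.update_rotations = update_rotations

    def fine_params(self, knots: np.ndarray) -> np.ndarray:
        return self.interp_w @ knots

    def objective(self, state_u, knots, spectrum=None) -> float:
        f = self.op.misfit(state_u, self.fine_params(knots), self.data,
                           spectrum=spectrum)
        if self.mu > 0:
            f += self.mu * motion_penalty(self.interp_w @ knots)
        return f


def palm_iteration(state: SolverState, ctx: _StageContext) -> SolverState:
    """One alternation: image prox-gradient step, then motion step.

    The image step is a gradient step on the misfit followed by
    projection onto the TV ball (the prox of the constraint indicator),
    accepted under the standard sufficient-decrease condition; the
    motion step is a preconditioned gradient step on the knot
    parameters (analytic translation derivatives, finite-difference
    rotation derivatives), backtracked until the misfit decreases, then
    the temporal-penalty prox when ``mu > 0``.  The misfit never
    increases across an accepted iteration.
    """
    op, data = ctx.op, ctx.data
    params = ctx.fine_params(state.knots)

    # ---- u-update --------------------------------------------------------
    spectrum = op.plan.spectrum(state.u)
    resid = op.forward(state.u, params, spectrum=spectrum) - data.samples
    f0 = 0.5 * float(np.vdot(resid, resid).real)
    grad = op.adjoint(resid, params)

    t = state.t_u
    accepted = False
    for _ in range(12):
        cand, p_dual = project_tv_ball(state.u - t * grad, state.eps, ctx.guide,
                                       p0=state.p_dual)
        delta = cand - state.u
        f_new = op.misfit(cand, params, data)
        # prox-gradient sufficient decrease (descent lemma)
        bound = f0 + float(np.vdot(grad, delta).real) \
            + float(np.vdot(delta, delta).real) / (2.0 * t)
        if f_new <= bound + 1e-12 * max(f0, 1.0):
            accepted = True
            break
        if not ctx.backtracking:
            break
        t *= 0.5
    # the dual projection is approximate, so the sufficient-decrease bound
    # is not exact: discard any update that raised the misfit, keeping the
    # stage trace non-increasing
    if accepted and f_new > f0 + 1e-12 * max(f0, 1.0):
        accepted = False
    if accepted:
        state.u = cand
        state.p_dual = p_dual
        state.t_u = min(t * 1.3, 1e6 * t)
        f_u = f_new
    else:
        f_u = f0

    # ---- theta-update ----------------------------------------------------
    if ctx.estimate_motion:
        spectrum = op.plan.spectrum(state.u)
        f1, gk, gn = op.misfit_grad_knots(state.u, state.knots, ctx.interp_w, data,
                                          spectrum=spectrum, return_gn_diag=True,
                                          compute_rotations=ctx.update_rotations)
        # damped diagonal Gauss-Newton metric: well-scaled steps for the
        # heterogeneous units (mm vs radians) without hand tuning
        damping = 1e-3 * float(gn.max()) + 1e-30
        direction = gk / (gn + damping)
        if not ctx.update_rotations:
            direction[:, 3:] = 0.0
        # trust region: rotations are poorly resolved on coarse grids, so
        # confident Gauss-Newton steps there can jump into wrong basins
        cap = np.concatenate([np.asarray(data.spacing, dtype=float),
                              np.deg2rad([2.0, 2.0, 2.0])])
        t = state.t_theta
        for _ in range(30):
            cand_k = state.knots - np.clip(t * direction, -cap, cap)
            if ctx.mu > 0:
                cand_k = motion_penalty_prox(cand_k, ctx.mu * t)
            f_new = op.misfit(state.u, ctx.fine_params(cand_k), data,
                              spectrum=spectrum)
            if f_new <= f1 + 1e-12 * max(f1, 1.0):
                state.knots = cand_k
                state.t_theta = min(t * 1.5, 1.0)
                f_u = f_new
                break
            if not ctx.backtracking:
                break
            t *= 0.5
        else:
            state.t_theta = t

    state.objective = f_u + (ctx.mu * motion_penalty(ctx.fine_params(state.knots))
                             if ctx.mu > 0 else 0.0)
    state.trace.append(state.objective)
    return state


def _detect_change_times(knots: np.ndarray, knot_times: np.ndarray,
                         tau_thresh: float = 0.5,
                         phi_thresh: float = np.deg2rad(0.75)) -> list[float]:
    """Change points of a stepwise trajectory from the knot estimates.

    Every jumping knot gap yields a candidate boundary: spurious
    candidates are cheap (the pooled refinement merges segments whose
    poses agree), whereas a missed change poisons the pooled estimates
    of both neighboring poses.
    """
    k = knots.copy()
    if k.shape[0] >= 3:
        from scipy.ndimage import median_filter
        k = median_filter(k, size=(3, 1), mode="nearest")
    d = np.diff(k, axis=0)
    mag = np.maximum(np.abs(d[:, :3]).max(axis=1) / tau_thresh,
                     np.abs(d[:, 3:]).max(axis=1) / phi_thresh)
    return [0.5 * float(knot_times[j] + knot_times[j + 1])
            for j in np.nonzero(mag >= 1.0)[0]]


def stepwise_refine(ctx: _StageContext, u: np.ndarray, knots: np.ndarray,
                    knot_times: np.ndarray, line_times: np.ndarray,
                    n_iter: int, em_rounds: int = 3):
    """Re-estimate the trajectory under a held-pose (stepwise) model.

    Change points are detected from the knot trajectory; each held pose
    is then refined by pooling all of its readout lines (a large
    variance reduction over per-knot estimates), alternating with a
    per-line reassignment step near the boundaries that localizes each
    change to the exact readout where it happened.  Adjacent segments
    whose refined poses agree are merged (spurious detections die out).

    Returns ``(assign, poses, change_times)`` with ``assign`` the
    per-line segment index.
    """
    change_times = _detect_change_times(knots, knot_times)
    n_lines = line_times.size
    assign = np.searchsorted(np.asarray(change_times), line_times, side="right")
    fine = ctx.interp_w @ knots
    spacing_t = float(np.median(np.diff(knot_times))) if len(knot_times) > 1 else 1.0
    spectrum = ctx.op.plan.spectrum(u)
    min_lines = 24  # below this a pooled rotation estimate is unreliable

    def line_costs(pose: np.ndarray, lines: np.ndarray) -> np.ndarray:
        params = np.tile(pose, (lines.size, 1))
        pred = ctx.op.forward_lines(spectrum, params, lines)
        return np.sum(np.abs(pred - ctx.data.samples[lines]) ** 2, axis=1)

    def compress(assign, poses):
        ids, assign = np.unique(assign, return_inverse=True)
        return assign, poses[ids]

    def pooled_refine(assign, poses=None):
        n_seg = assign.max() + 1
        if poses is None:
            poses = np.stack([
                np.median(fine[assign == s], axis=0) if np.any(assign == s)
                else np.zeros(6) for s in range(n_seg)])
        w_seg = np.zeros((n_lines, n_seg))
        w_seg[np.arange(n_lines), assign] = 1.0
        sub = _StageContext(op=ctx.op, data=ctx.data, guide=ctx.guide,
                            interp_w=w_seg, mu=0.0, estimate_motion=True,
                            backtracking=ctx.backtracking)
        return theta_refine(sub, u, poses, n_iter)

    def mode_filter(assign, half_width=4, passes=2):
        """Majority vote over a temporal window: held poses dwell, so
        isolated assignment flips are noise."""
        for _ in range(passes):
            out = assign.copy()
            for i in range(assign.size):
                lo, hi = max(0, i - half_width), min(assign.size, i + half_width + 1)
                votes = np.bincount(assign[lo:hi])
                best = int(np.argmax(votes))
                if votes[best] > votes[assign[i]]:
                    out[i] = best
            assign = out
        return assign

    def cleanup(assign, poses):
        """Cluster-merge agreeing poses, then absorb small segments."""
        n_seg = poses.shape[0]
        if n_seg > 1:
            # union-find over all pose pairs that agree within tolerance
            parent = list(range(n_seg))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n_seg):
                for j in range(i + 1, n_seg):
                    d = poses[i] - poses[j]
                    if (np.abs(d[:3]).max() < 0.5
                            and np.abs(d[3:]).max() < np.deg2rad(1.0)):
                        parent[find(j)] = find(i)
            roots = [find(s) for s in range(n_seg)]
            uniq_roots = sorted(set(roots))
            remap = np.array([uniq_roots.index(r) for r in roots])
            assign = remap[assign]
            poses = poses[uniq_roots]
            assign, poses = compress(assign, poses)
        n_seg = poses.shape[0]
        counts = np.bincount(assign, minlength=n_seg)
        for s in np.nonzero(counts < min_lines)[0]:
            lines_s = np.nonzero(assign == s)[0]
            others = [q for q in range(n_seg)
                      if q != s and counts[q] >= min_lines]
            if lines_s.size == 0 or not others:
                continue
            costs = np.stack([line_costs(poses[q], lines_s) for q in others])
            assign[lines_s] = np.asarray(others)[np.argmin(costs, axis=0)]
        return compress(assign, poses)

    poses = pooled_refine(assign)
    assign, poses = cleanup(assign, poses)
    for _ in range(em_rounds):
        poses = pooled_refine(assign, poses)
        n_seg = poses.shape[0]
        # localize each change: reassign boundary-adjacent lines to the
        # better-fitting pose
        for b in range(n_seg - 1):
            left = line_times[assign == b]
            right = line_times[assign == b + 1]
            if left.size == 0 or right.size == 0:
                continue
            tb = 0.5 * (left.max() + right.min())
            near = np.nonzero((np.abs(line_times - tb) <= 2.0 * spacing_t)
                              & ((assign == b) | (assign == b + 1)))[0]
            if near.size == 0:
                continue
            costs = np.stack([line_costs(poses[s], near) for s in (b, b + 1)])
            assign[near] = np.where(costs[0] <= costs[1], b, b + 1)
        assign = mode_filter(assign)
        assign, poses = cleanup(assign, poses)
    poses = pooled_refine(assign, poses)

    def total_misfit(assign, poses):
        pred = ctx.op.forward_lines(spectrum, poses[assign],
                                    np.arange(n_lines))
        return float(np.sum(np.abs(pred - ctx.data.samples) ** 2))

    # final global sweep: every line picks its best-fitting pose, which
    # dissolves clusters stuck in spurious rotation basins; kept only if
    # it actually improves the fit (with unreliable poses — e.g. a badly
    # degraded reference — a global reshuffle can do harm)
    if poses.shape[0] > 1:
        before = (assign.copy(), poses.copy(), total_misfit(assign, poses))
        all_lines = np.arange(n_lines)
        costs = np.stack([line_costs(poses[s], all_lines)
                          for s in range(poses.shape[0])])
        assign = np.argmin(costs, axis=0)
        assign = mode_filter(assign)
        assign, poses = compress(assign, poses)
        assign, poses = cleanup(assign, poses)
        poses = pooled_refine(assign, poses)
        if total_misfit(assign, poses) > before[2]:
            assign, poses = before[0], before[1]

    change_times = []
    for b in range(poses.shape[0] - 1):
        left = line_times[assign == b]
        right = line_times[assign == b + 1]
        if left.size and right.size:
            change_times.append(0.5 * float(left.max() + right.min()))
        else:
            change_times.append(float(b + 1) / poses.shape[0])
    return assign, poses, change_times


def theta_refine(ctx: _StageContext, u: np.ndarray, knots: np.ndarray,
                 n_iter: int, include_rotations: bool = True) -> np.ndarray:
    """Damped Gauss-Newton refinement of the motion knots at fixed image.

    Rotation estimation needs an image with full-band structure to lock
    onto; the solver therefore refines the pose trajectory in dedicated
    passes against the current reconstruction rather than inside the
    strongly-constrained continuation stages.
    """
    op, data = ctx.op, ctx.data
    spectrum = op.plan.spectrum(u)
    cap = np.concatenate([np.asarray(data.spacing, dtype=float),
                          np.deg2rad([2.0, 2.0, 2.0])])
    t = 1.0
    for _ in range(n_iter):
        f0, gk, gn = op.misfit_grad_knots(u, knots, ctx.interp_w, data,
                                          spectrum=spectrum, return_gn_diag=True,
                                          compute_rotations=include_rotations)
        direction = gk / (gn + 1e-3 * float(gn.max()) + 1e-30)
        if not include_rotations:
            direction[:, 3:] = 0.0
        accepted = False
        for _ in range(30):
            cand = knots - np.clip(t * direction, -cap, cap)
            f_new = op.misfit(u, ctx.fine_params(cand), data, spectrum=spectrum)
            if f_new <= f0:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        knots = cand
        t = min(t * 1.5, 1.0)
    return knots


@dataclass
class MotionCorrectionModel:
    """Joint rigid-motion correction and reconstruction for one dataset.

    Parameters
    ----------
    data : KSpaceData
        Motion-corrupted coil-combined k-space samples plus pattern.
    reference : ImageVolume
        Motion-free reference contrast; may differ in resolution (it is
        resampled onto the reconstruction grid) and need not be
        co-registered.
    regularizer : RegularizerSpec
        TV flavor (``guided_tv`` or ``plain_tv``), alpha schedule,
        temporal penalty weight ``mu`` and guide ``eta``.
    schedule : MultiScaleSchedule
        Spatial factors, iterations per stage and knot count.
    estimate_motion : bool
        Disable to solve a reconstruction-only problem at fixed zero
        motion (useful for calibration experiments).
    """

    data: KSpaceData
    reference: ImageVolume | None = None
    regularizer: RegularizerSpec = field(default_factory=RegularizerSpec)
    schedule: MultiScaleSchedule = field(default_factory=MultiScaleSchedule)
    estimate_motion: bool = True
    trajectory_model: str = "stepwise"  # "stepwise" | "knots"
    nufft_width: int = 6

    def __post_init__(self) -> None:
        if self.regularizer.mode == "guided_tv" and self.reference is None:
            raise ValueError("guided_tv requires a reference volume")
        if self.trajectory_model not in ("stepwise", "knots"):
            raise ValueError(f"unknown trajectory model {self.trajectory_model!r}")
        shape = self.data.pattern.grid_shape
        for f in self.schedule.spatial_factors:
            if any(n % f for n in shape):
                raise ValueError(f"grid {shape} not divisible by factor {f}")

    @classmethod
    def from_files(cls, kspace_path, reference_path=None, **kwargs
                   ) -> "MotionCorrectionModel":
        from rigidmoco.io import read_kspace, read_volume
        data = read_kspace(kspace_path)
        ref = read_volume(reference_path) if reference_path else None
        return cls(data=data, reference=ref, **kwargs)

    # -- scale plumbing -----------------------------------------------------
    def _reference_at(self, shape) -> ImageVolume | None:
        if self.reference is None:
            return None
        v = self.reference.data
        if v.shape == tuple(shape):
            return self.reference
        if all(s % m == 0 for s, m in zip(v.shape, shape)):
            # band-limited, amplitude-preserving downsample: central spectrum crop
            spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(v)))
            sl = tuple(slice(N // 2 - n // 2, N // 2 - n // 2 + n)
                       for n, N in zip(shape, v.shape))
            out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec[sl])))
            out *= np.prod(shape) / np.prod(v.shape)
            return ImageVolume(out, self.reference.spacing * (v.shape[0] // shape[0]))
        raise ValueError("reference grid must be an integer multiple of the "
                         "reconstruction grid at every scale")

    def fit(self, verbose: bool = False) -> "MotionCorrectionResults":
        """Run the multiscale alternating solver and return results."""
        sched = self.schedule
        reg = self.regularizer
        alphas = sched.alpha_schedule or reg.alpha_schedule
        knot_times = (np.linspace(0.0, 1.0, sched.knot_count)
                      if sched.knot_count > 1 else np.zeros(1))
        knots = np.zeros((sched.knot_count, 6))
        u = None
        prev_shape = None
        fine_override = None
        step_poses = step_times = None
        scale_log: list[dict] = []
        traces: list[list[float]] = []
        t_start = time.time()

        zero_filled_full: ImageVolume | None = None
        for factor in sched.spatial_factors:
            cdata, line_times = restrict_kspace(self.data, factor)
            op = RigidMotionOperator(cdata.pattern, spacing=cdata.spacing,
                                     nufft_width=self.nufft_width)
            shape = cdata.pattern.grid_shape
            interp_w = interp_weights(knot_times, line_times, "piecewise-linear")
            ref_c = self._reference_at(shape)
            guide = (build_guide(ref_c, target_shape=shape, eta_rel=reg.eta_rel)
                     if reg.mode == "guided_tv" else None)

            zf = op.zero_filled(cdata)
            if factor == 1:
                zero_filled_full = ImageVolume(zf.copy(), cdata.spacing)
            if u is None:
                u = zf.copy()
            elif prev_shape != shape:
                u = upsample_volume(u, shape)

            lip = _power_iteration_lipschitz(op)
            t_u0 = 1.0 / lip
            g_corrupted = tv_value(zf, guide)

            ctx = _StageContext(op=op, data=cdata, guide=guide, interp_w=interp_w,
                                mu=reg.mu, estimate_motion=self.estimate_motion,
                                backtracking=sched.step_rule == "backtracking",
                                update_rotations=False)

            def run_alpha_loop(alpha_seq, u, knots, tag):
                for alpha in alpha_seq:
                    eps = float(alpha) * g_corrupted
                    state = SolverState(u=u, knots=knots, eps=eps, t_u=t_u0,
                                        t_theta=1.0)
                    # enter the feasible set once per stage
                    state.u, state.p_dual = project_tv_ball(state.u, eps, guide)
                    for _ in range(sched.iters_per_stage):
                        palm_iteration(state, ctx)
                    u, knots = state.u, state.knots
                    traces.append(state.trace)
                    scale_log.append({
                        "factor": factor, "alpha": float(alpha), "eps": eps,
                        "phase": tag, "iterations": sched.iters_per_stage,
                        "final_misfit": state.trace[-1] if state.trace else None,
                        "elapsed_s": time.time() - t_start,
                    })
                    if verbose:
                        print(f"[rigidmoco] scale 1/{factor} {tag} alpha={alpha:g} "
                              f"misfit={state.trace[-1]:.4e}")
                return u, knots

            # Motion is identifiable only while the TV constraint binds:
            # once eps admits an exact data fit, the residual carries no
            # pose information.  The probe stages (small alpha) therefore
            # drive the motion estimate; the loose stages only bake the
            # final image at fixed motion.
            probe, bake = alphas[:2], alphas[2:]
            u, knots = run_alpha_loop(probe, u, knots, "probe")
            if self.estimate_motion and min(shape) >= 16:
                # rotations need sufficient k-space radius and a
                # full-band image; refine them in dedicated passes
                for _ in range(sched.refine_cycles):
                    knots = theta_refine(ctx, u, knots, sched.refine_iters)
                    u, knots = run_alpha_loop(probe[-1:], u, knots, "rebake")
                knots = theta_refine(ctx, u, knots, sched.refine_iters)
            if (factor == 1 and self.estimate_motion
                    and self.trajectory_model == "stepwise"):
                assign, poses, change_times = stepwise_refine(
                    ctx, u, knots, knot_times, line_times, sched.refine_iters)
                w_seg = np.zeros((line_times.size, poses.shape[0]))
                w_seg[np.arange(line_times.size), assign] = 1.0
                ctx.interp_w = w_seg
                # polish: the pose estimates are only as good as the image
                # they were refined against; alternate binding-strength
                # re-reconstruction with pooled pose refinement
                polish_alpha = (sched.polish_alpha if sched.polish_alpha
                                else probe[-1])
                for _ in range(sched.refine_cycles):
                    ctx.estimate_motion = False
                    u, _ = run_alpha_loop([polish_alpha], u, poses, "polish")
                    ctx.estimate_motion = self.estimate_motion
                    poses = theta_refine(ctx, u, poses, sched.refine_iters)
                # plausibility check: head repositioning beyond ~10 deg /
                # 8 voxels is rare, and poses that large are the signature
                # of a spurious rotation basin the image has colluded
                # with.  When one appears, re-reconstruct from the same
                # zero-filled start under both the estimated and the null
                # trajectory (same schedule: a fair comparison) and keep
                # whichever explains the data better.
                implausible = (np.abs(poses[:, :3]).max() > 8.0 * float(
                    np.min(cdata.spacing)) or
                    np.abs(poses[:, 3:]).max() > np.deg2rad(10.0))
                if implausible:
                    ctx.estimate_motion = False
                    u_null, _ = run_alpha_loop(probe, zf.copy(),
                                               np.zeros_like(poses),
                                               "null-check")
                    f_null = scale_log[-1]["final_misfit"]
                    u_est, _ = run_alpha_loop(probe, zf.copy(), poses,
                                              "est-check")
                    f_est = scale_log[-1]["final_misfit"]
                    ctx.estimate_motion = self.estimate_motion
                    # rotated samples sit in the undersampled nullspace and
                    # can be overfit almost freely, so an implausible
                    # trajectory must win decisively, not marginally
                    if f_null <= 2.0 * f_est:
                        poses = np.zeros((1, 6))
                        assign = np.zeros(line_times.size, dtype=int)
                        w_seg = np.ones((line_times.size, 1))
                        ctx.interp_w = w_seg
                        u = u_null
                fine_override = poses[assign]
                step_poses, step_times = poses, change_times
                # bake the image against the stepwise trajectory
                ctx.estimate_motion = False
                if bake:
                    u, _ = run_alpha_loop(bake, u, poses, "bake")
                ctx.estimate_motion = self.estimate_motion
                ctx.interp_w = interp_w
            else:
                fine_override = None
                if bake:
                    ctx.estimate_motion = False
                    u, _ = run_alpha_loop(bake, u, knots, "bake")
                    ctx.estimate_motion = self.estimate_motion
            prev_shape = shape

        n_t = self.data.pattern.n_t
        if fine_override is not None:
            # piecewise-constant representation of the per-line poses:
            # one knot per contiguous run of equal poses
            change = np.r_[True, np.any(np.diff(fine_override, axis=0) != 0, axis=1)]
            idx = np.nonzero(change)[0]
            times = idx / max(n_t - 1, 1)
            traj = MotionTrajectory.from_arrays(times, fine_override[idx], n_t,
                                                interp_mode="piecewise-constant")
        else:
            traj = MotionTrajectory.from_arrays(knot_times, knots, n_t,
                                                interp_mode="piecewise-linear")
        return MotionCorrectionResults(
            model=self,
            image=ImageVolume(u, self.data.spacing),
            knots=knots.copy(),
            knot_times=knot_times.copy(),
            trajectory=traj,
            objective_traces=traces,
            scale_log=scale_log,
            zero_filled=zero_filled_full,
            fine_params_override=fine_override,
        )


@dataclass
class MotionCorrectionResults:
    """Estimates, diagnostics and reporting for a fitted model."""

    model: MotionCorrectionModel
    image: ImageVolume
    knots: np.ndarray
    knot_times: np.ndarray
    trajectory: MotionTrajectory
    objective_traces: list[list[float]]
    scale_log: list[dict]
    zero_filled: ImageVolume | None = None
    fine_params_override: np.ndarray | None = None

    def fine_params(self) -> np.ndarray:
        """Recovered fine trajectory, ``(n_t, 6)`` (tau mm, phi rad).

        Under the stepwise trajectory model this is the per-readout
        pose assignment (exact, including the estimated change lines);
        otherwise the interpolated knot trajectory.
        """
        if self.fine_params_override is not None:
            return self.fine_params_override
        return self.trajectory.fine_params()

    def motion_table(self) -> np.ndarray:
        """Per-line table: t_index, tau (mm), phi (degrees)."""
        p = self.fine_params()
        out = np.zeros((p.shape[0], 7))
        out[:, 0] = np.arange(p.shape[0])
        out[:, 1:4] = p[:, :3]
        out[:, 4:7] = np.rad2deg(p[:, 3:])
        return out

    def evaluate(self, ground_truth: ImageVolume):
        from rigidmoco.metrics import evaluate_quality
        return evaluate_quality(self.image, ground_truth)

    def summary(self) -> str:
        """Human-readable fit report (stages, misfits, motion extent)."""
        lines = ["Rigid-motion correction results",
                 "=" * 46]
        pat = self.model.data.pattern
        lines.append(f"grid {pat.grid_shape}, {pat.n_t} readout lines, "
                     f"mode {self.model.regularizer.mode}")
        lines.append(f"{len(self.scale_log)} continuation stages "
                     f"({len(self.knots)} motion knots)")
        lines.append("-" * 46)
        lines.append(f"{'scale':>6} {'alpha':>7} {'eps':>12} {'misfit':>12}")
        for row in self.scale_log:
            lines.append(f"{'1/' + str(row['factor']):>6} {row['alpha']:>7g} "
                         f"{row['eps']:>12.4e} {row['final_misfit']:>12.4e}")
        lines.append("-" * 46)
        p = self.fine_params()
        tau_span = p[:, :3].max(axis=0) - p[:, :3].min(axis=0)
        phi_span = np.rad2deg(p[:, 3:].max(axis=0) - p[:, 3:].min(axis=0))
        lines.append("recovered motion extent:")
        lines.append(f"  translation span (mm):  "
                     f"{tau_span[0]:.2f}, {tau_span[1]:.2f}, {tau_span[2]:.2f}")
        lines.append(f"  rotation span (deg):    "
                     f"{phi_span[0]:.2f}, {phi_span[1]:.2f}, {phi_span[2]:.2f}")
        return "\n".join(lines)

    def save_trajectory_csv(self, path) -> None:
        """CSV with columns t_index, tau_{x,y,z}_mm, phi_{x,y,z}_deg."""
        table = self.motion_table()
        header = "t_index,tau_x_mm,tau_y_mm,tau_z_mm,phi_x_deg,phi_y_deg,phi_z_deg"
        np.savetxt(path, table, delimiter=",", header=header, comments="",
                   fmt=["%d"] + ["%.6f"] * 6)

    def plot_motion(self, path=None):
        """Per-parameter step plots of the recovered trajectory."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        table = self.motion_table()
        fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
        labels_t = ["tau_x", "tau_y", "tau_z"]
        labels_p = ["phi_x", "phi_y", "phi_z"]
        for j, lab in enumerate(labels_t):
            axes[0].plot(table[:, 0], table[:, 1 + j], label=lab)
        for j, lab in enumerate(labels_p):
            axes[1].plot(table[:, 0], table[:, 4 + j], label=lab)
        axes[0].set_ylabel("translation (mm)")
        axes[1].set_ylabel("rotation (deg)")
        axes[1].set_xlabel("readout line index")
        for ax in axes:
            ax.legend(loc="best", fontsize=8)
            ax.grid(True, alpha=0.3)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=110)
            plt.close(fig)
            return None
        return fig
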
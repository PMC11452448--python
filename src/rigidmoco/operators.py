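"""The rigid-motion k-space forward model, its adjoint, and the data misfit.

A rigidly moved object has spectrum equal to a translational phase ramp
times the rotated spectrum of the still object:

    F_theta u (k) = exp(-i k . tau) * F u (R_phi^{-1} k).

Acquisition samples this perturbed spectrum one Cartesian readout line
per time index t, with pose theta_t frozen within a line.  Because the
rotation acts on the *sample coordinates*, the whole acquisition needs a
single NUFFT evaluation of the image spectrum regardless of how many
poses occur; per-pose work is pure interpolation.

Conventions (declared once, tested via a Parseval identity):
wavevectors are in radians/voxel on the centered grid ``k = 2*pi*q/n``,
``q = -n//2 .. n//2-1``; the forward transform is the unnormalized
Fourier sum; :func:`adjoint` is its exact adjoint, so the zero-filled
inverse reconstruction is ``adjoint(d) / n_vox``.  Translations are
carried in mm and converted to voxels via the image spacing inside the
operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from rigidmoco._nufft import NufftPlan
from rigidmoco.geometry import (ImageVolume, MotionTrajectory, RigidMotion,
                                rotation_matrices)

__all__ = [
    "SamplingPattern",
    "KSpaceData",
    "RigidMotionOperator",
    "kspace_coords",
    "perturbed_fourier",
    "forward",
    "adjoint",
    "misfit",
    "misfit_grad_u",
    "misfit_grad_theta",
    "ROTATION_FD_STEP",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: central finite-difference step (radians) for rotation derivatives
ROTATION_FD_STEP = 1e-4


@dataclass
class SamplingPattern:
    """Per-time-index Cartesian readout lines.

    ``lines`` holds one centered integer phase-encode offset pair per
    readout, ordered by acquisition time; each line sweeps the full
    readout axis.  Offsets live in ``[-n//2, n//2)`` for the respective
    phase-encode axis.
    """

    grid_shape: tuple[int, int, int]
    readout_axis: str = "x"
    lines: np.ndarray = field(default_factory=lambda: np.zeros((1, 2), dtype=np.int32))

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 2 for n in self.grid_shape):
            raise ValueError("grid_shape must be three sizes >= 2")
        if self.readout_axis not in _AXES:
            raise ValueError(f"readout_axis must be one of x, y, z, got {self.readout_axis!r}")
        self.lines = np.asarray(self.lines, dtype=np.int32).reshape(-1, 2)
        lo = np.array([-(n // 2) for n in self.phase_encode_shape])
        hi = np.array([(n - 1) // 2 for n in self.phase_encode_shape])
        if np.any(self.lines < lo) or np.any(self.lines > hi):
            raise ValueError("phase-encode offsets fall outside the Cartesian grid")

    @property
    def readout_index(self) -> int:
        return _AXES[self.readout_axis]

    @property
    def phase_encode_indices(self) -> tuple[int, int]:
        return tuple(i for i in range(3) if i != self.readout_index)  # type: ignore[return-value]

    @property
    def phase_encode_shape(self) -> tuple[int, int]:
        pe = self.phase_encode_indices
        return (self.grid_shape[pe[0]], self.grid_shape[pe[1]])

    @property
    def n_r(self) -> int:
        return self.grid_shape[self.readout_index]

    @property
    def n_t(self) -> int:
        return int(self.lines.shape[0])

    def all_coords(self) -> np.ndarray:
        """All wavevectors as an ``(n_t, n_r, 3)`` array (radians/voxel)."""
        n_ro = self.n_r
        ro = 2.0 * np.pi * (np.arange(n_ro) - n_ro // 2) / n_ro
        pe = self.phase_encode_indices
        pe_shape = self.phase_encode_shape
        coords = np.zeros((self.n_t, n_ro, 3))
        coords[:, :, self.readout_index] = ro[None, :]
        for j, (axis, n) in enumerate(zip(pe, pe_shape)):
            coords[:, :, axis] = (2.0 * np.pi * self.lines[:, j] / n)[:, None]
        return coords

    @classmethod
    def full(cls, grid_shape, readout_axis: str = "x",
             order: str = "low-first") -> "SamplingPattern":
        """Fully sampled pattern, one line per phase-encode location."""
        pat = cls(grid_shape=tuple(grid_shape), readout_axis=readout_axis,
                  lines=np.zeros((1, 2), dtype=np.int32))
        n1, n2 = pat.phase_encode_shape
        q1 = np.arange(n1) - n1 // 2
        q2 = np.arange(n2) - n2 // 2
        lines = np.stack(np.meshgrid(q1, q2, indexing="ij"), axis=-1).reshape(-1, 2)
        if order == "low-first":
            lines = lines[np.lexsort((np.arange(len(lines)), (lines ** 2).sum(axis=1)))]
        pat.lines = lines.astype(np.int32)
        return pat


@dataclass
class KSpaceData:
    """Complex k-space samples, one row per readout line."""

    samples: np.ndarray
    pattern: SamplingPattern
    noise_sigma: float = 0.0
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.shape != (self.pattern.n_t, self.pattern.n_r):
            raise ValueError(
                f"samples shape {self.samples.shape} inconsistent with pattern "
                f"({self.pattern.n_t} lines x {self.pattern.n_r} readout samples)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)


def kspace_coords(pattern: SamplingPattern, t: int) -> np.ndarray:
    """Wavevectors of readout line ``t`` as ``(n_r, 3)`` in radians/voxel."""
    if not 0 <= t < pattern.n_t:
        raise IndexError(f"time index {t} out of range [0, {pattern.n_t})")
    return pattern.all_coords()[t]


def _fine_params(traj, n_t: int | None = None) -> np.ndarray:
    """Normalize a trajectory argument to an ``(n_t, 6)`` parameter array."""
    if isinstance(traj, MotionTrajectory):
        return traj.fine_params()
    if isinstance(traj, RigidMotion):
        return traj.as_vector()[None, :]
    if isinstance(traj, (list, tuple)) and traj and isinstance(traj[0], RigidMotion):
        return np.stack([m.as_vector() for m in traj])
    arr = np.asarray(traj, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[-1] != 6:
        raise ValueError("trajectory parameters must be 6-vectors")
    return arr


class RigidMotionOperator:
    """The acquisition operator ``u -> {S_t F_theta_t u}`` for one pattern.

    Caches the NUFFT plan and the Cartesian line coordinates so repeated
    forward/adjoint/gradient evaluations (the solver's inner loop) only
    pay for FFTs and interpolation.
    """

    def __init__(self, pattern: SamplingPattern, spacing=(1.0, 1.0, 1.0),
                 nufft_width: int = 8):
        self.pattern = pattern
        self.spacing = np.asarray(spacing, dtype=float).reshape(3)
        self.plan = NufftPlan(pattern.grid_shape, width=nufft_width)
        self.base_coords = pattern.all_coords()  # (n_t, n_r, 3)
        self.shape = pattern.grid_shape

    # -- pose geometry ------------------------------------------------------
    def _pose_coords_phase(self, params: np.ndarray, t_sel=None):
        """Rotated sample coordinates and translational phase per line."""
        base = self.base_coords if t_sel is None else self.base_coords[t_sel]
        rots = rotation_matrices(params[:, 3:])  # (n_t, 3, 3), vectorized
        # row-vector k @ R == R^T k == R^{-1} k
        coords = np.einsum("trj,tjk->trk", base, rots)
        tau_vox = params[:, :3] / self.spacing  # mm -> voxels
        phase = np.exp(-1j * np.einsum("trj,tj->tr", base, tau_vox))
        return coords, phase

    # -- forward / adjoint --------------------------------------------------
    def forward(self, u: np.ndarray, params: np.ndarray,
                spectrum: np.ndarray | None = None) -> np.ndarray:
        """Samples ``(n_t, n_r)``; pass a precomputed ``spectrum`` to reuse it."""
        params = _fine_params(params)
        if params.shape[0] != self.pattern.n_t:
            raise ValueError("trajectory length must match the number of readout lines")
        if spectrum is None:
            spectrum = self.plan.spectrum(u)
        coords, phase = self._pose_coords_phase(params)
        vals = self.plan.interpolate(spectrum, coords.reshape(-1, 3))
        return phase * vals.reshape(self.pattern.n_t, self.pattern.n_r)

    def forward_lines(self, spectrum: np.ndarray, params: np.ndarray, t_sel) -> np.ndarray:
        """Forward restricted to the lines in ``t_sel`` (for partial updates)."""
        coords, phase = self._pose_coords_phase(params, t_sel)
        vals = self.plan.interpolate(spectrum, coords.reshape(-1, 3))
        return phase * vals.reshape(len(t_sel), self.pattern.n_r)

    def adjoint(self, samples: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (unnormalized)."""
        params = _fine_params(params)
        samples = np.asarray(samples, dtype=np.complex128)
        if samples.shape != (self.pattern.n_t, self.pattern.n_r):
            raise ValueError("sample array inconsistent with the sampling pattern")
        coords, phase = self._pose_coords_phase(params)
        weighted = (samples * np.conj(phase)).reshape(-1)
        grid = self.plan.spread(coords.reshape(-1, 3), weighted)
        return self.plan.image(grid)

    def zero_filled(self, data: KSpaceData, params: np.ndarray | None = None) -> np.ndarray:
        """Adjoint-inverse reconstruction ``A^H d / n_vox``."""
        if params is None:
            params = np.zeros((self.pattern.n_t, 6))
        return self.adjoint(data.samples, params) / np.prod(self.shape)

    # -- misfit and gradients ----------------------------------------------
    def misfit(self, u: np.ndarray, params: np.ndarray, data: KSpaceData,
               spectrum: np.ndarray | None = None) -> float:
        r = self.forward(u, params, spectrum=spectrum) - data.samples
        return 0.5 * float(np.vdot(r, r).real)

    def misfit_grad_u(self, u: np.ndarray, params: np.ndarray,
                      data: KSpaceData) -> tuple[float, np.ndarray]:
        """Misfit value and its gradient in ``u`` (Wirtinger, ``A^H(Au-d)``)."""
        params = _fine_params(params)
        r = self.forward(u, params) - data.samples
        g = self.adjoint(r, params)
        return 0.5 * float(np.vdot(r, r).real), g

    def misfit_grad_knots(self, u: np.ndarray, knot_params: np.ndarray,
                          interp_w: np.ndarray, data: KSpaceData,
                          spectrum: np.ndarray | None = None,
                          fd_step: float = ROTATION_FD_STEP,
                          return_gn_diag: bool = False,
                          compute_rotations: bool = True):
        """Misfit and its gradient in the coarse knot parameters.

        Translation derivatives are analytic (phase-ramp derivative of
        the shift factor); rotation derivatives use central finite
        differences of the predicted samples per knot angle,
        re-evaluating only the readout lines whose interpolated pose
        the knot influences.  With ``return_gn_diag`` the per-parameter
        Gauss-Newton curvature ``sum |d(sample)/d(param)|^2`` is also
        returned (the solver's step metric).
        """
        if spectrum is None:
            spectrum = self.plan.spectrum(u)
        params = interp_w @ knot_params  # (n_t, 6)
        pred = self.forward(u, params, spectrum=spectrum)
        resid = pred - data.samples
        f0 = 0.5 * float(np.vdot(resid, resid).real)

        n_k = knot_params.shape[0]
        grad = np.zeros((n_k, 6))
        gn = np.zeros((n_k, 6))

        # analytic translation derivatives: d(sample)/d(tau_mm_a)
        #   = w_tj * (-i k_a / spacing_a) * sample
        for a in range(3):
            ka = self.base_coords[:, :, a] / self.spacing[a]
            g_fine = np.sum((np.conj(resid) * (-1j) * ka * pred).real, axis=1)
            grad[:, a] = interp_w.T @ g_fine
            h_fine = np.sum((ka * np.abs(pred)) ** 2, axis=1)
            gn[:, a] = (interp_w ** 2).T @ h_fine

        # sample-level central differences for rotation derivatives; all
        # perturbed coordinate sets are gathered into one NUFFT
        # interpolation call to amortize per-call overhead
        if compute_rotations:
            chunks: list[np.ndarray] = []
            metas: list[tuple[int, int, np.ndarray, int]] = []
            for j in range(n_k):
                t_sel = np.nonzero(interp_w[:, j])[0]
                if t_sel.size == 0:
                    continue
                base_sel = self.base_coords[t_sel]
                w_sel = interp_w[t_sel, j]
                phi_sel = params[t_sel, 3:]
                for a in range(3, 6):
                    for sgn in (+1.0, -1.0):
                        phis = phi_sel.copy()
                        phis[:, a - 3] += sgn * fd_step * w_sel
                        rots = rotation_matrices(phis)
                        coords = np.einsum("trj,tjk->trk", base_sel, rots)
                        chunks.append(coords.reshape(-1, 3))
                    metas.append((j, a, t_sel, base_sel.shape[0]))
            if chunks:
                vals = self.plan.interpolate(spectrum, np.concatenate(chunks))
                tau_vox = params[:, :3] / self.spacing
                pos = 0
                for j, a, t_sel, n_lines in metas:
                    block = n_lines * self.pattern.n_r
                    phase = np.exp(-1j * np.einsum(
                        "trj,tj->tr", self.base_coords[t_sel], tau_vox[t_sel]))
                    pred_p = phase * vals[pos:pos + block].reshape(n_lines, -1)
                    pred_m = phase * vals[pos + block:pos + 2 * block].reshape(n_lines, -1)
                    pos += 2 * block
                    ds = (pred_p - pred_m) / (2.0 * fd_step)
                    r_sel = resid[t_sel]
                    grad[j, a] = float(np.vdot(r_sel, ds).real)
                    gn[j, a] = float(np.vdot(ds, ds).real)
        if return_gn_diag:
            return f0, grad, gn
        return f0, grad


def _volume_and_spacing(u) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(u, ImageVolume):
        return u.data, u.spacing
    return np.asarray(u, dtype=np.complex128), np.ones(3)


def perturbed_fourier(u, theta: RigidMotion, coords: np.ndarray) -> np.ndarray:
    """Spectrum of the rigidly moved ``u`` at arbitrary wavevectors.

    ``coords`` (radians/voxel) must lie in the Nyquist box [-pi, pi];
    rotated coordinates may leave it and are evaluated modulo the
    periodic Fourier sum.
    """
    data, spacing = _volume_and_spacing(u)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if np.any(np.abs(coords) > np.pi + 1e-9):
        raise ValueError("wavevectors must lie within the Nyquist box [-pi, pi]")
    plan = NufftPlan(data.shape)
    rot = theta.rotation()
    tau_vox = theta.tau / spacing
    vals = plan.execute(data, coords @ rot)
    return np.exp(-1j * coords @ tau_vox) * vals


def _operator_for(u, pattern: SamplingPattern) -> RigidMotionOperator:
    _, spacing = _volume_and_spacing(u)
    return RigidMotionOperator(pattern, spacing=spacing)


def forward(u, traj, pattern: SamplingPattern, noise_sigma: float = 0.0) -> KSpaceData:
    """Acquire ``u`` under the trajectory: row t is ``S_t F_theta_t u``."""
    data, spacing = _volume_and_spacing(u)
    params = _fine_params(traj)
    if params.shape[0] == 1 and pattern.n_t > 1:
        params = np.repeat(params, pattern.n_t, axis=0)
    if params.shape[0] != pattern.n_t:
        raise ValueError("trajectory length must equal the number of readout lines")
    op = RigidMotionOperator(pattern, spacing=spacing)
    samples = op.forward(data, params)
    return KSpaceData(samples=samples, pattern=pattern, noise_sigma=noise_sigma,
                      spacing=spacing)


def adjoint(d: KSpaceData, traj) -> ImageVolume:
    """Exact adjoint of :func:`forward` applied to the samples of ``d``."""
    params = _fine_params(traj)
    if params.shape[0] == 1 and d.pattern.n_t > 1:
        params = np.repeat(params, d.pattern.n_t, axis=0)
    op = RigidMotionOperator(d.pattern, spacing=d.spacing)
    return ImageVolume(op.adjoint(d.samples, params), d.spacing)


def misfit(u, traj, d: KSpaceData) -> float:
    """Data misfit ``sum_t 0.5 * ||F_theta_t u - d_t||^2``."""
    data, spacing = _volume_and_spacing(u)
    op = RigidMotionOperator(d.pattern, spacing=spacing)
    return op.misfit(data, _fine_params(traj), d)


def misfit_grad_u(u, traj, d: KSpaceData) -> ImageVolume:
    """Gradient of the misfit in the image, ``A^H (A u - d)``."""
    data, spacing = _volume_and_spacing(u)
    op = RigidMotionOperator(d.pattern, spacing=spacing)
    _, g = op.misfit_grad_u(data, _fine_params(traj), d)
    return ImageVolume(g, spacing)


def misfit_grad_theta(u, traj: MotionTrajectory, d: KSpaceData) -> np.ndarray:
    """Gradient of the misfit in the coarse knot parameters, ``(n_knots, 6)``."""
    from rigidmoco.geometry import interpolation_matrix

    data, spacing = _volume_and_spacing(u)
    op = RigidMotionOperator(d.pattern, spacing=spacing)
    _, g = op.misfit_grad_knots(data, traj.knot_params(), interpolation_matrix(traj), d)
    return g
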
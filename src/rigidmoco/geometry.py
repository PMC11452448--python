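"""Rigid-motion parameterization and image-domain rigid transforms.

A rigid pose is a 6-vector ``theta = (tau, phi)``: three translations in
mm and three rotation angles in radians about the x, y, z axes.  The
image-domain action used throughout the package is *rotate about the
volume center, then translate*,

    (T_theta u)(x) = u(R_phi^{-1}(x - tau)),

which in k-space becomes a phase ramp times the rotated spectrum — the
form the Fourier-domain operators in :mod:`rigidmoco.operators` rely on.
The image-domain resampler here (trilinear, zero outside the field of
view) serves as simulation oracle; the solver itself never resamples
images.

Axis convention: x = left-right, y = posterior-anterior, z =
inferior-superior; the xy plane is axial, xz coronal, yz sagittal.
Rotations follow the right-hand rule and compose as
``R = R_z(phi_z) @ R_y(phi_y) @ R_x(phi_x)`` (x applied first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "RigidMotion",
    "MotionTrajectory",
    "ImageVolume",
    "AffineTransform",
    "rotation_matrix",
    "apply_rigid_transform",
    "invert",
    "interpolate_trajectory",
    "grid_center",
]


def _wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Map angles to the canonical range (-pi, pi]."""
    return -((-np.asarray(phi, dtype=float) + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class RigidMotion:
    """A rigid pose: translation ``tau`` (mm) and rotation ``phi`` (rad).

    Angles are stored in the canonical range (-pi, pi].
    """

    tau: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phi: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float).reshape(3)
        phi = np.asarray(self.phi, dtype=float).reshape(3)
        if not (np.all(np.isfinite(tau)) and np.all(np.isfinite(phi))):
            raise ValueError("rigid-motion parameters must be finite")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "phi", _wrap_angle(phi))

    @classmethod
    def identity(cls) -> "RigidMotion":
        return cls()

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "RigidMotion":
        vec = np.asarray(vec, dtype=float).reshape(6)
        return cls(tau=vec[:3], phi=vec[3:])

    def as_vector(self) -> np.ndarray:
        """Return ``[tau_x, tau_y, tau_z, phi_x, phi_y, phi_z]``."""
        return np.concatenate([self.tau, self.phi])

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.tau == 0.0) and np.all(self.phi == 0.0))

    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.phi)

    def as_affine(self) -> "AffineTransform":
        """The point map ``x -> R_phi x + tau`` of this pose."""
        return AffineTransform(matrix=self.rotation(), translation=self.tau)


@dataclass(frozen=True)
class AffineTransform:
    """A general affine point map ``x -> A x + b`` in physical (mm) coordinates.

    Needed because the inverse of rotate-then-translate is
    translate-then-rotate, which is not expressible as a
    :class:`RigidMotion` with the package's fixed operation order.
    """

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map ``x -> self(other(x))``."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.translation + self.translation)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)


@dataclass
class ImageVolume:
    """A complex 3D image with voxel spacing in mm.

    ``data`` has shape ``(n1, n2, n3)`` along (x, y, z).  The coordinate
    origin used by all operators is the voxel with index ``n // 2`` per
    axis (the center of the symmetric DFT grid).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or data.size == 0:
            raise ValueError("image volume must be a non-empty 3D array")
        if not np.iscomplexobj(data):
            data = data.astype(np.complex128)
        self.data = data
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing.copy())


def grid_center(shape: Sequence[int]) -> np.ndarray:
    """Voxel index of the coordinate origin (center of the DFT grid)."""
    return np.asarray([n // 2 for n in shape], dtype=float)


def rotation_matrix(phi: Sequence[float]) -> np.ndarray:
    """Right-handed rotation ``R_z(phi_z) @ R_y(phi_y) @ R_x(phi_x)``.

    The x-rotation is applied first.  The result is orthonormal with
    determinant +1.
    """
    phi = np.asarray(phi, dtype=float).reshape(3)
    if not np.all(np.isfinite(phi)):
        raise ValueError("rotation angles must be finite")
    return rotation_matrices(phi[None, :])[0]


def rotation_matrices(phis: np.ndarray) -> np.ndarray:
    """Vectorized :func:`rotation_matrix` for an ``(n, 3)`` angle array."""
    phis = np.asarray(phis, dtype=float).reshape(-1, 3)
    cx, sx = np.cos(phis[:, 0]), np.sin(phis[:, 0])
    cy, sy = np.cos(phis[:, 1]), np.sin(phis[:, 1])
    cz, sz = np.cos(phis[:, 2]), np.sin(phis[:, 2])
    r = np.empty((phis.shape[0], 3, 3))
    # rows of R_z R_y R_x written out once
    r[:, 0, 0] = cz * cy
    r[:, 0, 1] = cz * sy * sx - sz * cx
    r[:, 0, 2] = cz * sy * cx + sz * sx
    r[:, 1, 0] = sz * cy
    r[:, 1, 1] = sz * sy * sx + cz * cx
    r[:, 1, 2] = sz * sy * cx - cz * sx
    r[:, 2, 0] = -sy
    r[:, 2, 1] = cy * sx
    r[:, 2, 2] = cy * cx
    return r


def invert(theta: RigidMotion) -> AffineTransform:
    """Exact inverse of the pose's point map: ``x -> R^T x - R^T tau``."""
    r = theta.rotation()
    return AffineTransform(r.T, -r.T @ theta.tau)


def _resample_affine(u: ImageVolume, affine: AffineTransform) -> ImageVolume:
    """Resample ``u`` so that output(x) = u(affine(x)), trilinear, zero fill."""
    shape = u.shape
    center = grid_center(shape)
    idx = np.indices(shape, dtype=float)  # (3, n1, n2, n3)
    pts = idx.reshape(3, -1).T  # voxel indices
    phys = (pts - center) * u.spacing
    src = affine.apply_to_points(phys) / u.spacing + center
    coords = src.T.reshape(3, *shape)
    re = map_coordinates(u.data.real, coords, order=1, mode="constant", cval=0.0)
    im = map_coordinates(u.data.imag, coords, order=1, mode="constant", cval=0.0)
    return ImageVolume(re + 1j * im, u.spacing.copy())


def apply_rigid_transform(u: ImageVolume, theta: RigidMotion) -> ImageVolume:
    """Move ``u`` rigidly: output(x) = u(R_phi^{-1}(x - tau)).

    Rotation is about the volume center; resampling is trilinear with
    zeros outside the field of view.  This is the image-domain
    counterpart of the k-space perturbed Fourier operator and is used as
    its oracle and for simulation.
    """
    if theta.is_identity:
        return u.copy()
    # the resampler evaluates u at the *inverse* point map of the pose
    return _resample_affine(u, invert(theta))


def apply_affine_transform(u: ImageVolume, affine: AffineTransform) -> ImageVolume:
    """Resample ``u`` under an arbitrary affine point map ``y = affine(x)``."""
    return _resample_affine(u, affine.inverse())


@dataclass
class MotionTrajectory:
    """Coarse motion knots plus a time-interpolation rule.

    ``knots`` is an ordered list of ``(time_fraction, RigidMotion)`` with
    strictly increasing time fractions in [0, 1]; ``n_t`` is the number
    of fine time steps (one per readout line).
    """

    knots: list[tuple[float, RigidMotion]]
    n_t: int
    interp_mode: Literal["piecewise-constant", "piecewise-linear"] = "piecewise-linear"

    def __post_init__(self) -> None:
        if len(self.knots) == 0:
            raise ValueError("trajectory needs at least one knot")
        times = np.asarray([t for t, _ in self.knots], dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if self.n_t < 1:
            raise ValueError("n_t must be positive")
        if self.interp_mode not in ("piecewise-constant", "piecewise-linear"):
            raise ValueError(f"unknown interpolation mode {self.interp_mode!r}")

    @classmethod
    def from_arrays(cls, times: Sequence[float], params: np.ndarray, n_t: int,
                    interp_mode: str = "piecewise-linear") -> "MotionTrajectory":
        params = np.asarray(params, dtype=float).reshape(len(times), 6)
        knots = [(float(t), RigidMotion.from_vector(p)) for t, p in zip(times, params)]
        return cls(knots=knots, n_t=n_t, interp_mode=interp_mode)  # type: ignore[arg-type]

    def knot_times(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.knots], dtype=float)

    def knot_params(self) -> np.ndarray:
        return np.stack([m.as_vector() for _, m in self.knots])

    def fine_times(self) -> np.ndarray:
        if self.n_t == 1:
            return np.zeros(1)
        return np.arange(self.n_t) / (self.n_t - 1)

    def materialize(self) -> list[RigidMotion]:
        return interpolate_trajectory(self)

    def fine_params(self) -> np.ndarray:
        """The fine trajectory as an ``(n_t, 6)`` array."""
        return interpolation_matrix(self) @ self.knot_params()

    def __iter__(self) -> Iterator[RigidMotion]:
        return iter(self.materialize())


def interp_weights(knot_times: np.ndarray, fine_times: np.ndarray,
                   mode: str = "piecewise-linear") -> np.ndarray:
    """Time-interpolation operator mapping knot values to fine times.

    Returns the ``(len(fine_times), len(knot_times))`` matrix whose row
    t gives the weights with which the knot parameter vectors combine
    into the pose at time t.  Piecewise-constant mode holds each knot's
    value until the next knot; piecewise-linear interpolates each
    parameter independently.  Times before the first / after the last
    knot clamp to the end knots.
    """
    times = np.asarray(knot_times, dtype=float)
    fine = np.asarray(fine_times, dtype=float)
    n_k = times.size
    n_f = fine.size
    w = np.zeros((n_f, n_k))
    if mode == "piecewise-constant":
        idx = np.searchsorted(times, fine, side="right") - 1
        idx = np.clip(idx, 0, n_k - 1)
        w[np.arange(n_f), idx] = 1.0
    elif mode == "piecewise-linear":
        if n_k == 1:
            w[:, 0] = 1.0
        else:
            j = np.clip(np.searchsorted(times, fine, side="right"), 1, n_k - 1)
            t0, t1 = times[j - 1], times[j]
            lam = np.clip((fine - t0) / (t1 - t0), 0.0, 1.0)
            w[np.arange(n_f), j - 1] = 1.0 - lam
            w[np.arange(n_f), j] = lam
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return w


def interpolation_matrix(traj: MotionTrajectory) -> np.ndarray:
    """The ``(n_t, n_knots)`` time-interpolation operator of a trajectory."""
    return interp_weights(traj.knot_times(), traj.fine_times(), traj.interp_mode)


def interpolate_trajectory(traj: MotionTrajectory) -> list[RigidMotion]:
    """Materialize the fine trajectory as a length-``n_t`` list of poses."""
    params = interpolation_matrix(traj) @ traj.knot_params()
    return [RigidMotion.from_vector(p) for p in params]
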
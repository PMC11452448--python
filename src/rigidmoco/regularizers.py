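"""Structure-guided and plain total variation, TV-ball projection, and
the temporal motion penalty.

The structural prior couples two contrasts of the same anatomy.  From a
motion-free reference ``v`` one builds a unit-capped directional field

    xi|_x = grad v|_x / sqrt(||grad v|_x||^2 + eta^2),

and penalizes only the component of ``grad u`` orthogonal to it:

    g_u(u) = sum_x || (I - xi xi^H) grad u|_x ||.

With ``xi = 0`` this reduces to plain isotropic TV.  Regularization is
imposed as a hard constraint ``g_u(u) <= eps`` by Euclidean projection
onto the corresponding set, computed with an accelerated dual
projected-gradient method.

Gradients use forward differences with replicate-edge (Neumann)
boundaries; :func:`divergence` is the exact negative adjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.ndimage import zoom as _ndzoom

from rigidmoco.geometry import ImageVolume

__all__ = [
    "StructureGuide",
    "RegularizerSpec",
    "discrete_gradient",
    "divergence",
    "build_guide",
    "guided_tv",
    "plain_tv",
    "project_tv_ball",
    "motion_penalty",
    "motion_penalty_prox",
]


def _as_array(u) -> np.ndarray:
    return u.data if isinstance(u, ImageVolume) else np.asarray(u)


def discrete_gradient(u) -> np.ndarray:
    """Forward-difference gradient, shape ``(3, n1, n2, n3)``, Neumann edges."""
    a = _as_array(u)
    g = np.zeros((3,) + a.shape, dtype=a.dtype)
    g[0, :-1] = a[1:] - a[:-1]
    g[1, :, :-1] = a[:, 1:] - a[:, :-1]
    g[2, :, :, :-1] = a[:, :, 1:] - a[:, :, :-1]
    return g


def divergence(w: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`discrete_gradient`: ``<grad u, w> = -<u, div w>``."""
    w = np.asarray(w)
    out = np.zeros(w.shape[1:], dtype=w.dtype)
    out[:-1] += w[0, :-1]
    out[1:] -= w[0, :-1]
    out[:, :-1] += w[1, :, :-1]
    out[:, 1:] -= w[1, :, :-1]
    out[:, :, :-1] += w[2, :, :, :-1]
    out[:, :, 1:] -= w[2, :, :, :-1]
    return out


@dataclass
class StructureGuide:
    """Directional field ``xi`` (one complex 3-vector per voxel) and its ``eta``."""

    xi: np.ndarray  # (3, n1, n2, n3) complex
    eta: float
    source_shape: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi)
        if self.xi.ndim != 4 or self.xi.shape[0] != 3:
            raise ValueError("guide field must have shape (3, n1, n2, n3)")
        norms = np.sqrt(np.sum(np.abs(self.xi) ** 2, axis=0))
        if np.any(norms >= 1.0):
            raise ValueError("guide vectors must have norm < 1 (eta > 0 guarantees this)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.xi.shape[1:]  # type: ignore[return-value]

    def project(self, w: np.ndarray) -> np.ndarray:
        """Apply ``Pi = I - xi xi^H`` voxelwise to a gradient field ``w``."""
        inner = np.sum(np.conj(self.xi) * w, axis=0)
        return w - self.xi * inner[None]


@dataclass
class RegularizerSpec:
    """Image-regularizer configuration: flavor, constraint level, schedule."""

    mode: str = "guided_tv"  # "guided_tv" | "plain_tv"
    epsilon: float = 0.0
    alpha_schedule: tuple[float, ...] = (0.01, 0.1, 0.5, 0.8)
    mu: float = 0.0
    eta_rel: float = 0.01  # eta as a fraction of max ||grad v||

    def __post_init__(self) -> None:
        if self.mode not in ("guided_tv", "plain_tv"):
            raise ValueError(f"unknown regularizer mode {self.mode!r}")
        alphas = tuple(float(a) for a in self.alpha_schedule)
        if any(not 0 < a <= 1 for a in alphas) or any(
                b <= a for a, b in zip(alphas, alphas[1:])):
            raise ValueError("alpha schedule must be strictly increasing within (0, 1]")
        self.alpha_schedule = alphas
        if self.epsilon < 0 or self.mu < 0:
            raise ValueError("epsilon and mu must be nonnegative")


def build_guide(v, eta: float | None = None, target_shape=None,
                use_magnitude: bool = True, eta_rel: float = 0.01) -> StructureGuide:
    """Build the directional field from a motion-free reference volume.

    ``v`` is resampled (trilinear) to ``target_shape`` if the shapes
    differ; no registration is performed — the solver's motion estimate
    absorbs any rigid misalignment.  When ``eta`` is not given it is set
    to ``eta_rel`` times the maximum gradient magnitude of the
    (resampled) reference, making the guide contrast-invariant.
    """
    a = _as_array(v)
    a = np.abs(a) if use_magnitude else a
    if target_shape is not None and tuple(target_shape) != a.shape:
        factors = [t / s for t, s in zip(target_shape, a.shape)]
        if np.iscomplexobj(a):
            a = _ndzoom(a.real, factors, order=1) + 1j * _ndzoom(a.imag, factors, order=1)
        else:
            a = _ndzoom(a, factors, order=1)
        if a.shape != tuple(target_shape):  # guard against rounding
            raise ValueError("reference resampling produced a mismatched grid")
    g = discrete_gradient(a)
    gnorm = np.sqrt(np.sum(np.abs(g) ** 2, axis=0))
    if eta is None:
        eta = eta_rel * float(gnorm.max())
        if eta == 0.0:
            eta = 1.0  # constant reference: guide degenerates to zero field
    if eta <= 0:
        raise ValueError("eta must be positive")
    xi = g / np.sqrt(gnorm**2 + eta**2)[None]
    return StructureGuide(xi=xi, eta=float(eta), source_shape=a.shape)


def plain_tv(u) -> float:
    """Isotropic total variation ``sum_x ||grad u|_x||``."""
    g = discrete_gradient(u)
    return float(np.sum(np.sqrt(np.sum(np.abs(g) ** 2, axis=0))))


def guided_tv(u, guide: StructureGuide) -> float:
    """Structure-guided TV ``sum_x ||Pi|_x grad u|_x||``."""
    a = _as_array(u)
    if a.shape != guide.shape:
        raise ValueError(f"image shape {a.shape} does not match guide {guide.shape}")
    w = guide.project(discrete_gradient(a))
    return float(np.sum(np.sqrt(np.sum(np.abs(w) ** 2, axis=0))))


def tv_value(u, guide: StructureGuide | None = None) -> float:
    """Guided TV when a guide is given, else plain TV."""
    return plain_tv(u) if guide is None else guided_tv(u, guide)


def _field_norms(p: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(np.abs(p) ** 2, axis=0))


def _project_l1_ball(x: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of a nonnegative vector onto the l1 ball (sorting)."""
    if x.sum() <= radius:
        return x
    s = np.sort(x)[::-1]
    css = np.cumsum(s)
    idx = np.arange(1, x.size + 1)
    rho = np.nonzero(s - (css - radius) / idx > 0)[0][-1]
    lam = (css[rho] - radius) / (rho + 1.0)
    return np.maximum(x - lam, 0.0)


def _project_l21_ball(p: np.ndarray, radius: float) -> np.ndarray:
    """Projection of a vector field onto ``{p : sum_x ||p_x|| <= radius}``."""
    norms = _field_norms(p)
    total = norms.sum()
    if total <= radius:
        return p
    new_norms = _project_l1_ball(norms.ravel(), radius).reshape(norms.shape)
    scale = np.where(norms > 0, new_norms / np.maximum(norms, 1e-300), 0.0)
    return p * scale[None]


def project_tv_ball(u, epsilon: float, guide: StructureGuide | None = None,
                    max_iter: int = 500, tol: float = 1e-3,
                    p0: np.ndarray | None = None):
    """Euclidean projection of ``u`` onto ``{w : g(w) <= epsilon}``.

    ``g`` is guided TV when a ``guide`` is passed, plain TV otherwise.
    Solved by FISTA on the dual problem

        min_p  0.5 * ||K^H p - u||^2 + eps * ||p||_{2,inf},

    whose prox is a projection onto the (2,1)-norm ball; the primal
    iterate is ``w = u - K^H p``.  A final homogeneity rescale around
    the image mean guarantees ``g(result) <= eps * (1 + tol)``.

    Returns ``(w, p)``; feed ``p`` back as ``p0`` to warm-start the next
    projection of a nearby image.
    """
    a = _as_array(u)
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if guide is not None and a.shape != guide.shape:
        raise ValueError("image and guide shapes differ")

    def K(x):
        g = discrete_gradient(x)
        return guide.project(g) if guide is not None else g

    def KH(p):
        q = guide.project(p) if guide is not None else p  # Pi is Hermitian idempotent
        return -divergence(q)

    g0 = float(np.sum(_field_norms(K(a))))
    if g0 <= epsilon:
        return (u.copy() if hasattr(u, "copy") else np.array(a)), None
    if epsilon == 0.0 and guide is None:
        # L2-closest zero-TV image is the constant mean
        w = np.full_like(a, a.mean())
        return (ImageVolume(w, u.spacing) if isinstance(u, ImageVolume) else w), None

    lip = 12.0  # ||K||^2 <= 12 for the 3D forward-difference gradient; Pi non-expansive
    p_dtype = np.complex128 if np.iscomplexobj(a) else np.float64
    p = np.zeros((3,) + a.shape, dtype=p_dtype) if p0 is None else p0.astype(p_dtype)
    y = p.copy()
    t_acc = 1.0
    w = a - KH(p)
    w_norm0 = max(float(np.linalg.norm(a)), 1e-30)
    for _ in range(max_iter):
        grad = -K(a - KH(y))
        q = y - grad / lip
        p_new = q - _project_l21_ball(q, epsilon / lip)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        y = p_new + ((t_acc - 1.0) / t_new) * (p_new - p)
        p, t_acc = p_new, t_new
        w_new = a - KH(p)
        stalled = float(np.linalg.norm(w_new - w)) <= 0.1 * tol * w_norm0
        w = w_new
        if stalled:
            break
    gv = float(np.sum(_field_norms(K(w))))
    if gv > epsilon * (1.0 + tol):
        if gv > epsilon * (1.0 + 10.0 * tol):
            warnings.warn("TV-ball projection: feasible rescale after incomplete "
                          "dual convergence", RuntimeWarning)
        c = a.mean()
        w = c + (epsilon / gv) * (w - c)
    if isinstance(u, ImageVolume):
        return ImageVolume(w, u.spacing), p
    return w, p


def motion_penalty(theta_seq: np.ndarray) -> float:
    """Temporal smoothness penalty ``sum_t 0.5 * ||theta_{t+1} - theta_t||^2``."""
    th = np.asarray(theta_seq, dtype=float)
    if th.ndim == 1:
        th = th[:, None]
    d = np.diff(th, axis=0)
    return 0.5 * float(np.sum(d * d))


def motion_penalty_prox(theta_seq: np.ndarray, step: float) -> np.ndarray:
    """Prox of ``step * motion_penalty``: solves ``(I + step L) x = theta``.

    ``L`` is the free-boundary second-difference operator; the
    symmetric tridiagonal system is solved exactly per parameter.
    """
    th = np.asarray(theta_seq, dtype=float)
    squeeze = th.ndim == 1
    if squeeze:
        th = th[:, None]
    n = th.shape[0]
    if n == 1 or step == 0.0:
        out = th.copy()
        return out[:, 0] if squeeze else out
    diag = np.full(n, 1.0 + 2.0 * step)
    diag[0] = diag[-1] = 1.0 + step
    ab = np.zeros((2, n))
    ab[0, 1:] = -step
    ab[1] = diag
    out = solveh_banded(ab, th)
    return out[:, 0] if squeeze else out
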
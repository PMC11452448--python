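"""Synthetic phantoms, motion trajectories, sampling patterns and
acquisitions for end-to-end experiments without scanner data.

The generators emulate a multi-contrast brain session: two piecewise-
smooth ellipsoid phantoms that share anatomy (identical region
boundaries) but have independent per-region intensities, a stepwise
pose trajectory (the volunteer repositions a prescribed number of times
and holds still in between), variable-density randomized or regular
2x2-accelerated Cartesian phase-encode patterns with a fully sampled
center block, complex Gaussian noise, and k-space low-pass smoothing of
the reference to emulate a lower-resolution prior.

Everything is deterministic under its ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from rigidmoco.geometry import (ImageVolume, MotionTrajectory, RigidMotion,
                                apply_rigid_transform, rotation_matrix)
from rigidmoco.operators import KSpaceData, RigidMotionOperator, SamplingPattern

__all__ = [
    "PhantomSpec",
    "make_phantom_pair",
    "make_stepwise_trajectory",
    "make_sampling_pattern",
    "simulate_acquisition",
    "smooth_reference",
    "CENTER_BLOCK_FRACTION",
]

#: fully sampled central block radius, as a fraction of the grid extent
CENTER_BLOCK_FRACTION = 0.08


@dataclass
class PhantomSpec:
    """Recipe for an anatomy-sharing multi-contrast phantom pair."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_blobs: int = 8
    seed: int = 0
    misregistration: RigidMotion = field(default_factory=RigidMotion.identity)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    smooth_sigma: float = 0.8      # voxels; softens region edges (band-limits)
    modulation: float = 0.1        # amplitude of the smooth intensity modulation
    phase_amplitude: float = 0.5   # radians; smooth phase of the target contrast

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if any(n < 16 for n in self.shape):
            raise ValueError("phantom grids need at least 16 voxels per axis")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be nonnegative")


def _ellipsoid_mask(shape, center, semiaxes, rot) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    rel = np.stack([idx[a] - center[a] for a in range(3)])  # (3, ...)
    local = np.einsum("ji,i...->j...", rot.T, rel)
    q = sum((local[a] / semiaxes[a]) ** 2 for a in range(3))
    return q <= 1.0


def _smooth_field(shape, rng, sigma_frac=0.15) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sm = gaussian_filter(noise, sigma=[sigma_frac * n for n in shape])
    sm -= sm.mean()
    peak = np.abs(sm).max()
    return sm / peak if peak > 0 else sm


def make_phantom_pair(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume]:
    """Target contrast ``u_true`` (complex) and reference contrast ``v_ref``.

    Both contrasts share an outer head ellipsoid and ``n_blobs`` inner
    ellipsoidal regions — identical boundaries, independent intensities —
    with a mild smooth modulation per contrast.  The target receives a
    smooth phase map; the reference is magnitude-valued and optionally
    rigidly misregistered.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    n = np.asarray(shape, dtype=float)
    center = np.asarray([s // 2 for s in shape], dtype=float)

    if spec.n_blobs == 0:
        # degenerate case: two constant volumes
        ones = np.ones(shape)
        return (ImageVolume(ones.astype(np.complex128), np.asarray(spec.spacing)),
                ImageVolume(ones.astype(np.complex128), np.asarray(spec.spacing)))

    labels = np.zeros(shape, dtype=np.int32)
    head = _ellipsoid_mask(shape, center, 0.42 * n, np.eye(3))
    labels[head] = 1
    for b in range(spec.n_blobs):
        c = center + rng.uniform(-0.18, 0.18, 3) * n
        ax = rng.uniform(0.06, 0.18, 3) * n
        ang = rng.uniform(-np.pi, np.pi, 3)
        mask = _ellipsoid_mask(shape, c, ax, rotation_matrix(ang))
        labels[mask & (labels >= 1)] = b + 2

    n_regions = spec.n_blobs + 2
    intens_u = np.concatenate([[0.0], rng.uniform(0.35, 1.0, n_regions - 1)])
    intens_v = np.concatenate([[0.0], rng.uniform(0.35, 1.0, n_regions - 1)])
    u_mag = intens_u[labels]
    v_mag = intens_v[labels]

    mod_u = 1.0 + spec.modulation * _smooth_field(shape, rng)
    mod_v = 1.0 + spec.modulation * _smooth_field(shape, rng)
    u_mag = u_mag * mod_u
    v_mag = v_mag * mod_v
    if spec.smooth_sigma > 0:
        u_mag = gaussian_filter(u_mag, spec.smooth_sigma)
        v_mag = gaussian_filter(v_mag, spec.smooth_sigma)

    phase = spec.phase_amplitude * _smooth_field(shape, rng, sigma_frac=0.25)
    u = ImageVolume(u_mag * np.exp(1j * phase), np.asarray(spec.spacing))
    v = ImageVolume(v_mag.astype(np.complex128), np.asarray(spec.spacing))
    if not spec.misregistration.is_identity:
        v = apply_rigid_transform(v, spec.misregistration)
    return u, v


def make_stepwise_trajectory(n_t: int, n_moves: int, max_translation: float,
                             max_rotation: float, seed: int = 0,
                             pose_mode: str = "walk") -> MotionTrajectory:
    """Piecewise-constant trajectory with ``n_moves + 1`` poses.

    Pose changes occur at uniformly spaced change points; the first pose
    is the identity (the patient starts aligned).  Translations are in
    mm (= voxels at unit spacing); rotations bounded in degrees.

    ``pose_mode`` selects the repositioning statistics:

    * ``"walk"`` — each move adds a delta to the previous pose whose
      components have magnitude uniform in ``[0.3, 1.0]`` times the
      bound, with random sign (deliberate repositioning rather than
      micro-motion; the head wanders).
    * ``"jump"`` — every held pose sits at a fixed displacement from
      the start (component magnitude ``0.75`` times the bound, random
      signs), so poses are distinct but comparably far from the
      reference position.  Corruption then grows reproducibly with the
      number of moves, which makes this the mode of choice for
      motion-complexity comparisons.
    """
    if n_moves < 0 or max_translation < 0 or max_rotation < 0:
        raise ValueError("n_moves and motion bounds must be nonnegative")
    if n_moves >= n_t:
        raise ValueError("cannot fit more pose changes than readout lines")
    if pose_mode not in ("walk", "jump"):
        raise ValueError(f"unknown pose_mode {pose_mode!r}")
    rng = np.random.default_rng(seed)
    bounds = np.concatenate([np.full(3, max_translation),
                             np.full(3, np.deg2rad(max_rotation))])
    poses = [np.zeros(6)]
    for _ in range(n_moves):
        sgn = rng.choice([-1.0, 1.0], 6)
        if pose_mode == "walk":
            delta = rng.uniform(0.3, 1.0, 6) * sgn * bounds
            poses.append(poses[-1] + delta)
        else:
            poses.append(0.75 * sgn * bounds)
    times = [0.0] + [(i + 1) / (n_moves + 1) for i in range(n_moves)]
    knots = [(t, RigidMotion.from_vector(p)) for t, p in zip(times, poses)]
    return MotionTrajectory(knots=knots, n_t=n_t, interp_mode="piecewise-constant")


def make_sampling_pattern(shape, mode: str = "randomized", acceleration: float = 1.0,
                          seed: int = 0, readout_axis: str = "x",
                          order: str | None = None) -> SamplingPattern:
    """Cartesian phase-encode pattern with a fully sampled center block.

    ``randomized``: lines drawn without replacement from a centered
    Gaussian density over the phase-encode plane; ``regular``: every
    second line along both phase-encode axes (2x2 acceleration).

    Line order in time defaults to a seeded pseudo-random shuffle for
    randomized patterns (emulating clinical pseudo-random fills, and
    spreading every pose over all frequency bands) and to
    low-frequency-first for regular patterns; pass ``order`` explicitly
    ("low-first" or "shuffle") to override.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    if mode not in ("randomized", "regular"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    if order is None:
        order = "shuffle" if mode == "randomized" else "low-first"
    pat = SamplingPattern(grid_shape=tuple(shape), readout_axis=readout_axis,
                          lines=np.zeros((1, 2), dtype=np.int32))
    n1, n2 = pat.phase_encode_shape
    q1 = np.arange(n1) - n1 // 2
    q2 = np.arange(n2) - n2 // 2
    qq1, qq2 = np.meshgrid(q1, q2, indexing="ij")
    allq = np.stack([qq1.ravel(), qq2.ravel()], axis=1)
    r1 = max(1, round(CENTER_BLOCK_FRACTION * n1))
    r2 = max(1, round(CENTER_BLOCK_FRACTION * n2))
    in_center = ((allq[:, 0] / r1) ** 2 + (allq[:, 1] / r2) ** 2) <= 1.0

    rng = np.random.default_rng(seed)
    if mode == "regular":
        keep = ((allq[:, 0] % 2 == 0) & (allq[:, 1] % 2 == 0)) | in_center
        lines = allq[keep]
    else:
        n_target = int(round(allq.shape[0] / acceleration))
        center_lines = allq[in_center]
        if n_target < center_lines.shape[0]:
            raise ValueError("acceleration too high to keep the fully sampled center")
        rest = allq[~in_center]
        n_draw = n_target - center_lines.shape[0]
        sig1, sig2 = n1 / 4.0, n2 / 4.0
        dens = np.exp(-0.5 * ((rest[:, 0] / sig1) ** 2 + (rest[:, 1] / sig2) ** 2))
        dens /= dens.sum()
        idx = rng.choice(rest.shape[0], size=n_draw, replace=False, p=dens)
        lines = np.concatenate([center_lines, rest[np.sort(idx)]], axis=0)

    if order == "low-first":
        key = (lines[:, 0] / n1) ** 2 + (lines[:, 1] / n2) ** 2
        lines = lines[np.lexsort((np.arange(len(lines)), key))]
    elif order == "shuffle":
        lines = lines[rng.permutation(len(lines))]
    else:
        raise ValueError(f"unknown line order {order!r}")
    pat.lines = lines.astype(np.int32)
    return pat


def simulate_acquisition(u_true: ImageVolume, traj, pattern: SamplingPattern,
                         noise_sigma: float | None = None, seed: int = 0) -> KSpaceData:
    """Acquire ``u_true`` under the trajectory and add complex Gaussian noise.

    ``noise_sigma`` is the per-sample standard deviation (split equally
    between real and imaginary parts); when ``None`` it defaults to 1%
    of the RMS magnitude of the clean samples, which puts the
    zero-filled image SNR around 30 dB — typical of clinical scans.
    """
    op = RigidMotionOperator(pattern, spacing=u_true.spacing)
    params = traj.fine_params() if isinstance(traj, MotionTrajectory) else np.asarray(traj)
    if params.shape[0] != pattern.n_t:
        raise ValueError("trajectory length must match the sampling pattern")
    clean = op.forward(u_true.data, params)
    if noise_sigma is None:
        noise_sigma = 0.01 * float(np.sqrt(np.mean(np.abs(clean) ** 2)))
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = (rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape))
    samples = clean + noise_sigma / np.sqrt(2.0) * noise
    return KSpaceData(samples=samples, pattern=pattern, noise_sigma=float(noise_sigma),
                      spacing=u_true.spacing)


def smooth_reference(v: ImageVolume, level: int) -> ImageVolume:
    """Low-pass the reference: cutoff f_Nyquist (level 0), /4 (1), /8 (2).

    A hard box filter in k-space, per axis; level 0 returns the volume
    unchanged.
    """
    if level not in (0, 1, 2):
        raise ValueError("smoothing level must be 0, 1 or 2")
    if level == 0:
        return v.copy()
    frac = {1: 0.25, 2: 0.125}[level]
    spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(v.data)))
    mask = np.ones(v.shape, dtype=bool)
    for ax, n in enumerate(v.shape):
        q = np.arange(n) - n // 2
        cutoff = frac * (n / 2.0)
        keep = np.abs(q) <= cutoff
        sl = [None, None, None]
        sl[ax] = slice(None)
        mask &= keep[tuple(sl)]
    out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec * mask)))
    return ImageVolume(out, v.spacing.copy())
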
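"""Perturbed-Fourier forward model, adjoint, and misfit gradients."""

import numpy as np
import pytest
import scipy.fft as sfft

from rigidmoco.geometry import ImageVolume, MotionTrajectory, RigidMotion, interp_weights
from rigidmoco.operators import (KSpaceData, RigidMotionOperator, SamplingPattern,
                                 adjoint, forward, kspace_coords, misfit,
                                 misfit_grad_theta, misfit_grad_u,
                                 perturbed_fourier)


class TestSamplingPattern:
    def test_center_line_coordinates(self):
        pat = SamplingPattern((8, 8, 8), readout_axis="x",
                              lines=np.zeros((1, 2), dtype=np.int32))
        coords = kspace_coords(pat, 0)
        assert np.allclose(coords[:, 1:], 0.0)
        assert np.allclose(coords[:, 0], 2 * np.pi * (np.arange(8) - 4) / 8)

    def test_full_pattern_covers_the_dft_grid_once(self):
        pat = SamplingPattern.full((8, 8, 8))
        coords = pat.all_coords().reshape(-1, 3)
        qs = np.round(coords * 8 / (2 * np.pi)).astype(int)
        seen = {tuple(q) for q in qs}
        assert len(seen) == 8 ** 3
        assert pat.n_t == 64

    def test_duplicate_lines_give_identical_coordinates(self):
        pat = SamplingPattern((8, 8, 8), lines=np.array([[1, -2], [1, -2]], np.int32))
        assert np.array_equal(kspace_coords(pat, 0), kspace_coords(pat, 1))

    def test_time_index_out_of_range(self):
        pat = SamplingPattern.full((8, 8, 8))
        with pytest.raises(IndexError):
            kspace_coords(pat, pat.n_t)

    def test_offsets_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            SamplingPattern((8, 8, 8), lines=np.array([[5, 0]], np.int32))


class TestPerturbedFourier:
    def test_zero_motion_equals_dft(self, random_volume, full_pattern):
        d = forward(random_volume, np.zeros(6), full_pattern)
        spec = sfft.fftshift(sfft.fftn(sfft.ifftshift(random_volume.data)))
        pat = full_pattern
        n = pat.grid_shape
        pe = pat.phase_encode_indices
        errs = []
        for t in range(0, pat.n_t, 37):
            q1, q2 = pat.lines[t]
            idx = [0, 0, 0]
            idx[pe[0]], idx[pe[1]] = q1 + n[pe[0]] // 2, q2 + n[pe[1]] // 2
            for r in range(pat.n_r):
                idx[pat.readout_index] = r
                errs.append(abs(d.samples[t, r] - spec[tuple(idx)]))
        assert max(errs) / np.abs(spec).max() < 1e-6

    def test_translation_is_a_phase_ramp(self, random_volume, full_pattern):
        tau = np.array([1.5, -2.0, 0.7])
        d0 = forward(random_volume, np.zeros(6), full_pattern)
        d1 = forward(random_volume, RigidMotion(tau=tau).as_vector(), full_pattern)
        coords = full_pattern.all_coords()
        phase = np.exp(-1j * np.einsum("trj,j->tr", coords, tau))
        rel = (np.linalg.norm(d1.samples - phase * d0.samples)
               / np.linalg.norm(d0.samples))
        assert rel < 1e-6

    def test_rotation_preserves_spectrum_of_spherical_object(self, gaussian_blob):
        pat = SamplingPattern.full(gaussian_blob.shape)
        d0 = forward(gaussian_blob, np.zeros(6), pat)
        dr = forward(gaussian_blob,
                     RigidMotion(phi=[0.3, -0.2, 0.5]).as_vector(), pat)
        rel = (np.linalg.norm(np.abs(dr.samples) - np.abs(d0.samples))
               / np.linalg.norm(np.abs(d0.samples)))
        assert rel < 1e-4

    def test_matches_image_domain_transform(self, gaussian_blob):
        # the image-domain resampler is the independent oracle for the
        # k-space formulation
        from rigidmoco.geometry import apply_rigid_transform
        theta = RigidMotion(tau=[1.0, -0.5, 0.8], phi=[0.08, 0.12, -0.1])
        pat = SamplingPattern.full(gaussian_blob.shape)
        via_kspace = forward(gaussian_blob, theta.as_vector(), pat)
        moved = apply_rigid_transform(gaussian_blob, theta)
        via_image = forward(moved, np.zeros(6), pat)
        rel = (np.linalg.norm(via_kspace.samples - via_image.samples)
               / np.linalg.norm(via_image.samples))
        assert rel < 0.05  # limited by trilinear interpolation of the oracle

    def test_out_of_nyquist_coords_rejected(self, random_volume):
        with pytest.raises(ValueError):
            perturbed_fourier(random_volume, RigidMotion.identity(),
                              np.array([[3.5, 0.0, 0.0]]))


class TestForwardAdjoint:
    def test_zero_image_gives_zero_samples(self, full_pattern):
        u = ImageVolume(np.zeros((16, 16, 16), dtype=complex))
        d = forward(u, np.zeros(6), full_pattern)
        assert np.all(d.samples == 0)

    def test_stepwise_trajectory_matches_per_line_evaluation(self, random_volume):
        pat = SamplingPattern.full((16, 16, 16))
        rng = np.random.default_rng(5)
        pose2 = rng.uniform(-0.3, 0.3, 6)
        params = np.zeros((pat.n_t, 6))
        params[pat.n_t // 2:] = pose2
        d = forward(random_volume, params, pat)
        # naive oracle: one perturbed-Fourier call per line
        for t in (0, pat.n_t // 2, pat.n_t - 1):
            ref = perturbed_fourier(random_volume,
                                    RigidMotion.from_vector(params[t]),
                                    kspace_coords(pat, t))
            assert np.linalg.norm(d.samples[t] - ref) / np.linalg.norm(ref) < 1e-8

    def test_adjoint_identity_random_motions(self, rng):
        shape = (16, 16, 16)
        pat = SamplingPattern.full(shape)
        op = RigidMotionOperator(pat)
        for _ in range(20):
            u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            d = (rng.standard_normal((pat.n_t, pat.n_r))
                 + 1j * rng.standard_normal((pat.n_t, pat.n_r)))
            params = rng.uniform(-0.3, 0.3, (pat.n_t, 6))
            f = op.forward(u, params)
            a = op.adjoint(d, params)
            err = abs(np.vdot(f, d) - np.vdot(u, a))
            assert err / (np.linalg.norm(u) * np.linalg.norm(d)) < 1e-6

    def test_zero_data_gives_zero_volume(self, full_pattern):
        d = KSpaceData(np.zeros((full_pattern.n_t, full_pattern.n_r)), full_pattern)
        out = adjoint(d, np.zeros(6))
        assert np.all(out.data == 0)

    def test_unitary_case_inverts(self, random_volume, full_pattern):
        # zero motion, fully sampled: adjoint / n_vox is the inverse FFT
        d = forward(random_volume, np.zeros(6), full_pattern)
        rec = adjoint(d, np.zeros(6)).data / random_volume.n_voxels
        rel = np.linalg.norm(rec - random_volume.data) / np.linalg.norm(random_volume.data)
        assert rel < 1e-6

    def test_parseval_normalization(self, random_volume, full_pattern):
        # tight tolerance needs the high-accuracy kernel width
        op = RigidMotionOperator(full_pattern, nufft_width=10)
        d = op.forward(random_volume.data, np.zeros((full_pattern.n_t, 6)))
        lhs = np.vdot(d, d).real
        rhs = random_volume.n_voxels * np.vdot(random_volume.data,
                                               random_volume.data).real
        assert abs(lhs - rhs) / rhs < 1e-8

    def test_trajectory_length_mismatch_rejected(self, random_volume, full_pattern):
        with pytest.raises(ValueError):
            forward(random_volume, np.zeros((3, 6)), full_pattern)


class TestMisfitGradients:
    @pytest.fixture(scope="class")
    def problem(self):
        rng = np.random.default_rng(11)
        shape = (16, 16, 16)
        pat = SamplingPattern.full(shape)
        op = RigidMotionOperator(pat, spacing=(1.0, 1.2, 0.9))
        u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        u_other = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        knot_times = np.linspace(0, 1, 4)
        knots = rng.uniform(-0.2, 0.2, (4, 6))
        w = interp_weights(knot_times, np.arange(pat.n_t) / (pat.n_t - 1))
        d = KSpaceData(op.forward(u_other, w @ (0.5 * knots)), pat,
                       spacing=np.array([1.0, 1.2, 0.9]))
        return op, u, knots, w, d

    def test_exact_fit_has_zero_misfit_and_gradient(self, problem):
        op, u, knots, w, d = problem
        params = w @ knots
        d_exact = KSpaceData(op.forward(u, params), d.pattern, spacing=d.spacing)
        f, g = op.misfit_grad_u(u, params, d_exact)
        assert f < 1e-15 * np.linalg.norm(d_exact.samples) ** 2
        assert np.linalg.norm(g) < 1e-6 * np.linalg.norm(u)

    def test_zero_image_misfit_is_half_data_energy(self, problem):
        op, _, knots, w, d = problem
        f = op.misfit(np.zeros(op.shape, complex), w @ knots, d)
        assert abs(f - 0.5 * np.vdot(d.samples, d.samples).real) < 1e-6 * f

    def test_image_gradient_matches_finite_differences(self, problem, rng):
        op, u, knots, w, d = problem
        params = w @ knots
        _, g = op.misfit_grad_u(u, params, d)
        v = rng.standard_normal(op.shape) + 1j * rng.standard_normal(op.shape)
        h = 1e-6
        fd = (op.misfit(u + h * v, params, d)
              - op.misfit(u - h * v, params, d)) / (2 * h)
        an = np.vdot(g, v).real
        assert abs(fd - an) / abs(fd) < 1e-4

    def test_knot_gradient_matches_finite_differences(self, problem):
        op, u, knots, w, d = problem
        _, g = op.misfit_grad_knots(u, knots, w, d)
        h = 1e-5
        for j in range(knots.shape[0]):
            for a in range(6):
                kp, km = knots.copy(), knots.copy()
                kp[j, a] += h
                km[j, a] -= h
                fd = (op.misfit(u, w @ kp, d) - op.misfit(u, w @ km, d)) / (2 * h)
                assert abs(fd - g[j, a]) / max(abs(fd), 1e-8) < 1e-4

    def test_module_level_wrappers(self, problem):
        op, u, knots, w, d = problem
        traj = MotionTrajectory.from_arrays(np.linspace(0, 1, 4), knots,
                                            d.pattern.n_t)
        vol = ImageVolume(u, d.spacing)
        assert misfit(vol, traj, d) == pytest.approx(
            op.misfit(u, w @ knots, d), rel=1e-10)
        g_u = misfit_grad_u(vol, traj, d)
        g_t = misfit_grad_theta(vol, traj, d)
        assert g_u.shape == vol.shape
        assert g_t.shape == (4, 6)
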
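"""Solver machinery: stages, scale transfer, PALM iterations, results API."""

import numpy as np
import pytest

from rigidmoco.geometry import interp_weights
from rigidmoco.model import (MotionCorrectionModel, MotionCorrectionResults,
                             MultiScaleSchedule, SolverState, _StageContext,
                             epsilon_from_alpha, palm_iteration, restrict_kspace,
                             upsample_volume)
from rigidmoco.operators import KSpaceData, RigidMotionOperator
from rigidmoco.regularizers import RegularizerSpec, build_guide, plain_tv, project_tv_ball
from rigidmoco.synthetic import (PhantomSpec, make_phantom_pair,
                                 make_sampling_pattern, make_stepwise_trajectory,
                                 simulate_acquisition)


@pytest.fixture(scope="module")
def tiny_problem():
    shape = (16, 16, 16)
    u, v = make_phantom_pair(PhantomSpec(shape=shape, n_blobs=5, seed=2))
    pat = make_sampling_pattern(shape, "randomized", acceleration=2, seed=2)
    data = simulate_acquisition(u, np.zeros((pat.n_t, 6)), pat, seed=2)
    return u, v, pat, data


class TestEpsilonFromAlpha:
    def test_alpha_one_keeps_the_image_fixed(self, tiny_problem):
        u, v, _, _ = tiny_problem
        guide = build_guide(v, target_shape=u.shape)
        eps = epsilon_from_alpha(u.data, guide, 1.0)
        w, _ = project_tv_ball(u.data, eps, guide)
        assert np.array_equal(w, u.data)

    def test_one_percent_of_corrupted_tv(self, tiny_problem):
        u, _, _, _ = tiny_problem
        eps = epsilon_from_alpha(u.data, None, 0.01)
        assert eps == pytest.approx(0.01 * plain_tv(u.data))

    def test_homogeneity(self, tiny_problem):
        u, _, _, _ = tiny_problem
        assert epsilon_from_alpha(2 * u.data, None, 0.1) == pytest.approx(
            2 * epsilon_from_alpha(u.data, None, 0.1))

    def test_alpha_out_of_range(self, tiny_problem):
        u, _, _, _ = tiny_problem
        with pytest.raises(ValueError):
            epsilon_from_alpha(u.data, None, 0.0)


class TestRestriction:
    def test_factor_one_is_identity(self, tiny_problem):
        *_, data = tiny_problem
        coarse, times = restrict_kspace(data, 1)
        assert coarse is data
        assert times.size == data.pattern.n_t

    def test_coarse_samples_match_coarse_forward(self, tiny_problem):
        # the data model stays exact across scales: restricted samples of a
        # still object equal the forward model of the spectrum-cropped object
        u, _, pat, _ = tiny_problem
        clean = simulate_acquisition(u, np.zeros((pat.n_t, 6)), pat,
                                     noise_sigma=0.0)
        coarse, _ = restrict_kspace(clean, 2)
        import scipy.fft as sfft
        spec = sfft.fftshift(sfft.fftn(sfft.ifftshift(u.data)))
        sl = tuple(slice(n // 2 - n // 4, n // 2 + n // 4) for n in u.shape)
        u_c = sfft.fftshift(sfft.ifftn(sfft.ifftshift(spec[sl])))
        u_c *= (1 / 8)  # amplitude-preserving: N_c / N_f
        op = RigidMotionOperator(coarse.pattern, spacing=coarse.spacing)
        pred = op.forward(u_c, np.zeros((coarse.pattern.n_t, 6)))
        rel = np.linalg.norm(pred - coarse.samples) / np.linalg.norm(coarse.samples)
        assert rel < 1e-5

    def test_retained_line_times_are_original(self, tiny_problem):
        *_, data = tiny_problem
        coarse, times = restrict_kspace(data, 2)
        assert coarse.pattern.n_t == times.size
        assert np.all((times >= 0) & (times <= 1))
        assert np.all(np.diff(times) > 0)

    def test_upsample_preserves_amplitude_and_low_frequencies(self, rng):
        u = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        up = upsample_volume(u, (16, 16, 16))
        assert up.shape == (16, 16, 16)
        assert np.mean(up) == pytest.approx(np.mean(u), rel=1e-10)
        # round trip through the spectrum crop recovers the original
        import scipy.fft as sfft
        spec = sfft.fftshift(sfft.fftn(sfft.ifftshift(up)))
        sl = tuple(slice(4, 12) for _ in range(3))
        back = sfft.fftshift(sfft.ifftn(sfft.ifftshift(spec[sl]))) / 8
        assert np.allclose(back, u, atol=1e-10)


def _make_context(u, v, pat, data, estimate_motion=True):
    op = RigidMotionOperator(pat, spacing=data.spacing)
    guide = build_guide(v, target_shape=u.shape)
    n_k = 4
    w = interp_weights(np.linspace(0, 1, n_k),
                       np.arange(pat.n_t) / (pat.n_t - 1))
    ctx = _StageContext(op=op, data=data, guide=guide, interp_w=w, mu=0.0,
                        estimate_motion=estimate_motion, backtracking=True)
    return ctx, n_k


class TestPalmIteration:
    def test_exact_solution_is_a_fixed_point(self, tiny_problem):
        u, v, pat, _ = tiny_problem
        clean = simulate_acquisition(u, np.zeros((pat.n_t, 6)), pat,
                                     noise_sigma=0.0)
        ctx, n_k = _make_context(u, v, pat, clean)
        eps = 2.0 * plain_tv(u.data)  # truth comfortably feasible
        state = SolverState(u=u.data.copy(), knots=np.zeros((n_k, 6)), eps=eps,
                            t_u=1.0 / u.data.size, t_theta=1.0)
        palm_iteration(state, ctx)
        assert np.linalg.norm(state.u - u.data) < 1e-8 * np.linalg.norm(u.data)
        assert np.abs(state.knots).max() < 1e-8

    def test_first_step_from_zero_is_scaled_adjoint(self, tiny_problem):
        u, v, pat, _ = tiny_problem
        clean = simulate_acquisition(u, np.zeros((pat.n_t, 6)), pat,
                                     noise_sigma=0.0)
        ctx, n_k = _make_context(u, v, pat, clean, estimate_motion=False)
        huge = 1e9
        t_u = 0.5 / u.data.size
        state = SolverState(u=np.zeros_like(u.data), knots=np.zeros((n_k, 6)),
                            eps=huge, t_u=t_u, t_theta=1.0)
        palm_iteration(state, ctx)
        params = np.zeros((pat.n_t, 6))
        expected = t_u * ctx.op.adjoint(clean.samples, params)
        assert np.linalg.norm(state.u - expected) < 1e-8 * np.linalg.norm(expected)

    def test_misfit_trace_is_monotone(self, tiny_problem):
        u, v, pat, data = tiny_problem
        ctx, n_k = _make_context(u, v, pat, data)
        rng = np.random.default_rng(0)
        start = (rng.standard_normal(u.shape) + 1j * rng.standard_normal(u.shape))
        eps = 0.5 * plain_tv(start)
        start, p0 = project_tv_ball(start, eps, ctx.guide)
        state = SolverState(u=start, knots=np.zeros((n_k, 6)), eps=eps,
                            t_u=1.0 / u.data.size, t_theta=1.0, p_dual=p0)
        for _ in range(6):
            palm_iteration(state, ctx)
        trace = np.asarray(state.trace)
        assert np.all(np.diff(trace) <= 1e-6 * trace[0] + 1e-12)


class TestFitSmallProblems:
    def test_motion_free_recovery_and_determinism(self, tiny_problem):
        u, v, pat, data = tiny_problem
        sched = MultiScaleSchedule(spatial_factors=(2, 1), iters_per_stage=6,
                                   knot_count=6, refine_cycles=1, refine_iters=10)
        model = MotionCorrectionModel(data=data, reference=v, schedule=sched)
        res1 = model.fit()
        res2 = MotionCorrectionModel(data=data, reference=v, schedule=sched).fit()
        # determinism: identical inputs give bit-identical outputs
        assert np.array_equal(res1.image.data, res2.image.data)
        assert np.array_equal(res1.fine_params(), res2.fine_params())
        # null motion: translations recovered tightly; rotation accuracy
        # is limited by the k-space radius of this small grid
        p = res1.fine_params()
        assert np.abs(p[:, :3]).max() <= 0.2
        assert np.rad2deg(np.abs(p[:, 3:])).max() <= 3.0

    def test_scale_consistency_on_motion_free_convex_problem(self, tiny_problem):
        # with motion fixed the problem is convex: solving coarse-then-fine
        # agrees with solving directly at the fine scale
        u, v, pat, _ = tiny_problem
        clean = simulate_acquisition(u, np.zeros((pat.n_t, 6)), pat,
                                     noise_sigma=0.0)
        common = dict(iters_per_stage=40, knot_count=4)
        two_scale = MotionCorrectionModel(
            data=clean, reference=v, estimate_motion=False,
            schedule=MultiScaleSchedule(spatial_factors=(2, 1), **common)).fit()
        one_scale = MotionCorrectionModel(
            data=clean, reference=v, estimate_motion=False,
            schedule=MultiScaleSchedule(spatial_factors=(1,), **common)).fit()
        rel = (np.linalg.norm(two_scale.image.data - one_scale.image.data)
               / np.linalg.norm(one_scale.image.data))
        assert rel <= 1e-3

    def test_results_surface(self, tiny_problem, tmp_path):
        u, v, pat, data = tiny_problem
        sched = MultiScaleSchedule(spatial_factors=(2, 1), iters_per_stage=3,
                                   knot_count=4, refine_cycles=1, refine_iters=5)
        res = MotionCorrectionModel(data=data, reference=v, schedule=sched).fit()
        assert isinstance(res, MotionCorrectionResults)
        text = res.summary()
        assert "guided_tv" in text and "alpha" in text
        res.save_trajectory_csv(tmp_path / "traj.csv")
        table = np.loadtxt(tmp_path / "traj.csv", delimiter=",", skiprows=1)
        assert table.shape == (pat.n_t, 7)
        report = res.evaluate(u)
        assert report.psnr_db > 0
        res.plot_motion(tmp_path / "m.png")
        assert (tmp_path / "m.png").exists()

    def test_plain_tv_mode_runs_without_reference(self, tiny_problem):
        *_, data = tiny_problem
        sched = MultiScaleSchedule(spatial_factors=(2, 1), iters_per_stage=2,
                                   knot_count=4, refine_cycles=1, refine_iters=3)
        res = MotionCorrectionModel(
            data=data, reference=None,
            regularizer=RegularizerSpec(mode="plain_tv"),
            schedule=sched).fit()
        assert res.image.shape == data.pattern.grid_shape

    def test_guided_mode_requires_reference(self, tiny_problem):
        *_, data = tiny_problem
        with pytest.raises(ValueError):
            MotionCorrectionModel(data=data, reference=None)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            MultiScaleSchedule(spatial_factors=(2, 4, 1))
        with pytest.raises(ValueError):
            MultiScaleSchedule(spatial_factors=(4, 2))
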
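import numpy as np
import pytest

from diffdcm.dynamics import (DrivingInput, FluctuationSpec, ModelParameters,
                              ObservedSeries, discretize, drift_diffusion_rhs,
                              drift_matrix, minmax_normalize, observe,
                              read_series, simulate, write_series)
from diffdcm.stability import jacobian
from tests.conftest import random_graph


class TestRhs:
    def test_equal_states_reduce_to_pure_drift(self, fig1_graph):
        # zero structural gradients: the diffusion term vanishes and the
        # generalised equation reduces to the classic drift
        rng = np.random.default_rng(0)
        p = rng.standard_normal((3, 3))
        params = ModelParameters(p=p, sigma=1.7, q=np.zeros((1, 3)))
        x = np.full(3, 0.83)
        np.testing.assert_allclose(
            drift_diffusion_rhs(x, [0.0], params, fig1_graph), p @ x,
            atol=1e-12)

    def test_pure_diffusion_on_path_graph(self, fig1_graph):
        params = ModelParameters(p=np.zeros((3, 3)), sigma=1.0,
                                 q=np.zeros((1, 3)))
        rate = drift_diffusion_rhs([1.0, 0.0, 0.0], [0.0], params, fig1_graph)
        np.testing.assert_allclose(rate, [2.0, -1.0, -1.0])

    def test_pure_drift(self, fig1_graph, decay_params):
        rate = drift_diffusion_rhs(np.ones(3), [0.0], decay_params, fig1_graph)
        np.testing.assert_allclose(rate, [-1.0, -1.0, -1.0])

    def test_dimension_mismatch_rejected(self, fig1_graph, decay_params):
        with pytest.raises(ValueError):
            drift_diffusion_rhs(np.ones(4), [0.0], decay_params, fig1_graph)

    def test_gradient_and_laplacian_formulations_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            g = random_graph(n, rng)
            x = rng.standard_normal(n)
            params = ModelParameters(p=np.zeros((n, n)),
                                     sigma=float(rng.random()),
                                     q=np.zeros((1, n)))
            explicit = params.sigma * np.array(
                [sum(g.k[i, j] * (x[i] - x[j]) for j in range(n))
                 for i in range(n)])
            np.testing.assert_allclose(
                drift_diffusion_rhs(x, [0.0], params, g), explicit,
                atol=1e-12)


class TestSimulate:
    def test_origin_is_fixed_point(self, fig1_graph, decay_params):
        inp = DrivingInput.zeros(1, 50, 0.5)
        traj = simulate(decay_params, fig1_graph, inp, np.zeros(3))
        assert np.all(traj.x == 0.0)

    def test_scalar_decay_is_monotone(self, fig1_graph, decay_params):
        inp = DrivingInput.zeros(1, 80, 0.25)
        traj = simulate(decay_params, fig1_graph, inp, np.ones(3))
        assert np.all(np.diff(traj.x, axis=1) <= 0)
        assert np.all(traj.x[:, -1] > 0)

    def test_superposition_of_inputs(self, fig1_graph):
        rng = np.random.default_rng(7)
        params = ModelParameters(p=-0.8 * np.eye(3) + 0.05, sigma=0.2,
                                 q=rng.random((2, 3)))
        t = 60
        v1 = rng.standard_normal((2, t))
        v2 = rng.standard_normal((2, t))
        run = lambda v: simulate(params, fig1_graph,
                                 DrivingInput(v, 0.5), np.zeros(3)).x
        lhs = run(v1 + v2)
        rhs = run(v1) + run(v2) - run(np.zeros((2, t)))
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_euler_converges_to_exact_discretisation(self, fig1_graph):
        params = ModelParameters(p=-0.5 * np.eye(3), sigma=0.1,
                                 q=np.zeros((1, 3)))
        x0 = np.array([1.0, -0.5, 0.25])
        t_end = 8.0
        exact = simulate(params, fig1_graph,
                         DrivingInput.zeros(1, 17, 0.5), x0).x[:, -1]
        errs = []
        for dt in (0.1, 0.05):
            steps = int(t_end / dt) + 1
            euler = simulate(params, fig1_graph,
                             DrivingInput.zeros(1, steps, dt), x0,
                             method="euler").x[:, -1]
            errs.append(np.abs(euler - exact).max())
        # first-order scheme: halving dt roughly halves the endpoint error
        assert errs[1] < 0.7 * errs[0]

    def test_divergence_truncates_with_flag(self, fig1_graph):
        params = ModelParameters(p=5.0 * np.eye(3), sigma=0.0,
                                 q=np.zeros((1, 3)))
        traj = simulate(params, fig1_graph, DrivingInput.zeros(1, 500, 1.0),
                        np.ones(3))
        assert traj.diverged
        assert traj.n_samples < 500
        assert np.all(np.isfinite(traj.x))

    def test_stability_flag_matches_longrun_norm(self):
        # trajectory decays to zero iff max Re eig(P + sigma L) < 0;
        # near-marginal spectra are skipped (verdict needs a finite horizon)
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            n = int(rng.integers(2, 6))
            g = random_graph(n, rng)
            p = np.diag(-rng.uniform(0.2, 1.5, n)) \
                + 0.1 * rng.standard_normal((n, n))
            params = ModelParameters(p=p, sigma=float(rng.uniform(0, 0.4)),
                                     q=np.zeros((1, n)))
            summ = jacobian(params, g)
            if abs(summ.max_real) < 0.02:
                continue
            checked += 1
            x0 = rng.standard_normal(n)
            traj = simulate(params, g, DrivingInput.zeros(1, 400, 1.0), x0)
            n0 = np.linalg.norm(x0)
            n_end = np.linalg.norm(traj.x[:, -1]) if not traj.diverged else np.inf
            if summ.stable:
                assert not traj.diverged
                assert n_end < 1e-2 * max(n0, 1.0)
            else:
                assert traj.diverged or n_end > n0


class TestDiscretize:
    def test_matches_expm_and_input_integral(self):
        rng = np.random.default_rng(2)
        j = rng.standard_normal((4, 4))
        from scipy.linalg import expm
        a, g = discretize(j, 0.3)
        np.testing.assert_allclose(a, expm(j * 0.3), atol=1e-12)
        np.testing.assert_allclose(g, np.linalg.solve(j, a - np.eye(4)),
                                   atol=1e-10)


class TestObserve:
    def test_zero_noise_is_identity_and_seeds_reproduce(self, fig1_graph,
                                                        decay_params):
        traj = simulate(decay_params, fig1_graph,
                        DrivingInput.zeros(1, 30, 0.5), np.ones(3))
        assert np.array_equal(observe(traj, 0.0).y, traj.x)
        y1 = observe(traj, 0.3, seed=9).y
        y2 = observe(traj, 0.3, seed=9).y
        assert np.array_equal(y1, y2)

    def test_noise_sd_matches_target(self):
        from diffdcm.dynamics import Trajectory
        traj = Trajectory(x=np.zeros((4, 3000)), dt=1.0)
        y = observe(traj, 0.1, seed=1).y
        assert abs(y.std() - 0.1) < 0.005


class TestMinMax:
    def test_scales_rows_to_unit_interval(self):
        s = ObservedSeries(y=np.array([[2.0, 4.0, 6.0]]), dt=1.0)
        out = minmax_normalize(s)
        np.testing.assert_allclose(out.y, [[0.0, 0.5, 1.0]])
        assert out.normalization == {"min": [2.0], "max": [6.0]}

    def test_already_normalised_row_unchanged(self):
        s = ObservedSeries(y=np.array([[0.0, 0.25, 1.0]]), dt=1.0)
        np.testing.assert_allclose(minmax_normalize(s).y, s.y)

    def test_constant_row_rejected(self):
        s = ObservedSeries(y=np.ones((1, 5)), dt=1.0)
        with pytest.raises(ValueError, match="degenerate range"):
            minmax_normalize(s)


class TestFluctuations:
    def test_autocorrelation_time_tracks_smoothness(self):
        spec = FluctuationSpec(amplitude=1.0, smoothness=1.0, seed=4)
        w = spec.sample(1, 5000, 0.1)[0]
        w = w - w.mean()
        ac = np.correlate(w, w, "full")[w.size - 1:]
        ac /= ac[0]
        tau_e = 0.1 * np.argmax(ac < np.exp(-1))
        # Gaussian kernel of width s: correlation exp(-tau^2/(4 s^2)),
        # so the e-folding lag is 2 s
        assert abs(tau_e / 2.0 - 1.0) < 0.2

    def test_amplitude_and_seed(self):
        spec = FluctuationSpec(amplitude=0.3, smoothness=0.5, seed=5)
        w = spec.sample(3, 2000, 0.1)
        assert np.allclose(w.std(axis=1), 0.3, atol=0.01)
        assert np.array_equal(w, FluctuationSpec(0.3, 0.5, 5).sample(3, 2000, 0.1))


class TestSeriesIO:
    def test_roundtrip_with_dt_header(self, tmp_path):
        y = np.random.default_rng(0).standard_normal((3, 20))
        path = tmp_path / "y.tsv"
        write_series(path, y, 2.16, ["a", "b", "c"])
        back, dt, labels = read_series(path)
        np.testing.assert_allclose(back, y)
        assert dt == 2.16
        assert labels == ["a", "b", "c"]
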
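import numpy as np
import pytest

from diffdcm.dynamics import DrivingInput, ModelParameters
from diffdcm.intervention import (InterventionConfig, mirror_sweep,
                                  preictal_response, prepare_preictal,
                                  rank_single_node, suppression_metric)
from diffdcm.stability import jacobian
from diffdcm.synth import demo_unstable_fixture, star_fixture


@pytest.fixture(scope="module")
def unstable():
    params, graph, pre, cfg = demo_unstable_fixture(t_samples=300, dt=2.16)
    return params, graph, pre, cfg


@pytest.fixture(scope="module")
def sweep(unstable):
    params, graph, pre, cfg = unstable
    small_cfg = InterventionConfig(target_nodes=cfg.target_nodes,
                                   stimulated_nodes=cfg.stimulated_nodes,
                                   n_models=51)
    return mirror_sweep(params, graph, pre, small_cfg), small_cfg


class TestConfig:
    def test_overlapping_nodes_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            InterventionConfig(target_nodes=(0, 1), stimulated_nodes=(1, 2))

    def test_beta_grid_must_span_unit_interval(self):
        with pytest.raises(ValueError):
            InterventionConfig(target_nodes=(0,), stimulated_nodes=(1,),
                               beta_grid=np.linspace(0.2, 1.0, 5))


class TestPreictalResponse:
    def test_stable_system_bounded(self, unstable):
        _, graph, pre, cfg = unstable
        n = graph.n_regions
        q = np.zeros((1, n))
        q[0, 0] = q[0, 1] = 1.0
        stable_params = ModelParameters(p=-0.3 * np.eye(n), sigma=0.01, q=q)
        assert jacobian(stable_params, graph).stable
        traj = preictal_response(stable_params, graph, pre, cfg)
        assert not traj.diverged
        assert np.abs(traj.x).max() < 50.0

    def test_unstable_system_climbs_at_eigenvalue_rate(self, unstable):
        params, graph, pre, cfg = unstable
        traj = preictal_response(params, graph, pre, cfg)
        resp = np.abs(traj.x[list(cfg.target_nodes)]).max(axis=0)
        assert resp[-1] > 10.0 * np.abs(pre.v).max()
        # late-time growth should match the leading Jacobian eigenvalue
        lam = jacobian(params, graph).max_real
        t = traj.times
        tail = slice(traj.n_samples // 2, None)
        fit = np.polyfit(t[tail], np.log(resp[tail]), 1)[0]
        assert abs(fit - lam) / lam < 0.05

    def test_zero_input_zero_response(self, unstable):
        params, graph, _, cfg = unstable
        flat = DrivingInput(np.vstack([np.zeros(100), np.linspace(0, 1, 100)]),
                            2.16)
        with pytest.raises(ValueError):
            prepare_preictal(DrivingInput(np.zeros((1, 100)) + 0.5, 2.16))
        traj = preictal_response(params, graph,
                                 DrivingInput(np.linspace(0, 1, 100)[None], 2.16),
                                 cfg)
        assert traj.x[:, 0].max() == 0.0
        del flat

    def test_target_out_of_range_rejected(self, unstable):
        params, graph, pre, _ = unstable
        cfg = InterventionConfig(target_nodes=(99,), stimulated_nodes=(1,))
        with pytest.raises(ValueError, match="out of range"):
            preictal_response(params, graph, pre, cfg)


class TestSuppressionMetric:
    def test_constant_at_baseline_is_zero(self):
        assert suppression_metric(np.full(50, 0.7), 0.7) == 0.0

    def test_sinusoid_peak(self):
        t = np.linspace(0, 2 * np.pi, 1000)
        assert suppression_metric(0.3 + np.sin(t), 0.3) == pytest.approx(1.0, abs=1e-4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal(100)
        m1 = suppression_metric(r, 0.0)
        m2 = suppression_metric(r + 5.0, 5.0)
        assert m1 == pytest.approx(m2)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty window"):
            suppression_metric(np.ones(10), 0.0, window=slice(5, 5))


class TestMirrorSweep:
    def test_zero_beta_row_equals_unstimulated_response(self, unstable, sweep):
        params, graph, pre, _ = unstable
        res, cfg = sweep
        traj = preictal_response(params, graph, pre, cfg)
        expected = traj.x[list(cfg.target_nodes)].mean(axis=0)
        np.testing.assert_allclose(res.responses_raw[0], expected, atol=1e-10)

    def test_row_count_matches_beta_grid(self, sweep):
        res, cfg = sweep
        assert res.responses.shape[0] == cfg.n_models
        assert res.beta_grid.size == cfg.n_models

    def test_full_mirroring_suppresses(self, sweep):
        res, _ = sweep
        assert res.metric[-1] < 0.05 * res.metric[0]
        assert res.suppressed_at is not None

    def test_metric_nonincreasing_in_beta(self, sweep):
        res, _ = sweep
        assert np.all(np.diff(res.metric) <= 1e-9 * res.metric[0])

    def test_responses_linear_in_beta(self, sweep):
        res, _ = sweep
        r0, r1 = res.responses_raw[0], res.responses_raw[-1]
        mid = res.responses_raw[25]
        beta = res.beta_grid[25]
        np.testing.assert_allclose(mid, r0 + beta * (r1 - r0), atol=1e-8)

    def test_jacobian_untouched_by_stimulation(self, unstable):
        # stimulation only reshapes inputs; the Jacobian is input-independent
        params, graph, *_ = unstable
        before = jacobian(params, graph).j.copy()
        eig_before = jacobian(params, graph).eigenvalues
        after = jacobian(params, graph).j
        assert np.array_equal(before, after)
        assert np.array_equal(eig_before, jacobian(params, graph).eigenvalues)

    def test_gradient_reduction_at_full_mirroring(self, sweep, unstable):
        # mirroring shrinks inter-node activity gradients along graph edges
        _, graph, *_ = unstable
        res, cfg = sweep
        def mean_gradient(traj):
            x = traj.x
            i, j = np.nonzero(np.triu(graph.k, 1))
            return np.abs(x[i] - x[j]).mean()
        assert mean_gradient(res.traj_beta1) < 0.01 * mean_gradient(res.traj_beta0)


class TestRanking:
    def test_star_fixture_single_effective_node(self):
        params, graph, pre, cfg = star_fixture()
        table = rank_single_node(params, graph, pre, cfg, gain_cap=200.0)
        assert table.rows[0].node == "node_1"
        assert table.rows[0].relative_strength == pytest.approx(1.0)
        assert all(r.relative_strength is None for r in table.rows[1:])

    def test_agrees_with_exhaustive_grid_search(self):
        params, graph, pre, cfg = star_fixture()
        from diffdcm.intervention import (_dual_channel, _pad_states,
                                          _stim_params)
        from diffdcm.dynamics import simulate
        prep = prepare_preictal(pre)
        dual = _dual_channel(prep)
        n = params.n_regions
        t_steps = prep.n_samples

        def metric_sim(nodes, gain):
            traj = simulate(_stim_params(params, cfg, gain, nodes), graph,
                            dual, np.zeros(n))
            resp = _pad_states(traj, t_steps)[list(cfg.target_nodes)].mean(axis=0)
            return suppression_metric(resp, cfg.baseline)

        ref = metric_sim(tuple(i for i in range(n)
                               if i not in cfg.target_nodes), 1.0)
        criterion = 1.05 * ref
        gain_cap = 200.0
        grid = np.linspace(0, gain_cap, 201)[1:]
        table = rank_single_node(params, graph, pre, cfg, gain_cap=gain_cap)
        by_node = {r.node: r for r in table.rows}
        for c in (1, 2, 3):
            passing = [g for g in grid if metric_sim((c,), g) <= criterion]
            row = by_node[f"node_{c}"]
            if not passing:
                assert row.relative_strength is None
            else:
                # bisected gain within one exhaustive-grid step
                assert abs(row.gain - passing[0]) <= gain_cap / 200

    def test_symmetric_candidates_tie_broken_by_order(self):
        # two nodes coupled identically to the target get equal strengths
        n = 4
        k = np.zeros((n, n), dtype=np.int64)
        k[0, 1] = k[1, 0] = k[0, 2] = k[2, 0] = 1
        from diffdcm.graph import AdjacencyGraph
        d = k.sum(axis=1)
        graph = AdjacencyGraph(k=k, d=d, laplacian=np.diag(d) - k,
                               threshold=0.5)
        q = np.zeros((1, n))
        q[0, 0] = 1.0
        params = ModelParameters(p=-0.05 * np.eye(n), sigma=0.04, q=q)
        pre = DrivingInput(np.linspace(0, 1, 150)[None] ** 2, 1.0)
        cfg = InterventionConfig(target_nodes=(0,), stimulated_nodes=(1, 2, 3),
                                 n_models=10)
        table = rank_single_node(params, graph, pre, cfg, gain_cap=50.0)
        r1, r2 = table.rows[0], table.rows[1]
        assert {r1.node, r2.node} == {"region_1", "region_2"}
        assert r1.node == "region_1"  # tie broken by node order
        assert r1.gain == pytest.approx(r2.gain, rel=1e-3)
        assert r1.relative_strength == r2.relative_strength == pytest.approx(1.0)

    def test_gain_cap_below_effective_gain_gives_all_na(self):
        params, graph, pre, cfg = star_fixture()
        with pytest.warns(UserWarning, match="N/A"):
            table = rank_single_node(params, graph, pre, cfg, gain_cap=1e-4)
        assert all(r.relative_strength is None for r in table.rows)
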
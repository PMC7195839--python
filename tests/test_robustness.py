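import numpy as np
import pytest

from nlgrn.datamodel import (
    DataError,
    GeneEdge,
    GeneExpressionDataset,
    InferredNetwork,
    ModelParameters,
    NltEdge,
    TimeGrid,
)
from nlgrn.robustness_pruning import (
    DeletionStep,
    PruneConfig,
    RobustnessConfig,
    greedy_prune,
    perturb,
    replay_removals,
    robustness,
    score_removal,
    trace_to_csv,
)


class TestPerturb:
    def test_mu_zero_identity(self, decay_model):
        net, params = decay_model
        rng = np.random.default_rng(0)
        out = perturb(params, RobustnessConfig(mu=0.0), rng)
        assert out.degradation == params.degradation

    def test_known_eps(self):
        params = ModelParameters(alpha={}, beta={}, degradation={"A": 0.5})

        class FixedRng:
            def standard_normal(self, size):
                return np.ones(size)

        cfg = RobustnessConfig(mu=0.4, targets="degradation_only")
        out = perturb(params, cfg, FixedRng())
        assert out.degradation["A"] == pytest.approx(0.7)

    def test_empirical_sd_matches_mu(self):
        params = ModelParameters(alpha={}, beta={}, degradation={"A": 1.0})
        cfg = RobustnessConfig(mu=0.4)
        rng = np.random.default_rng(123)
        draws = np.array(
            [perturb(params, cfg, rng).degradation["A"] for _ in range(100_000)]
        )
        assert np.std(draws) == pytest.approx(0.4, rel=0.02)

    def test_targets_degradation_only(self):
        params = ModelParameters(
            alpha={("B", "A"): 1.0}, beta={}, degradation={"A": 0.5, "B": 0.5}
        )
        rng = np.random.default_rng(1)
        cfg = RobustnessConfig(mu=0.4, targets="degradation_only")
        out = perturb(params, cfg, rng)
        assert out.alpha == params.alpha
        assert out.degradation != params.degradation


class TestRobustness:
    def test_mu_zero_exact(self, decay_model, decay_dataset):
        net, params = decay_model
        rep = robustness(net, params, decay_dataset,
                         RobustnessConfig(mu=0.0, n_perturb=20, seed=4))
        assert rep.RA == 0.0
        assert rep.RSTD == 0.0
        assert rep.n_failed == 0

    def test_stubbed_constant_distances(self, decay_model, decay_dataset, monkeypatch):
        net, params = decay_model
        import nlgrn.robustness_pruning as rb

        base = rb.simulate(params, net, decay_dataset.values[:, 0],
                           decay_dataset.grid)
        calls = {"n": 0}

        def fake_simulate(p, n, x0, grid, **kw):
            calls["n"] += 1
            if calls["n"] == 1:
                return base
            vals = base.values.copy()
            vals[0, -1] += 0.75  # constant displacement regardless of draw
            return type(base)(grid, vals, "ok")

        monkeypatch.setattr(rb, "simulate", fake_simulate)
        rep = rb.robustness(net, params, decay_dataset,
                            RobustnessConfig(mu=0.4, n_perturb=10, seed=0))
        assert rep.RA == pytest.approx(0.75)
        assert rep.RSTD == pytest.approx(0.0, abs=1e-15)

    def test_draw_order_invariance(self, decay_model, decay_dataset):
        net, params = decay_model
        rep = robustness(net, params, decay_dataset,
                         RobustnessConfig(mu=0.2, n_perturb=40, seed=7))
        assert np.mean(rep.distances) == pytest.approx(rep.RA)
        assert np.std(rep.distances, ddof=1) == pytest.approx(rep.RSTD)
        # statistics are symmetric functions of the distances
        shuffled = np.random.default_rng(0).permutation(rep.distances)
        assert np.mean(shuffled) == pytest.approx(rep.RA)
        assert np.std(shuffled, ddof=1) == pytest.approx(rep.RSTD)

    def test_small_mu_linear_slope(self, decay_model, decay_dataset):
        # analytic small-mu limit: RA ~ sqrt(2/pi) * k*mu * ||t exp(-kt)||_2
        net, params = decay_model
        t = decay_dataset.grid.as_array()
        k = 0.5
        scale = np.sqrt(np.sum((t * np.exp(-k * t)) ** 2))
        for mu in (0.01, 0.005):
            rep = robustness(
                net, params, decay_dataset,
                RobustnessConfig(mu=mu, n_perturb=400, seed=11,
                                 targets="degradation_only"),
            )
            analytic = np.sqrt(2 / np.pi) * k * mu * scale
            assert rep.RA == pytest.approx(analytic, rel=0.10)

    def test_baseline_failure_raises(self, decay_dataset):
        net = InferredNetwork(("A",))
        bad = ModelParameters.__new__(ModelParameters)
        bad.alpha, bad.beta = {}, {}
        bad.degradation = {"A": -2.0}  # explosive baseline
        with pytest.raises(DataError, match="baseline"):
            robustness(net, bad, decay_dataset,
                       RobustnessConfig(mu=0.1, n_perturb=5))


def _two_gene_fixture():
    grid = TimeGrid(tuple(float(t) for t in range(0, 20, 2)))
    names = ("A", "B")
    net = InferredNetwork(
        names, (GeneEdge("A", "B"),), (NltEdge(("A", "B"), "B"),)
    )
    params = ModelParameters(
        alpha={("B", "A"): 0.2},
        beta={("B", ("A", "B")): 0.0},  # a genuinely inert regulation
        degradation={"A": 0.3, "B": 0.4},
    )
    from nlgrn.dynamics import simulate

    x0 = np.array([1.5, 1.0])
    traj = simulate(params, net, x0, grid)
    ds = GeneExpressionDataset(names, grid, np.abs(traj.values))
    return net, params, ds


class TestScoreRemoval:
    def test_zero_coefficient_edge_leaves_se_unchanged(self):
        net, params, ds = _two_gene_fixture()
        rcfg = RobustnessConfig(mu=0.4, n_perturb=10, seed=0)
        base = score_removal(net, params, ds, rcfg=rcfg)
        zeroed = score_removal(
            net, params, ds, nlt_edges=[(("A", "B"), "B")], rcfg=rcfg
        )
        assert zeroed.SE == base.SE  # exact: the trajectory is unchanged

    def test_removing_all_edges_gives_decay_only(self):
        net, params, ds = _two_gene_fixture()
        rcfg = RobustnessConfig(mu=0.1, n_perturb=5, seed=0)
        st = score_removal(
            net, params, ds,
            gene_edges=[("A", "B")], nlt_edges=[(("A", "B"), "B")],
            rcfg=rcfg,
        )
        from nlgrn.dynamics import simulate, simulation_error

        bare = InferredNetwork(("A", "B"))
        bare_params = ModelParameters(
            alpha={}, beta={}, degradation=params.degradation
        )
        traj = simulate(bare_params, bare, ds.values[:, 0], ds.grid,
                        rtol=rcfg.rtol, atol=rcfg.atol)
        assert st.SE == pytest.approx(simulation_error(traj, ds), abs=1e-9)

    def test_missing_edge_rejected(self):
        net, params, ds = _two_gene_fixture()
        with pytest.raises(DataError, match="not"):
            score_removal(net, params, ds, gene_edges=[("B", "A")])


class TestGreedyPrune:
    def test_immediate_stop_with_tau_zero(self):
        net, params, ds = _two_gene_fixture()
        # remove the inert NLT edge first; then the gene edge would worsen
        # both SE and RA, so with tau=0 the trace stops
        rcfg = RobustnessConfig(mu=0.4, n_perturb=30, seed=1)
        trace = greedy_prune(net, params, ds, rcfg,
                             PruneConfig(tau=0.0, screen_n=30))
        assert trace.steps[0].label == "OES"
        labels = [s.label for s in trace.steps]
        assert len(labels) == len(set(labels))

    def test_replay_consistency(self):
        net, params, ds = _two_gene_fixture()
        rcfg = RobustnessConfig(mu=0.4, n_perturb=20, seed=1)
        trace = greedy_prune(net, params, ds, rcfg,
                             PruneConfig(tau=0.5, screen_n=20))
        replayed = replay_removals(net, trace.steps)
        assert replayed.total_edges == trace.final_network.total_edges
        assert net.total_edges - trace.total_removed() == replayed.total_edges

    def test_trace_csv(self, tmp_path):
        net, params, ds = _two_gene_fixture()
        rcfg = RobustnessConfig(mu=0.4, n_perturb=10, seed=1)
        trace = greedy_prune(net, params, ds, rcfg,
                             PruneConfig(tau=0.0, screen_n=10))
        path = tmp_path / "trace.csv"
        trace_to_csv(trace, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "Model,RR,SE,RA,RSTD"
        assert lines[1].startswith("OES,N/A,")


class TestReplay:
    def test_nested_and_counted(self):
        from nlgrn.presets import published_network, published_removal_steps

        for lineage, start, left in (("erythroid", 92, 85), ("neutrophil", 80, 76)):
            net = published_network(lineage)
            assert net.total_edges == start
            steps = published_removal_steps(lineage)
            out = replay_removals(net, steps)
            assert out.total_edges == left
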
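import numpy as np
import pandas as pd
import pytest

from csense import propagation as pr
from csense.errors import InvalidParameterError, InvalidSeedError, LookupError_, MappingError
from csense.sensitivity_graph import METABOLITE, SPECIES, Edge, SensitivityGraph


def graph_of(edges, nodes):
    g = SensitivityGraph(nodes=nodes, edges=edges)
    g.validate()
    return g


@pytest.fixture
def six_node_graph():
    nodes = {"m1": METABOLITE, "m2": METABOLITE, "m3": METABOLITE,
             "s1": SPECIES, "s2": SPECIES, "s3": SPECIES}
    edges = [
        Edge("m1", "s1", 0.9, 0.01, "uptake"),
        Edge("m1", "s2", -0.4, 0.01, "uptake"),
        Edge("m2", "s2", 0.7, 0.01, "uptake"),
        Edge("m3", "s3", 0.5, 0.01, "uptake"),
        Edge("s1", "m2", 0.6, 0.01, "secretion"),
        Edge("s3", "m1", -0.3, 0.01, "secretion"),
    ]
    return graph_of(edges, nodes)


def random_graph(rng, n_m=3, n_s=3):
    nodes = {f"m{i}": METABOLITE for i in range(n_m)}
    nodes.update({f"s{i}": SPECIES for i in range(n_s)})
    edges = []
    for m in [f"m{i}" for i in range(n_m)]:
        for s in [f"s{i}" for i in range(n_s)]:
            if rng.random() < 0.5:
                edges.append(Edge(m, s, float(rng.uniform(-1, 1)), 0.01, "uptake"))
            if rng.random() < 0.3:
                edges.append(Edge(s, m, float(rng.uniform(-1, 1)), 0.01, "secretion"))
    if not edges:
        edges.append(Edge("m0", "s0", 0.5, 0.01, "uptake"))
    return graph_of(edges, nodes)


class TestNormalizeWeights:
    def test_signs_preserved_unit_sum(self):
        g = graph_of(
            [Edge("m", "s1", 0.8, 0.01, "uptake"), Edge("m", "s2", -0.2, 0.01, "uptake")],
            {"m": METABOLITE, "s1": SPECIES, "s2": SPECIES})
        node_ids, P = pr.normalize_weights(g)
        i = node_ids.index("m")
        assert P[i, node_ids.index("s1")] == pytest.approx(0.8)
        assert P[i, node_ids.index("s2")] == pytest.approx(-0.2)

    def test_balanced_signs_normalized(self):
        g = graph_of(
            [Edge("m", "s1", 1.0, 0.01, "uptake"), Edge("m", "s2", -1.0, 0.01, "uptake")],
            {"m": METABOLITE, "s1": SPECIES, "s2": SPECIES})
        node_ids, P = pr.normalize_weights(g)
        i = node_ids.index("m")
        assert P[i, node_ids.index("s1")] == pytest.approx(0.5)
        assert P[i, node_ids.index("s2")] == pytest.approx(-0.5)

    def test_substochastic_rows(self, rng):
        for _ in range(20):
            _, P = pr.normalize_weights(random_graph(rng))
            assert (np.abs(P).sum(axis=1) <= 1 + 1e-12).all()


class TestPropagate:
    def test_closed_form_without_clamp(self, six_node_graph):
        node_ids, P = pr.normalize_weights(six_node_graph)
        seeds = pr.SeedSet({"s1": 1.0, "s3": 0.5}, mode=pr.SPECIES_SEED)
        state = pr.propagate(six_node_graph, seeds, restart=0.3, clamp=False, tol=1e-12)
        idx = {n: i for i, n in enumerate(node_ids)}
        s = np.zeros(len(node_ids))
        s[idx["s1"]], s[idx["s3"]] = 1.0, 0.5
        closed = 0.3 * np.linalg.solve(np.eye(len(node_ids)) - 0.7 * P.T, s)
        iterated = np.array([state.weights[n] for n in node_ids])
        np.testing.assert_allclose(iterated, closed, atol=1e-8)
        assert state.converged

    def test_single_negative_inflow_clamped_to_zero(self):
        g = graph_of([Edge("m", "sp", -0.9, 0.01, "uptake")],
                     {"m": METABOLITE, "sp": SPECIES})
        seeds = pr.SeedSet({"m": 1.0}, mode=pr.ENVIRONMENT)
        state = pr.propagate(g, seeds, clamp=True)
        assert state.weights["sp"] == 0.0

    def test_clamp_noop_on_all_positive_graph(self, rng):
        nodes = {"m0": METABOLITE, "m1": METABOLITE, "s0": SPECIES, "s1": SPECIES}
        edges = [Edge("m0", "s0", 0.8, 0.01, "uptake"),
                 Edge("m1", "s1", 0.6, 0.01, "uptake"),
                 Edge("s0", "m1", 0.5, 0.01, "secretion")]
        g = graph_of(edges, nodes)
        seeds = pr.SeedSet({"s0": 1.0, "s1": 2.0}, mode=pr.SPECIES_SEED)
        on = pr.propagate(g, seeds, clamp=True)
        off = pr.propagate(g, seeds, clamp=False)
        assert on.weights == off.weights

    def test_clamp_never_negative(self, rng):
        for _ in range(100):
            g = random_graph(rng)
            seeds = pr.SeedSet(
                {s: float(rng.uniform(0.01, 1)) for s in g.species_nodes()},
                mode=pr.SPECIES_SEED)
            state = pr.propagate(g, seeds, clamp=True)
            assert min(state.weights.values()) >= 0.0

    def test_environment_nodes_pinned(self, six_node_graph):
        seeds = pr.SeedSet({"m1": 0.6, "m2": 0.3, "m3": 0.1}, mode=pr.ENVIRONMENT)
        state = pr.propagate(six_node_graph, seeds)
        assert state.weights["m1"] == 0.6
        assert state.weights["m2"] == 0.3
        assert state.weights["m3"] == 0.1

    def test_mixed_kind_seeds_rejected(self, six_node_graph):
        seeds = pr.SeedSet({"m1": 1.0}, mode=pr.SPECIES_SEED)
        with pytest.raises(InvalidSeedError):
            pr.propagate(six_node_graph, seeds)
        seeds2 = pr.SeedSet({"s1": 1.0}, mode=pr.ENVIRONMENT)
        with pytest.raises(InvalidSeedError):
            pr.propagate(six_node_graph, seeds2)

    def test_restart_validation(self, six_node_graph):
        seeds = pr.SeedSet({"s1": 1.0}, mode=pr.SPECIES_SEED)
        with pytest.raises(InvalidParameterError):
            pr.propagate(six_node_graph, seeds, restart=0.0)

    def test_nonconvergence_reported_not_raised(self, six_node_graph):
        seeds = pr.SeedSet({"s1": 1.0}, mode=pr.SPECIES_SEED)
        state = pr.propagate(six_node_graph, seeds, clamp=False, tol=1e-16, max_iter=3)
        assert not state.converged
        assert state.iterations == 3
        assert len(state.residual_history) == 3

    def test_node_order_invariance(self, rng):
        # same graph, node ids renamed so sorted order differs
        g1 = random_graph(rng)
        mapping = {n: f"zz_{n}" if n.startswith("m") else f"aa_{n}" for n in g1.nodes}
        g2 = graph_of(
            [Edge(mapping[e.source_id], mapping[e.target_id], e.weight,
                  e.p_value, e.mode) for e in g1.edges],
            {mapping[n]: k for n, k in g1.nodes.items()})
        seeds1 = pr.SeedSet({s: 1.0 for s in g1.species_nodes()}, mode=pr.SPECIES_SEED)
        seeds2 = pr.SeedSet({mapping[s]: 1.0 for s in g1.species_nodes()},
                            mode=pr.SPECIES_SEED)
        w1 = pr.propagate(g1, seeds1).weights
        w2 = pr.propagate(g2, seeds2).weights
        for n in g1.nodes:
            assert w1[n] == pytest.approx(w2[mapping[n]], abs=1e-12)

    def test_absorbing_extinction_is_permanent(self):
        # m1 drives sp negative early; with absorbing=True sp stays dead
        nodes = {"m1": METABOLITE, "m2": METABOLITE, "sp": SPECIES}
        edges = [Edge("m1", "sp", -1.0, 0.01, "uptake"),
                 Edge("m2", "sp", 0.4, 0.01, "uptake")]
        g = graph_of(edges, nodes)
        seeds = pr.SeedSet({"m1": 1.0, "m2": 0.2}, mode=pr.ENVIRONMENT)
        absorbing = pr.propagate(g, seeds, clamp=True, absorbing=True)
        assert absorbing.weights["sp"] == 0.0


class TestSeeds:
    def test_seed_from_abundance_top_n(self):
        table = pd.DataFrame({"a": [5.0], "b": [3.0], "c": [1.0]}, index=["s1"])
        seeds = pr.seed_from_abundance(table, "s1", top_n=2)
        assert seeds.values == {"a": 5.0, "b": 3.0}
        assert seeds.mode == pr.SPECIES_SEED

    def test_seed_from_abundance_top_n_exceeds(self):
        table = pd.DataFrame({"a": [5.0], "b": [3.0]}, index=["s1"])
        assert set(pr.seed_from_abundance(table, "s1", top_n=10).values) == {"a", "b"}

    def test_seed_from_abundance_tie_break(self):
        table = pd.DataFrame({"b": [5.0], "a": [5.0], "c": [1.0]}, index=["s1"])
        assert pr.seed_from_abundance(table, "s1", top_n=1).values == {"a": 5.0}

    def test_seed_from_abundance_unknown_sample(self):
        table = pd.DataFrame({"a": [1.0]}, index=["s1"])
        with pytest.raises(LookupError_):
            pr.seed_from_abundance(table, "nope", top_n=1)

    def test_seed_from_environment_renormalizes(self):
        table = pd.DataFrame({"f1": [3.0], "f2": [1.0]}, index=["s1"])
        seeds = pr.seed_from_environment(table, "s1", {"f1": "m1", "f2": "m2"})
        assert seeds.values == {"m1": 0.75, "m2": 0.25}
        assert seeds.mode == pr.ENVIRONMENT

    def test_unmapped_feature_ignored_with_warning(self, caplog):
        table = pd.DataFrame({"f1": [3.0], "f2": [1.0]}, index=["s1"])
        with caplog.at_level("WARNING"):
            seeds = pr.seed_from_environment(
                table, "s1", {"f1": "m1", "f2": "ghost"}, graph_metabolites={"m1"})
        assert seeds.values == {"m1": 1.0}
        assert "ghost" in caplog.text

    def test_all_unmapped_raises(self):
        table = pd.DataFrame({"f1": [3.0]}, index=["s1"])
        with pytest.raises(MappingError):
            pr.seed_from_environment(table, "s1", {"f1": "ghost"},
                                     graph_metabolites={"m1"})

    def test_negative_seed_rejected(self):
        with pytest.raises(InvalidSeedError):
            pr.SeedSet({"a": -1.0}, mode=pr.SPECIES_SEED)
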
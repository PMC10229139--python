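"""Edge signs, SHD, similarity, consensus, TPR and stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sccausal as sc
from sccausal.graph import CausalNetwork
from sccausal.network import ValidationError, build_consensus_report

NODES = tuple("ABCD")


def net(directed=(), undirected=()):
    return CausalNetwork.from_edges(NODES, directed, undirected)


def random_network(seed: int, p: int = 5) -> CausalNetwork:
    rng = np.random.default_rng(seed)
    nodes = tuple(f"n{k}" for k in range(p))
    directed, undirected = set(), set()
    for a in range(p):
        for b in range(a + 1, p):
            u = rng.random()
            if u < 0.2:
                directed.add((nodes[a], nodes[b]))
            elif u < 0.4:
                directed.add((nodes[b], nodes[a]))
            elif u < 0.55:
                undirected.add((nodes[a], nodes[b]))
    return CausalNetwork(nodes, directed, undirected)


class TestSigns:
    def test_activation_repression_and_constant(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        data = np.column_stack([a, 2 * a, -a, np.ones(100)])
        g = net(directed=[("A", "B")], undirected=[("A", "C"), ("A", "D")])
        with pytest.warns(UserWarning, match="constant"):
            out = sc.annotate_edge_signs(g, data, NODES)
        assert out.sign[("A", "B")] == 1
        assert out.sign[("A", "C")] == -1
        assert out.sign[("A", "D")] == 0


class TestShd:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            (net(directed=[("A", "B")]), net(directed=[("A", "B")]), 0),
            (net(directed=[("A", "B")]), net(), 1),  # presence mismatch
            (net(directed=[("A", "B")]), net(directed=[("B", "A")]), 1),  # flip
            (net(directed=[("A", "B")]), net(undirected=[("A", "B")]), 1),  # mark change
        ],
    )
    def test_mismatch_classes(self, g1, g2, expected):
        assert sc.shd(g1, g2) == expected

    def test_node_set_mismatch_rejected(self):
        other = CausalNetwork(("A", "B"))
        with pytest.raises(ValidationError):
            sc.shd(net(), other)

    def test_metric_axioms_on_random_triples(self):
        for seed in range(0, 600, 3):
            g1, g2, g3 = (random_network(seed + k) for k in range(3))
            assert sc.shd(g1, g1) == 0
            assert sc.shd(g1, g2) == sc.shd(g2, g1)
            assert sc.shd(g1, g3) <= sc.shd(g1, g2) + sc.shd(g2, g3)


class TestSimilarity:
    def test_closed_form_values(self):
        # distance 0 → 1; distance 50 with σ=5 → exp(−50/50) = e⁻¹
        g0 = net()
        report = sc.similarity_matrix([g0, g0], sigma=5.0)
        assert report.similarity[0, 1] == 1.0
        assert math.exp(-50 / (2 * 5.0**2)) == pytest.approx(math.exp(-1))
        d = np.array([[0.0, 50.0], [50.0, 0.0]])
        np.testing.assert_allclose(np.exp(-d / 50.0)[0, 1], math.exp(-1))

    def test_similarity_is_monotone_in_shd(self):
        nets = [random_network(s) for s in range(5)]
        report = sc.similarity_matrix(nets)
        order_by_d = np.argsort(report.shd_matrix[np.triu_indices(5, 1)])
        order_by_s = np.argsort(-report.similarity[np.triu_indices(5, 1)])
        np.testing.assert_array_equal(order_by_d, order_by_s)
        vals = report.similarity[np.triu_indices(5, 1)]
        assert ((vals > 0) & (vals <= 1)).all()


class TestConsensus:
    def test_identity_intersection(self):
        g = net(directed=[("A", "B")], undirected=[("C", "D")])
        out = sc.consensus_network([g, g.copy()], ["x", "y"])
        assert set(out.directed) == {("A", "B")}
        assert out.undirected == {("C", "D")}

    def test_direction_conflict_becomes_undirected(self):
        out = sc.consensus_network(
            [net(directed=[("A", "B")]), net(directed=[("B", "A")])], ["x", "y"]
        )
        assert not out.directed
        assert out.undirected == {("A", "B")}

    def test_empty_intersection(self):
        out = sc.consensus_network([net(directed=[("A", "B")]), net()], ["x", "y"])
        assert out.n_edges() == 0

    def test_consensus_subset_of_every_member(self):
        nets = [random_network(s) for s in range(4)]
        nets = [CausalNetwork(nets[0].nodes, n.directed, n.undirected) for n in nets]
        out = sc.consensus_network(nets)
        for member in nets:
            assert out.adjacencies() <= member.adjacencies()

    def test_unknown_member_label_rejected(self):
        with pytest.raises(ValidationError):
            sc.consensus_network([net(), net()], ["x", "y"], members=["nope", "x"])


class TestTpr:
    def test_worked_example_73_over_106(self):
        """A network sharing 73 interactions with the consensus and holding
        33 specific ones has TPR 73/(73+33) = 68.9 %."""
        nodes = tuple(f"g{k}" for k in range(40))
        pairs = [(a, b) for a in nodes for b in nodes if a < b]
        shared, specific = pairs[:73], pairs[73 : 73 + 33]
        member = CausalNetwork(nodes, set(), set(shared) | set(specific))
        consensus = CausalNetwork(nodes, set(), set(shared))
        tpr = sc.tpr_vs_consensus(member, consensus)
        assert tpr == pytest.approx(73 / 106)
        assert round(100 * tpr, 1) == 68.9

    def test_identical_network_scores_one(self):
        g = net(directed=[("A", "B")])
        assert sc.tpr_vs_consensus(g, g.copy()) == 1.0

    def test_disjoint_networks_score_zero(self):
        assert sc.tpr_vs_consensus(net(directed=[("A", "B")]), net(directed=[("C", "D")])) == 0.0

    def test_empty_network_is_vacuously_one(self):
        with pytest.warns(UserWarning):
            assert sc.tpr_vs_consensus(net(), net(directed=[("A", "B")])) == 1.0

    def test_overlap_plus_specific_consistency(self):
        nets = [random_network(s) for s in range(3)]
        nets = [CausalNetwork(nets[0].nodes, n.directed, n.undirected) for n in nets]
        cons = sc.consensus_network(nets)
        for g in nets:
            a, c = g.adjacencies(), cons.adjacencies()
            assert len(a & c) + len(a - c) == len(a)


class TestStability:
    def test_identical_runs_fully_stable(self):
        g = net(directed=[("A", "B")], undirected=[("C", "D")])
        prof = sc.edge_stability([g, g.copy(), g.copy()])
        assert prof.cumulative_fraction[3] == 1.0
        assert prof.exact_fraction[3] == 1.0

    def test_disjoint_runs_all_singletons(self):
        prof = sc.edge_stability([net(directed=[("A", "B")]), net(directed=[("C", "D")])])
        assert prof.exact_fraction[1] == 1.0
        assert prof.cumulative_fraction[2] == 0.0

    def test_cumulative_fraction_non_increasing(self):
        nets = [random_network(s, p=6) for s in range(5)]
        nets = [CausalNetwork(nets[0].nodes, n.directed, n.undirected) for n in nets]
        prof = sc.edge_stability(nets)
        vals = [prof.cumulative_fraction[k] for k in range(1, 6)]
        assert vals == sorted(vals, reverse=True)
        assert sum(prof.exact_fraction.values()) == pytest.approx(1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(0, 10_000))
def test_shd_symmetry_property(s1, s2):
    g1, g2 = random_network(s1), random_network(s2)
    assert sc.shd(g1, g2) == sc.shd(g2, g1)


def test_consensus_report_end_to_end(tmp_path):
    nets = [random_network(s) for s in range(4)]
    nets = [CausalNetwork(nets[0].nodes, n.directed, n.undirected) for n in nets]
    report = build_consensus_report(nets, ["a", "b", "c", "d"])
    assert set(report.members) <= set(report.labels)
    assert set(report.tpr) == set(report.labels)
    report.to_json(tmp_path / "report.json")
    assert (tmp_path / "report.json").exists()
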
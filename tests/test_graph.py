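"""Admixture-graph algebra and scenario fitting."""

import itertools

import numpy as np
import pytest

import oracles
from admixkit import (
    AdmixtureGraph,
    F4Vector,
    GraphError,
    ScenarioModel,
    compare_scenarios,
    expected_f2,
    expected_f4,
    fit_scenario,
    leaf_edge_weights,
)


def exact_observation(graph, quartets):
    F = np.array([expected_f4(graph, q) for q in quartets])
    return F4Vector(
        entries=[(tuple(q), float(v)) for q, v in zip(quartets, F)],
        S=np.eye(len(quartets)),
        statistic_kind="f4",
    )


def identifiable_quartets(leaves):
    """All distinct quartets plus f2-style repeats, pinning every edge."""
    qs = [tuple(q) for q in itertools.combinations(leaves, 4)]
    qs += [(a, b, a, b) for a, b in itertools.combinations(leaves, 2)]
    return qs


class TestStructure:
    def test_cycle_is_rejected(self):
        with pytest.raises(GraphError, match="cycle|root"):
            AdmixtureGraph(edges={("A", "B"): 0.1, ("B", "A"): 0.1})

    def test_two_parents_require_alpha(self):
        with pytest.raises(GraphError, match="alpha"):
            AdmixtureGraph(
                edges={("R", "A"): 0.1, ("R", "B"): 0.1,
                       ("A", "X"): 0.0, ("B", "X"): 0.0}
            )

    def test_file_round_trip(self, admixed_graph, tmp_path):
        path = tmp_path / "g.dag"
        admixed_graph.to_file(path)
        back = AdmixtureGraph.from_file(path)
        assert back.edges == admixed_graph.edges
        assert back.admixture == admixed_graph.admixture


class TestLeafEdgeWeights:
    def test_pure_tree_weights_are_indicator(self, simple_tree_graph):
        w = leaf_edge_weights(simple_tree_graph)
        assert w["P1"][("n", "P1")] == 1.0
        assert w["P1"][("R", "I")] == 1.0
        assert w["P1"][("I", "P3")] == 0.0

    def test_admixture_child_splits_alpha(self):
        g = AdmixtureGraph(
            edges={("R", "A"): 0.1, ("R", "B"): 0.1,
                   ("A", "X"): 0.0, ("B", "X"): 0.0},
            admixture={"X": ("A", "B", 0.25)},
        )
        w = leaf_edge_weights(g)
        assert w["X"][("A", "X")] == pytest.approx(0.25)
        assert w["X"][("B", "X")] == pytest.approx(0.75)

    def test_stacked_admixture_matches_path_enumeration(self):
        # two stacked events (alpha = 0.5 then 0.4): the three root paths
        # carry probabilities {0.4*0.5, 0.4*... } enumerated independently
        g = AdmixtureGraph(
            edges={
                ("R", "a"): 0.1, ("R", "b"): 0.1, ("R", "c"): 0.1,
                ("a", "m1"): 0.0, ("b", "m1"): 0.0,
                ("m1", "mid"): 0.05,
                ("mid", "m2"): 0.0, ("c", "m2"): 0.0,
                ("m2", "X"): 0.01,
                ("a", "A"): 0.1, ("b", "B"): 0.1, ("c", "C"): 0.1,
            },
            admixture={"m1": ("a", "b", 0.5), "m2": ("mid", "c", 0.4)},
        )
        paths = oracles.graph_paths(g.edges, g.admixture, "X")
        probs = sorted(p for p, _ in paths)
        assert probs == pytest.approx([0.2, 0.2, 0.6])
        w = leaf_edge_weights(g)
        for e in g.edges:
            oracle_w = sum(p for p, es in paths if e in es)
            assert w["X"][e] == pytest.approx(oracle_w)


class TestExpectedF4:
    def test_disjoint_pairs_give_zero(self):
        g = AdmixtureGraph(
            edges={("R", "x"): 0.1, ("R", "y"): 0.2,
                   ("x", "A"): 0.1, ("x", "B"): 0.1,
                   ("y", "C"): 0.1, ("y", "D"): 0.1}
        )
        assert expected_f4(g, ("A", "B", "C", "D")) == pytest.approx(0.0)
        # crossing the pairs picks up exactly the two root edges
        assert expected_f4(g, ("A", "C", "B", "D")) == pytest.approx(0.3)

    def test_admixed_graph_matches_pathpair_oracle(self, admixed_graph):
        g = admixed_graph
        for q in itertools.combinations(g.leaves, 4):
            oracle = oracles.f4_pathpairs(g.edges, g.admixture, q)
            assert expected_f4(g, q) == pytest.approx(oracle, abs=1e-12)

    def test_f2_decomposition_on_graph_expectations(self, admixed_graph):
        g = admixed_graph
        for a, b, c, d in itertools.combinations(g.leaves, 4):
            lhs = expected_f4(g, (a, b, c, d))
            rhs = 0.5 * (
                expected_f2(g, a, d) + expected_f2(g, b, c)
                - expected_f2(g, a, c) - expected_f2(g, b, d)
            )
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_subdividing_an_edge_with_zero_drift_is_neutral(self, admixed_graph):
        g = admixed_graph
        edges = dict(g.edges)
        d = edges.pop(("I", "n1"))
        edges[("I", "mid")] = d
        edges[("mid", "n1")] = 0.0
        g2 = AdmixtureGraph(edges=edges, admixture=dict(g.admixture))
        for q in itertools.combinations(g.leaves, 4):
            assert expected_f4(g2, q) == pytest.approx(expected_f4(g, q))

    def test_unknown_leaf_raises(self, admixed_graph):
        with pytest.raises(GraphError):
            expected_f4(admixed_graph, ("A", "B", "C", "ZZ"))


class TestScenarioFit:
    def test_perfect_fit_recovers_parameters(self, admixed_graph):
        g = admixed_graph
        obs = exact_observation(g, identifiable_quartets(g.leaves))
        res = ScenarioModel(g, obs, scenario_id="truth").fit(restarts=3, seed=1)
        assert res.minimal_error <= 1e-8
        assert res.alphas["X0"] == pytest.approx(0.3, abs=1e-3)
        # every identifiable drift (all but the fused root pair) recovered
        fused = set(res.fused_root_edges)
        for e, d in res.drifts.items():
            if e in fused or e in {("Bp", "X0"), ("Cp", "X0")}:
                continue
            assert d == pytest.approx(g.edges[e], abs=1e-3)
        root_sum = sum(res.drifts[e] for e in fused)
        true_sum = sum(g.edges[e] for e in fused)
        assert root_sum == pytest.approx(true_sum, abs=1e-3)

    def test_cost_invariant_under_joint_reordering(self, admixed_graph):
        g = admixed_graph
        qs = identifiable_quartets(g.leaves)
        rng = np.random.default_rng(0)
        S = np.eye(len(qs)) + 0.1 * np.ones((len(qs), len(qs)))
        F = np.array([expected_f4(g, q) for q in qs]) + 0.001
        perm = rng.permutation(len(qs))
        obs1 = F4Vector([(tuple(q), float(v)) for q, v in zip(qs, F)], S, "f4")
        obs2 = F4Vector(
            [(tuple(qs[i]), float(F[i])) for i in perm],
            S[np.ix_(perm, perm)], "f4",
        )
        m1, m2 = ScenarioModel(g, obs1), ScenarioModel(g, obs2)
        x = m1._initial_alphas(np.random.default_rng(1), 0.5)
        assert m1.cost(x) == pytest.approx(m2.cost(x), rel=1e-9)

    def test_single_scenario_returned_unchanged(self, admixed_graph):
        g = admixed_graph
        obs = exact_observation(g, identifiable_quartets(g.leaves))
        fits = compare_scenarios({"only": g}, obs, restarts=2, seed=0)
        assert len(fits) == 1 and fits[0].scenario_id == "only"

    def test_parsimony_breaks_ties_between_nested_scenarios(self):
        # truth is a pure tree; a rival adds a spurious admixture edge:
        # both reach (near) zero error, the simpler scenario must rank first
        tree = AdmixtureGraph(
            edges={("R", "O"): 0.05, ("R", "I"): 0.02,
                   ("I", "C"): 0.03, ("I", "n"): 0.01,
                   ("n", "A"): 0.02, ("n", "B"): 0.02}
        )
        spurious = AdmixtureGraph(
            edges={("R", "O"): 0.05, ("R", "I"): 0.02,
                   ("I", "Cp"): 0.03, ("Cp", "C"): 0.0,
                   ("I", "n"): 0.01, ("n", "A"): 0.02, ("n", "Bp"): 0.0,
                   ("Bp", "B"): 0.02,
                   ("Bp", "X0"): 0.0, ("Cp", "X0"): 0.0, ("X0", "X"): 0.01},
            admixture={"X0": ("Bp", "Cp", 0.5)},
        )
        # rival carries an extra leaf; restrict quartets to the shared leaves
        qs = identifiable_quartets(tree.leaves)
        obs = exact_observation(tree, qs)
        fits = compare_scenarios(
            {"tree": tree, "extra": spurious}, obs, restarts=3, seed=2,
            tie_tol=1e-4,
        )
        assert fits[0].scenario_id == "tree"
        assert fits[0].minimal_error <= 1e-8
        assert fits[1].minimal_error <= 1e-6

    def test_d_mode_fits_scale(self, admixed_graph):
        g = admixed_graph
        qs = identifiable_quartets(g.leaves)
        F = 7.5 * np.array([expected_f4(g, q) for q in qs])
        obs = F4Vector([(tuple(q), float(v)) for q, v in zip(qs, F)],
                       np.eye(len(qs)), "D")
        res = fit_scenario(g, obs, restarts=3, seed=3)
        assert res.minimal_error <= 1e-8
        # scale trades off against the overall drift magnitude; only the
        # products scale * d_e are identifiable
        assert res.scale * res.drifts[("n1", "A")] == pytest.approx(
            7.5 * g.edges[("n1", "A")], rel=1e-2
        )
        assert res.alphas["X0"] == pytest.approx(0.3, abs=5e-3)
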
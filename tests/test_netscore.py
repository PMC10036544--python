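"""BUM calibration and maximal-scoring subnetwork solvers."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import brentq

from adhesomics import synthio
from adhesomics.netscore import (
    BumFit,
    build_scored_graph,
    bum_tau,
    fit_bum,
    mwcs_to_pcst,
    score_nodes,
    solve_mwcs_exact,
    solve_mwcs_heuristic,
)
from conftest import brute_force_mwcs


class TestFitBum:
    def test_pure_noise_pi_near_one(self):
        p = synthio.gen_bum_pvalues(10_000, lam=1.0, a=0.5, seed=0)
        fit = fit_bum(p)
        assert fit.pi_upper >= 0.95

    def test_parameter_recovery(self):
        p = synthio.gen_bum_pvalues(10_000, lam=0.7, a=0.3, seed=3)
        fit = fit_bum(p)
        assert abs(fit.lam - 0.7) < 0.05
        assert abs(fit.a - 0.3) < 0.05

    def test_beats_uniform_only_candidate(self):
        p = synthio.gen_bum_pvalues(2000, lam=0.5, a=0.2, seed=1)
        fit = fit_bum(p)
        # uniform-only model (lam=1) has density 1 everywhere: log lik 0
        assert fit.log_lik >= 0.0

    def test_clamps_nonpositive_with_warning(self):
        p = np.concatenate([[0.0], synthio.gen_bum_pvalues(200, 0.5, 0.3, seed=2)])
        with pytest.warns(UserWarning):
            fit_bum(p)

    def test_rejects_values_above_one(self):
        with pytest.raises(ValueError):
            fit_bum(np.full(200, 1.5))


class TestBumTau:
    def test_closed_form_substitution(self):
        # lam=0, a=0.5: tau = (0.5/0.05)^(1/-0.5) = 0.01
        fit = BumFit(lam=0.0, a=0.5, log_lik=0.0)
        assert bum_tau(fit, 0.05) == pytest.approx(0.01)

    def test_matches_numeric_root_of_fdr_definition(self):
        fit = BumFit(lam=0.5, a=0.5, log_lik=0.0)
        tau = bum_tau(fit, 0.05)

        def fdr_of(t):
            # expected false fraction among calls at threshold t
            calls = fit.lam * t + (1 - fit.lam) * t**fit.a
            return fit.pi_upper * t / calls

        root = brentq(lambda t: fdr_of(t) - 0.05, 1e-12, 1 - 1e-12)
        assert tau == pytest.approx(root, rel=1e-9)

    def test_no_signal_component_error(self):
        with pytest.raises(ValueError):
            bum_tau(BumFit(lam=1.0, a=0.5, log_lik=0.0), 0.05)

    def test_fdr_outside_unit_interval_error(self):
        fit = BumFit(lam=0.5, a=0.5, log_lik=0.0)
        with pytest.raises(ValueError):
            bum_tau(fit, 1.0)
        with pytest.raises(ValueError):
            bum_tau(fit, 0.0)


class TestScoreNodes:
    def setup_method(self):
        self.fit = BumFit(lam=0.6, a=0.3, log_lik=0.0)
        self.tau = bum_tau(self.fit, 0.05)

    def test_zero_at_tau_and_one_log_unit(self):
        s = score_nodes(self.fit, {"x": self.tau, "y": self.tau / math.e})
        assert s["x"] == pytest.approx(0.0, abs=1e-12)
        assert s["y"] == pytest.approx(1 - self.fit.a)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        pmap = {f"n{i}": float(1 - rng.random()) for i in range(50)}
        s = score_nodes(self.fit, pmap)
        for n, p in pmap.items():
            expected = (self.fit.a - 1) * (math.log(p) - math.log(self.tau))
            assert s[n] == pytest.approx(expected)

    def test_sign_agrees_with_threshold(self):
        rng = np.random.default_rng(5)
        pmap = {f"n{i}": float(1 - rng.random()) for i in range(200)}
        s = score_nodes(self.fit, pmap)
        for n, p in pmap.items():
            assert math.copysign(1, s[n]) == math.copysign(1, self.tau - p) or s[n] == 0

    def test_missing_nodes_get_default(self):
        s = score_nodes(self.fit, {"a": 0.01}, nodes=["a", "b"])
        expected = (self.fit.a - 1) * (math.log(0.5) - math.log(self.tau))
        assert s["b"] == pytest.approx(expected)


class TestPcstTransform:
    def test_all_positive_scores(self):
        g = build_scored_graph([("a", "b")], {"a": 1.0, "b": 2.0})
        inst = mwcs_to_pcst(g)
        assert inst.edge_cost == 0.0
        assert inst.profits == {"a": 1.0, "b": 2.0}

    def test_negative_offset(self):
        g = build_scored_graph([("a", "b")], {"a": 3.0, "b": -2.0})
        inst = mwcs_to_pcst(g)
        assert inst.profits == {"a": 5.0, "b": 0.0}
        assert inst.edge_cost == 2.0

    def test_objectives_share_argmax_over_all_subtrees(self):
        rng = np.random.default_rng(6)
        g = nx.gnp_random_graph(7, 0.5, seed=11)
        while not nx.is_connected(g):  # pragma: no cover
            g = nx.gnp_random_graph(7, 0.5, seed=12)
        scores = {n: float(rng.normal(0, 2)) for n in g.nodes}
        sg = build_scored_graph(list(g.edges), scores)
        inst = mwcs_to_pcst(sg)

        def best(objective):
            top, arg = -np.inf, None
            for r in range(1, 8):
                for sub in itertools.combinations(sg.nodes, r):
                    if not nx.is_connected(sg.subgraph(sub)):
                        continue
                    val = objective(sub)
                    if val > top + 1e-12:
                        top, arg = val, tuple(sorted(sub))
            return arg

        mwcs_arg = best(lambda sub: sum(scores[n] for n in sub))
        pcst_arg = best(
            lambda sub: sum(inst.profits[n] for n in sub)
            - inst.edge_cost * (len(sub) - 1)
        )
        assert mwcs_arg == pcst_arg


class TestExactSolver:
    def test_all_positive_returns_everything(self):
        g = build_scored_graph([("a", "b"), ("b", "c")], {"a": 1, "b": 1, "c": 1})
        assert solve_mwcs_exact(g).members == ("a", "b", "c")

    def test_all_negative_returns_best_single(self):
        g = build_scored_graph([("a", "b")], {"a": -1.0, "b": -2.0})
        mod = solve_mwcs_exact(g)
        assert mod.members == ("a",)
        assert mod.total_score == -1.0

    def test_seven_node_path(self):
        # brute-force oracle: the singleton scoring 4 beats the left block
        # summing to 3, so the optimum is the last node alone
        edges = [(f"v{i}", f"v{i+1}") for i in range(6)]
        scores = dict(zip([f"v{i}" for i in range(7)], [2, -1, -1, 3, -5, -1, 4]))
        g = build_scored_graph(edges, scores)
        mod = solve_mwcs_exact(g)
        assert brute_force_mwcs(g) == (4.0, ("v6",))
        assert mod.members == ("v6",)
        assert mod.total_score == pytest.approx(4.0)

    def test_matches_brute_force_on_random_instances(self):
        suite = synthio.gen_mwcs_suite(25, max_nodes=9, seed=77)
        for edges, scores in suite:
            g = build_scored_graph(edges, scores)
            mod = solve_mwcs_exact(g)
            bs, bk = brute_force_mwcs(g)
            assert mod.total_score == pytest.approx(bs)
            assert mod.members == bk

    def test_rejects_large_graphs(self):
        edges = [(f"n{i}", f"n{i+1}") for i in range(25)]
        scores = {f"n{i}": 1.0 for i in range(26)}
        with pytest.raises(ValueError, match="heuristic"):
            solve_mwcs_exact(build_scored_graph(edges, scores))


class TestHeuristicSolver:
    def test_single_positive_amid_negatives(self):
        g = build_scored_graph(
            [("a", "b"), ("b", "c")], {"a": -1.0, "b": 2.0, "c": -3.0}
        )
        mod = solve_mwcs_heuristic(g)
        assert mod.members == ("b",)

    def test_profitable_bridge(self):
        g = build_scored_graph(
            [("a", "b"), ("b", "c")], {"a": 5.0, "b": -0.1, "c": 5.0}
        )
        mod = solve_mwcs_heuristic(g)
        assert mod.members == ("a", "b", "c")
        assert mod.total_score == pytest.approx(9.9)

    def test_connected_output_and_quality_on_suite(self):
        suite = synthio.gen_mwcs_suite(40, seed=12345)
        equal = 0
        for edges, scores in suite:
            g = build_scored_graph(edges, scores)
            h = solve_mwcs_heuristic(g)
            assert nx.is_connected(g.subgraph(h.members))
            ex = solve_mwcs_exact(g)
            assert h.total_score >= 0.9 * ex.total_score - 1e-12
            if abs(h.total_score - ex.total_score) <= 1e-9:
                equal += 1
        assert equal >= 0.8 * len(suite)

    def test_multi_component_returns_global_best(self):
        g = build_scored_graph(
            [("a", "b"), ("c", "d")], {"a": 1.0, "b": 1.0, "c": 5.0, "d": -0.5}
        )
        mod = solve_mwcs_heuristic(g)
        assert mod.members == ("c",)

    def test_strong_planted_signal_recovered(self):
        # planted members get strong Beta(0.05, 1) p-values: the module is
        # the maximal-scoring subgraph and the heuristic finds most of it
        edges, truth = synthio.gen_ppi_network(200, 4.0, 20, seed=0)
        rng = np.random.default_rng(0)
        nodes = sorted({u for e in edges for u in e})
        pmap = {
            n: (1 - rng.random()) ** (1 / 0.05)
            if n in truth.planted_members
            else 1 - rng.random()
            for n in nodes
        }
        fit = fit_bum(np.array([pmap[n] for n in nodes]))
        g = build_scored_graph(edges, score_nodes(fit, pmap))
        mod = solve_mwcs_heuristic(g)
        members = set(mod.members)
        recall = len(members & truth.planted_members) / len(truth.planted_members)
        extraneous = len(members - truth.planted_members) / len(members)
        assert recall >= 0.8
        assert extraneous <= 0.2
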
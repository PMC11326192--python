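import math

import numpy as np
import pytest

from assemblypath.graph import (
    DeadLayerError,
    EnumerationCapError,
    Snapshot,
    Trajectory,
    best_trajectory,
    build_graph,
    count_trajectories,
    enumerate_trajectories,
    graph_model_precision,
    marginal_node_weights,
    score_trajectories,
    transition_allowed,
)
from assemblypath.system import Composition


def snap(sid, t, sites=(), log_score=0.0):
    comp = Composition(t, (("T", len(sites)),), frozenset(sites))
    return Snapshot(sid, t, comp, log_score)


def dummy_layers(sizes, log_scores=None):
    """Fully-connectable layers of site-nested snapshots (all empty sites)."""
    out = {}
    for li, n in enumerate(sizes):
        t = f"t{li}"
        out[t] = [
            snap(f"t{li}n{i:02d}", t,
                 log_score=0.0 if log_scores is None else log_scores[li][i])
            for i in range(n)
        ]
    return out


def random_layered_graph(seed, max_layers=5, max_width=4):
    """Random sparse layered graph with real-valued transition weights.

    Regenerates until at least one complete path exists and no layer is
    entirely dead (so build_graph accepts it).
    """
    rng = np.random.default_rng(seed)
    while True:
        sizes = rng.integers(1, max_width + 1, size=rng.integers(3, max_layers + 1))
        layers = dummy_layers(
            sizes,
            log_scores=[rng.normal(0, 1, size=n) for n in sizes],
        )
        weights = {}
        for (ta, snaps_a), (tb, snaps_b) in zip(
            list(layers.items()), list(layers.items())[1:]
        ):
            for a in snaps_a:
                for b in snaps_b:
                    weights[(a.id, b.id)] = (
                        float(rng.uniform(0.1, 2.0)) if rng.random() < 0.7 else 0.0
                    )
        scorer = lambda a, b: weights[(a.id, b.id)]  # noqa: E731
        try:
            graph = build_graph(layers, mode="custom-random", transition_scorer=scorer)
        except DeadLayerError:
            continue
        if count_trajectories(graph) > 0:
            return graph


def brute_force_paths(graph):
    """Independent DFS oracle over positive-weight edges."""
    first, last = graph.time_labels[0], graph.time_labels[-1]
    paths = []

    def walk(node, acc):
        acc = acc + [node]
        t = graph.snapshots[node].time_label
        if t == last:
            paths.append(tuple(acc))
            return
        for succ in graph.graph.successors(node):
            walk(succ, acc)

    for start in graph.layers[first]:
        walk(start, [])
    return paths


class TestTransitionRule:
    def test_identical_composition_allowed(self):
        a = snap("a", "t0", ("s1", "s2"))
        b = snap("b", "t1", ("s1", "s2"))
        assert transition_allowed(a, b) == 1

    def test_removal_disallowed(self):
        # a subcomplex present earlier but absent later means disassembly
        a = snap("a", "t0", ("s1", "s2"))
        b = snap("b", "t1", ("s2", "s3"))
        assert transition_allowed(a, b) == 0

    def test_empty_start_allowed_everywhere(self):
        a = snap("a", "t0", ())
        b = snap("b", "t1", ("s1", "s2", "s3"))
        assert transition_allowed(a, b) == 1

    def test_subset_rule_transitive_along_paths(self):
        graph = build_graph(
            {
                "t0": [snap("a", "t0", ("s1",))],
                "t1": [snap("b", "t1", ("s1", "s2"))],
                "t2": [snap("c", "t2", ("s1", "s2", "s4"))],
            },
            mode="constrained",
        )
        for traj in enumerate_trajectories(graph):
            first = graph.snapshots[traj.snapshot_ids[0]].composition
            last = graph.snapshots[traj.snapshot_ids[-1]].composition
            assert first.is_subset_of(last)


class TestBuildGraph:
    def test_unconstrained_edge_count_small(self):
        graph = build_graph(dummy_layers([2, 2]), mode="unconstrained")
        assert graph.n_edges == 4

    def test_unconstrained_edge_count_paper_layers(self):
        graph = build_graph(dummy_layers([15, 20, 22, 18, 15, 1]), mode="unconstrained")
        assert graph.n_edges == 15 * 20 + 20 * 22 + 22 * 18 + 18 * 15 + 15 * 1
        assert graph.n_edges == 1421

    def test_constrained_edges_subset_of_unconstrained(self):
        layers = {
            "t0": [snap("a0", "t0", ()), snap("a1", "t0", ("s1",))],
            "t1": [snap("b0", "t1", ("s1",)), snap("b1", "t1", ("s2",))],
        }
        con = build_graph(layers, mode="constrained")
        unc = build_graph(layers, mode="unconstrained")
        assert set(con.graph.edges()) <= set(unc.graph.edges())
        assert con.n_zero_edges == unc.n_edges - con.n_edges

    def test_dead_layer_raises(self):
        layers = {
            "t0": [snap("a", "t0", ("s1", "s2"))],
            "t1": [snap("b", "t1", ("s3",))],  # not a superset: no edge
        }
        with pytest.raises(DeadLayerError, match="t0"):
            build_graph(layers, mode="constrained")

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError):
            build_graph({"t0": [snap("a", "t0")], "t1": []})


class TestEnumeration:
    def test_two_by_two_has_four_paths(self):
        graph = build_graph(dummy_layers([2, 2]), mode="unconstrained")
        assert count_trajectories(graph) == 4
        assert len(enumerate_trajectories(graph)) == 4

    def test_paper_layer_sizes_count_without_materializing(self):
        graph = build_graph(dummy_layers([15, 20, 22, 18, 15, 1]), mode="unconstrained")
        assert graph.n_nodes == 91
        assert count_trajectories(graph) == 1_782_000

    def test_cap_exceeded_is_an_explicit_error(self):
        graph = build_graph(dummy_layers([3, 3]), mode="unconstrained")
        with pytest.raises(EnumerationCapError, match="marginal_node_weights"):
            enumerate_trajectories(graph, cap=8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dfs_oracle_on_random_graphs(self, seed):
        graph = random_layered_graph(seed)
        oracle = sorted(brute_force_paths(graph))
        got = [t.snapshot_ids for t in enumerate_trajectories(graph)]
        assert got == oracle
        assert count_trajectories(graph) == len(oracle)


class TestScoring:
    def test_single_path_weight_is_one(self):
        graph = build_graph(dummy_layers([1, 1, 1]), mode="unconstrained")
        scored = score_trajectories(graph, enumerate_trajectories(graph))
        assert scored[0].weight == pytest.approx(1.0)
        assert marginal_node_weights(graph) == {
            sid: pytest.approx(1.0) for sid in graph.snapshots
        }

    def test_symmetric_paths_split_evenly(self):
        graph = build_graph(dummy_layers([2, 1]), mode="unconstrained")
        scored = score_trajectories(graph, enumerate_trajectories(graph))
        assert [t.weight for t in scored] == [pytest.approx(0.5)] * 2

    def test_three_to_one_score_ratio(self):
        layers = dummy_layers([2, 1], log_scores=[[math.log(3.0), 0.0], [0.0]])
        graph = build_graph(layers, mode="unconstrained")
        scored = score_trajectories(graph, enumerate_trajectories(graph))
        weights = {t.snapshot_ids[0]: t.weight for t in scored}
        assert weights["t0n00"] == pytest.approx(0.75)
        assert weights["t0n01"] == pytest.approx(0.25)

    def test_zero_transition_gives_exact_zero_weight(self):
        graph = build_graph(dummy_layers([2, 1]), mode="unconstrained")
        bogus = Trajectory(("t0n00", "t0n00"))  # no such edge
        scored = score_trajectories(
            graph, enumerate_trajectories(graph) + [bogus]
        )
        assert scored[-1].weight == 0.0 and scored[-1].log_weight == -math.inf

    @pytest.mark.parametrize("seed", range(5))
    def test_markov_factorization_reproduces_log_weights(self, seed):
        graph = random_layered_graph(seed)
        scored = score_trajectories(graph, enumerate_trajectories(graph))
        finite = [t for t in scored if t.weight > 0]
        log_z = math.log(
            sum(
                math.exp(
                    sum(graph.snapshots[s].log_score for s in t.snapshot_ids)
                    + sum(
                        graph.edge_log_weight(u, v)
                        for u, v in zip(t.snapshot_ids, t.snapshot_ids[1:])
                    )
                )
                for t in finite
            )
        )
        for t in finite:
            per_step = sum(graph.snapshots[s].log_score for s in t.snapshot_ids) + sum(
                graph.edge_log_weight(u, v)
                for u, v in zip(t.snapshot_ids, t.snapshot_ids[1:])
            )
            assert t.log_weight == pytest.approx(per_step - log_z, abs=1e-12)


class TestMarginalsAndPrecision:
    @pytest.mark.parametrize("seed", range(8))
    def test_dp_marginals_match_enumeration(self, seed):
        graph = random_layered_graph(seed)
        scored = score_trajectories(graph, enumerate_trajectories(graph))
        expected = {sid: 0.0 for sid in graph.snapshots}
        for t in scored:
            for sid in t.snapshot_ids:
                expected[sid] += t.weight
        got = marginal_node_weights(graph)
        for sid in graph.snapshots:
            assert got[sid] == pytest.approx(expected[sid], rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_per_layer_marginals_sum_to_one(self, seed):
        graph = random_layered_graph(seed)
        marg = marginal_node_weights(graph)
        for t in graph.time_labels:
            assert sum(marg[sid] for sid in graph.layers[t]) == pytest.approx(
                1.0, abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_gamma_matches_enumerated_sum_of_squares(self, seed):
        graph = random_layered_graph(seed)
        scored = score_trajectories(graph, enumerate_trajectories(graph))
        gamma_enum = sum(t.weight**2 for t in scored)
        assert graph_model_precision(graph) == pytest.approx(gamma_enum, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_best_trajectory_is_the_argmax(self, seed):
        graph = random_layered_graph(seed)
        scored = score_trajectories(graph, enumerate_trajectories(graph))
        top = best_trajectory(graph)
        best_enum = max(scored, key=lambda t: (t.weight, t.snapshot_ids))
        assert top.weight == pytest.approx(best_enum.weight, rel=1e-10)
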
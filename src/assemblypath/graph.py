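"""Layered DAG of snapshots and weighted trajectory enumeration.

Snapshots at adjacent time points are connected into a directed acyclic graph
whose edges carry transition weights.  In the *constrained* mode a transition
is allowed only when every subcomplex present in the earlier snapshot is still
present — at the same site — in the later one (components do not dissociate);
the *unconstrained* mode connects all adjacent pairs.  A trajectory is a path
from the first to the last layer; its weight is the product of snapshot scores
and transition weights along the path, normalized over all trajectories.  All
weight arithmetic is done in log space; marginal node weights and the
trajectory-count/precision bookkeeping use forward-backward dynamic
programming so nothing needs to be materialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .system import Composition
from .structure import StructureEnsemble

__all__ = [
    "Snapshot",
    "Trajectory",
    "TrajectoryGraph",
    "transition_allowed",
    "build_graph",
    "count_trajectories",
    "enumerate_trajectories",
    "score_trajectories",
    "marginal_node_weights",
    "graph_log_evidence",
    "graph_model_precision",
    "best_trajectory",
    "DeadLayerError",
    "EnumerationCapError",
]

DEFAULT_ENUMERATION_CAP = 10_000_000


class DeadLayerError(RuntimeError):
    """Every node of some layer has no allowed outgoing transition."""


class EnumerationCapError(RuntimeError):
    """Too many trajectories to materialize; use DP-based quantities instead."""


@dataclass
class Snapshot:
    """One scored snapshot model: composition plus a positive score.

    ``log_score`` stores ``log P(X, N | D)``; the likelihood-scale score is
    exposed as a property and is positive by construction.
    """

    id: str
    time_label: str
    composition: Composition
    log_score: float = 0.0
    ensemble: StructureEnsemble | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_score):
            raise ValueError(f"snapshot {self.id!r}: log_score must be finite")

    @property
    def score(self) -> float:
        return math.exp(self.log_score)


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of snapshot ids, one per time point, with weight."""

    snapshot_ids: tuple[str, ...]
    log_weight: float = float("nan")  # normalized, -inf for weight 0
    weight: float = float("nan")

    @property
    def id(self) -> str:
        return ">".join(self.snapshot_ids)


def transition_allowed(s1: Snapshot, s2: Snapshot) -> int:
    """1 iff s1's occupied sites are a subset of s2's (same location assignment)."""
    return int(s1.composition.is_subset_of(s2.composition))


class TrajectoryGraph:
    """Layered DAG over snapshots with log-space transition weights."""

    def __init__(
        self,
        time_labels: Sequence[str],
        snapshots: Mapping[str, Snapshot],
        graph: nx.DiGraph,
        n_zero_edges: int,
        mode: str,
    ):
        self.time_labels = tuple(time_labels)
        self.snapshots = dict(snapshots)
        self.graph = graph
        self.n_zero_edges = n_zero_edges
        self.mode = mode
        self.layers: dict[str, tuple[str, ...]] = {t: () for t in self.time_labels}
        by_time: dict[str, list[str]] = {t: [] for t in self.time_labels}
        for sid, snap in self.snapshots.items():
            by_time[snap.time_label].append(sid)
        for t in self.time_labels:
            self.layers[t] = tuple(sorted(by_time[t]))

    @property
    def n_nodes(self) -> int:
        return len(self.snapshots)

    @property
    def n_edges(self) -> int:
        """Edges with nonzero transition weight."""
        return self.graph.number_of_edges()

    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(len(self.layers[t]) for t in self.time_labels)

    def edge_log_weight(self, u: str, v: str) -> float:
        data = self.graph.get_edge_data(u, v)
        return -math.inf if data is None else data["log_weight"]


def build_graph(
    snapshots_by_time: Mapping[str, Sequence[Snapshot]],
    mode: str = "constrained",
    transition_scorer: Callable[[Snapshot, Snapshot], float] | None = None,
) -> TrajectoryGraph:
    """Connect snapshots at adjacent time points into a scored layered DAG.

    ``snapshots_by_time`` maps ordered time labels to their snapshots.  The
    constrained mode weights edges by :func:`transition_allowed`; the
    unconstrained mode admits every adjacent pair with weight 1.  Zero-weight
    edges are counted but not stored.  A layer whose every node lacks an
    allowed outgoing edge makes any trajectory impossible and raises
    :class:`DeadLayerError`.
    """
    time_labels = tuple(snapshots_by_time)
    if not time_labels:
        raise ValueError("no time labels")
    for t in time_labels:
        if not snapshots_by_time[t]:
            raise ValueError(f"time label {t!r} has no snapshots")
    if transition_scorer is None:
        if mode == "constrained":
            transition_scorer = transition_allowed
        elif mode == "unconstrained":
            transition_scorer = lambda a, b: 1.0  # noqa: E731
        else:
            raise ValueError(f"unknown mode {mode!r}")

    snapshots: dict[str, Snapshot] = {}
    for t in time_labels:
        for snap in snapshots_by_time[t]:
            if snap.time_label != t:
                raise ValueError(f"snapshot {snap.id!r} labeled {snap.time_label!r} under {t!r}")
            if snap.id in snapshots:
                raise ValueError(f"duplicate snapshot id {snap.id!r}")
            snapshots[snap.id] = snap

    g = nx.DiGraph()
    g.add_nodes_from(snapshots)
    n_zero = 0
    for t_prev, t_next in zip(time_labels, time_labels[1:]):
        any_out = False
        for s1 in snapshots_by_time[t_prev]:
            for s2 in snapshots_by_time[t_next]:
                w = float(transition_scorer(s1, s2))
                if w > 0:
                    g.add_edge(s1.id, s2.id, log_weight=math.log(w))
                    any_out = True
                else:
                    n_zero += 1
        if not any_out:
            raise DeadLayerError(
                f"no allowed transition out of layer {t_prev!r}; no trajectory can exist"
            )
    return TrajectoryGraph(time_labels, snapshots, g, n_zero, mode)


def count_trajectories(graph: TrajectoryGraph) -> int:
    """Exact number of first-to-last-layer paths (dynamic programming)."""
    ways = {sid: 1 for sid in graph.layers[graph.time_labels[0]]}
    for t in graph.time_labels[1:]:
        nxt: dict[str, int] = {}
        for sid in graph.layers[t]:
            nxt[sid] = sum(ways.get(u, 0) for u in graph.graph.predecessors(sid))
        ways = nxt
    return sum(ways.values())


def enumerate_trajectories(
    graph: TrajectoryGraph, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[Trajectory]:
    """All positive-weight paths, in lexicographic node-id order.

    Raises :class:`EnumerationCapError` (never silently truncates) when the
    path count exceeds ``cap``; marginal quantities remain available through
    :func:`marginal_node_weights` and :func:`graph_model_precision`.
    """
    n = count_trajectories(graph)
    if n > cap:
        raise EnumerationCapError(
            f"{n} trajectories exceed the cap of {cap}; "
            "use marginal_node_weights / graph_model_precision instead"
        )
    last_layer = set(graph.layers[graph.time_labels[-1]])
    n_layers = len(graph.time_labels)
    out: list[Trajectory] = []
    stack: list[str] = []

    def dfs(node: str, depth: int) -> None:
        stack.append(node)
        if depth == n_layers - 1:
            if node in last_layer:
                out.append(Trajectory(tuple(stack)))
        else:
            for succ in sorted(graph.graph.successors(node)):
                dfs(succ, depth + 1)
        stack.pop()

    for start in graph.layers[graph.time_labels[0]]:
        dfs(start, 0)
    return out


def _path_log_weight(graph: TrajectoryGraph, ids: Sequence[str]) -> float:
    lw = 0.0
    for sid in ids:
        lw += graph.snapshots[sid].log_score
    for u, v in zip(ids, ids[1:]):
        elw = graph.edge_log_weight(u, v)
        if elw == -math.inf:
            return -math.inf
        lw += elw
    return lw


def score_trajectories(
    graph: TrajectoryGraph, trajectories: Sequence[Trajectory]
) -> list[Trajectory]:
    """Weight trajectories by the product of snapshot scores and transitions.

    Unnormalized log-weights are summed in log space and normalized so the
    weights sum to one; a trajectory through any zero-weight transition gets
    weight exactly 0.
    """
    raw = np.array([_path_log_weight(graph, t.snapshot_ids) for t in trajectories])
    finite = raw[np.isfinite(raw)]
    if finite.size == 0:
        raise ValueError("all trajectories have weight 0")
    log_z = float(logsumexp(finite))
    out = []
    for t, lw in zip(trajectories, raw):
        if lw == -math.inf:
            out.append(Trajectory(t.snapshot_ids, -math.inf, 0.0))
        else:
            norm = lw - log_z
            out.append(Trajectory(t.snapshot_ids, norm, math.exp(norm)))
    return out


def _forward_backward(
    graph: TrajectoryGraph, scale: float = 1.0
) -> tuple[dict[str, float], dict[str, float], float]:
    """Log-space forward/backward messages with all log-terms scaled by ``scale``.

    alpha(v): logsumexp over partial paths ending at v, including v's score.
    beta(v):  logsumexp over completions from v, excluding v's score.
    """
    s = {sid: scale * snap.log_score for sid, snap in graph.snapshots.items()}
    alpha: dict[str, float] = {}
    for sid in graph.layers[graph.time_labels[0]]:
        alpha[sid] = s[sid]
    for t in graph.time_labels[1:]:
        for sid in graph.layers[t]:
            terms = [
                alpha[u] + scale * graph.edge_log_weight(u, sid)
                for u in graph.graph.predecessors(sid)
                if u in alpha and alpha[u] > -math.inf
            ]
            alpha[sid] = float(logsumexp(terms)) + s[sid] if terms else -math.inf
    beta: dict[str, float] = {}
    for sid in graph.layers[graph.time_labels[-1]]:
        beta[sid] = 0.0
    for t in reversed(graph.time_labels[:-1]):
        for sid in graph.layers[t]:
            terms = [
                scale * graph.edge_log_weight(sid, v) + s[v] + beta[v]
                for v in graph.graph.successors(sid)
                if beta.get(v, -math.inf) > -math.inf
            ]
            beta[sid] = float(logsumexp(terms)) if terms else -math.inf
    last = [alpha[sid] for sid in graph.layers[graph.time_labels[-1]]]
    finite = [a for a in last if a > -math.inf]
    if not finite:
        raise DeadLayerError("no positive-weight trajectory reaches the final layer")
    log_z = float(logsumexp(finite))
    return alpha, beta, log_z


def graph_log_evidence(graph: TrajectoryGraph) -> float:
    """log of the sum over all trajectories of unnormalized trajectory scores."""
    return _forward_backward(graph)[2]


def marginal_node_weights(graph: TrajectoryGraph) -> dict[str, float]:
    """Summed normalized weight of all trajectories through each node.

    Computed by forward-backward dynamic programming in log space without
    materializing paths; within each layer the weights sum to 1.
    """
    alpha, beta, log_z = _forward_backward(graph)
    out: dict[str, float] = {}
    for sid in graph.snapshots:
        a, b = alpha.get(sid, -math.inf), beta.get(sid, -math.inf)
        out[sid] = 0.0 if a == -math.inf or b == -math.inf else math.exp(a + b - log_z)
    return out


def graph_model_precision(graph: TrajectoryGraph) -> float:
    """Model precision gamma = sum of squared normalized trajectory weights.

    Uses a second DP pass with doubled log-terms: gamma = Z2 / Z^2 where Z2
    sums squared path scores, so no trajectory set is materialized.
    """
    _, _, log_z = _forward_backward(graph, scale=1.0)
    _, _, log_z2 = _forward_backward(graph, scale=2.0)
    return float(math.exp(log_z2 - 2.0 * log_z))


def best_trajectory(graph: TrajectoryGraph) -> Trajectory:
    """Highest-weight trajectory (Viterbi max-sum), with normalized weight.

    Ties are broken toward the lexicographically smaller node id.
    """
    s = {sid: snap.log_score for sid, snap in graph.snapshots.items()}
    delta: dict[str, float] = {}
    back: dict[str, str] = {}
    for sid in graph.layers[graph.time_labels[0]]:
        delta[sid] = s[sid]
    for t in graph.time_labels[1:]:
        for sid in graph.layers[t]:
            best_u, best_val = None, -math.inf
            for u in sorted(graph.graph.predecessors(sid)):
                val = delta.get(u, -math.inf) + graph.edge_log_weight(u, sid)
                if val > best_val:
                    best_u, best_val = u, val
            delta[sid] = best_val + s[sid] if best_u is not None else -math.inf
            if best_u is not None:
                back[sid] = best_u
    last = graph.layers[graph.time_labels[-1]]
    end = min(last, key=lambda sid: (-delta.get(sid, -math.inf), sid))
    if delta.get(end, -math.inf) == -math.inf:
        raise DeadLayerError("no positive-weight trajectory reaches the final layer")
    ids = [end]
    while ids[-1] in back:
        ids.append(back[ids[-1]])
    ids.reverse()
    log_z = graph_log_evidence(graph)
    lw = delta[end] - log_z
    return Trajectory(tuple(ids), lw, math.exp(lw))
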
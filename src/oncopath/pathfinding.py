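"""Recursive enumeration of the K cheapest directed paths.

Edge scores are turned into costs with c(e) = 1 − OP(e), so that paths made
of high-scoring edges are cheap: for a fixed number of edges n, minimizing
the summed cost C is the same as maximizing the summed score n − C.

The enumerator is the recursive enumeration algorithm (REA) for k-shortest
paths: after one backward Dijkstra pass that yields, for every node v, the
optimal suffix path to the target, the k-th cheapest path at v is obtained
by popping a per-node candidate heap that is refilled lazily — when the
(k−1)-th path at v continues via neighbor u with u's j-th suffix, the single
new candidate is u's (j+1)-th suffix, computed on demand.  Paths are walks:
they may revisit nodes, exactly as the algorithm defines them.

Determinism: paths are totally ordered by (cost, edge count, node sequence).
This order is prefix-monotone (prepending an edge preserves it), which is
all REA's correctness argument needs, and unlike a pure lexicographic rule
it stays well defined when zero-cost cycles make equal-cost walks of every
length available.  Ties are therefore broken toward shorter walks, then
lexicographically smaller node sequences.

A guard (``max_hops``) can cap walk length to keep enumeration sane on
graphs with zero-cost cycles; by default no cap is applied, since a finite
K bounds the work regardless.
"""

from __future__ import annotations

import heapq
import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx

from .scoring import ScoredNetwork

logger = logging.getLogger("oncopath")


def op_to_cost(scored: ScoredNetwork) -> nx.DiGraph:
    """Cost graph with c(e) = 1 − OP(e) on every collapsed directed edge."""
    g = nx.DiGraph()
    g.add_nodes_from(scored.net.nodes)
    for (s, t), op in scored.op.items():
        if not 0.0 <= op <= 1.0:
            raise ValueError(f"OP {op} outside [0,1] on edge {(s, t)}")
        g.add_edge(s, t, cost=1.0 - op, OP=op)
    return g


@dataclass(frozen=True)
class Path:
    """A directed walk with its total cost."""

    nodes: tuple[int, ...]
    cost: float

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(zip(self.nodes[:-1], self.nodes[1:]))

    def is_simple(self) -> bool:
        return len(set(self.nodes)) == len(self.nodes)


# internal path record: (cost, n_nodes, node tuple, via node, via index)
_Rec = tuple[float, int, tuple[int, ...], int | None, int]


class _REA:
    """Per-target enumeration state shared across k requests."""

    def __init__(self, g: nx.DiGraph, t: int, max_hops: int | None) -> None:
        self.g = g
        self.t = t
        self.max_nodes = None if max_hops is None else max_hops + 1
        self.cost = {(u, v): d["cost"] for u, v, d in g.edges(data=True)}
        self.d = nx.single_source_dijkstra_path_length(g.reverse(copy=False), t, weight="cost")
        self._build_suffix_tree()
        self.paths: dict[int, list[_Rec]] = {}
        self.heap: dict[int, list[_Rec]] = {}
        self.init2: set[int] = set()
        self.stream_pushed: dict[int, bool] = {}
        self.no_more: dict[int, bool] = {}
        for v in self.d:
            self.paths[v] = [self._first_path(v)]
            self.heap[v] = []
            self.stream_pushed[v] = False
            self.no_more[v] = False

    # -- optimal suffix tree, ordered by (cost, hops, sequence) -----------

    def _build_suffix_tree(self) -> None:
        d = self.d
        optimal_pred: dict[int, list[int]] = {v: [] for v in d}
        for (u, v), c in self.cost.items():
            # edge u->v is on a cheapest suffix from u iff c + d[v] == d[u]
            if u in d and v in d and c + d[v] == d[u]:
                optimal_pred[v].append(u)
        hops: dict[int, int] = {self.t: 0}
        queue = deque([self.t])
        while queue:
            v = queue.popleft()
            for u in optimal_pred[v]:
                if u not in hops:
                    hops[u] = hops[v] + 1
                    queue.append(u)
        self.hops = hops
        succ: dict[int, int] = {}
        for v in d:
            if v == self.t:
                continue
            best = [
                u
                for u in self.g.successors(v)
                if u in d
                and self.cost[(v, u)] + self.d[u] == self.d[v]
                and hops.get(u, -2) == hops[v] - 1
            ]
            succ[v] = min(best)
        self.succ = succ

    def _first_path(self, v: int) -> _Rec:
        if v == self.t:
            return (0.0, 1, (v,), None, 0)
        chain = [v]
        while chain[-1] != self.t:
            chain.append(self.succ[chain[-1]])
        return (self.d[v], len(chain), tuple(chain), self.succ[v], 1)

    # -- lazy candidate machinery ----------------------------------------

    def _push(self, v: int, u: int, j: int) -> None:
        """Push the candidate 'v followed by the j-th path at u' (1-based)."""
        cost, n, nodes, *_ = self.paths[u][j - 1]
        if self.max_nodes is not None and n + 1 > self.max_nodes:
            return
        heapq.heappush(
            self.heap[v], (self.cost[(v, u)] + cost, n + 1, (v,) + nodes, u, j)
        )

    def _init_candidates(self, v: int) -> None:
        tree_succ = self.succ.get(v)
        for u in self.g.successors(v):
            if u in self.d and u != tree_succ:
                self._push(v, u, 1)
        self.init2.add(v)

    def _advance(self, v: int) -> None:
        """Produce the next path at v, driving dependencies iteratively."""
        work = [v]
        while work:
            x = work[-1]
            if self.no_more[x]:
                work.pop()
                continue
            if x not in self.init2:
                self._init_candidates(x)
            if not self.stream_pushed[x]:
                *_, via_u, via_j = self.paths[x][-1]
                if via_u is not None:
                    need = via_j + 1
                    if len(self.paths[via_u]) >= need:
                        self._push(x, via_u, need)
                    elif not self.no_more[via_u]:
                        work.append(via_u)  # one advance at via_u suffices
                        continue
                    # else: stream exhausted, no candidate
                self.stream_pushed[x] = True
            if self.heap[x]:
                self.paths[x].append(heapq.heappop(self.heap[x]))
                self.stream_pushed[x] = False
            else:
                self.no_more[x] = True
            work.pop()

    def kth(self, v: int, k: int) -> _Rec | None:
        """1-based k-th cheapest path from v to the target, or None."""
        while len(self.paths[v]) < k and not self.no_more[v]:
            self._advance(v)
        if len(self.paths[v]) >= k:
            return self.paths[v][k - 1]
        return None


def rea_k_shortest_paths(
    g: nx.DiGraph, s: int, t: int, K: int, max_hops: int | None = None
) -> list[Path]:
    """The min(K, available) cheapest directed walks s→t in nondecreasing
    (cost, edge count, node sequence) order.

    ``g`` must carry a non-negative ``cost`` attribute on every edge.
    Returns an empty list (with a logged warning) when t is unreachable.
    """
    if s not in g or t not in g:
        raise ValueError(f"source {s} or target {t} not in graph")
    if s == t:
        raise ValueError("source and target must differ")
    if K < 1:
        raise ValueError("K must be >= 1")
    if any(d["cost"] < 0 for *_, d in g.edges(data=True)):
        raise ValueError("negative edge cost")
    state = _REA(g, t, max_hops)
    if s not in state.d:
        logger.warning("target %s unreachable from source %s", t, s)
        return []
    out: list[Path] = []
    for k in range(1, K + 1):
        rec = state.kth(s, k)
        if rec is None:
            break
        cost, _, nodes, *_ = rec
        out.append(Path(nodes=nodes, cost=cost))
    return out


def paths_prefixes(paths: list[Path], k_ladder: list[int]) -> dict[int, list[Path]]:
    """Split one enumeration into the per-K groups of a K ladder.

    Enumeration order is deterministic, so the first K paths of a longer run
    equal a run with that K.
    """
    return {k: paths[: min(k, len(paths))] for k in k_ladder}


#: the default K ladder: 100..1000 step 100, 2000..10000 step 1000,
#: 20000..100000 step 10000, 200000..1000000 step 100000,
#: 1500000..3000000 step 500000 (41 values)
DEFAULT_K_LADDER: list[int] = (
    list(range(100, 1001, 100))
    + list(range(2000, 10001, 1000))
    + list(range(20000, 100001, 10000))
    + list(range(200000, 1000001, 100000))
    + list(range(1500000, 3000001, 500000))
)
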
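"""Threshold subnetworks and clustering-based selection.

Each group of K enumerated paths for a source/target pair is turned into a
candidate signaling subnetwork in four moves:

1. every path's cost C is converted to a weight W = n − C, with n the number
   of edges — equivalently the summed OP of the path's edges;
2. weights are min–max normalized within the group,
   W_norm = (W − W_min) / (W_max − W_min); when all weights coincide the
   normalization is undefined and every path is assigned W_norm = 1 so that
   the procedure stays well defined (every path survives every threshold);
3. twenty candidates are built for thresholds θ = 0, 0.05, …, 0.95, each
   merging the edges of all paths with W_norm ≥ θ;
4. the candidate with the highest average clustering coefficient (mean over
   the candidate's own nodes of the undirected local clustering, nodes with
   fewer than two neighbors contributing 0) wins; ties go to the candidate
   with fewer edges, then to the larger θ — the most specific subnetwork.

Running the sweep for every K of a ladder and taking the best per-K winner
by the same rule yields the final extracted subnetwork for the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .pathfinding import Path, paths_prefixes, rea_k_shortest_paths, op_to_cost
from .scoring import ScoredNetwork
from .training import Edge

logger = logging.getLogger("oncopath")

THETA_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(20))


@dataclass
class PathGroup:
    """The K cheapest paths for one source/target pair, with weights."""

    source: int
    target: int
    K: int
    paths: list[Path]
    weights: np.ndarray | None = None
    norm_weights: np.ndarray | None = None


def path_weights(pg: PathGroup) -> PathGroup:
    """W = n − C per path (the summed OP of its edges)."""
    pg.weights = np.array([p.n_edges - p.cost for p in pg.paths])
    return pg


def normalize_weights(pg: PathGroup) -> PathGroup:
    """Min–max normalization of W within the group; all-equal groups map to 1."""
    if pg.weights is None:
        pg = path_weights(pg)
    w = pg.weights
    if len(w) == 0:
        raise ValueError("empty path group")
    lo, hi = float(w.min()), float(w.max())
    if hi == lo:
        pg.norm_weights = np.ones_like(w)
    else:
        pg.norm_weights = (w - lo) / (hi - lo)
    return pg


@dataclass
class SubnetworkCandidate:
    """Merged edge set of the paths surviving one threshold."""

    theta: float
    edges: set[Edge] = field(default_factory=set)
    n_paths: int = 0
    avg_cc: float = 0.0
    K: int | None = None

    @property
    def nodes(self) -> set[int]:
        return {n for e in self.edges for n in e}

    @property
    def empty(self) -> bool:
        return not self.edges


def average_clustering(edges: set[Edge]) -> float:
    """Mean undirected local clustering over the edge set's own nodes."""
    if not edges:
        return 0.0
    g = nx.Graph()
    g.add_edges_from(edges)
    return float(np.mean(list(nx.clustering(g).values())))


def build_threshold_subnetworks(pg: PathGroup) -> list[SubnetworkCandidate]:
    """Exactly 20 candidates, θ from 0 to 0.95 in steps of 0.05.

    Candidate θ merges the edges of every path with W_norm ≥ θ; candidates
    retaining no path stay empty (they are skipped by selection).  Edge sets
    are nested: a larger θ keeps a subset of the paths, hence of the edges.
    """
    if pg.norm_weights is None:
        pg = normalize_weights(pg)
    cands = []
    for theta in THETA_GRID:
        keep = [p for p, wn in zip(pg.paths, pg.norm_weights) if wn >= theta]
        edges: set[Edge] = set()
        for p in keep:
            edges.update(p.edges)
        cands.append(
            SubnetworkCandidate(
                theta=theta,
                edges=edges,
                n_paths=len(keep),
                avg_cc=average_clustering(edges),
                K=pg.K,
            )
        )
    return cands


def _selection_key(c: SubnetworkCandidate) -> tuple[float, int, float]:
    # max avg_cc, tie -> fewer edges, tie -> larger theta
    return (c.avg_cc, -len(c.edges), c.theta)


def select_by_clustering(cands: list[SubnetworkCandidate]) -> SubnetworkCandidate:
    """The non-empty candidate maximizing average clustering coefficient."""
    nonempty = [c for c in cands if not c.empty]
    if not nonempty:
        raise ValueError("all candidates are empty")
    return max(nonempty, key=_selection_key)


@dataclass
class ExtractionResult:
    source: int
    target: int
    candidate: SubnetworkCandidate | None
    status: str  # "ok" or an explanation for an empty result
    per_k: dict[int, SubnetworkCandidate] = field(default_factory=dict)


def extract_signaling_subnetwork(
    scored: ScoredNetwork,
    s: int,
    t: int,
    k_ladder: list[int],
    max_hops: int | None = None,
    simple_only: bool = False,
) -> ExtractionResult:
    """Full extraction for one source/target pair across a K ladder.

    For each K: enumerate the K cheapest paths, weight and normalize them,
    build the 20 threshold candidates and pick the per-K winner; the final
    subnetwork is the per-K winner with the highest average clustering
    coefficient (same tie rule, then the smaller K).  One enumeration at the
    ladder maximum supplies every K group as a prefix.  ``simple_only``
    drops node-revisiting walks before subnetwork construction.
    """
    g = op_to_cost(scored)
    all_paths = rea_k_shortest_paths(g, s, t, max(k_ladder), max_hops=max_hops)
    if not all_paths:
        return ExtractionResult(s, t, None, status=f"{t} unreachable from {s}")
    per_k: dict[int, SubnetworkCandidate] = {}
    for k, group in paths_prefixes(all_paths, sorted(k_ladder)).items():
        if simple_only:
            group = [p for p in group if p.is_simple()]
        if not group:
            continue
        pg = normalize_weights(path_weights(PathGroup(s, t, k, list(group))))
        cands = build_threshold_subnetworks(pg)
        per_k[k] = select_by_clustering(cands)
    if not per_k:
        return ExtractionResult(s, t, None, status="no usable paths")
    best_k = max(per_k, key=lambda k: _selection_key(per_k[k]) + (-k,))
    return ExtractionResult(s, t, per_k[best_k], status="ok", per_k=per_k)


def write_sif(cand: SubnetworkCandidate, scored: ScoredNetwork, path: str) -> None:
    """Cytoscape-ready SIF export; the type column joins the edge's itypes."""
    with open(path, "w") as fh:
        for sgene, tgene in sorted(cand.edges):
            types = "|".join(sorted(scored.net.edge_types(sgene, tgene))) or "edge"
            fh.write(f"{sgene}\t{types}\t{tgene}\n")
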
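"""Vote ensemble, oncogenic-potential scores and edge-set enrichment.

All bagged models trained on the normal datasets are merged into one vote
ensemble whose output for an edge is the arithmetic mean of member outputs —
equivalently, with equal bag sizes, the mean over every constituent tree.
That mean is the edge's oncogenic potential OP in [0, 1]; parallel typed
edges of an ordered gene pair share one OP because the features depend only
on the endpoints.

Enrichment of a designated edge set among high-OP edges is assessed with an
upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import InteractionNetwork
from .training import BaggedTreeModel, Edge, build_edge_features

logger = logging.getLogger("oncopath")


@dataclass
class VoteEnsemble:
    """Average-of-probabilities combination of bagged models."""

    members: list[BaggedTreeModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        sigs = {m.n_features_ for m in self.members}
        if len(sigs) != 1 or None in sigs:
            raise ValueError(f"mixed or unfitted feature signatures: {sigs}")

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba_pos(X) for m in self.members], axis=0)


def combine_models(models: list[BaggedTreeModel]) -> VoteEnsemble:
    return VoteEnsemble(list(models))


@dataclass
class ScoredNetwork:
    """An interaction network with one OP score per collapsed directed edge."""

    net: InteractionNetwork
    op: dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.net.simple_edges() - set(self.op)
        if missing:
            raise ValueError(f"{len(missing)} edges lack OP scores")
        bad = [e for e, v in self.op.items() if not 0.0 <= v <= 1.0]
        if bad:
            raise ValueError(f"OP outside [0,1] for edges {bad[:5]}")


def assign_scores(
    net: InteractionNetwork, cent: pd.DataFrame, ens: VoteEnsemble
) -> ScoredNetwork:
    """Score every collapsed edge of the network with the vote ensemble."""
    edges = sorted(net.simple_edges())
    missing = [e for e in edges for g in e if g not in cent.index]
    if missing:
        raise ValueError(f"edges with endpoints missing from centralities: {missing[:5]}")
    x = build_edge_features(cent, edges)
    scores = ens.score(x)
    return ScoredNetwork(net, dict(zip(edges, map(float, scores))))


@dataclass
class EnrichmentResult:
    population: int  # N: all edges
    population_successes: int  # K: special edges in the network
    sample: int  # n: edges above the OP threshold
    sample_successes: int  # s: special edges above the threshold
    p_value: float


def enrichment_test(
    scored: ScoredNetwork, special: set[Edge], threshold: float = 0.7
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of ``special`` edges
    among edges with OP strictly above ``threshold``.

    p = P(X >= s) for X ~ Hypergeom(N, K, n).
    """
    edges = scored.net.simple_edges()
    if not special <= edges:
        raise ValueError("special edges must be a subset of network edges")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    high = {e for e in edges if scored.op[e] > threshold}
    n_pop, n_k, n_sample = len(edges), len(special), len(high)
    n_s = len(high & special)
    if n_sample == 0:
        logger.warning("no edges above OP threshold %.2f", threshold)
        return EnrichmentResult(n_pop, n_k, 0, 0, 1.0)
    p = float(stats.hypergeom.sf(n_s - 1, n_pop, n_k, n_sample))
    return EnrichmentResult(n_pop, n_k, n_sample, n_s, min(p, 1.0))
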
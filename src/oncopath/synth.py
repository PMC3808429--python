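"""Seeded synthetic networks, planted positives, and planted backbones.

Real integrated gene networks are heavy-tailed: a few hub genes concentrate
most interactions.  The generator therefore grows a preferential-attachment
(Barabási–Albert) skeleton and types each undirected link by a configurable
mixture; physical links become both directed edges (a physical contact
transmits signal either way) while regulatory and metabolic links get one
random orientation.  The high share of bidirectional edges keeps the bulk of
the network mutually reachable, as in the real composite network.

Planted structure makes every downstream stage testable without downloads:

- *positives*: a set of edges whose endpoints are biased toward the
  high-degree stratum (top decile by degree).  Because degree — and the
  centralities correlated with it — is a training feature, these edges carry
  a learnable signal; ``centrality_shift=0`` turns the bias off and yields a
  null dataset on which any apparent model skill is overfitting.
- *backbones*: an explicit directed chain s → … → t inserted into the
  network and returned as a reference linear pathway, so extraction can be
  checked for exact recovery once the chain's edges are given high scores.

The generator does not emulate everything about real data: no assortativity
structure, no per-database noise or confidence scores, and the planted
signal is purely centrality-based by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .centrality import degree_centrality
from .evaluation import LinearPathway
from .network import Interaction, InteractionNetwork
from .training import Edge

INTERACTION_TYPES = ("physical", "regulatory", "metabolic")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the desk-scale study setup: ~2000 genes with 3
    attachments per new node (heavy-tailed degrees), a 70/20/10
    physical/regulatory/metabolic mixture echoing the real network's
    dominance of physical interactions, 265 planted positive edges, and a
    full-strength centrality shift so the positives are learnable.
    """

    n_genes: int = 2000
    m_attach: int = 3
    type_mixture: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_positives: int = 265
    centrality_shift: float = 1.0  # fraction of positives drawn from the hub stratum
    stratum_quantile: float = 0.9  # degree quantile defining the hub stratum
    backbone_length: int = 4
    backbone_op: float = 0.95  # score given to backbone edges in boosted scoring
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_positives < 1 or self.m_attach < 1:
            raise ValueError("counts must be positive")
        if abs(sum(self.type_mixture) - 1.0) > 1e-9:
            raise ValueError("type mixture must sum to 1")
        if not 0.0 <= self.centrality_shift <= 1.0:
            raise ValueError("centrality_shift must lie in [0,1]")


def generate_network(cfg: SynthConfig) -> InteractionNetwork:
    """Seeded scale-free-ish directed typed network.

    Gene ids are 1..n_genes.  A degenerate configuration (n_genes too small
    to attach) yields a network of isolated nodes.
    """
    net = InteractionNetwork()
    for gene in range(1, cfg.n_genes + 1):
        net.add_node(gene)
    if cfg.n_genes <= cfg.m_attach:
        return net
    rng = np.random.default_rng(cfg.seed)
    skeleton = nx.barabasi_albert_graph(cfg.n_genes, cfg.m_attach, seed=int(cfg.seed))
    for a, b in sorted(skeleton.edges()):
        s, t = a + 1, b + 1  # gene ids are 1-based
        itype = INTERACTION_TYPES[rng.choice(3, p=cfg.type_mixture)]
        if itype == "physical":
            net.add(Interaction(s, t, itype))
            net.add(Interaction(t, s, itype))
        else:
            if rng.random() < 0.5:
                s, t = t, s
            net.add(Interaction(s, t, itype))
    return net


def directed_reachability_fraction(net: InteractionNetwork) -> float:
    """Fraction of ordered node pairs of the largest weak component joined
    by a directed path (diagnostic for generator connectivity)."""
    g = net.to_digraph()
    if g.number_of_nodes() < 2:
        return 0.0
    comp = max(nx.weakly_connected_components(g), key=len)
    sub = g.subgraph(comp)
    n = sub.number_of_nodes()
    reachable = sum(
        len(nx.descendants(sub, v)) for v in sub
    )
    return reachable / (n * (n - 1))


def plant_positive_edges(net: InteractionNetwork, cfg: SynthConfig) -> list[Edge]:
    """Sample the planted positive edge set.

    A fraction ``centrality_shift`` of the positives is drawn from edges
    whose two endpoints both sit in the top-decile degree stratum; the rest
    are uniform over the remaining edges.  With shift 0 this is a plain
    uniform sample (the null case)."""
    rng = np.random.default_rng(cfg.seed + 1)
    edges = sorted(net.simple_edges())
    if len(edges) < cfg.n_positives:
        raise ValueError("network has fewer edges than requested positives")
    degree = degree_centrality(net)
    cut = float(np.quantile(list(degree.values()), cfg.stratum_quantile))
    stratum = {g for g, k in degree.items() if k >= cut}
    hub_edges = [e for e in edges if e[0] in stratum and e[1] in stratum]
    n_hub = round(cfg.centrality_shift * cfg.n_positives)
    if len(hub_edges) < n_hub:
        raise ValueError(
            f"hub stratum supplies only {len(hub_edges)} edges, "
            f"need {n_hub}"
        )
    chosen: list[Edge] = [
        hub_edges[i] for i in rng.choice(len(hub_edges), size=n_hub, replace=False)
    ]
    rest_pool = sorted(set(edges) - set(chosen))
    n_rest = cfg.n_positives - n_hub
    chosen += [
        rest_pool[i] for i in rng.choice(len(rest_pool), size=n_rest, replace=False)
    ]
    return sorted(chosen)


def plant_backbone(
    net: InteractionNetwork,
    s: int,
    t: int,
    length: int,
    seed: int = 0,
) -> LinearPathway:
    """Insert (or reuse) a directed chain s → v1 → … → t of ``length`` edges.

    Intermediate nodes are drawn from the network's other nodes; chain edges
    absent from the network are added with type ``regulatory``.  The chain
    is returned as a reference linear pathway for later recovery checks.
    """
    if s == t:
        raise ValueError("backbone endpoints must differ")
    if length < 3:
        raise ValueError("backbone length must be at least 3")
    rng = np.random.default_rng(seed)
    pool = sorted(net.nodes - {s, t})
    if len(pool) < length - 1:
        raise ValueError("not enough nodes for backbone intermediates")
    mids = [pool[i] for i in rng.choice(len(pool), size=length - 1, replace=False)]
    chain = [s, *mids, t]
    for a, b in zip(chain[:-1], chain[1:]):
        if (a, b) not in net.simple_edges():
            net.add(Interaction(a, b, "regulatory"))
    return LinearPathway(tuple(chain), tag=f"backbone_{s}_{t}")


def boost_backbone_scores(
    op: dict[Edge, float], olp: LinearPathway, backbone_op: float
) -> dict[Edge, float]:
    """Copy of an OP map with the backbone's edges raised to ``backbone_op``."""
    out = dict(op)
    for e in olp.edges:
        out[e] = backbone_op
    return out


def write_dataset(
    outdir: str | Path,
    net: InteractionNetwork,
    positives: list[Edge],
    olps: list[LinearPathway],
    cfg: SynthConfig,
) -> None:
    """Emit edge-list TSV, positives TSV, pathway file, and a seed manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "network.tsv", "w") as fh:
        fh.write("# source\ttarget\titype\n")
        for s, t, ty in sorted(net.typed_edges):
            fh.write(f"{s}\t{t}\t{ty}\n")
    with open(outdir / "positives.tsv", "w") as fh:
        for s, t in positives:
            fh.write(f"{s}\t{t}\n")
    with open(outdir / "pathways.tsv", "w") as fh:
        for olp in olps:
            genes = "\t".join(str(g) for g in olp.genes)
            tag = f"{olp.tag}: " if olp.tag else ""
            fh.write(f"{tag}{genes}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(cfg).items()
                },
                "n_genes": len(net),
                "n_typed_edges": net.n_edges(),
            },
            fh,
            indent=2,
        )
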
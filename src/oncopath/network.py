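"""Integrated directed gene-interaction networks.

The object of study is a directed network over genes (opaque positive-integer
identifiers, Entrez-style) whose edges come in three flavors:

``physical``
    protein–protein interactions; experimentally these are undirected, so each
    reported pair {A, B} is expanded into the two directed edges A→B and B→A,
    because a physical contact can transmit signal either way.
``regulatory``
    transcription-factor → target-gene regulation; inherently directed.
``metabolic``
    enzyme → enzyme edges derived from a reaction table: E1→E2 whenever a
    reaction catalysed by E1 produces a metabolite that a reaction catalysed
    by E2 consumes.  Ubiquitous "currency" metabolites (ATP, H2O, ...) are
    excluded so that shared cofactors do not create meaningless shortcuts.

An ordered gene pair may carry up to three typed edges; typed parallel edges
are stored distinctly (so per-type counts are additive) but every downstream
computation — centralities, path search — works on the collapsed simple
digraph, and an edge score is shared by all typed variants of the same
ordered pair.

Self-interactions are dropped everywhere: a loop at a single node carries no
signal-flow meaning in this model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger("oncopath")

INTERACTION_TYPES = ("physical", "regulatory", "metabolic")

#: default currency metabolites, standing in for the eight most connected
#: metabolites of a genome-scale human reconstruction
DEFAULT_CURRENCY = frozenset(
    {"ADP", "ATP", "H+", "H2O", "NADP+", "NADPH", "Pi", "PPi"}
)


class ParseError(ValueError):
    """Malformed input row; message names the offending line number."""


@dataclass(frozen=True)
class Interaction:
    """One directed, typed gene interaction."""

    source: int
    target: int
    itype: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-interaction {self.source}->{self.target}")
        if self.source <= 0 or self.target <= 0:
            raise ValueError("gene ids must be positive integers")
        if self.itype not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")


class InteractionNetwork:
    """Directed gene network with typed, possibly parallel edges.

    Nodes are gene ids; edges are (source, target, itype) triples stored as a
    set, so at most one edge exists per triple and typed parallel edges of
    the same ordered pair are counted separately.
    """

    def __init__(
        self,
        interactions: Iterable[Interaction] = (),
        nodes: Iterable[int] = (),
        provenance: str | None = None,
    ) -> None:
        self._edges: set[tuple[int, int, str]] = set()
        self._nodes: set[int] = set(nodes)
        self.provenance: list[str] = [provenance] if provenance else []
        for ia in interactions:
            self.add(ia)

    # -- construction -----------------------------------------------------

    def add(self, ia: Interaction) -> None:
        self._edges.add((ia.source, ia.target, ia.itype))
        self._nodes.add(ia.source)
        self._nodes.add(ia.target)

    def add_node(self, gene: int) -> None:
        self._nodes.add(int(gene))

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> set[int]:
        return set(self._nodes)

    @property
    def typed_edges(self) -> set[tuple[int, int, str]]:
        return set(self._edges)

    def simple_edges(self) -> set[tuple[int, int]]:
        """Collapsed directed edges: typed variants merged per ordered pair."""
        return {(s, t) for s, t, _ in self._edges}

    def edge_types(self, source: int, target: int) -> set[str]:
        return {ty for s, t, ty in self._edges if (s, t) == (source, target)}

    def n_edges(self, itype: str | None = None) -> int:
        if itype is None:
            return len(self._edges)
        return sum(1 for *_, ty in self._edges if ty == itype)

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[tuple[int, int, str]]:
        return iter(sorted(self._edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return (
            f"InteractionNetwork({len(self._nodes)} genes, "
            f"{len(self._edges)} typed edges)"
        )

    def to_digraph(self) -> nx.DiGraph:
        """Collapsed simple digraph used for centralities and path search."""
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self.simple_edges())
        return g

    # -- serialization ----------------------------------------------------

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, t, ty in sorted(self._edges):
                fh.write(f"{s}\t{ty}\t{t}\n")
            for gene in sorted(self._nodes - {n for e in self._edges for n in e[:2]}):
                fh.write(f"{gene}\n")

    def write_graphml(self, path: str | Path, op: dict[tuple[int, int], float] | None = None) -> None:
        """Export as GraphML (one multi-edge per typed triple).

        When ``op`` is given, each edge also carries its score as attribute
        ``OP`` (shared by all typed variants of an ordered pair).
        """
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._nodes)
        for s, t, ty in sorted(self._edges):
            attrs = {"itype": ty}
            if op is not None:
                attrs["OP"] = float(op[(s, t)])
            g.add_edge(s, t, **attrs)
        nx.write_graphml(g, path)

    @classmethod
    def read_graphml(cls, path: str | Path) -> "InteractionNetwork":
        g = nx.read_graphml(path)
        net = cls()
        for n in g.nodes:
            net.add_node(int(n))
        for u, v, data in g.edges(data=True):
            net.add(Interaction(int(u), int(v), data["itype"]))
        return net

    @classmethod
    def read_sif(cls, path: str | Path) -> "InteractionNetwork":
        net = cls(provenance=str(path))
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts or line.startswith("#"):
                    continue
                if len(parts) == 1:
                    net.add_node(_parse_gene(parts[0], path, lineno))
                    continue
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 1 or 3 columns")
                s = _parse_gene(parts[0], path, lineno)
                t = _parse_gene(parts[2], path, lineno)
                if s == t:
                    logger.info("%s:%d: dropping self-interaction %d", path, lineno, s)
                    continue
                net.add(Interaction(s, t, parts[1]))
        return net


def _parse_gene(token: str, path: str | Path, lineno: int) -> int:
    try:
        gene = int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer gene id {token!r}") from None
    if gene <= 0:
        raise ParseError(f"{path}:{lineno}: gene id must be positive, got {gene}")
    return gene


def read_edge_list(path: str | Path, itype: str | None = None) -> InteractionNetwork:
    """Read a TSV edge list ``source<TAB>target[<TAB>itype]``.

    ``itype`` supplies the type for two-column rows; three-column rows carry
    their own.  Duplicate (source, target, itype) rows collapse to one edge;
    self-loops are dropped with a logged count.  Lines starting with ``#``
    are comments.  An empty file yields an empty network with a warning.
    """
    net = InteractionNetwork(provenance=str(path))
    n_loops = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            s = _parse_gene(parts[0], path, lineno)
            t = _parse_gene(parts[1], path, lineno)
            row_type = parts[2] if len(parts) > 2 else itype
            if row_type is None:
                raise ParseError(f"{path}:{lineno}: no interaction type given")
            if row_type not in INTERACTION_TYPES:
                raise ParseError(f"{path}:{lineno}: unknown interaction type {row_type!r}")
            n_rows += 1
            if s == t:
                n_loops += 1
                continue
            net.add(Interaction(s, t, row_type))
    if n_loops:
        logger.info("%s: dropped %d self-loop rows", path, n_loops)
    if n_rows == 0:
        logger.warning("%s: empty edge list", path)
    return net


def direct_physical_edges(
    undirected_pairs: Iterable[tuple[int, int]]
) -> InteractionNetwork:
    """Expand undirected protein pairs into both directed physical edges.

    Each pair {A, B} with A != B yields A→B and B→A; pairs with A == B are
    dropped and logged.
    """
    net = InteractionNetwork()
    n_loops = 0
    for a, b in undirected_pairs:
        if a == b:
            n_loops += 1
            continue
        net.add(Interaction(a, b, "physical"))
        net.add(Interaction(b, a, "physical"))
    if n_loops:
        logger.info("dropped %d self-pairs during physical-edge direction", n_loops)
    return net


@dataclass
class Reaction:
    reaction_id: str
    enzymes: tuple[int, ...]
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValueError(f"reaction {self.reaction_id}: no enzymes")
        if not (self.reactants or self.products):
            raise ValueError(f"reaction {self.reaction_id}: no metabolites")


@dataclass
class ReactionTable:
    """Simple reaction table from which metabolic edges are derived."""

    reactions: list[Reaction] = field(default_factory=list)
    currency: frozenset[str] = DEFAULT_CURRENCY

    @classmethod
    def read_tsv(
        cls, path: str | Path, currency: Iterable[str] | None = None
    ) -> "ReactionTable":
        """Read ``reaction_id<TAB>enzymes<TAB>reactants<TAB>products<TAB>rev``.

        Enzyme and metabolite fields are comma-separated; the reversible flag
        is 0/1; an empty metabolite field is written ``-``.
        """
        rows: list[Reaction] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 5:
                    raise ParseError(f"{path}:{lineno}: expected 5 columns")
                rid, enz, reac, prod, rev = parts
                try:
                    enzymes = tuple(int(e) for e in enz.split(",") if e)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer enzyme id") from None
                rows.append(
                    Reaction(
                        rid,
                        enzymes,
                        tuple(m for m in reac.split(",") if m and m != "-"),
                        tuple(m for m in prod.split(",") if m and m != "-"),
                        rev == "1",
                    )
                )
        cur = DEFAULT_CURRENCY if currency is None else frozenset(currency)
        return cls(rows, cur)

    def metabolite_degree(self) -> dict[str, int]:
        """Number of reactions each metabolite participates in."""
        deg: dict[str, int] = {}
        for rx in self.reactions:
            for m in set(rx.reactants) | set(rx.products):
                deg[m] = deg.get(m, 0) + 1
        return deg

    def top_connected_metabolites(self, m: int = 8) -> frozenset[str]:
        """Alternative currency rule: the m most-connected metabolites."""
        deg = self.metabolite_degree()
        ranked = sorted(deg, key=lambda k: (-deg[k], k))
        return frozenset(ranked[:m])


def derive_metabolic_interactions(rt: ReactionTable) -> InteractionNetwork:
    """Enzyme→enzyme edges through shared non-currency metabolites.

    For every metabolite M outside the currency set, every enzyme of a
    reaction producing M is linked to every enzyme of a reaction consuming M.
    A reversible reaction plays both roles: its reactants double as products
    and vice versa.
    """
    known = {m for rx in rt.reactions for m in set(rx.reactants) | set(rx.products)}
    for m in rt.currency - known:
        logger.warning("currency metabolite %r absent from reaction table", m)

    producers: dict[str, set[int]] = {}
    consumers: dict[str, set[int]] = {}
    for rx in rt.reactions:
        produced = set(rx.products) | (set(rx.reactants) if rx.reversible else set())
        consumed = set(rx.reactants) | (set(rx.products) if rx.reversible else set())
        for m in produced - rt.currency:
            producers.setdefault(m, set()).update(rx.enzymes)
        for m in consumed - rt.currency:
            consumers.setdefault(m, set()).update(rx.enzymes)

    net = InteractionNetwork()
    for gene in {e for rx in rt.reactions for e in rx.enzymes}:
        net.add_node(gene)
    for m, prods in producers.items():
        for e1 in prods:
            for e2 in consumers.get(m, ()):  # noqa: B020
                if e1 != e2:
                    net.add(Interaction(e1, e2, "metabolic"))
    return net


def integrate(parts: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Union of typed networks over a shared gene-id namespace.

    Node set and typed-edge set are plain set unions, so identical
    (source, target, itype) triples appearing in several parts count once
    while typed parallel edges of different types stay distinct.
    """
    merged = InteractionNetwork()
    for part in parts:
        merged._nodes |= part._nodes
        merged._edges |= part._edges
        merged.provenance.extend(part.provenance)
    return merged
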
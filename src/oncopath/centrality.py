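"""Node centralities used as training features.

Four per-gene measures are computed on the collapsed simple digraph:

- degree ``k``: in-degree + out-degree (a bidirectionalized physical pair
  contributes 2 to each endpoint);
- clustering coefficient ``C``: computed on the undirected projection,
  C(i) = 2 e(i) / (n(i) (n(i)-1)) with n(i) the neighbor count and e(i) the
  number of links among neighbors, 0 when n(i) < 2;
- betweenness ``B``: directed, unnormalized pair-fraction sum
  B(i) = Σ_{s≠t≠i} σ_st(i)/σ_st over unweighted shortest paths;
- closeness ``Cl``: along outgoing edges, with r(i) nodes reachable from i
  and S(i) the sum of their distances, Cl(i) = (r/S)·(r/(N-1)) and 0 when
  nothing is reachable.  The second factor scales partially-reaching nodes
  down so values are comparable across components and bounded in [0, 1].

Betweenness is left unnormalized on purpose: the downstream tree learners
only ever threshold features, so any monotone rescaling is model-equivalent,
but one convention has to be fixed for reproducibility.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .network import InteractionNetwork

COLUMNS = ("degree", "clustering", "betweenness", "closeness")


def degree_centrality(net: InteractionNetwork) -> dict[int, int]:
    g = net.to_digraph()
    return {i: g.in_degree(i) + g.out_degree(i) for i in g}


def clustering_coefficient(net: InteractionNetwork) -> dict[int, float]:
    g = net.to_digraph().to_undirected()
    return nx.clustering(g)


def betweenness_centrality(net: InteractionNetwork) -> dict[int, float]:
    return nx.betweenness_centrality(net.to_digraph(), normalized=False)


def closeness_centrality(net: InteractionNetwork) -> dict[int, float]:
    g = net.to_digraph()
    n = g.number_of_nodes()
    out: dict[int, float] = {}
    for i in g:
        lengths = nx.single_source_shortest_path_length(g, i)
        r = len(lengths) - 1  # excludes i itself
        if r == 0 or n < 2:
            out[i] = 0.0
            continue
        s = sum(lengths.values())
        out[i] = (r / s) * (r / (n - 1))
    return out


def centrality_table(net: InteractionNetwork) -> pd.DataFrame:
    """All four centralities as a DataFrame indexed by gene id."""
    table = pd.DataFrame(
        {
            "degree": pd.Series(degree_centrality(net), dtype=float),
            "clustering": pd.Series(clustering_coefficient(net), dtype=float),
            "betweenness": pd.Series(betweenness_centrality(net), dtype=float),
            "closeness": pd.Series(closeness_centrality(net), dtype=float),
        }
    )
    table.index.name = "gene"
    return table.sort_index()


def write_centralities(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_centralities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
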
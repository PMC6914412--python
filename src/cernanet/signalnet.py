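"""Gene-gene signal network construction and hub ranking.

The signal net is the induced subgraph of a directed relation table on a
member set (typically the intersected differentially expressed genes).
Hubness is measured two ways:

* connectivity ``Ki = sum_{u != i} a_ui`` — the sum of connection strengths
  to all other network genes, computed on the undirected weighted
  projection (parallel relation rows between the same pair collapse to one
  edge with summed weight); in/outdegree are additionally reported on the
  directed graph;
* relative betweenness centrality
  ``C'B(v) = 2/((n-1)(n-2)) * sum_{s != v != t} sigma_st(v)/sigma_st``
  over unordered pairs on the undirected, unweighted projection, where
  ``sigma_st`` counts shortest paths and ``sigma_st(v)`` those passing
  strictly through v.  Disconnected pairs contribute 0; C'B is 1 exactly for
  a vertex lying on every pairwise shortest path (a star center).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from cernanet.io_formats import RelationTable

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["feature_id", "connectivity", "indegree", "outdegree", "betweenness"]


@dataclass
class SignalNet:
    """Directed gene graph plus its collapsed undirected projection."""

    directed: nx.DiGraph
    undirected: nx.Graph
    dropped_isolated: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.directed.nodes)

    def __len__(self) -> int:
        return self.directed.number_of_nodes()


def build_signalnet(relations: RelationTable, members) -> SignalNet:
    """Induced subgraph of the relation table on ``members``.

    Members with no retained edge are dropped (and reported); parallel rows
    between the same ordered pair are collapsed with summed weight.
    """
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    dg = nx.DiGraph()
    ug = nx.Graph()
    for e in relations:
        if e.source not in members or e.target not in members:
            continue
        arcs = [(e.source, e.target)] if e.directed else [(e.source, e.target), (e.target, e.source)]
        for u, v in arcs:
            if dg.has_edge(u, v):
                dg[u][v]["weight"] += e.weight
                if e.relation not in dg[u][v]["relation"].split("|"):
                    dg[u][v]["relation"] += f"|{e.relation}"
            else:
                dg.add_edge(u, v, weight=e.weight, relation=e.relation)
        # each relation row contributes its weight exactly once undirected
        if ug.has_edge(e.source, e.target):
            ug[e.source][e.target]["weight"] += e.weight
        else:
            ug.add_edge(e.source, e.target, weight=e.weight)

    dropped = sorted(members - set(dg.nodes))
    if dropped:
        logger.info("dropped %d isolated member(s): %s...", len(dropped), dropped[:5])
    net = SignalNet(directed=dg, undirected=ug, dropped_isolated=dropped)
    logger.info("signal net: %d nodes, %d directed edges", len(net), dg.number_of_edges())
    return net


def connectivity(net: SignalNet) -> pd.DataFrame:
    """Per-node connectivity Ki plus directed in/outdegree counts."""
    rows = []
    for v in net.nodes:
        ki = sum(d["weight"] for _, _, d in net.undirected.edges(v, data=True))
        rows.append((v, float(ki), net.directed.in_degree(v), net.directed.out_degree(v)))
    return pd.DataFrame(rows, columns=["feature_id", "connectivity", "indegree", "outdegree"]).set_index("feature_id")


def relative_betweenness(net: SignalNet) -> pd.Series:
    """Freeman relative betweenness C'B(v) in [0, 1] per node.

    Computed on the undirected unweighted projection.  With fewer than 3
    nodes the normalizer (n-1)(n-2) vanishes and all centralities are
    reported as 0 with a warning.
    """
    n = len(net)
    if n < 3:
        logger.warning("betweenness undefined for n=%d < 3; reporting 0", n)
        return pd.Series(0.0, index=net.nodes, name="betweenness")
    cb = nx.betweenness_centrality(net.undirected, normalized=True, weight=None)
    return pd.Series({v: cb[v] for v in net.nodes}, name="betweenness")


def node_metrics(net: SignalNet) -> pd.DataFrame:
    """Connectivity, in/outdegree, and relative betweenness for every node."""
    df = connectivity(net)
    df["betweenness"] = relative_betweenness(net)
    return df.reset_index()


def rank_hubs(net: SignalNet, by: str = "connectivity") -> list[str]:
    """Nodes in descending metric order, ties broken by feature_id."""
    if by not in ("connectivity", "betweenness"):
        raise ValueError(f"rank key must be 'connectivity' or 'betweenness', got {by!r}")
    df = node_metrics(net)
    df = df.sort_values([by, "feature_id"], ascending=[False, True], kind="mergesort")
    return df["feature_id"].tolist()
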
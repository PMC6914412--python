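"""Sign-constrained ceRNA network assembly.

Under the ceRNA hypothesis a lncRNA sponges a miRNA and thereby de-represses
the miRNA's mRNA targets, so in tumor expression data a genuine triplet
shows negative miRNA-lncRNA and miRNA-mRNA correlation and (indirectly)
positive lncRNA-mRNA correlation, with the miRNA differentially expressed in
the direction opposite to both partners.

An miRNA-centered edge is retained when ALL of:

1. the pair is predicted by the seed-match stage,
2. both members are differentially expressed with opposite directions,
3. Pearson r < 0 on tumor samples,
4. the correlation p-value passes the gate (default p < 0.05, uncorrected;
   a BH option is provided).

Triplets form through shared miRNAs and the network splits into two
direction-stratified sub-networks (up-miRNA with down partners, and the
converse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from cernanet.diffexpr import bh_fdr
from cernanet.io_formats import ExpressionMatrix
from cernanet.target_prediction import TargetPair

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["miRNA_id", "partner_id", "partner_class", "r", "p", "best_class", "n_sites"]
TRIPLET_COLUMNS = [
    "lncRNA_id",
    "miRNA_id",
    "mRNA_id",
    "r_lnc_mi",
    "p_lnc_mi",
    "r_mi_m",
    "p_mi_m",
    "r_lnc_m",
    "p_lnc_m",
    "dir_lncRNA",
    "dir_miRNA",
    "dir_mRNA",
]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r*sqrt((n-2)/(1-r^2)).

    Returns (nan, nan) for zero-variance input (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero-variance vector in correlation; reported as missing")
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


@dataclass
class CeRNANetwork:
    """Assembled ceRNA network: typed nodes, gated edges, and triplets."""

    nodes: pd.DataFrame  # feature_id, feature_class, direction
    edges: pd.DataFrame  # EDGE_COLUMNS
    triplets: pd.DataFrame  # TRIPLET_COLUMNS
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_triplets(self) -> int:
        return len(self.triplets)

    def subnetwork(self, mirna_direction: str) -> "CeRNANetwork":
        """The direction-stratified sub-network whose miRNAs all have
        ``mirna_direction`` (partners necessarily have the opposite)."""
        mirs = set(self.nodes.query("feature_class == 'miRNA' and direction == @mirna_direction")["feature_id"])
        edges = self.edges[self.edges["miRNA_id"].isin(mirs)].reset_index(drop=True)
        trip = self.triplets[self.triplets["miRNA_id"].isin(mirs)].reset_index(drop=True)
        keep_nodes = set(edges["miRNA_id"]) | set(edges["partner_id"])
        nodes = self.nodes[self.nodes["feature_id"].isin(keep_nodes)].reset_index(drop=True)
        return CeRNANetwork(nodes=nodes, edges=edges, triplets=trip, graph=self.graph.subgraph(keep_nodes).copy())


def _tumor_vectors(matrices: Mapping[str, ExpressionMatrix], tumor_only: bool) -> dict[str, pd.Series]:
    vectors: dict[str, pd.Series] = {}
    sample_sets = []
    for cls, mat in matrices.items():
        sub = mat.subset_condition("tumor") if tumor_only else mat
        sample_sets.append(tuple(sub.sample_ids))
        for fid in sub.feature_ids:
            vectors[fid] = sub.values.loc[fid]
    if len(set(sample_sets)) > 1:
        raise ValueError("expression matrices must share the same (tumor) sample columns for correlation")
    return vectors


def build_cerna(
    de_records: pd.DataFrame,
    pairs_mi_m: list[TargetPair],
    pairs_mi_lnc: list[TargetPair],
    expr: Mapping[str, ExpressionMatrix],
    max_p: float = 0.05,
    require_negative_r: bool = True,
    require_positive_lnc_m: bool = False,
    correct_fdr: bool = False,
    tumor_only: bool = True,
) -> CeRNANetwork:
    """Assemble the ceRNA network from DE calls, predicted pairs, and
    tumor-sample correlations.

    ``de_records`` needs columns feature_id, feature_class, direction and
    must already be threshold-selected.  ``expr`` maps feature class to the
    matrix holding those features (the mRNA/lncRNA/miRNA matrices must share
    tumor sample columns).  Edges failing any gate are dropped; the
    lncRNA-mRNA correlation is reported on triplets but only required when
    ``require_positive_lnc_m`` is set.
    """
    if de_records.empty or (not pairs_mi_m and not pairs_mi_lnc):
        logger.warning("empty inputs; returning empty ceRNA network")
        return _empty_network()
    direction = dict(zip(de_records["feature_id"], de_records["direction"]))
    fclass = dict(zip(de_records["feature_id"], de_records["feature_class"]))
    vectors = _tumor_vectors(expr, tumor_only)

    edge_rows = []
    for pairs, partner_class in ((pairs_mi_lnc, "lncRNA"), (pairs_mi_m, "mRNA")):
        for pair in pairs:
            mir, tgt = pair.miRNA_id, pair.target_id
            if mir not in direction or tgt not in direction:
                continue
            if direction[mir] == direction[tgt]:
                continue
            if mir not in vectors or tgt not in vectors:
                continue
            r, p = pearson_with_p(vectors[mir].to_numpy(), vectors[tgt].to_numpy())
            if np.isnan(r):
                continue
            edge_rows.append((mir, tgt, partner_class, r, p, pair.best_class, pair.n_sites))
    edges = pd.DataFrame(edge_rows, columns=EDGE_COLUMNS)
    if not edges.empty:
        gate = pd.Series(True, index=edges.index)
        if require_negative_r:
            gate &= edges["r"] < 0
        pcol = bh_fdr(edges["p"].to_numpy()) if correct_fdr else edges["p"].to_numpy()
        gate &= pd.Series(pcol, index=edges.index) < max_p
        edges = edges[gate].reset_index(drop=True)
    edges = edges.sort_values(["miRNA_id", "partner_id"], kind="mergesort").reset_index(drop=True)

    # triplets through shared miRNAs
    trip_rows = []
    lnc_edges = edges[edges["partner_class"] == "lncRNA"]
    m_edges = edges[edges["partner_class"] == "mRNA"]
    for mir in sorted(set(lnc_edges["miRNA_id"]) & set(m_edges["miRNA_id"])):
        for _, le in lnc_edges[lnc_edges["miRNA_id"] == mir].iterrows():
            for _, me in m_edges[m_edges["miRNA_id"] == mir].iterrows():
                lnc, m = le["partner_id"], me["partner_id"]
                r_lm, p_lm = pearson_with_p(vectors[lnc].to_numpy(), vectors[m].to_numpy())
                if require_positive_lnc_m and not (r_lm > 0 and p_lm < max_p):
                    continue
                trip_rows.append(
                    (lnc, mir, m, le["r"], le["p"], me["r"], me["p"], r_lm, p_lm,
                     direction[lnc], direction[mir], direction[m])
                )
    triplets = pd.DataFrame(trip_rows, columns=TRIPLET_COLUMNS)

    node_ids = sorted(set(edges["miRNA_id"]) | set(edges["partner_id"]))
    nodes = pd.DataFrame(
        {
            "feature_id": node_ids,
            "feature_class": [fclass[f] for f in node_ids],
            "direction": [direction[f] for f in node_ids],
        }
    )
    graph = nx.Graph()
    for _, row in nodes.iterrows():
        graph.add_node(row["feature_id"], feature_class=row["feature_class"], direction=row["direction"])
    for _, row in edges.iterrows():
        graph.add_edge(row["miRNA_id"], row["partner_id"], r=float(row["r"]), p=float(row["p"]),
                       evidence="predicted+correlated", best_class=row["best_class"])
    logger.info(
        "ceRNA network: %d nodes, %d edges, %d triplets", len(nodes), len(edges), len(triplets)
    )
    return CeRNANetwork(nodes=nodes, edges=edges, triplets=triplets, graph=graph)


def _empty_network() -> CeRNANetwork:
    return CeRNANetwork(
        nodes=pd.DataFrame(columns=["feature_id", "feature_class", "direction"]),
        edges=pd.DataFrame(columns=EDGE_COLUMNS),
        triplets=pd.DataFrame(columns=TRIPLET_COLUMNS),
        graph=nx.Graph(),
    )


def summarize_network(net: CeRNANetwork) -> dict:
    """Class-wise node counts, edge/triplet totals, and a per-node degree table."""
    counts = net.nodes["feature_class"].value_counts().to_dict() if not net.nodes.empty else {}
    degree = (
        pd.DataFrame(sorted(net.graph.degree), columns=["feature_id", "degree"])
        if net.graph.number_of_nodes()
        else pd.DataFrame(columns=["feature_id", "degree"])
    )
    return {
        "n_lncRNA": int(counts.get("lncRNA", 0)),
        "n_miRNA": int(counts.get("miRNA", 0)),
        "n_mRNA": int(counts.get("mRNA", 0)),
        "n_edges": int(len(net.edges)),
        "n_triplets": int(net.n_triplets),
        "degree": degree,
    }
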
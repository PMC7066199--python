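"""Thresholded Pearson correlation networks over compound profiles.

All compound pairs are correlated; two-sided p-values come from the exact
t-transform t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom, and
the whole p set is Benjamini-Hochberg adjusted. An edge survives iff
|r| >= r_min and q <= q_max; the standard thresholds are r_min = 0.8,
q_max = 0.05. The threshold applies to |r|: negative edges are retained and
their sign carried as an attribute. Communities come from the walktrap
random-walk algorithm on |r| edge weights, cut at maximum modularity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CompoundMatrix


@dataclass
class CorrelationNetwork:
    """Compound graph whose edges carry Pearson r, raw p and BH q."""

    graph: nx.Graph
    r_min: float = 0.8
    q_max: float = 0.05
    n_samples: int = 0

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_pairs(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    pe_ne_ratio: float          # inf when there is no negative edge
    edge_density: float
    avg_weighted_degree: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if math.isinf(d["pe_ne_ratio"]):
            d["pe_ne_ratio"] = "inf"
        return d


@dataclass
class CommunityPartition:
    """Walktrap partition: node -> 1-based contiguous community label."""

    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def members(self, label: int) -> set[str]:
        return {n for n, c in self.membership.items() if c == label}

    def same_community(self, a: str, b: str) -> bool:
        return self.membership[a] == self.membership[b]


# ---------------------------------------------------------------------------
# correlation tables

def correlate_all_pairs(matrix: CompoundMatrix) -> pd.DataFrame:
    """Pearson r, two-sided p and BH q for every unordered compound pair.

    Zero-variance compounds cannot be tested; their pairs are excluded from
    the table (and hence from any network) with a warning.
    """
    vals = matrix.values
    if vals.isna().to_numpy().any():
        raise ValueError("correlate_all_pairs requires a complete (imputed) matrix")
    n = vals.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for edge testing")
    sd = vals.to_numpy().std(axis=0, ddof=0)
    degenerate = np.nonzero(sd == 0)[0]
    cols = list(vals.columns)
    if degenerate.size:
        bad = [cols[i] for i in degenerate]
        warnings.warn(
            f"excluding zero-variance compounds from correlation testing: {bad}"
        )
    keep = [c for i, c in enumerate(cols) if i not in set(degenerate)]
    X = vals[keep].to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    iu, ju = np.triu_indices(len(keep), k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    q = multipletests(p, method="fdr_bh")[1] if p.size else np.array([])
    return pd.DataFrame(
        {
            "compound_a": [keep[i] for i in iu],
            "compound_b": [keep[j] for j in ju],
            "r": r,
            "p": p,
            "q": q,
        }
    )


def build_network(
    matrix: CompoundMatrix,
    tables: pd.DataFrame | None = None,
    r_min: float = 0.8,
    q_max: float = 0.05,
) -> CorrelationNetwork:
    """Keep edges with |r| >= r_min and q <= q_max; keep every compound as a node."""
    if not 0 < r_min <= 1:
        raise ValueError("r_min must be in (0, 1]")
    if not 0 < q_max <= 1:
        raise ValueError("q_max must be in (0, 1]")
    if tables is None:
        tables = correlate_all_pairs(matrix)
    g = nx.Graph()
    for comp in matrix.values.columns:
        g.add_node(comp, compound_class=str(matrix.compound_classes.get(comp, "unknown")))
    hit = tables[(tables["r"].abs() >= r_min) & (tables["q"] <= q_max)]
    for row in hit.itertuples(index=False):
        g.add_edge(
            row.compound_a,
            row.compound_b,
            r=float(row.r),
            p=float(row.p),
            q=float(row.q),
            sign=1 if row.r >= 0 else -1,
        )
    return CorrelationNetwork(g, r_min=r_min, q_max=q_max, n_samples=matrix.n_samples)


# ---------------------------------------------------------------------------
# statistics

def network_stats(net: CorrelationNetwork) -> NetworkStats:
    g = net.graph
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = len(signs) - n_pos
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_positive_edges=n_pos,
        n_negative_edges=n_neg,
        pe_ne_ratio=stats_pe_ne_ratio(n_pos, n_neg),
        edge_density=stats_edge_density(g.number_of_nodes(), g.number_of_edges()),
        avg_weighted_degree=_avg_weighted_degree(g),
    )


def stats_pe_ne_ratio(n_positive: int, n_negative: int) -> float:
    """Positive-to-negative edge count ratio (inf when no negative edges)."""
    return math.inf if n_negative == 0 else n_positive / n_negative


def stats_edge_density(n_nodes: int, n_edges: int) -> float:
    """2 * |E| / (|V| * (|V| - 1))."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def _avg_weighted_degree(g: nx.Graph) -> float:
    """Mean over all nodes (isolated included) of summed incident |r|."""
    if g.number_of_nodes() == 0:
        return 0.0
    total = sum(abs(d["r"]) for _, _, d in g.edges(data=True))
    return 2.0 * total / g.number_of_nodes()


# ---------------------------------------------------------------------------
# walktrap communities

def detect_communities(net: CorrelationNetwork, steps: int = 4) -> CommunityPartition:
    """Walktrap community detection on |r| weights, cut at max modularity.

    Isolated nodes become singleton communities. Deterministic given node
    ordering (walktrap is seedless).
    """
    nodes = list(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in net.graph.edges]
    weights = [abs(d["r"]) for _, _, d in net.graph.edges(data=True)]
    if not edges:
        membership = {n: i + 1 for i, n in enumerate(nodes)}
        return CommunityPartition(membership, 0.0)
    g = ig.Graph(n=len(nodes), edges=edges)
    dendrogram = g.community_walktrap(weights=weights, steps=steps)
    clustering = dendrogram.as_clustering()
    modularity = g.modularity(clustering.membership, weights=weights)
    # relabel to contiguous 1-based labels in first-appearance order
    relabel: dict[int, int] = {}
    membership: dict[str, int] = {}
    for node, raw in zip(nodes, clustering.membership):
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        membership[node] = relabel[raw]
    return CommunityPartition(membership, float(modularity))


# ---------------------------------------------------------------------------
# set algebra

def network_set_ops(
    net_a: CorrelationNetwork,
    net_b: CorrelationNetwork,
    keep_all_nodes: bool = False,
) -> dict[str, CorrelationNetwork]:
    """Intersection / difference / symmetric-difference networks.

    Edge identity is the unordered node pair; the surviving edge carries the
    attributes of its own source network (``net_a`` for intersection,
    a-minus-b and the a-side of the symmetric difference). By default node
    sets shrink to the endpoints of surviving edges; ``keep_all_nodes``
    retains the full shared compound universe instead.
    """
    nodes_a, nodes_b = set(net_a.graph.nodes), set(net_b.graph.nodes)
    if nodes_a != nodes_b:
        unmatched = sorted(nodes_a ^ nodes_b)
        raise ValueError(f"compound universes differ; unmatched ids: {unmatched}")
    pairs_a, pairs_b = net_a.edge_pairs(), net_b.edge_pairs()

    def _subnet(pairs: set[frozenset], sources: list[CorrelationNetwork]) -> CorrelationNetwork:
        g = nx.Graph()
        if keep_all_nodes:
            for n in nodes_a:
                g.add_node(n, **net_a.graph.nodes[n])
        for pair in pairs:
            a, b = tuple(pair)
            for src in sources:
                if src.graph.has_edge(a, b):
                    for n in (a, b):
                        if n not in g:
                            g.add_node(n, **src.graph.nodes[n])
                    g.add_edge(a, b, **src.graph.edges[a, b])
                    break
        return CorrelationNetwork(g, net_a.r_min, net_a.q_max, net_a.n_samples)

    return {
        "intersection": _subnet(pairs_a & pairs_b, [net_a]),
        "a_minus_b": _subnet(pairs_a - pairs_b, [net_a]),
        "b_minus_a": _subnet(pairs_b - pairs_a, [net_b]),
        "symmetric_difference": _subnet(pairs_a ^ pairs_b, [net_a, net_b]),
    }


# ---------------------------------------------------------------------------
# export / import

def export_network(
    net: CorrelationNetwork,
    path: str | Path,
    fmt: str = "edge-tsv",
    partition: CommunityPartition | None = None,
) -> Path:
    """Write a network as an edge-list TSV or GraphML file."""
    path = Path(path)
    if fmt == "edge-tsv":
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "r": repr(d["r"]),
                "p": repr(d["p"]),
                "q": repr(d["q"]),
                "sign": d["sign"],
            }
            for a, b, d in sorted(net.graph.edges(data=True))
        ]
        header = "node_a\tnode_b\tr\tp\tq\tsign"
        lines = [header] + [
            "\t".join(str(row[k]) for k in ("node_a", "node_b", "r", "p", "q", "sign"))
            for row in rows
        ]
        isolated = sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0)
        lines += [f"#node\t{n}" for n in isolated]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "graphml":
        g = net.graph.copy()
        if partition is not None:
            nx.set_node_attributes(g, partition.membership, "community")
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    return path


def import_network(
    path: str | Path,
    fmt: str = "edge-tsv",
    r_min: float = 0.8,
    q_max: float = 0.05,
    n_samples: int = 0,
) -> CorrelationNetwork:
    """Read back a network written by :func:`export_network` (lossless)."""
    path = Path(path)
    if fmt == "edge-tsv":
        g = nx.Graph()
        for line in path.read_text(encoding="utf-8").splitlines()[1:]:
            if line.startswith("#node\t"):
                g.add_node(line.split("\t", 1)[1])
                continue
            a, b, r, p, q, sign = line.split("\t")
            g.add_edge(a, b, r=float(r), p=float(p), q=float(q), sign=int(sign))
        return CorrelationNetwork(g, r_min, q_max, n_samples)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return CorrelationNetwork(nx.Graph(g), r_min, q_max, n_samples)
    raise ValueError(f"unknown format: {fmt!r}")
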
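"""Gene-interaction networks and the row-stochastic transition matrix.

Networks come either from an edge-list file (e.g. a pathway-derived
interaction network) or from hard-thresholded Pearson co-expression on an
expression matrix. The transition matrix is the row-normalized adjacency
used by the random walk; dangling nodes receive a self-loop so that every
row sums to one and the walk conserves probability mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "TransitionMatrix",
    "load_edge_list",
    "build_coexpression_network",
    "bh_adjust",
    "row_normalize",
    "degree",
]


class InteractionNetwork:
    """A directed multigraph-free gene network.

    Undirected networks are materialized with both arc orientations so a
    single directed representation serves both cases. Edge attributes
    (e.g. a signed correlation) are metadata only and never enter the
    transition-matrix normalization.
    """

    def __init__(self, graph: nx.DiGraph, directed: bool):
        self.graph = graph
        self.directed = directed

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple],
        directed: bool,
        nodes: list[str] | None = None,
    ) -> "InteractionNetwork":
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(str(n) for n in nodes)
        n_dup = 0
        for edge in edges:
            u, v = str(edge[0]), str(edge[1])
            attrs = {"weight": float(edge[2])} if len(edge) > 2 and edge[2] is not None else {}
            pairs = [(u, v)] if directed or u == v else [(u, v), (v, u)]
            for a, b in pairs:
                if g.has_edge(a, b):
                    n_dup += 1
                else:
                    g.add_edge(a, b, **attrs)
        if n_dup:
            logger.warning("collapsed %d duplicated edges", n_dup if directed else n_dup // 2)
        return cls(g, directed)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def to_edge_list(self, path: str) -> None:
        with open(path, "w") as fh:
            for u, v, data in self.graph.edges(data=True):
                if not self.directed and u > v:
                    continue  # write each undirected edge once
                w = data.get("weight")
                fh.write(f"{u}\t{v}" + (f"\t{w:.6g}" if w is not None else "") + "\n")


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix M over a fixed node order (sorted node ids)."""

    node_order: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.node_order)
        if self.M.shape != (n, n):
            raise ValueError("transition matrix dimensions do not match node count")
        if (self.M < 0).any():
            raise ValueError("transition matrix must be nonnegative")
        rs = self.M.sum(axis=1)
        if not np.allclose(rs, 1.0, rtol=0, atol=1e-12):
            raise ValueError("every transition-matrix row must sum to 1")


def load_edge_list(path: str, directed: bool = False) -> InteractionNetwork:
    """Read a TSV edge list ``source<TAB>target[<TAB>weight]``.

    Lines starting with ``#`` are comments. Duplicate edges are collapsed
    (with a logged count); self-loops are preserved.
    """
    edges: list[tuple] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{ln}: malformed edge line {line!r}")
            w = None
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(f"{path}:{ln}: non-numeric edge weight {parts[2]!r}") from None
            edges.append((parts[0].strip(), parts[1].strip(), w))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    return InteractionNetwork.from_edges(edges, directed=directed)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pearson_pvalues(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided Student P (t with n-2 df)."""
    n = values.shape[1]
    r = np.corrcoef(values)
    np.fill_diagonal(r, 0.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rr) >= 1.0] = 0.0  # |r|=1 limit
    return rr, p


def build_coexpression_network(
    expr: ExpressionMatrix, p_cut: float = 1e-7, adjust: bool = True
) -> InteractionNetwork:
    """Undirected co-expression network thresholded on pairwise Pearson P.

    Every feature pair is tested (Pearson r, two-sided Student P on n-2 df);
    by default the BH-adjusted P over all p*(p-1)/2 tests is compared with
    ``p_cut`` (set ``adjust=False`` to threshold the raw P instead). The
    correlation is stored on each edge. Zero-variance features are excluded
    with a warning.
    """
    if expr.n_samples < 3:
        raise ValueError("co-expression P-values need at least 3 samples")
    if expr.n_features < 2:
        raise ValueError("co-expression needs at least 2 features")
    sd = expr.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance features from co-expression")
    feats = [f for f, k in zip(expr.feature_ids, keep) if k]
    vals = expr.values[keep]
    r, p = _pearson_pvalues(vals)
    iu, ju = np.triu_indices(len(feats), k=1)
    pu = p[iu, ju]
    padj = bh_adjust(pu) if adjust else pu
    sel = padj < p_cut
    edges = [(feats[i], feats[j], r[i, j]) for i, j in zip(iu[sel], ju[sel])]
    return InteractionNetwork.from_edges(edges, directed=False, nodes=feats)


def row_normalize(net: InteractionNetwork) -> TransitionMatrix:
    """Row-normalized adjacency; dangling nodes get a self-loop first."""
    order = net.node_ids
    A = nx.to_numpy_array(net.graph, nodelist=order, weight=None)
    out = A.sum(axis=1)
    dangling = out == 0
    if dangling.any():
        A[dangling, dangling] = 1.0
        out = A.sum(axis=1)
    return TransitionMatrix(order, A / out[:, None])


def degree(net: InteractionNetwork, node: str) -> int:
    """Incident edge count (undirected) or in+out degree (directed)."""
    if node not in net.graph:
        raise KeyError(f"unknown node {node!r}")
    if net.directed:
        return net.graph.in_degree(node) + net.graph.out_degree(node)
    return net.graph.out_degree(node)
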
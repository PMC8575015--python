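"""Cell-type association network from panel-restricted profiles.

Dependence between two cell types is measured as the mutual information of
their log2(expression+1) values across the selected panel genes, estimated
with a product Gaussian kernel density (per-variable Silverman bandwidth)
and reported in nats. Edges are kept where MI exceeds a hard cutoff (0.25
by default — note this scale depends on the estimator and transform, so the
cutoff is a tunable, not a universal constant), the resulting unweighted
graph is partitioned by greedy (Clauset–Newman–Moore) modularity
maximization, and each module can be annotated with its most frequent
node labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, subset_genes

__all__ = [
    "CellTypeNetwork",
    "mutual_information",
    "build_network",
    "detect_modules",
    "modularity",
    "annotate_modules",
]


@dataclass
class CellTypeNetwork:
    nodes: tuple[str, ...]
    mi: np.ndarray  # symmetric (m, m), diagonal = self-information
    cutoff: float
    graph: nx.Graph  # unweighted graph on nodes with mi > cutoff edges
    modules: list[set[str]] | None = None
    Q: float | None = None
    annotations: list[list[tuple[str, int]]] | None = None

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def mi_frame(self) -> pd.DataFrame:
        ids = list(self.nodes)
        return pd.DataFrame(self.mi, index=ids, columns=ids)


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * N^(-1/5)."""
    n = x.size
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Kernel-density MI estimate (nats) between two paired samples.

    The joint density is a product-Gaussian KDE with per-variable Silverman
    bandwidths, the marginals are the matching 1-D KDEs (so the joint
    integrates to the marginals and the estimate is symmetric), and MI is
    the sample average of log(joint / (marg*marg)), clipped at 0. Densities
    are evaluated leave-one-out: the kernel centred on the evaluation point
    is excluded, otherwise the self-kernel inflates the joint density more
    than the marginals and independent data score well above zero. A
    constant input has no defined density scale; MI is reported as 0 with a
    warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples for a KDE estimate; "
                         "5+ recommended")
    hx, hy = _silverman_bandwidth(x), _silverman_bandwidth(y)
    if hx <= 0 or hy <= 0:
        warnings.warn("constant vector: mutual information undefined, returning 0",
                      stacklevel=2)
        return 0.0
    dx = (x[:, None] - x[None, :]) / hx  # (i, j): eval point i, kernel centre j
    dy = (y[:, None] - y[None, :]) / hy
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    kj = kx * ky
    np.fill_diagonal(kx, 0.0)
    np.fill_diagonal(ky, 0.0)
    np.fill_diagonal(kj, 0.0)
    denom = x.size - 1
    # normalization constants cancel between joint and product of marginals
    fj = kj.sum(axis=1) / denom
    fx = kx.sum(axis=1) / denom
    fy = ky.sum(axis=1) / denom
    tiny = np.finfo(float).tiny
    mi = float(np.mean(np.log(np.maximum(fj, tiny))
                       - np.log(np.maximum(fx, tiny))
                       - np.log(np.maximum(fy, tiny))))
    return max(mi, 0.0)


def build_network(
    em: ExpressionMatrix,
    panel: list[str],
    cutoff: float = 0.25,
    log_transform: bool = True,
) -> CellTypeNetwork:
    """MI network over cell types restricted to the panel genes.

    Profiles are log2(value+1)-transformed before estimation. An undirected,
    unweighted edge joins cell types with MI strictly above the cutoff;
    isolated nodes are retained.
    """
    missing = [g for g in panel if g not in em.gene_ids]
    if missing:
        raise ValueError(f"panel genes missing from the matrix: {missing}")
    if len(panel) < 5:
        warnings.warn(
            f"panel of {len(panel)} genes is small for a KDE MI estimate; "
            "5+ recommended", stacklevel=2,
        )
    sub = subset_genes(em, panel)
    X = np.log2(sub.S + 1.0) if log_transform else sub.S
    m = sub.m
    mi = np.zeros((m, m))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-profile warnings handled as 0
        for i in range(m):
            mi[i, i] = mutual_information(X[i], X[i])
            for j in range(i + 1, m):
                mi[i, j] = mi[j, i] = mutual_information(X[i], X[j])
    G = nx.Graph()
    G.add_nodes_from(em.cell_type_ids)
    for i in range(m):
        for j in range(i + 1, m):
            if mi[i, j] > cutoff:
                G.add_edge(em.cell_type_ids[i], em.cell_type_ids[j])
    return CellTypeNetwork(nodes=em.cell_type_ids, mi=mi, cutoff=cutoff, graph=G)


def modularity(graph: nx.Graph, modules: list[set[str]]) -> float:
    """Newman modularity Q = Σ_c (e_cc − a_c²) of a partition.

    e_cc is the fraction of edges inside module c and a_c the fraction of
    edge ends attached to it. An edgeless graph has Q = 0 by convention.
    """
    E = graph.number_of_edges()
    if E == 0:
        return 0.0
    node_to_mod = {n: ci for ci, mod in enumerate(modules) for n in mod}
    e = np.zeros(len(modules))
    a = np.zeros(len(modules))
    for u, v in graph.edges:
        cu, cv = node_to_mod[u], node_to_mod[v]
        if cu == cv:
            e[cu] += 1
        a[cu] += 0.5
        a[cv] += 0.5
    return float(np.sum(e / E - (a / E) ** 2))


def detect_modules(net: CellTypeNetwork) -> tuple[list[set[str]], float]:
    """Greedy agglomerative modularity maximization (Newman's fast method).

    Returns the partition at the maximal-Q point of the merge path. With no
    edges every node is its own module and Q = 0 by convention. The result
    is stored on the network object as well.
    """
    G = net.graph
    if G.number_of_edges() == 0:
        modules = [{n} for n in sorted(G.nodes)]
        Q = 0.0
    else:
        comms = nx.community.greedy_modularity_communities(G)
        modules = [set(c) for c in comms]
        Q = modularity(G, modules)
    net.modules, net.Q = modules, Q
    return modules, Q


def annotate_modules(
    modules: list[set[str]],
    node_labels: dict[str, str],
    top: int = 5,
) -> list[list[tuple[str, int]]]:
    """Per-module (label, count) lists, by descending count then label name.

    Every node must be labeled; each module's list is truncated to ``top``
    entries (the five most frequent annotations by default).
    """
    out = []
    for mod in modules:
        counts: dict[str, int] = {}
        for node in sorted(mod):
            if node not in node_labels:
                raise ValueError(f"node {node!r} has no label")
            lab = node_labels[node]
            counts[lab] = counts.get(lab, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append(ranked[:top])
    return out
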
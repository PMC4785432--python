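"""First-neighbour PPI subnetworks and the topology statistics reported for them."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["PowerLawFit", "first_neighbor_subnetwork", "topology_summary", "fit_power_law"]


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power law y = beta * x**a fitted on log-log axes."""

    beta: float
    a: float
    r_squared: float


def first_neighbor_subnetwork(
    ppi: nx.Graph, seeds, include_neighbor_edges: bool = False
) -> nx.Graph:
    """Subgraph of seed genes, their direct neighbours, and seed-incident edges.

    Edges between two non-seed neighbours are excluded by default (set
    ``include_neighbor_edges`` for the inclusive variant).  Seeds absent from
    the parent network are retained as isolated nodes with a warning.
    """
    seeds = set(seeds)
    missing = seeds - set(ppi.nodes)
    if missing:
        warnings.warn(f"{len(missing)} seed(s) absent from the parent network; kept isolated")
    sub = nx.Graph()
    sub.add_nodes_from(seeds)
    for s in seeds & set(ppi.nodes):
        for nb in ppi.neighbors(s):
            sub.add_edge(s, nb)
    if include_neighbor_edges:
        nodes = set(sub.nodes)
        for u, v in ppi.edges():
            if u in nodes and v in nodes:
                sub.add_edge(u, v)
    return sub


def topology_summary(graph: nx.Graph) -> dict:
    """Topology statistics: degree distribution, clustering, connectivity, etc.

    - ``degree_distribution``: map degree k -> node count P(k)
    - ``mean_clustering``: average of 2*triangles / (k*(k-1)) over nodes
    - ``mean_neighborhood_connectivity``: average over nodes of the mean
      degree of their neighbours
    - ``diameter``: of the largest connected component
    - ``density``, ``centralization`` (Freeman degree), ``heterogeneity``
      (coefficient of variation of the degrees)
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be non-empty")
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    dist: dict[int, int] = {}
    for d in degrees.astype(int):
        dist[int(d)] = dist.get(int(d), 0) + 1

    n = graph.number_of_nodes()
    mean_clust = float(nx.average_clustering(graph)) if n > 0 else 0.0

    ncs = []
    for node in graph.nodes:
        nbrs = list(graph.neighbors(node))
        if nbrs:
            ncs.append(float(np.mean([graph.degree(nb) for nb in nbrs])))
    mean_nc = float(np.mean(ncs)) if ncs else 0.0

    if graph.number_of_edges() > 0 or n > 1:
        components = list(nx.connected_components(graph))
        giant = graph.subgraph(max(components, key=len))
        diameter = nx.diameter(giant) if giant.number_of_nodes() > 1 else 0
    else:
        diameter = 0

    density = nx.density(graph) if n > 1 else 0.0
    if n > 2:
        dmax = degrees.max()
        centralization = float((dmax - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0

    return {
        "degree_distribution": dist,
        "mean_clustering": mean_clust,
        "mean_neighborhood_connectivity": mean_nc,
        "diameter": int(diameter),
        "density": float(density),
        "centralization": centralization,
        "heterogeneity": heterogeneity,
    }


def fit_power_law(degree_distribution: dict[int, float]) -> PowerLawFit:
    """Fit y = beta * k**a to the degree distribution by log-log least squares.

    Only strictly positive degrees and counts enter the fit (log-transform);
    at least two distinct degrees are required.
    """
    pts = [(k, c) for k, c in degree_distribution.items() if k > 0 and c > 0]
    if len(pts) < 2:
        raise ValueError("need >= 2 positive-degree points to fit a power law")
    logk = np.log10([k for k, _ in pts])
    logc = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(logk, logc, 1)
    fitted = slope * logk + intercept
    ss_tot = float(((logc - logc.mean()) ** 2).sum())
    ss_res = float(((logc - fitted) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(beta=float(10**intercept), a=float(slope), r_squared=float(r2))
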
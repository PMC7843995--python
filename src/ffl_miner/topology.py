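"""Node-level topology metrics and the degree-distribution power-law fit.

Metrics are computed on the undirected simple projection of the typed
network (all edges symmetrized, relation colors ignored, parallel relations
between one node pair counted once), matching how network viewers report
them: degree, clustering coefficient, topological coefficient, and
neighborhood connectivity (mean neighbor degree).

The power-law fit is an ordinary least-squares line on (log degree,
log frequency) over degrees with positive frequency, returning
f(x) = a * x**b and the r-squared of the log-log regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import RegulatoryNetwork


@dataclass
class PowerLawFit:
    a: float
    b: float
    r_squared: float


def to_simple_graph(net: RegulatoryNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.roles)
    g.add_edges_from((s, t) for s, t, _ in net.edges)
    return g


def topological_coefficient(g: nx.Graph, node) -> float:
    """Mean, over partners m sharing at least one neighbor with n, of
    (shared neighbors of n and m, plus 1 if m is adjacent to n) / deg(n).
    Nodes with fewer than two neighbors score 0."""
    neigh = set(g[node])
    if len(neigh) < 2:
        return 0.0
    partners: dict = {}
    for u in neigh:
        for m in g[u]:
            if m == node:
                continue
            partners[m] = partners.get(m, 0) + 1
    if not partners:
        return 0.0
    deg = len(neigh)
    total = sum(shared + (1 if m in neigh else 0) for m, shared in partners.items())
    return total / (len(partners) * deg)


def compute_node_metrics(net: RegulatoryNetwork) -> pd.DataFrame:
    """Per-node degree, clustering coefficient, topological coefficient and
    neighborhood connectivity on the symmetrized simple graph."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = to_simple_graph(net)
    clustering = nx.clustering(g)
    neigh_conn = nx.average_neighbor_degree(g)
    rows = []
    for n in sorted(g.nodes):
        deg = g.degree(n)
        rows.append(
            {
                "node": n,
                "degree": deg,
                "clustering": clustering[n],
                "topological_coeff": topological_coefficient(g, n),
                "neighborhood_connectivity": neigh_conn[n] if deg > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def fit_power_law(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    """OLS on log-log scale; returns a = exp(intercept), b = slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (x > 0) & (y > 0)
    x, y = x[mask], y[mask]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct positive degree values")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(a=float(np.exp(intercept)), b=float(slope), r_squared=r2)


def fit_degree_power_law(profile: pd.DataFrame) -> PowerLawFit:
    """Power-law fit of the raw degree-frequency histogram of a node-metrics
    table (degree-0 nodes excluded; frequencies are raw node counts)."""
    degrees = profile["degree"].to_numpy()
    degrees = degrees[degrees > 0]
    values, counts = np.unique(degrees, return_counts=True)
    return fit_power_law(values, counts)
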
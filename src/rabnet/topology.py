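"""Topological metrics, power-law degree fits and kneedle hub detection.

The characteristic path length (CPL) here is measured in *intermediate
nodes* — shortest-path edge count minus one — so two proteins joined only
through one shared effector are at distance 1.  The conventional edge-count
CPL is exported alongside as ``cpl_edges``.  Both are averaged over node
pairs within the largest connected component, since distances between
disconnected pairs are undefined.

Hubs are the nodes ranked before the elbow of the descending rank-vs-degree
curve; the elbow is located with the kneedle algorithm (convex-decreasing
orientation, which is the geometry of a heavy-tailed degree plot).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "topology_summary",
    "fit_power_law",
    "detect_hubs",
    "kneedle_elbow",
    "intermediate_path_length",
    "normalize_summaries",
]


@dataclass
class TopologySummary:
    """Scalar metrics plus degree distribution, hubs and power-law exponent."""

    n_nodes: int
    n_edges: int
    density: float
    avg_neighbours: float
    clustering: float
    cpl: float
    cpl_edges: float
    degree_distribution: dict[int, int]
    gamma: float | None = None
    hubs: set = field(default_factory=set)
    elbow_k: int | None = None

    def to_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "avg_neighbours": self.avg_neighbours,
            "clustering": self.clustering,
            "cpl": self.cpl,
            "cpl_edges": self.cpl_edges,
            "gamma": self.gamma,
            "hubs": sorted(self.hubs),
            "elbow_k": self.elbow_k,
            "degree_distribution": {str(k): v for k, v in sorted(self.degree_distribution.items())},
        }
        return d


def intermediate_path_length(net: nx.Graph, a: str, b: str) -> int:
    """Shortest-path length between two nodes in intermediate-node units."""
    return nx.shortest_path_length(net, a, b) - 1


def _cpl(net: nx.Graph) -> tuple[float, float]:
    """(intermediate-node CPL, edge-count CPL) over the largest component."""
    lcc = max(nx.connected_components(net), key=len)
    if len(lcc) < 2:
        return 0.0, 0.0
    sub = net.subgraph(lcc)
    total = 0
    n_pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(sub):
        total += sum(dists.values())
        n_pairs += len(dists) - 1  # exclude self
    n_pairs //= 2  # ordered → unordered; total double-counts symmetrically
    cpl_edges = total / 2 / n_pairs
    return cpl_edges - 1.0, cpl_edges


def topology_summary(
    net: nx.Graph,
    sensitivity: float = 1.0,
    fit_gamma: bool = True,
    find_hubs: bool = True,
) -> TopologySummary:
    """Compute the per-network metric panel.

    density = 2E/(N(N−1)); avg_neighbours = 2E/N; clustering is the mean
    local clustering coefficient (nodes of degree < 2 contribute 0); CPL as
    described in the module docstring.  The power-law exponent and hub set
    are filled in when enough support exists (``None``/empty otherwise).
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("network must have at least 2 nodes")
    e = net.number_of_edges()
    density = 2 * e / (n * (n - 1))
    avg_neighbours = 2 * e / n
    clustering = nx.average_clustering(net)
    cpl, cpl_edges = _cpl(net)
    dist = dict(Counter(d for _, d in net.degree()))
    gamma = None
    if fit_gamma:
        try:
            gamma = fit_power_law(dist)
        except ValueError as exc:
            logger.info("power-law fit skipped: %s", exc)
    hubs: set = set()
    elbow_k = None
    if find_hubs and n >= 5:
        hubs, elbow_k = detect_hubs(net, sensitivity=sensitivity)
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        density=density,
        avg_neighbours=avg_neighbours,
        clustering=clustering,
        cpl=cpl,
        cpl_edges=cpl_edges,
        degree_distribution=dist,
        gamma=gamma,
        hubs=hubs,
        elbow_k=elbow_k,
    )


def fit_power_law(degree_distribution: dict[int, int]) -> float:
    """Exponent γ of p(k) = k^−γ by OLS on the log-log degree distribution.

    Only degrees ``k >= 1`` with nonzero counts enter the regression of
    log10(count) on log10(k); γ is the negated slope.  At least three
    usable points are required.
    """
    pts = [(k, c) for k, c in degree_distribution.items() if k >= 1 and c > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct degrees with nonzero counts")
    k = np.log10([p[0] for p in pts])
    c = np.log10([p[1] for p in pts])
    slope, _ = np.polyfit(k, c, 1)
    return float(-slope)


def kneedle_elbow(y: np.ndarray, sensitivity: float = 1.0) -> int | None:
    """Kneedle knee index on a descending curve (convex-decreasing case).

    The curve is min-max normalized, flipped vertically into the canonical
    concave-increasing form, and the knee is the first local maximum of the
    difference curve ``d = (1 − y_n) − x_n`` whose height is not regained
    before ``d`` drops below ``d_max − sensitivity · mean(Δx)``.  Returns
    ``None`` when the curve is flat or no knee satisfies the threshold.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3 or y.max() == y.min():
        return None
    x_n = np.arange(n) / (n - 1)
    y_n = (y - y.min()) / (y.max() - y.min())
    d = (1.0 - y_n) - x_n
    step = sensitivity / (n - 1)  # sensitivity · mean grid spacing
    maxima = [
        i
        for i in range(1, n - 1)
        if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    for j, lm in enumerate(maxima):
        threshold = d[lm] - step
        end = maxima[j + 1] if j + 1 < len(maxima) else n - 1
        for i in range(lm + 1, end + 1):
            if d[i] < threshold:
                return lm
    return None


def detect_hubs(net: nx.Graph, sensitivity: float = 1.0) -> tuple[set, int | None]:
    """Hub set and degree threshold from the elbow of the degree plot.

    Nodes are sorted by descending degree (symbol as deterministic
    tie-break); kneedle locates the elbow on the rank-vs-degree curve;
    hubs are the nodes ranked strictly before the elbow, extended by any
    ties at the resulting degree threshold ``elbow_k`` (the lowest hub
    degree), so hub degrees always dominate non-hub degrees.
    """
    if net.number_of_nodes() < 5:
        raise ValueError("hub detection needs at least 5 nodes")
    ranked = sorted(net.degree(), key=lambda nd: (-nd[1], nd[0]))
    degrees = np.array([d for _, d in ranked], dtype=float)
    idx = kneedle_elbow(degrees, sensitivity=sensitivity)
    if idx is None or idx == 0:
        logger.warning("no detectable knee on the degree curve; empty hub set")
        return set(), None
    elbow_k = int(degrees[idx - 1])
    hubs = {node for node, deg in ranked if deg >= elbow_k}
    return hubs, elbow_k


def normalize_summaries(summaries: list[TopologySummary]) -> pd.DataFrame:
    """Min-max normalize scalar metrics across a series of networks.

    Rows are networks (indexed by node count); a metric constant across the
    series normalizes to 0 with a warning.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to normalize a series")
    cols = ["density", "avg_neighbours", "clustering", "cpl", "cpl_edges"]
    raw = pd.DataFrame(
        [[getattr(s, c) for c in cols] for s in summaries],
        columns=cols,
        index=pd.Index([s.n_nodes for s in summaries], name="n_nodes"),
    )
    out = raw.copy()
    for c in cols:
        lo, hi = raw[c].min(), raw[c].max()
        if hi == lo:
            logger.warning("metric %s constant across series; normalized to 0", c)
            out[c] = 0.0
        else:
            out[c] = (raw[c] - lo) / (hi - lo)
    return out
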
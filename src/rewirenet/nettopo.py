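"""Thresholded coexpression networks, topology metrics and rewired nulls.

A coexpression network connects two genes when |r| exceeds a threshold
(strictly).  Topology is summarized by the mean local clustering
coefficient, the fitted power-law exponent gamma of the degree distribution
and the R² of its log–log fit (the scale-free topology criterion), and hub
retention (overlap of the k most-connected genes between two networks).

Null networks preserve every gene's degree but randomize who connects to
whom, via repeated Maslov–Sneppen double-edge swaps; random gene pairs for
annotation-sharing nulls are edges sampled from such a rewired network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .diffcoexpr import CorrelationSet

logger = logging.getLogger(__name__)

__all__ = [
    "threshold_network",
    "TopologySummary",
    "summarize_topology",
    "clustering_coefficient",
    "fit_degree_powerlaw",
    "scale_free_fit",
    "hub_overlap",
    "rewire_random",
    "random_gene_pairs",
]


def threshold_network(corr: CorrelationSet, tau: float) -> nx.Graph:
    """Network with an edge wherever |r| > tau (strict); all genes kept as nodes."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    n = len(corr.genes)
    iu = np.triu_indices(n, k=1)
    hit = np.abs(corr.r) > tau
    g = nx.Graph()
    g.add_nodes_from(corr.genes)
    g.add_edges_from(
        (corr.genes[i], corr.genes[j])
        for i, j in zip(iu[0][hit], iu[1][hit])
    )
    return g


def clustering_coefficient(net: nx.Graph, include_low_degree: bool = True) -> float:
    """Mean local clustering coefficient.

    Per node with degree >= 2: (2 × triangles through the node) /
    (deg·(deg−1)); degree-<2 nodes contribute 0 and are included in the mean
    by default (set ``include_low_degree=False`` to average over eligible
    nodes only).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if include_low_degree:
        return float(nx.average_clustering(net))
    nodes = [v for v in net if net.degree(v) >= 2]
    if not nodes:
        return 0.0
    return float(nx.average_clustering(net, nodes=nodes))


def fit_degree_powerlaw(degrees, n_bins: int = 10) -> tuple[float, float]:
    """Power-law exponent and scale-free fit index from a degree sequence.

    Nonzero degrees are binned into ``n_bins`` equal-width bins; each
    nonempty bin contributes its mean degree k̄ and the fraction of nodes it
    holds p(k̄).  A least-squares line of log10 p against log10 k̄ gives
    gamma = −slope; the regression R² is the scale-free topology criterion.
    """
    deg = np.asarray([d for d in degrees if d > 0], dtype=float)
    if len(np.unique(deg)) < 2:
        raise ValueError("need >=2 distinct nonzero degrees")
    edges = np.linspace(deg.min(), deg.max(), n_bins + 1)
    which = np.clip(np.digitize(deg, edges[1:-1]), 0, n_bins - 1)
    ks, ps = [], []
    for b in range(n_bins):
        in_bin = which == b
        if in_bin.any():
            ks.append(deg[in_bin].mean())
            ps.append(in_bin.mean())
    if len(ks) < 3:
        raise ValueError(f"only {len(ks)} nonempty degree bins; need >=3")
    x = np.log10(ks)
    y = np.log10(ps)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-slope), float(r2)


def scale_free_fit(net: nx.Graph, n_bins: int = 10) -> tuple[float, float]:
    """(gamma, R²) of the power-law fit to the network's degree distribution."""
    return fit_degree_powerlaw([d for _, d in net.degree()], n_bins=n_bins)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    degree_sequence: list[int]
    mean_clustering: float
    gamma: float | None
    scale_free_r2: float | None


def summarize_topology(net: nx.Graph, n_bins: int = 10) -> TopologySummary:
    """Node/edge counts, degrees, mean clustering and the power-law fit."""
    try:
        gamma, r2 = scale_free_fit(net, n_bins=n_bins)
    except ValueError:
        gamma = r2 = None
    return TopologySummary(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        degree_sequence=sorted((d for _, d in net.degree()), reverse=True),
        mean_clustering=clustering_coefficient(net),
        gamma=gamma,
        scale_free_r2=r2,
    )


def _ranked_by_degree(net: nx.Graph) -> list:
    """Nodes by descending degree, ties broken by gene ID order."""
    return [v for v, _ in sorted(net.degree(), key=lambda kv: (-kv[1], str(kv[0])))]


def hub_overlap(net_a: nx.Graph, net_b: nx.Graph, k: int) -> float:
    """Fraction of the k most-connected genes of net_a retained in net_b's top k."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > net_a.number_of_nodes() or k > net_b.number_of_nodes():
        raise ValueError("k exceeds network size")
    top_a = set(_ranked_by_degree(net_a)[:k])
    top_b = set(_ranked_by_degree(net_b)[:k])
    return len(top_a & top_b) / k


def rewire_random(net: nx.Graph, n_swaps: int | None = None,
                  seed: int = 0) -> nx.Graph:
    """Degree-preserving randomization by Maslov–Sneppen double-edge swaps.

    Two edges (a,b) and (c,d) are replaced by (a,d) and (c,b) when neither a
    self-loop nor a multi-edge would result; ``n_swaps`` accepted swaps are
    attempted (default 10 × edge count) with a proposal cap of 100·n_swaps.
    The degree multiset is preserved exactly (asserted).  Graphs admitting no
    valid swap (e.g. a triangle) are returned unchanged, with a log message.
    """
    if net.number_of_edges() < 2:
        raise ValueError("need >=2 edges to rewire")
    out = net.copy()
    if n_swaps is None:
        n_swaps = 10 * net.number_of_edges()
    try:
        nx.double_edge_swap(out, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXException as exc:
        logger.info("rewiring stopped early (%s); returning current state", exc)
    before = sorted(d for _, d in net.degree())
    after = sorted(d for _, d in out.degree())
    assert before == after, "double-edge swap changed the degree multiset"
    return out


def random_gene_pairs(net: nx.Graph, n_pairs: int, seed: int = 0) -> list[tuple]:
    """Random gene pairs drawn as edges of a degree-preserving null network.

    Pairs therefore reproduce the original network's edge-endpoint degree
    profile while destroying the specific pairings — the null for
    annotation-sharing comparisons.  If more pairs than edges are requested,
    sampling is with replacement (logged).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if n_pairs == 0:
        return []
    rng = np.random.default_rng(seed)
    null = rewire_random(net, seed=int(rng.integers(2**31)))
    edges = list(null.edges())
    replace = n_pairs > len(edges)
    if replace:
        logger.info("sampling %d pairs with replacement from %d edges",
                    n_pairs, len(edges))
    idx = rng.choice(len(edges), size=n_pairs, replace=replace)
    return [edges[i] for i in idx]
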
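"""Chronnet characterization: local and global network measures.

The measures here read off properties of the event stream from the graph:

* degree ``k_i`` — number of distinct other cells whose events ever occurred
  consecutively with cell ``i`` (self-loops excluded);
* strength ``s_i = sum_j w_ij`` — total number of consecutive co-occurrences
  the cell participates in, a proxy for its event frequency (the ``i = j``
  term appears in the sum, so self-loops are included by default);
* degree/strength distributions and their heavy-tail fits (discrete
  power-law with Clauset-style lower cutoff, log-normal);
* shortest-path statistics — a path length counts how many consecutive-event
  steps separate two cells historically;
* transitivity — the proportion of closed three-cycles, a recurrence /
  reinforcement pattern among three cells;
* degree, betweenness and closeness centralities, with the weighted variant
  of closeness mapping weight to distance as ``1/w`` (strong links = short
  temporal distance).

All functions accept directed or undirected chronnets; directed input is
aggregated to the undirected view first, matching the default analysis mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy import optimize, special, stats

from .build import to_undirected

__all__ = [
    "degrees",
    "strengths",
    "degree_distribution",
    "strength_distribution",
    "fit_discrete_powerlaw",
    "fit_lognormal",
    "tail_fit_comparison",
    "centrality",
    "transitivity",
    "path_stats",
    "edge_density",
    "summarize",
    "PowerLawFit",
    "LogNormalFit",
]


def _undirected(net) -> nx.Graph:
    return to_undirected(net) if net.is_directed() else net


def degrees(net) -> dict:
    """Number of distinct neighbors per node, self-loops excluded."""
    g = _undirected(net)
    return {n: sum(1 for m in g[n] if m != n) for n in g.nodes}


def strengths(net, include_self_loops: bool = True) -> dict:
    """Sum of incident link weights per node.

    The self-loop weight enters once (it is the ``j = i`` term of the sum);
    set ``include_self_loops=False`` to restrict to links to other cells.
    """
    g = _undirected(net)
    out = {}
    for n in g.nodes:
        s = sum(d["weight"] for m, d in g[n].items() if m != n)
        if include_self_loops and g.has_edge(n, n):
            s += g[n][n]["weight"]
        out[n] = s
    return out


def _distribution(values) -> tuple[np.ndarray, np.ndarray]:
    vals, counts = np.unique(np.asarray(list(values)), return_counts=True)
    return vals, counts / counts.sum()


def degree_distribution(net) -> tuple[np.ndarray, np.ndarray]:
    """(k, fraction-of-nodes-with-degree-k); fractions sum to one."""
    g = _undirected(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no degree distribution")
    return _distribution(degrees(g).values())


def strength_distribution(net, include_self_loops: bool = True):
    """(s, fraction of nodes with strength s); fractions sum to one."""
    g = _undirected(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no strength distribution")
    return _distribution(strengths(g, include_self_loops).values())


# ---------------------------------------------------------------------------
# heavy-tail fitting


@dataclass(frozen=True)
class PowerLawFit:
    """Discrete power-law tail fit ``P(k) ~ k^-gamma`` for ``k >= k_min``."""

    gamma: float
    k_min: float
    ks: float  # Kolmogorov-Smirnov distance of the tail fit
    n_tail: int


@dataclass(frozen=True)
class LogNormalFit:
    mu: float
    sigma: float
    ks: float
    n_tail: int


def fit_discrete_powerlaw(values, k_min: float | None = None) -> PowerLawFit:
    """Maximum-likelihood discrete power-law fit with KS-optimal lower cutoff.

    Uses the Clauset–Shalizi–Newman procedure as implemented by igraph's
    ``power_law_fit`` (plfit): for each candidate cutoff the exponent is
    estimated by maximum likelihood and the cutoff minimizing the
    Kolmogorov–Smirnov distance between data and fit is kept.  Pass ``k_min``
    to fix the cutoff instead.

    Raises
    ------
    ValueError
        On degenerate input (fewer than two distinct values).
    """
    vals = np.asarray(list(values))
    vals = vals[vals > 0]
    if np.unique(vals).size < 2:
        raise ValueError("degenerate sample: need at least two distinct positive values")
    fit = ig.power_law_fit([int(v) for v in vals], xmin=k_min)
    n_tail = int(np.sum(vals >= fit.xmin))
    return PowerLawFit(float(fit.alpha), float(fit.xmin), float(fit.D), n_tail)


def powerlaw_loglikelihood(values, gamma: float, k_min: int = 1) -> float:
    """Log-likelihood of a discrete power law (Hurwitz-zeta normalisation)."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[vals >= k_min]
    return float(-len(vals) * math.log(special.zeta(gamma, k_min)) - gamma * np.sum(np.log(vals)))


def fit_lognormal(values, x_min: float | None = None) -> LogNormalFit:
    """Log-normal fit by maximum likelihood on log-values above ``x_min``.

    Returns the location/scale ``(mu, sigma)`` of ``log X`` and the KS
    distance of the fitted tail.  Multiplying the sample by ``e`` shifts
    ``mu`` by one and leaves ``sigma`` unchanged.
    """
    vals = np.asarray(list(values), dtype=float)
    if x_min is not None:
        vals = vals[vals >= x_min]
    vals = vals[vals > 0]
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("degenerate sample for log-normal fit")
    logs = np.log(vals)
    mu, sigma = float(logs.mean()), float(logs.std(ddof=0))
    ks = float(stats.kstest(logs, stats.norm(mu, sigma).cdf).statistic)
    return LogNormalFit(mu, sigma, ks, int(vals.size))


def tail_fit_comparison(values, k_min: float | None = None):
    """Fit power-law and log-normal to the same tail; report both KS distances.

    The cutoff defaults to the KS-optimal power-law cutoff.  The comparison
    describes which family tracks the tail more closely; it deliberately does
    not declare the sample scale-free.
    """
    pl = fit_discrete_powerlaw(values, k_min=k_min)
    ln = _fit_truncated_lognormal(values, pl.k_min)
    return pl, ln


def _fit_truncated_lognormal(values, x_min: float) -> LogNormalFit:
    """MLE of a log-normal left-truncated at ``x_min`` plus its tail KS."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[vals >= x_min]
    logs = np.log(vals)
    lx = math.log(x_min) if x_min > 0 else -np.inf

    def nll(params):
        mu, sig = params
        if sig <= 0:
            return np.inf
        z = stats.norm(mu, sig)
        tail = 1.0 - z.cdf(lx)
        if tail <= 0:
            return np.inf
        return -(np.sum(z.logpdf(logs)) - len(logs) * math.log(tail))

    res = optimize.minimize(
        nll, x0=[logs.mean(), max(logs.std(ddof=0), 1e-3)], method="Nelder-Mead"
    )
    mu, sig = res.x
    z = stats.norm(mu, sig)
    denom = 1.0 - z.cdf(lx)

    def cdf(x):
        return (z.cdf(np.log(x)) - z.cdf(lx)) / denom

    ks = float(stats.kstest(vals, cdf).statistic)
    return LogNormalFit(float(mu), float(sig), ks, int(vals.size))


# ---------------------------------------------------------------------------
# paths, centralities, global structure


def _no_self_loops(g: nx.Graph) -> nx.Graph:
    if any(u == v for u, v in nx.selfloop_edges(g)):
        g = g.copy()
        g.remove_edges_from(list(nx.selfloop_edges(g)))
    return g


def _with_distances(g: nx.Graph) -> nx.Graph:
    """Attach ``distance = 1/weight`` so strong links are short."""
    g = g.copy()
    for u, v, d in g.edges(data=True):
        d["distance"] = 1.0 / d.get("weight", 1)
    return g


def centrality(net, kind: str = "degree", use_weights: bool = False) -> dict:
    """Per-node centrality: ``degree`` (C_i = k_i), ``betweenness`` or ``closeness``.

    Betweenness is the unnormalized pair count ``sum_{j<k} n_i^{jk} / g^{jk}``.
    Closeness is ``1 / sum_j l_ij`` with the sum over the node's connected
    component (components are scored independently; see :func:`components`).
    With ``use_weights`` shortest paths run on ``distance = 1/weight``.
    """
    g = _no_self_loops(_undirected(net))
    if kind == "degree":
        return degrees(g)
    weight = None
    if use_weights:
        g = _with_distances(g)
        weight = "distance"
    if kind == "betweenness":
        return nx.betweenness_centrality(g, normalized=False, weight=weight)
    if kind == "closeness":
        out = {}
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if len(comp) == 1:
                out[next(iter(comp))] = 0.0
                continue
            for n in sub.nodes:
                dist = (
                    nx.single_source_dijkstra_path_length(sub, n, weight=weight)
                    if weight
                    else nx.single_source_shortest_path_length(sub, n)
                )
                out[n] = 1.0 / sum(dist.values())
        return out
    raise ValueError(f"unknown centrality kind {kind!r}")


def transitivity(net) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples."""
    return nx.transitivity(_no_self_loops(_undirected(net)))


def path_stats(net, use_weights: bool = False) -> dict:
    """Average shortest path, diameter and component coverage.

    Hop-count distances by default (a path length is a count of consecutive
    event steps); ``use_weights`` switches to ``1/w`` distances.  Statistics
    are computed on the largest connected component; the returned dict
    reports how much of the graph that component covers.
    """
    g = _no_self_loops(_undirected(net))
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no path statistics")
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    weight = None
    if use_weights:
        giant = _with_distances(giant.copy())
        weight = "distance"
    if giant.number_of_nodes() < 2:
        avg, diam = 0.0, 0.0
    else:
        avg = nx.average_shortest_path_length(giant, weight=weight)
        if weight:
            ecc = nx.eccentricity(giant, weight=weight)
            diam = max(ecc.values())
        else:
            diam = nx.diameter(giant)
    return {
        "average_path_length": float(avg),
        "diameter": float(diam),
        "component_sizes": [len(c) for c in comps],
        "giant_fraction": len(comps[0]) / g.number_of_nodes(),
    }


def edge_density(net) -> float:
    """Existing links over possible links ``n(n-1)/2``; self-loops excluded."""
    g = _no_self_loops(_undirected(net))
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("edge density needs at least two nodes")
    return g.number_of_edges() / (n * (n - 1) / 2)


def summarize(net, fit_tails: bool = False) -> dict:
    """One-stop summary of the standard chronnet measures (JSON-friendly)."""
    g = _undirected(net)
    deg = degrees(g)
    stren = strengths(g)
    out = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "mean_degree": float(np.mean(list(deg.values()))) if deg else 0.0,
        "edge_density": edge_density(g) if g.number_of_nodes() >= 2 else None,
        "transitivity": transitivity(g),
        "total_strength": float(sum(stren.values())),
        "tau": g.graph.get("tau", 0),
    }
    out.update(path_stats(g))
    if fit_tails:
        try:
            pl = fit_discrete_powerlaw(list(deg.values()))
            out["degree_powerlaw"] = {
                "gamma": pl.gamma,
                "k_min": pl.k_min,
                "ks": pl.ks,
            }
        except ValueError:
            out["degree_powerlaw"] = None
        try:
            ln = fit_lognormal([s for s in stren.values() if s > 0])
            out["strength_lognormal"] = {"mu": ln.mu, "sigma": ln.sigma, "ks": ln.ks}
        except ValueError:
            out["strength_lognormal"] = None
    return out
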
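"""Spatiotemporal data mining on chronnets.

Communities in a chronnet group cells whose events occur in the same period:
a burst of activity in one region creates strong links among its cells, and
when activity moves elsewhere a new tightly linked group forms.  Hence

* :func:`detect_communities` — agglomerative modularity optimisation (fast
  greedy, yielding a dendrogram that can be cut at any number of groups) or
  seeded label propagation;
* :func:`cluster_events` — label each event with the community of its cell,
  producing the temporal label sequence ``C = {c_1, ..., c_T}``;
* :func:`smooth_labels` — the window correction ``f(C, delta)`` that repairs
  isolated outlier labels;
* :func:`change_points` — indices where the active community changes,
  i.e. where events start appearing in another region;
* :func:`outlier_nodes` — cells whose degree or strength is far above the
  rest (long or intense activity periods);
* :func:`adjusted_rand_index` — chance-corrected agreement with a reference
  labeling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .build import to_undirected
from .grid import CellSeries

__all__ = [
    "Partition",
    "detect_communities",
    "cut_dendrogram",
    "cluster_events",
    "smooth_labels",
    "change_points",
    "outlier_nodes",
    "adjusted_rand_index",
]


@dataclass
class Partition:
    """A node -> community-id map (ids contiguous from 1) with its modularity.

    Partitions from the agglomerative method keep the merge tree, so any
    number of communities ``k`` can be requested later via
    :func:`cut_dendrogram`.
    """

    labels: dict
    modularity: float
    method: str
    _nodes: list = field(default_factory=list, repr=False)
    _dendrogram: object | None = field(default=None, repr=False)
    _graph: object | None = field(default=None, repr=False)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    @property
    def has_dendrogram(self) -> bool:
        return self._dendrogram is not None

    def community_of(self, node):
        return self.labels[node]


def _to_igraph(net) -> tuple[ig.Graph, list]:
    """Simple weighted igraph copy (self-loops dropped), deterministic node order."""
    g = to_undirected(net) if net.is_directed() else net
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges, weights = [], []
    for u, v, w in g.edges(data="weight", default=1):
        if u == v:
            continue
        edges.append((index[u], index[v]))
        weights.append(float(w))
    h = ig.Graph(n=len(nodes), edges=edges)
    h.es["weight"] = weights
    return h, nodes


def _membership_to_labels(membership, nodes) -> dict:
    """Relabel community ids contiguously from 1, ordered by smallest member."""
    groups: dict[int, list] = {}
    for node, cid in zip(nodes, membership):
        groups.setdefault(cid, []).append(node)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    out = {}
    for new_id, members in enumerate(ordered, start=1):
        for node in members:
            out[node] = new_id
    return out


def detect_communities(
    net,
    method: str = "fastgreedy",
    seed: int = 0,
    n_restarts: int = 10,
) -> Partition:
    """Detect communities on an undirected weighted chronnet.

    ``method="fastgreedy"`` runs agglomerative modularity optimisation and
    returns the best-modularity cut together with the full dendrogram (cut it
    at any ``k`` with :func:`cut_dendrogram`).  ``method="labelprop"`` runs
    weighted label propagation ``n_restarts`` times from the given seed and
    keeps the run with maximal modularity — the algorithm is order-dependent,
    so seeding plus restarts makes the reported partition reproducible.
    Link weights are always taken into account: strong (recurrent) links bind
    communities.
    """
    h, nodes = _to_igraph(net)
    if h.vcount() == 0:
        raise ValueError("cannot detect communities on an empty graph")
    if method in ("fastgreedy", "agglomerative-modularity"):
        dendro = h.community_fastgreedy(weights="weight" if h.ecount() else None)
        clustering = dendro.as_clustering()
        labels = _membership_to_labels(clustering.membership, nodes)
        mod = h.modularity(clustering.membership, weights="weight" if h.ecount() else None)
        return Partition(labels, float(mod), "fastgreedy", nodes, dendro, h)
    if method in ("labelprop", "label-propagation"):
        rng = random.Random(seed)
        best = None
        for _ in range(max(1, n_restarts)):
            random.seed(rng.randrange(2**31))  # igraph draws from Python's RNG
            cl = h.community_label_propagation(weights="weight" if h.ecount() else None)
            mod = h.modularity(cl.membership, weights="weight" if h.ecount() else None)
            if best is None or mod > best[0]:
                best = (mod, cl.membership)
        labels = _membership_to_labels(best[1], nodes)
        return Partition(labels, float(best[0]), "labelprop", nodes)
    raise ValueError(f"unknown community method {method!r}")


def cut_dendrogram(partition: Partition, k: int) -> Partition:
    """Cut an agglomerative merge tree into exactly ``k`` communities."""
    if not partition.has_dendrogram:
        raise ValueError("partition carries no dendrogram (use the fastgreedy method)")
    n = len(partition._nodes)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    clustering = partition._dendrogram.as_clustering(n=k)
    h = partition._graph
    labels = _membership_to_labels(clustering.membership, partition._nodes)
    mod = h.modularity(clustering.membership, weights="weight" if h.ecount() else None)
    return Partition(
        labels, float(mod), partition.method, partition._nodes,
        partition._dendrogram, partition._graph,
    )


def cluster_events(cells, partition: Partition) -> np.ndarray:
    """Label each event with the community of its cell, in time order.

    This turns a node partition into the temporal sequence
    ``C = {c_1, ..., c_T}`` whose runs are spatiotemporal clusters.
    """
    ids = cells.cells if isinstance(cells, CellSeries) else np.asarray(cells)
    try:
        return np.array([partition.labels[int(c)] for c in ids], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"cell {exc.args[0]} is not labeled in the partition") from exc


def smooth_labels(seq, delta: int = 3) -> np.ndarray:
    """Window correction ``f(C, delta)`` for outlier labels.

    For each position ``t`` whose full window exists, if the surrounding
    labels ``{c_(t-delta), ..., c_(t-1), c_(t+1), ..., c_(t+delta)}`` (taken
    from the *original* sequence, excluding ``c_t`` itself) contain exactly
    one unique value, ``c_t`` is replaced by that value.  All corrections are
    applied simultaneously, so the result does not depend on scan order.
    Boundary positions without a full window are left unchanged.

    ``delta`` must be an odd natural number (it is the one-sided window
    radius in events).
    """
    if delta < 1 or delta % 2 == 0:
        raise ValueError("delta must be an odd natural number")
    c = np.asarray(seq)
    n = c.size
    out = c.copy()
    if n < 2 * delta + 1:
        return out
    neighbors = np.stack(
        [c[delta + off : n - delta + off] for off in range(-delta, delta + 1) if off != 0]
    )
    uniform = np.all(neighbors == neighbors[0], axis=0)
    out[delta : n - delta][uniform] = neighbors[0][uniform]
    return out


def change_points(seq) -> list[int]:
    """1-based indices ``t`` with ``c_t != c_(t-1)`` (first index is never one)."""
    c = np.asarray(seq)
    if c.size < 2:
        return []
    return [int(i) + 2 for i in np.flatnonzero(c[1:] != c[:-1])]


def outlier_nodes(net, by: str = "degree", top_fraction: float = 0.02) -> set:
    """Cells in the top fraction of degree or strength.

    High-degree cells had activity periods long enough to co-occur with many
    other cells; high-strength cells simply hosted many events.  Ties are
    broken deterministically by node id.  The result always contains at
    least one node.
    """
    from .measures import degrees, strengths  # local import avoids a cycle

    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    if by == "degree":
        stat = degrees(net)
    elif by == "strength":
        stat = strengths(net)
    else:
        raise ValueError(f"unknown statistic {by!r}")
    if not stat:
        return set()
    n_top = max(1, int(np.ceil(top_fraction * len(stat))))
    ranked = sorted(stat.items(), key=lambda kv: (-kv[1], kv[0]))
    return {node for node, _ in ranked[:n_top]}


def remove_outliers(net, by: str = "degree", top_fraction: float = 0.01):
    """Copy of the chronnet with the top-fraction outlier nodes removed."""
    out = net.copy()
    out.remove_nodes_from(outlier_nodes(net, by=by, top_fraction=top_fraction))
    return out


def strongest_links(net, fraction: float = 0.2):
    """Subgraph keeping only the given fraction of highest-weight links."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    edges = sorted(
        net.edges(data="weight"), key=lambda e: (-e[2], e[0], e[1])
    )
    keep = edges[: max(1, int(np.ceil(fraction * len(edges))))]
    out = net.__class__()
    out.graph.update(net.graph)
    out.add_nodes_from(net.nodes)
    out.add_weighted_edges_from(keep)
    return out


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings (1 = identical up to renaming)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))
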
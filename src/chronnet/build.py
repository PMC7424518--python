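"""Chronnet construction: chronological links between grid cells.

A chronnet is a weighted graph over grid cells in which a directed link
``(v_i, v_j)`` records that an event in cell ``i`` was followed, within a
sliding window of ``h`` event steps, by an event in cell ``j``.  The link
weight ``w_ij`` counts how often that happened, so recurrent consecutive
activity between two regions shows up as a strong link while sporadic
co-occurrences stay weak (and can be pruned).  Self-loops ``i == j`` count
consecutive events inside one cell.

Construction is a single pass over the time-sorted event sequence and is
linear in the number of events for fixed ``h``.

Parallel events — several events sharing one timestamp — are handled by
linking every node with an event at one timestamp to every *different* node
with an event at the next timestamp (all combinations of different nodes
between the two groups).  When every timestamp is unique this reduces exactly
to the consecutive-pair rule, which does allow ``i == j``; the
``parallel_self_loops`` flag extends self-loop counting to genuine parallel
groups as well.

Graphs are :mod:`networkx` objects whose ``graph`` attribute dict carries
provenance (the build configuration and any pruning threshold applied).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import networkx as nx
import numpy as np

__all__ = [
    "BuildConfig",
    "build_chronnet",
    "build_snapshots",
    "group_parallel",
    "to_undirected",
    "prune",
    "merge",
    "write_edgelist",
    "read_edgelist",
]

_EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class BuildConfig:
    """Parameters of the chronnet construction.

    Attributes
    ----------
    h
        Sliding-window size in event steps (>= 1).  An event is linked to
        every later event at lag ``1..h`` (or exactly ``h`` if ``strict_lag``).
    d_max
        Optional maximum distance between two events for a link to form
        (same units as the coordinates for ``metric="planar"``, kilometres
        for ``metric="greatcircle"``).  ``None`` disables the cutoff.
    metric
        ``"planar"`` (Euclidean) or ``"greatcircle"`` (haversine on lon/lat).
    delta_t
        Optional snapshot length in time units.  When set, links never cross
        snapshot boundaries; ``delta_t`` spanning the whole record reproduces
        the single static network.
    directed
        Return the directed graph (default); otherwise aggregate to the
        undirected one via :func:`to_undirected`.
    self_loops
        Count consecutive events in the same cell as self-loop weight.
    parallel_self_loops
        Also count same-node pairs across genuine parallel groups (groups
        with more than one distinct node); off by default, following the
        all-combinations-of-*different*-nodes rule.
    strict_lag
        Link only at lag exactly ``h`` instead of all lags ``1..h``.
    """

    h: int = 1
    d_max: float | None = None
    metric: str = "planar"
    delta_t: float | None = None
    directed: bool = True
    self_loops: bool = True
    parallel_self_loops: bool = False
    strict_lag: bool = False

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("window size h must be >= 1")
        if self.d_max is not None and self.d_max <= 0:
            raise ValueError("d_max must be positive when set")
        if self.delta_t is not None and self.delta_t <= 0:
            raise ValueError("delta_t must be positive when set")
        if self.metric not in ("planar", "greatcircle"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def lags(self) -> range:
        return range(self.h, self.h + 1) if self.strict_lag else range(1, self.h + 1)


def _pair_distance(coords: np.ndarray, ia, ib, metric: str) -> np.ndarray:
    a, b = coords[ia], coords[ib]
    if metric == "planar":
        return np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1])
    lon1, lat1, lon2, lat2 = map(np.radians, (a[:, 0], a[:, 1], b[:, 0], b[:, 1]))
    s = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0, 1)))


def group_parallel(times) -> list[np.ndarray]:
    """Split a sorted timestamp array into maximal runs of equal timestamps.

    Returns the list of index arrays, one per distinct timestamp, in time
    order.  With all-distinct timestamps every group is a singleton and the
    construction reduces to the plain consecutive-pair rule.
    """
    times = np.asarray(times)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("timestamps must be sorted")
    if times.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(times) != 0) + 1
    return np.split(np.arange(times.size), boundaries)


def _validate_inputs(cells, times, coords, cfg):
    cells = np.asarray(cells, dtype=np.int64)
    times = np.asarray(times)
    if cells.shape[0] != times.shape[0]:
        raise ValueError("cells and times must have equal length")
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("events must be time-sorted (use sort_events)")
    if cfg.d_max is not None:
        if coords is None:
            raise ValueError("d_max set but no coordinates given")
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] != cells.shape[0]:
            raise ValueError("coords length does not match events")
    return cells, times, coords


def _accumulate(cells, times, coords, cfg, counts: dict) -> None:
    """Add link counts for one snapshot's worth of events into ``counts``."""
    n = cells.size
    if n < 2:
        return
    distinct = not np.any(np.diff(times) == 0)
    if distinct:
        for g in cfg.lags:
            if g >= n:
                break
            ia = np.arange(0, n - g)
            ib = ia + g
            keep = np.ones(ia.size, dtype=bool)
            if not cfg.self_loops:
                keep &= cells[ia] != cells[ib]
            if cfg.d_max is not None:
                keep &= _pair_distance(coords, ia, ib, cfg.metric) <= cfg.d_max
            src, dst = cells[ia[keep]], cells[ib[keep]]
            if src.size == 0:
                continue
            base = int(cells.max()) + 1
            pairs, mult = np.unique(src.astype(np.int64) * base + dst, return_counts=True)
            for key, m in zip(pairs, mult):
                uv = (int(key) // base, int(key) % base)
                counts[uv] = counts.get(uv, 0) + int(m)
        return

    groups = group_parallel(times)
    for g in cfg.lags:
        for r in range(len(groups) - g):
            ga, gb = groups[r], groups[r + g]
            singletons = ga.size == 1 and gb.size == 1
            # one link per combination of nodes between the two groups
            seen = set()
            for a in ga:
                for b in gb:
                    u, v = int(cells[a]), int(cells[b])
                    if u == v:
                        if not cfg.self_loops:
                            continue
                        if not singletons and not cfg.parallel_self_loops:
                            continue
                    if (u, v) in seen:
                        continue
                    if cfg.d_max is not None and not _group_pair_in_range(
                        cells, coords, ga, gb, u, v, cfg
                    ):
                        continue
                    seen.add((u, v))
                    counts[(u, v)] = counts.get((u, v), 0) + 1


def _group_pair_in_range(cells, coords, ga, gb, u, v, cfg) -> bool:
    """True if any event pair realising node pair (u, v) is within d_max."""
    ia = ga[cells[ga] == u]
    ib = gb[cells[gb] == v]
    ii, jj = np.meshgrid(ia, ib, indexing="ij")
    d = _pair_distance(coords, ii.ravel(), jj.ravel(), cfg.metric)
    return bool(np.any(d <= cfg.d_max))


def _as_graph(counts: dict, nodes, cfg: BuildConfig) -> nx.DiGraph | nx.Graph:
    g = nx.DiGraph()
    g.add_nodes_from(int(c) for c in nodes)
    g.add_weighted_edges_from((u, v, w) for (u, v), w in counts.items())
    g.graph["config"] = asdict(cfg)
    g.graph["tau"] = 0
    if not cfg.directed:
        g = to_undirected(g)
    return g


def build_chronnet(cells, times, coords=None, cfg: BuildConfig | None = None):
    """Build a chronnet from a time-sorted, cell-assigned event sequence.

    Parameters
    ----------
    cells
        Per-event cell id (the node the event maps to).
    times
        Per-event timestamps, non-decreasing.
    coords
        Per-event ``(x, y)`` locations; required only when ``cfg.d_max`` is
        set, since the distance cutoff is evaluated between the events
        themselves, not between cell centers.
    cfg
        Build parameters; defaults to ``BuildConfig()`` (h=1, no distance or
        snapshot restriction, directed, self-loops on).

    Returns
    -------
    networkx.DiGraph or networkx.Graph
        Weighted graph over the active cells, with construction provenance
        in ``graph["config"]``.
    """
    cfg = cfg or BuildConfig()
    cells, times, coords = _validate_inputs(cells, times, coords, cfg)
    counts: dict = {}
    if cfg.delta_t is None or cells.size == 0:
        _accumulate(cells, times, coords, cfg, counts)
    else:
        for lo, hi in _window_slices(times, cfg.delta_t):
            _accumulate(
                cells[lo:hi],
                times[lo:hi],
                None if coords is None else coords[lo:hi],
                cfg,
                counts,
            )
    return _as_graph(counts, np.unique(cells), cfg)


def _window_slices(times: np.ndarray, delta_t: float):
    """Consecutive non-overlapping windows [t0 + k*dt, t0 + (k+1)*dt)."""
    t0 = times[0]
    win = np.floor((times - t0) / delta_t).astype(np.int64)
    bounds = np.flatnonzero(np.diff(win) != 0) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [times.size]))
    return list(zip(starts, ends))


def build_snapshots(cells, times, coords=None, cfg: BuildConfig | None = None):
    """Build the temporal-network layers: one chronnet per ``delta_t`` window.

    Windows are consecutive and non-overlapping; no link crosses a window
    boundary.  Empty windows yield empty graphs, preserved in sequence, so
    the list index is the window index.  A ``delta_t`` spanning the whole
    record returns a single snapshot identical to :func:`build_chronnet`.
    """
    cfg = cfg or BuildConfig()
    if cfg.delta_t is None:
        raise ValueError("build_snapshots requires cfg.delta_t")
    cells, times, coords = _validate_inputs(cells, times, coords, cfg)
    if cells.size == 0:
        return []
    t0 = times[0]
    n_windows = int(np.floor((times[-1] - t0) / cfg.delta_t)) + 1
    per_window: list[dict] = [dict() for _ in range(n_windows)]
    nodes_per_window: list[np.ndarray] = [np.empty(0, np.int64)] * n_windows
    for lo, hi in _window_slices(times, cfg.delta_t):
        k = int(np.floor((times[lo] - t0) / cfg.delta_t))
        _accumulate(
            cells[lo:hi],
            times[lo:hi],
            None if coords is None else coords[lo:hi],
            cfg,
            per_window[k],
        )
        nodes_per_window[k] = np.unique(cells[lo:hi])
    inner = replace(cfg, delta_t=None)
    return [
        _as_graph(counts, nodes, inner)
        for counts, nodes in zip(per_window, nodes_per_window)
    ]


def to_undirected(net: nx.DiGraph) -> nx.Graph:
    """Aggregate a directed chronnet to the undirected one.

    The undirected weight is the total number of co-occurrences regardless of
    order, ``w_ij + w_ji`` for ``i != j`` (sum of in- and out-link weights);
    self-loop weights are carried over unchanged.
    """
    if not net.is_directed():
        return net
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for u, v, w in net.edges(data="weight"):
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    g.graph.update(net.graph)
    cfg = dict(g.graph.get("config", {}))
    cfg["directed"] = False
    g.graph["config"] = cfg
    return g


def prune(net, tau: float):
    """Remove links whose weight is equal or lower than the threshold ``tau``.

    Weak links represent sporadic co-occurrences (often data noise); pruning
    them exposes the recurrent structure.  Nodes left isolated are retained —
    the grid provenance is kept — but listed in
    ``graph["isolated_after_prune"]`` so path-based measures can exclude
    them.  ``tau = 0`` is the identity on a freshly built chronnet (all
    weights are >= 1).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    g = net.copy()
    drop = [(u, v) for u, v, w in g.edges(data="weight") if w <= tau]
    g.remove_edges_from(drop)
    g.graph["tau"] = tau
    g.graph["isolated_after_prune"] = [n for n in g.nodes if g.degree(n) == 0]
    return g


def merge(*nets):
    """Merge chronnets built from consecutive chunks of one sorted data set.

    Weights of coincident links add.  Together with chunk-wise
    :func:`build_chronnet` this supports parallel construction; note that
    links spanning a chunk boundary must be added by building a small overlap
    chunk (the last ``h`` events of one chunk plus the next chunk).
    """
    if not nets:
        raise ValueError("nothing to merge")
    directed = nets[0].is_directed()
    out = nx.DiGraph() if directed else nx.Graph()
    out.graph.update(nets[0].graph)
    for net in nets:
        if net.is_directed() != directed:
            raise ValueError("cannot merge directed with undirected chronnets")
        out.add_nodes_from(net.nodes)
        for u, v, w in net.edges(data="weight"):
            if out.has_edge(u, v):
                out[u][v]["weight"] += w
            else:
                out.add_edge(u, v, weight=w)
    return out


def write_edgelist(net, path) -> None:
    """Write ``src,dst,weight`` comma-delimited text (self-loops as src == dst)."""
    with open(path, "w") as fh:
        fh.write("src,dst,weight\n")
        for u, v, w in net.edges(data="weight"):
            fh.write(f"{u},{v},{w}\n")


def read_edgelist(path, directed: bool = False):
    """Read a chronnet from the edge-list format written by :func:`write_edgelist`."""
    g = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if header.strip().lower() not in ("src,dst,weight", ""):
            raise ValueError(f"unrecognized edge-list header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            u, v, w = line.strip().split(",")
            g.add_edge(int(u), int(v), weight=float(w) if "." in w else int(w))
    g.graph["tau"] = 0
    return g
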
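import numpy as np
import pytest

from chronnet import BuildConfig, build_chronnet, to_undirected


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cell_sequence(rng, n_events, n_cells):
    """A random time-sorted cell sequence with distinct integer timestamps."""
    cells = rng.integers(0, n_cells, size=n_events)
    times = np.arange(1, n_events + 1)
    return cells, times


def brute_force_weights(cells, times, h=1, d_max=None, coords=None,
                        self_loops=True, strict_lag=False):
    """Independent O(T^2) enumeration of the chronological link rule.

    Valid for distinct timestamps: for every ordered event pair at sequence
    lag 1..h (or exactly h), one unit of weight goes to the ordered cell
    pair, subject to the optional distance cutoff.
    """
    assert len(set(times)) == len(times), "oracle assumes distinct timestamps"
    counts = {}
    lags = [h] if strict_lag else list(range(1, h + 1))
    n = len(cells)
    for a in range(n):
        for b in range(a + 1, n):
            if (b - a) not in lags:
                continue
            u, v = int(cells[a]), int(cells[b])
            if u == v and not self_loops:
                continue
            if d_max is not None:
                dx = coords[a][0] - coords[b][0]
                dy = coords[a][1] - coords[b][1]
                if (dx * dx + dy * dy) ** 0.5 > d_max:
                    continue
            counts[(u, v)] = counts.get((u, v), 0) + 1
    return counts


def edge_weights(net):
    """Weighted edge dict of a graph, ordered pairs for digraphs."""
    if net.is_directed():
        return {(u, v): w for u, v, w in net.edges(data="weight")}
    return {tuple(sorted((u, v))): w for u, v, w in net.edges(data="weight")}


@pytest.fixture
def random_undirected_chronnet(rng):
    """A mid-sized undirected chronnet from a random event sequence."""
    cells, times = random_cell_sequence(rng, 400, 30)
    return to_undirected(build_chronnet(cells, times, cfg=BuildConfig()))
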
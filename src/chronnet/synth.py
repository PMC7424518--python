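"""Synthetic spatiotemporal event generators.

The basic generator is a square grid ``Gr`` paired with a probability matrix
``P`` of the same shape: at every time step ``t = 1..T`` each cell emits an
event independently with its probability ``P_ij`` (so several events can
share a timestamp), the event landing uniformly inside the cell.  Varying the
distribution family of ``P`` (uniform, power-law, exponential) changes the
spatial heterogeneity of the stream and hence the degree/strength
distribution of the resulting chronnet.

Scenario builders compose this primitive into the structured data sets used
throughout the package's tests:

* :func:`four_period_scenario` — four consecutive intervals, each
  concentrating probability on a different quadrant of the grid, plus a tiny
  background probability that sprinkles outlier events anywhere;
* :func:`alternating_gaussians` — bursts of Gaussian-distributed points that
  cycle among a small set of spatial centers, giving spatiotemporal clusters
  with known change points;
* :func:`sample_trajectory` — fixed-step samples of the Lorenz or Rössler
  system in their chaotic regimes, projected onto two coordinates.

Every generator is seed-deterministic and, where a ground truth exists,
returns the planted label per event so downstream clustering can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventTable, events_from_arrays
from .grid import RectGrid

__all__ = [
    "ProbabilityMatrix",
    "make_probability_matrix",
    "generate_from_matrix",
    "four_period_scenario",
    "alternating_gaussians",
    "sample_trajectory",
]


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-cell event emission probabilities over a rectangular grid.

    ``p[iy, ix]`` is the per-step probability that cell ``(ix, iy)`` emits an
    event; the grid supplies the spatial embedding of the cells.
    """

    p: np.ndarray
    grid: RectGrid

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"matrix shape {p.shape} does not match grid ({self.grid.ny}, {self.grid.nx})"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", p)

    @property
    def p_max(self) -> float:
        return float(self.p.max())


def _unit_grid(nx: int, ny: int) -> RectGrid:
    return RectGrid(0.0, float(nx), 0.0, float(ny), nx, ny)


def make_probability_matrix(
    shape: tuple[int, int],
    kind: str = "uniform",
    p_max: float = 0.1,
    exponent: float = 2.5,
    rate: float = 1.0,
    seed: int = 0,
    grid: RectGrid | None = None,
) -> ProbabilityMatrix:
    """Draw per-cell probabilities from a named family, rescaled to ``p_max``.

    Parameters
    ----------
    shape
        ``(ny, nx)`` cell counts.
    kind
        ``"uniform"`` — flat spread; ``"powerlaw"`` — Pareto draws with the
        given ``exponent`` (a few very active cells, many quiet ones);
        ``"exponential"`` — exponential draws with the given ``rate``
        (intermediate heterogeneity).
    p_max
        The largest entry after rescaling; everything else scales
        proportionally, so ``p_max`` controls the overall event rate.
    """
    ny, nx = shape
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        raw = rng.uniform(0.0, 1.0, size=shape)
    elif kind == "powerlaw":
        raw = rng.pareto(exponent - 1.0, size=shape) + 1.0
    elif kind == "exponential":
        raw = rng.exponential(1.0 / rate, size=shape)
    else:
        raise ValueError(f"unknown probability-matrix kind {kind!r}")
    p = raw * (p_max / raw.max())
    return ProbabilityMatrix(p, grid or _unit_grid(nx, ny))


def generate_from_matrix(
    matrix: ProbabilityMatrix,
    T: int,
    seed: int = 0,
    t_offset: int = 0,
) -> EventTable:
    """Emit events for ``T`` steps from a probability matrix.

    At each step every cell flips its own coin; all events of one step share
    the timestamp (parallel events), ordered by cell id for determinism.
    Event positions are uniform within their cell.  ``t_offset`` shifts the
    timestamps, which lets scenario builders concatenate regimes.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    grid = matrix.grid
    ny, nx = matrix.p.shape
    hits = rng.random((T, ny, nx)) < matrix.p  # step-major: time order preserved
    t_idx, iy, ix = np.nonzero(hits)
    n = t_idx.size
    x = grid.x_min + (ix + rng.random(n)) * grid.cell_width
    y = grid.y_min + (iy + rng.random(n)) * grid.cell_height
    t = t_idx.astype(np.int64) + 1 + t_offset
    return events_from_arrays(x, y, t)


def _quadrant_matrix(nx: int, ny: int, quadrant: int, p_in: float, p_out: float) -> np.ndarray:
    """Probability matrix concentrated on one quadrant block of the grid."""
    p = np.full((ny, nx), p_out, dtype=float)
    hx, hy = nx // 2, ny // 2
    # chronological tour: lower-left, lower-right, upper-right, upper-left
    xs, ys = {
        0: (slice(0, hx), slice(0, hy)),
        1: (slice(hx, nx), slice(0, hy)),
        2: (slice(hx, nx), slice(hy, ny)),
        3: (slice(0, hx), slice(hy, ny)),
    }[quadrant]
    p[ys, xs] = p_in
    return p


def four_period_scenario(
    T: int = 12_000,
    grid_shape: tuple[int, int] = (20, 20),
    p_in: float = 0.02,
    p_out: float = 1e-5,
    seed: int = 0,
) -> tuple[EventTable, np.ndarray, RectGrid]:
    """Four consecutive activity regimes on the four quadrants of a grid.

    Time is split into four equal intervals; during interval ``q`` the cells
    of quadrant ``q`` each emit with probability ``p_in`` per step while
    every other cell keeps a tiny background probability ``p_out``, which
    produces a handful of outlier events outside the active region.  Events
    within one interval share timestamps freely (parallel events).

    Returns ``(events, planted_labels, grid)`` where the planted label of an
    event is its interval number ``1..4`` — the ground truth for
    spatiotemporal clustering.
    """
    if T % 4:
        raise ValueError("T must be divisible by 4")
    ny, nx = grid_shape
    grid = _unit_grid(nx, ny)
    rng = np.random.default_rng(seed)
    period = T // 4
    tables, labels = [], []
    for q in range(4):
        p = _quadrant_matrix(nx, ny, q, p_in, p_out)
        sub = generate_from_matrix(
            ProbabilityMatrix(p, grid),
            period,
            seed=int(rng.integers(2**31)),
            t_offset=q * period,
        )
        tables.append(sub)
        labels.append(np.full(sub.n_events, q + 1, dtype=np.int64))
    x = np.concatenate([t.x for t in tables])
    y = np.concatenate([t.y for t in tables])
    t = np.concatenate([t.t for t in tables])
    return events_from_arrays(x, y, t), np.concatenate(labels), grid


#: default burst centers on the [0, 3000]^2 domain.  The domain is chosen so
#: that with sigma = 100 the clusters are genuinely separated: the nearest
#: community boundary lies ~7.5 sigma from each center, so essentially no
#: event lands in a cell dominated by another cluster.
DEFAULT_CENTERS_2 = ((750.0, 1500.0), (2250.0, 1500.0))
DEFAULT_CENTERS_3 = ((750.0, 750.0), (2250.0, 750.0), (1500.0, 2250.0))


def alternating_gaussians(
    centers=DEFAULT_CENTERS_2,
    sigma: float = 100.0,
    n_bursts: int = 40,
    events_per_burst: int = 25_000,
    domain: tuple[float, float] = (0.0, 3000.0),
    seed: int = 0,
) -> tuple[EventTable, np.ndarray]:
    """Bursts of Gaussian point clouds cycling among fixed spatial centers.

    Burst ``b`` draws ``events_per_burst`` points from an isotropic Gaussian
    around ``centers[b % len(centers)]``; timestamps increase by one per
    event, so bursts follow each other without overlap and the planted
    change points sit exactly at burst boundaries.  Points are clipped to the
    square ``domain``.

    Returns ``(events, planted_labels)`` with the planted label = the center
    index (1-based) of the event's burst.
    """
    if len(centers) < 1:
        raise ValueError("need at least one center")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = domain
    xs, ys, labels = [], [], []
    for b in range(n_bursts):
        cx, cy = centers[b % len(centers)]
        pts = rng.normal((cx, cy), sigma, size=(events_per_burst, 2))
        np.clip(pts, lo, hi, out=pts)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        labels.append(np.full(events_per_burst, b % len(centers) + 1, dtype=np.int64))
    n = n_bursts * events_per_burst
    table = events_from_arrays(
        np.concatenate(xs), np.concatenate(ys), np.arange(1, n + 1)
    )
    return table, np.concatenate(labels)


# chaotic-regime defaults for the two benchmark systems
LORENZ_PARAMS = {"sigma": 10.0, "beta": 8.0 / 3.0, "rho": 28.0}
ROSSLER_PARAMS = {"a": 0.2, "b": 0.2, "c": 5.7}
_AXES = {"x": 0, "y": 1, "z": 2}


def _lorenz(state, p):
    x, y, z = state
    return np.array(
        [p["sigma"] * (y - x), x * (p["rho"] - z) - y, x * y - p["beta"] * z]
    )


def _rossler(state, p):
    x, y, z = state
    return np.array([-y - z, x + p["a"] * y, p["b"] + z * (x - p["c"])])


def sample_trajectory(
    system: str = "lorenz",
    params: dict | None = None,
    duration: float | None = None,
    dt: float | None = None,
    projection: tuple[str, str] | None = None,
    seed: int | None = None,
    burn_in: float = 10.0,
) -> EventTable:
    """Sample a chaotic trajectory at a fixed time step as an event stream.

    Integrates the Lorenz (defaults ``sigma=10, beta=8/3, rho=28``;
    ``duration=200, dt=0.01``, projection ``(x, y)``) or Rössler system
    (``a=b=0.2, c=5.7``; ``duration=1000, dt=0.02``, projection ``(x, z)``)
    with classic fixed-step fourth-order Runge–Kutta.  The first ``burn_in``
    time units are discarded so sampling starts on the attractor.  Each
    retained step becomes one event with timestamps ``1, 2, 3, ...``; the
    ``seed`` (if given) jitters the initial condition, yielding independent
    realisations of the same attractor.
    """
    if system == "lorenz":
        deriv, defaults = _lorenz, LORENZ_PARAMS
        duration = 200.0 if duration is None else duration
        dt = 0.01 if dt is None else dt
        projection = ("x", "y") if projection is None else projection
        state = np.array([1.0, 1.0, 1.0])
    elif system == "rossler":
        deriv, defaults = _rossler, ROSSLER_PARAMS
        duration = 1000.0 if duration is None else duration
        dt = 0.02 if dt is None else dt
        projection = ("x", "z") if projection is None else projection
        state = np.array([1.0, 1.0, 0.0])
    else:
        raise ValueError(f"unknown system {system!r}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = {**defaults, **(params or {})}
    if seed is not None:
        state = state + np.random.default_rng(seed).uniform(-0.5, 0.5, size=3)

    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt))
    ia, ib = _AXES[projection[0]], _AXES[projection[1]]
    out = np.empty((n_keep, 2))
    for step in range(n_burn + n_keep):
        k1 = deriv(state, p)
        k2 = deriv(state + 0.5 * dt * k1, p)
        k3 = deriv(state + 0.5 * dt * k2, p)
        k4 = deriv(state + dt * k3, p)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if step >= n_burn:
            out[step - n_burn] = state[ia], state[ib]
    return events_from_arrays(out[:, 0], out[:, 1], np.arange(1, n_keep + 1))
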
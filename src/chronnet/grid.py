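"""Mapping event coordinates onto grid cells.

The network construction starts by coarse-graining space: every event is
assigned to a cell of a regular grid, and each cell becomes a candidate node.
For planar data a rectangular grid (:class:`RectGrid`) is built here.  For
global geographic data an icosahedral hexagonal discrete global grid (DGGS)
gives cells of near-uniform area; the package computes the closed-form cell
count and mean cell area of such grids analytically and otherwise accepts
cell assignments produced by an external DGGS tool
(:func:`load_cell_assignment`).

Cell ids are 0-based and row-major: ``cell_id = iy * nx + ix`` with
``ix = floor((x - x_min) / cell_width)`` and analogously for ``iy``.  Cells
are half-open ``[low, high)`` intervals except the last cell along each axis,
which is closed so the maximum coordinate remains assignable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventTable

__all__ = [
    "RectGrid",
    "CellSeries",
    "fit_bounds",
    "assign_cells",
    "dggs_cell_count",
    "dggs_mean_cell_area",
    "load_cell_assignment",
    "EARTH_SURFACE_KM2",
]

#: conventional Earth surface area in km^2 (sphere of authalic radius)
EARTH_SURFACE_KM2 = 510_072_000.0


@dataclass(frozen=True)
class RectGrid:
    """A rectangular grid over the bounding box ``[x_min, x_max] x [y_min, y_max]``."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate grid extent: need x_min < x_max and y_min < y_max")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid needs at least one cell per axis")

    @property
    def cell_width(self) -> float:
        return (self.x_max - self.x_min) / self.nx

    @property
    def cell_height(self) -> float:
        return (self.y_max - self.y_min) / self.ny

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_id(self, ix, iy):
        """Row-major id of cell column ``ix``, row ``iy``."""
        return np.asarray(iy) * self.nx + np.asarray(ix)

    def cell_rowcol(self, cell_id):
        """Inverse of :meth:`cell_id`: ``(ix, iy)``."""
        cell_id = np.asarray(cell_id)
        return cell_id % self.nx, cell_id // self.nx

    def cell_center(self, cell_id):
        ix, iy = self.cell_rowcol(cell_id)
        return (
            self.x_min + (ix + 0.5) * self.cell_width,
            self.y_min + (iy + 0.5) * self.cell_height,
        )


@dataclass
class CellSeries:
    """Per-event cell ids, aligned to a (sorted) :class:`~chronnet.events.EventTable`."""

    cells: np.ndarray
    grid: RectGrid | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.grid is not None:
            if self.cells.size and (
                self.cells.min() < 0 or self.cells.max() >= self.grid.n_cells
            ):
                raise ValueError("cell id out of range for the attached grid")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_cells(self) -> int:
        """Number of distinct cells that received at least one event."""
        return int(np.unique(self.cells).size)


def fit_bounds(table: EventTable, nx: int, ny: int, padding: float = 0.0) -> RectGrid:
    """Fit an ``nx x ny`` grid to the bounding box of a non-empty event table.

    ``padding`` expands each side by that fraction of the corresponding
    coordinate range.  A table whose events are collinear along an axis has no
    usable extent and is rejected.
    """
    if table.n_events == 0:
        raise ValueError("cannot fit a grid to an empty event table")
    x, y = table.x, table.y
    dx, dy = x.max() - x.min(), y.max() - y.min()
    if dx <= 0 or dy <= 0:
        raise ValueError("degenerate extent: events span zero range along an axis")
    return RectGrid(
        x.min() - padding * dx,
        x.max() + padding * dx,
        y.min() - padding * dy,
        y.max() + padding * dy,
        nx,
        ny,
    )


def assign_cells(table: EventTable, grid: RectGrid) -> CellSeries:
    """Assign each event to its grid cell (floor rule, closed top edge).

    Raises
    ------
    ValueError
        If any event falls outside the grid; the message lists the first
        offending event indices.
    """
    x, y = table.x, table.y
    oob = (x < grid.x_min) | (x > grid.x_max) | (y < grid.y_min) | (y > grid.y_max)
    if oob.any():
        idx = np.flatnonzero(oob)
        shown = ", ".join(map(str, idx[:10]))
        more = "" if idx.size <= 10 else f" (+{idx.size - 10} more)"
        raise ValueError(f"events outside grid bounds at indices {shown}{more}")
    ix = np.floor((x - grid.x_min) / grid.cell_width).astype(np.int64)
    iy = np.floor((y - grid.y_min) / grid.cell_height).astype(np.int64)
    # top edge belongs to the last cell along each axis
    np.clip(ix, 0, grid.nx - 1, out=ix)
    np.clip(iy, 0, grid.ny - 1, out=iy)
    return CellSeries(grid.cell_id(ix, iy), grid)


def dggs_cell_count(aperture: int = 3, resolution: int = 0) -> int:
    """Cell count of an icosahedral aperture-``a`` hexagonal DGGS at a resolution.

    The closed form is ``10 * aperture**resolution + 2``: twelve base cells
    (the icosahedron vertices, realised as pentagons) plus hexagons whose
    number multiplies by the aperture per refinement level.  Resolution 0 is
    the 12-cell icosahedral base; aperture 3 at resolution 7 gives the
    21,872-cell grid whose cells average roughly 23,300 km^2 on Earth.
    """
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    if aperture < 2:
        raise ValueError("aperture must be >= 2")
    return 10 * aperture**resolution + 2


def dggs_mean_cell_area(
    aperture: int = 3, resolution: int = 0, surface_area: float = EARTH_SURFACE_KM2
) -> float:
    """Mean cell area (same units as ``surface_area``) of the DGGS grid.

    Exact conservation holds by construction:
    ``dggs_cell_count(...) * dggs_mean_cell_area(...) == surface_area``.
    """
    return surface_area / dggs_cell_count(aperture, resolution)


def load_cell_assignment(path, n_events: int | None = None) -> CellSeries:
    """Load an externally computed per-event cell assignment.

    Expected format: delimited text with a header and a ``cell`` column
    (optionally preceded by an event index / join key column); one row per
    event in record order.  This is the import path for hexagonal DGGS
    assignments computed by an external geometry tool.

    Raises
    ------
    ValueError
        On missing ids (naming the row) or on a length mismatch with
        ``n_events`` when given.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "cell" in df.columns:
        col = df["cell"]
    else:
        col = df[df.columns[-1]]
    vals = pd.to_numeric(col, errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"missing or non-numeric cell id at line {row}")
    if n_events is not None and len(vals) != n_events:
        raise ValueError(
            f"cell assignment length {len(vals)} does not match event count {n_events}"
        )
    return CellSeries(vals.to_numpy(dtype=np.int64))
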
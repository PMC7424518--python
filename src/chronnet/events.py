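"""Reading, validating, sorting and writing spatiotemporal event streams.

An *event* is a point in space and time, ``e = ((x, y), t)``, optionally
carrying extra scalar attributes (e.g. a detection confidence).  A data set is
a time-ordered sequence of events; downstream code assumes chronological
order, so :func:`sort_events` is the canonical entry point before any network
is built.

Two dialects are supported: a generic delimited-text table with ``x, y, t``
columns (:func:`read_events`) and the MODIS global active-fire location
product MCD14ML, which ships per-detection latitude/longitude, acquisition
date and time, a confidence percentage and a type code
(:func:`read_modis_fire`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "ParseReport",
    "read_events",
    "read_modis_fire",
    "sort_events",
    "write_events",
]

#: canonical column names of an event table
CORE_COLUMNS = ("x", "y", "t")


@dataclass
class ParseReport:
    """Records of input rows that failed validation (kept, never silently lost)."""

    bad_rows: list[tuple[int, str]] = field(default_factory=list)  # (1-based line, reason)

    def add(self, line: int, reason: str) -> None:
        self.bad_rows.append((line, reason))

    @property
    def n_bad(self) -> int:
        return len(self.bad_rows)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.bad_rows:
            return "all records parsed"
        lines = ", ".join(f"line {ln}: {why}" for ln, why in self.bad_rows[:10])
        more = "" if self.n_bad <= 10 else f" (+{self.n_bad - 10} more)"
        return f"{self.n_bad} bad record(s): {lines}{more}"


class EventTable:
    """A time-ordered collection of events backed by a :class:`pandas.DataFrame`.

    Parameters
    ----------
    df
        Frame with at least columns ``x``, ``y``, ``t``; any further columns
        are carried along as event attributes.
    coordinate_system
        ``"planar"`` for abstract/projected coordinates, ``"lonlat"`` for
        geographic degrees (x = longitude, y = latitude).
    parse_report
        Validation report from the reader that produced this table.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        coordinate_system: str = "planar",
        parse_report: ParseReport | None = None,
    ) -> None:
        if coordinate_system not in ("planar", "lonlat"):
            raise ValueError(f"unknown coordinate system {coordinate_system!r}")
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event frame lacks column(s) {missing}")
        df = df.reset_index(drop=True)
        for c in ("x", "y"):
            vals = np.asarray(df[c], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in column {c!r}")
            df[c] = vals
        df["t"] = _as_time_key(df["t"])
        self.df = df
        self.coordinate_system = coordinate_system
        self.parse_report = parse_report or ParseReport()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy()

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of event locations."""
        return self.df[["x", "y"]].to_numpy()

    def is_sorted(self) -> bool:
        t = self.t
        return bool(len(t) < 2 or np.all(np.diff(t) >= 0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return (
            self.coordinate_system == other.coordinate_system
            and self.df.shape == other.df.shape
            and list(self.df.columns) == list(other.df.columns)
            and bool(self.df.equals(other.df))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EventTable(n_events={self.n_events}, "
            f"coordinate_system={self.coordinate_system!r})"
        )


def _as_time_key(series: pd.Series) -> np.ndarray:
    """Coerce timestamps to a totally ordered numeric key.

    Integer steps stay integers; date-like strings become epoch seconds.
    """
    if pd.api.types.is_datetime64_any_dtype(series):
        return (series.astype("int64") // 10**9).to_numpy()
    vals = pd.to_numeric(series, errors="coerce")
    if vals.isna().any():
        # not numeric -> try datetimes
        dt = pd.to_datetime(series, errors="coerce", utc=True)
        if dt.isna().any():
            bad = series[dt.isna()].index[0]
            raise ValueError(f"unparseable timestamp at row {bad}: {series[bad]!r}")
        return (dt.astype("int64") // 10**9).to_numpy()
    arr = vals.to_numpy()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite timestamp")
    if np.allclose(arr, np.round(arr)):
        return arr.astype(np.int64)
    return arr


def read_events(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
    coordinate_system: str = "planar",
) -> EventTable:
    """Read a delimited event table with a header row.

    ``column_map`` maps the canonical names ``x``, ``y``, ``t`` to the file's
    column names (default: identical names).  Rows whose mapped fields cannot
    be parsed are dropped from the table but reported (with 1-based line
    numbers) in ``table.parse_report`` — bad records are never silently lost.

    Raises
    ------
    ValueError
        If a mapped column is absent (a configuration error, not a data error).
    """
    column_map = dict(column_map or {})
    for k in CORE_COLUMNS:
        column_map.setdefault(k, k)
    try:
        raw = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        return EventTable(pd.DataFrame(columns=list(CORE_COLUMNS)), coordinate_system)
    missing = [v for v in column_map.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}; have {list(raw.columns)}")

    report = ParseReport()
    core = {}
    bad = np.zeros(len(raw), dtype=bool)
    for canon in ("x", "y"):
        vals = pd.to_numeric(raw[column_map[canon]], errors="coerce")
        newly = vals.isna().to_numpy() & ~bad
        for idx in np.flatnonzero(newly):
            report.add(int(idx) + 2, f"non-numeric {canon}")  # +2: header + 1-based
        bad |= vals.isna().to_numpy()
        core[canon] = vals.to_numpy(dtype=float)
    tvals = pd.to_numeric(raw[column_map["t"]], errors="coerce")
    try:
        tdt = pd.to_datetime(
            raw[column_map["t"]], errors="coerce", utc=True, format="mixed"
        )
    except (ValueError, TypeError):
        tdt = pd.Series(pd.NaT, index=raw.index, dtype="datetime64[ns, UTC]")
    t_bad = (tvals.isna() & tdt.isna()).to_numpy()
    for idx in np.flatnonzero(t_bad & ~bad):
        report.add(int(idx) + 2, "unparseable t")
    bad |= t_bad
    epoch_s = (
        tdt.fillna(pd.Timestamp(0, tz="UTC")).astype("int64") // 10**9
    ).to_numpy(dtype=float)
    core["t"] = np.where(tvals.notna().to_numpy(), tvals.fillna(0).to_numpy(dtype=float), epoch_s)

    keep = ~bad
    df = pd.DataFrame({k: core[k][keep] for k in CORE_COLUMNS})
    # carry attribute columns, numeric where possible
    for col in raw.columns:
        if col in column_map.values():
            continue
        attr = pd.to_numeric(raw[col], errors="coerce")
        chosen = attr if not attr.isna().all() else raw[col]
        df[col] = chosen.to_numpy()[keep]
    report.bad_rows.sort()
    return EventTable(df, coordinate_system, report)


# columns accepted for each MCD14ML field (lower-cased)
_MODIS_ALIASES = {
    "lat": ("lat", "latitude"),
    "lon": ("lon", "longitude"),
    "conf": ("conf", "confidence"),
    "type": ("type",),
    "date": ("yyyymmdd", "acq_date", "date"),
    "time": ("hhmm", "acq_time", "time"),
}


def read_modis_fire(
    path,
    min_confidence: float = 75,
    keep_types="all",
) -> EventTable:
    """Read an MCD14ML-style active-fire detection file.

    The reader accepts the whitespace- or comma-delimited text distribution of
    the product: one detection per row with latitude, longitude, acquisition
    date (``YYYYMMDD``) and time (``HHMM``), a confidence percentage and a
    type code (0 = presumed vegetation fire; other codes mark volcanoes,
    offshore sources and other static land sources).

    Only records with confidence **strictly greater** than ``min_confidence``
    are retained.  ``keep_types`` is either ``"all"`` or an iterable of type
    codes; keeping all types deliberately retains the static-source
    detections so that outlier-cell analyses can rediscover them.
    """
    try:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        return EventTable(pd.DataFrame(columns=list(CORE_COLUMNS)), "lonlat")
    if raw.empty:
        return EventTable(pd.DataFrame(columns=list(CORE_COLUMNS)), "lonlat")
    cols = {c.lower().strip(): c for c in raw.columns}

    def pick(field: str, required: bool = True) -> str | None:
        for alias in _MODIS_ALIASES[field]:
            if alias in cols:
                return cols[alias]
        if required:
            raise ValueError(
                f"unrecognized fire-product dialect: no {field!r} column among "
                f"{list(raw.columns)}"
            )
        return None

    lat = pd.to_numeric(raw[pick("lat")], errors="coerce")
    lon = pd.to_numeric(raw[pick("lon")], errors="coerce")
    conf = pd.to_numeric(raw[pick("conf")], errors="coerce")
    typ_col = pick("type", required=False)
    typ = pd.to_numeric(raw[typ_col], errors="coerce") if typ_col else None

    date = raw[pick("date")].str.replace("-", "", regex=False).str.zfill(8)
    time = raw[pick("time")].str.replace(":", "", regex=False).str.zfill(4)
    stamp = pd.to_datetime(date + time, format="%Y%m%d%H%M", errors="coerce", utc=True)

    report = ParseReport()
    bad = (lat.isna() | lon.isna() | conf.isna() | stamp.isna()).to_numpy()
    for idx in np.flatnonzero(bad):
        report.add(int(idx) + 2, "unparseable fire record")

    keep = ~bad & (conf > min_confidence).to_numpy()
    if typ is not None and keep_types != "all":
        keep &= typ.isin(list(keep_types)).to_numpy()

    df = pd.DataFrame(
        {
            "x": lon[keep].astype(float),
            "y": lat[keep].astype(float),
            "t": (stamp[keep].astype("int64") // 10**9),
            "confidence": conf[keep].astype(float),
        }
    )
    if typ is not None:
        df["type"] = typ[keep].to_numpy()
    return sort_events(EventTable(df, "lonlat", report))


def sort_events(table: EventTable) -> EventTable:
    """Return the table stably sorted by timestamp.

    Stability matters: events sharing a timestamp (parallel events) keep
    their relative input order, which the builder's parallel-group handling
    relies on.  Idempotent — a sorted table round-trips unchanged.
    """
    df = table.df.sort_values("t", kind="stable", ignore_index=True)
    return EventTable(df, table.coordinate_system, table.parse_report)


def write_events(table: EventTable, path) -> None:
    """Write a table as comma-delimited text with columns ``x,y,t[,attrs...]``."""
    table.df.to_csv(path, index=False)


def events_from_arrays(
    x, y, t, coordinate_system: str = "planar", **attrs
) -> EventTable:
    """Build an :class:`EventTable` from parallel arrays (library entry point)."""
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), "t": t})
    for name, vals in attrs.items():
        df[name] = vals
    return EventTable(df, coordinate_system)
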
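"""Gridded forcing and track-table containers with NetCDF/CSV I/O.

Conventions
-----------
* Longitude is degrees east in ``[0, 360)`` everywhere; files using
  ``[-180, 180)`` are wrapped (and re-sorted) on ingest.
* Gridded variables live on a node-registered regular lon/lat grid with a
  regular time axis (6 days for ocean forcing); land is NaN at every time.
* Tracks are per-fix rows (id, timestamp, lon, lat) sorted by time within
  each id, with optional per-track release size/date metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from turtlehab.geo import wrap_lon

__all__ = [
    "GridField",
    "TrackTable",
    "FormatError",
    "OutOfDomainError",
    "read_grid",
    "write_grid",
    "read_tracks",
    "write_tracks",
    "sample_field",
]

_AXIS_RTOL = 1e-9


class FormatError(ValueError):
    """A file or container violates the expected gridded/track format."""


class OutOfDomainError(ValueError):
    """A query point lies outside the spatial or temporal grid bounds."""


def _check_regular(axis: np.ndarray, name: str) -> float:
    """Return the constant step of a strictly increasing regular axis."""
    axis = np.asarray(axis, dtype=float)
    if axis.size < 2:
        raise FormatError(f"{name} axis needs at least 2 points, got {axis.size}")
    steps = np.diff(axis)
    if np.any(steps <= 0):
        raise FormatError(f"{name} axis must be strictly increasing")
    step = steps[0]
    if np.any(np.abs(steps - step) > _AXIS_RTOL * max(1.0, abs(step))):
        raise FormatError(f"{name} axis step is irregular")
    return float(step)


@dataclass
class GridField:
    """One gridded space-time environmental variable.

    ``values`` has shape (time, lat, lon) with NaN marking land (missing
    at every time step).  ``land_mask`` is True on land.
    """

    name: str
    lon: np.ndarray
    lat: np.ndarray
    time: pd.DatetimeIndex
    values: np.ndarray
    units: str = ""
    land_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time = pd.DatetimeIndex(self.time)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.time) == 0:
            raise FormatError("empty time axis")
        self.lon_step = _check_regular(self.lon, "lon")
        self.lat_step = _check_regular(self.lat, "lat")
        if len(self.time) >= 2:
            _check_regular(self.time.view("int64"), "time")
        if np.any(self.lon < 0) or np.any(self.lon >= 360):
            raise FormatError("lon must be in [0, 360)")
        if np.any(np.abs(self.lat) > 90):
            raise FormatError("lat must be in [-90, 90]")
        expect = (len(self.time), len(self.lat), len(self.lon))
        if self.values.shape != expect:
            raise FormatError(f"values shape {self.values.shape} != (time,lat,lon) {expect}")
        missing = np.isnan(self.values)
        derived = missing.all(axis=0)
        if self.land_mask is None:
            self.land_mask = derived
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
            if self.land_mask.shape != expect[1:]:
                raise FormatError("land_mask shape mismatch")
            # land cells must be missing at every time
            self.values[:, self.land_mask] = np.nan

    @property
    def time_step(self) -> pd.Timedelta:
        if len(self.time) < 2:
            return pd.Timedelta(0)
        return self.time[1] - self.time[0]

    def with_values(self, values: np.ndarray, name: Optional[str] = None, units: Optional[str] = None) -> "GridField":
        """Same grid, new values (land mask re-imposed)."""
        return GridField(
            name=name if name is not None else self.name,
            lon=self.lon,
            lat=self.lat,
            time=self.time,
            values=np.array(values, dtype=float),
            units=units if units is not None else self.units,
            land_mask=self.land_mask.copy(),
        )


@dataclass
class TrackTable:
    """Per-fix track records plus per-track release metadata.

    ``fixes`` columns: id (str), t (datetime64), lon, lat; sorted by
    (id, t), strictly increasing t within id.  ``meta`` is indexed by id
    with optional columns ``scl_release`` (cm) and ``release_date``.
    """

    fixes: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(index=pd.Index([], name="id")))

    def __post_init__(self):
        fx = self.fixes.copy()
        fx["id"] = fx["id"].astype(str)
        fx["t"] = pd.to_datetime(fx["t"])
        fx["lon"] = wrap_lon(fx["lon"].to_numpy())
        fx["lat"] = fx["lat"].astype(float)
        if np.any(np.abs(fx["lat"].to_numpy()) > 90):
            raise FormatError("latitude out of [-90, 90]")
        fx = fx.sort_values(["id", "t"], kind="mergesort").reset_index(drop=True)
        dup = fx.duplicated(subset=["id", "t"])
        if dup.any():
            bad = fx.loc[dup.idxmax()]
            raise FormatError(f"duplicate (id, timestamp) fix: id={bad['id']} t={bad['t']}")
        self.fixes = fx
        if self.meta.index.name != "id":
            self.meta = self.meta.rename_axis("id")

    def track_ids(self) -> list[str]:
        return list(dict.fromkeys(self.fixes["id"]))

    def get_track(self, track_id: str) -> pd.DataFrame:
        sub = self.fixes[self.fixes["id"] == str(track_id)]
        if sub.empty:
            raise KeyError(f"no track with id {track_id!r}")
        return sub.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)


# ---------------------------------------------------------------------------
# NetCDF I/O

_LON_NAMES = ("lon", "longitude", "x")
_LAT_NAMES = ("lat", "latitude", "y")
_TIME_NAMES = ("time",)


def _find_coord(ds: xr.Dataset, candidates) -> str:
    for name in candidates:
        if name in ds.coords or name in ds.variables:
            return name
    raise FormatError(f"missing coordinate variable; looked for {candidates}")


def read_grid(path, variable: str) -> GridField:
    """Read one variable of a CF-style gridded NetCDF file.

    Longitudes are wrapped to [0, 360) and the lon axis re-sorted if the
    wrap reorders it.  Fill values / NaN become the land mask.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not in file {path}")
        lon_name = _find_coord(ds, _LON_NAMES)
        lat_name = _find_coord(ds, _LAT_NAMES)
        time_name = _find_coord(ds, _TIME_NAMES)
        da = ds[variable].transpose(time_name, lat_name, lon_name)
        lon = wrap_lon(ds[lon_name].values)
        order = np.argsort(lon, kind="stable")
        values = da.values.astype(float)
        if not np.all(order == np.arange(lon.size)):
            lon = lon[order]
            values = values[:, :, order]
        lat = np.asarray(ds[lat_name].values, dtype=float)
        if lat.size >= 2 and lat[0] > lat[-1]:
            lat = lat[::-1]
            values = values[:, ::-1, :]
        time = pd.DatetimeIndex(ds[time_name].values)
        units = str(da.attrs.get("units", ""))
    return GridField(name=variable, lon=lon, lat=lat, time=time, values=values, units=units)


def write_grid(grid: GridField, path) -> None:
    """Write a GridField as CF-style NetCDF (land as fill value)."""
    da = xr.DataArray(
        grid.values,
        dims=("time", "lat", "lon"),
        coords={"time": grid.time, "lat": grid.lat, "lon": grid.lon},
        name=grid.name,
        attrs={"units": grid.units} if grid.units else {},
    )
    da.coords["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    da.coords["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    enc = {grid.name: {"_FillValue": np.float64(-9.99e33)}}
    da.to_dataset().to_netcdf(path, engine="scipy", encoding=enc)


# ---------------------------------------------------------------------------
# Track CSV I/O

_TRACK_COLS = ("id", "timestamp", "lon", "lat")
_META_COLS = ("scl_release", "release_date")


def read_tracks(path) -> TrackTable:
    """Read a track CSV: header id,timestamp,lon,lat[,scl_release,release_date]."""
    raw = pd.read_csv(path, dtype={"id": str})
    for col in _TRACK_COLS:
        if col not in raw.columns:
            raise FormatError(f"track CSV missing column {col!r}")
    t = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce")
    bad = t.isna() & raw["timestamp"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(f"unparseable timestamp at line {line}: {raw.loc[bad.idxmax(), 'timestamp']!r}")
    fixes = pd.DataFrame({"id": raw["id"], "t": t, "lon": raw["lon"], "lat": raw["lat"]})
    meta_cols = [c for c in _META_COLS if c in raw.columns]
    if meta_cols:
        meta = raw.groupby("id", sort=False)[meta_cols].first()
        if "release_date" in meta.columns:
            meta["release_date"] = pd.to_datetime(meta["release_date"], format="ISO8601")
    else:
        meta = pd.DataFrame(index=pd.Index(raw["id"].unique(), name="id"))
    return TrackTable(fixes=fixes, meta=meta)


def write_tracks(table: TrackTable, path) -> None:
    """Write a TrackTable to CSV (inverse of :func:`read_tracks`)."""
    out = table.fixes.rename(columns={"t": "timestamp"}).copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    for col in _META_COLS:
        if col in table.meta.columns:
            mapped = out["id"].map(table.meta[col])
            if col == "release_date":
                mapped = pd.to_datetime(mapped).dt.strftime("%Y-%m-%dT%H:%M:%S")
            out[col] = mapped
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Space-time interpolation


def _bilinear_slice(values2d: np.ndarray, grid: GridField, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of one (lat, lon) slice at many points.

    Points whose 4 spatial neighbours include land fall back to the
    nearest non-land neighbour; NaN if all 4 are land.
    """
    fx = (lons - grid.lon[0]) / grid.lon_step
    fy = (lats - grid.lat[0]) / grid.lat_step
    i = np.clip(np.floor(fx).astype(int), 0, grid.lon.size - 2)
    j = np.clip(np.floor(fy).astype(int), 0, grid.lat.size - 2)
    tx = fx - i
    ty = fy - j
    v00 = values2d[j, i]
    v01 = values2d[j, i + 1]
    v10 = values2d[j + 1, i]
    v11 = values2d[j + 1, i + 1]
    out = (
        v00 * (1 - tx) * (1 - ty)
        + v01 * tx * (1 - ty)
        + v10 * (1 - tx) * ty
        + v11 * tx * ty
    )
    bad = np.flatnonzero(np.isnan(out))
    for k in bad:
        corners = np.array([v00[k], v01[k], v10[k], v11[k]])
        # squared distance of query point to each corner, in grid units
        d2 = np.array(
            [
                tx[k] ** 2 + ty[k] ** 2,
                (1 - tx[k]) ** 2 + ty[k] ** 2,
                tx[k] ** 2 + (1 - ty[k]) ** 2,
                (1 - tx[k]) ** 2 + (1 - ty[k]) ** 2,
            ]
        )
        wet = ~np.isnan(corners)
        out[k] = corners[wet][np.argmin(d2[wet])] if wet.any() else np.nan
    return out


def sample_field(grid: GridField, t, lon, lat):
    """Sample a GridField at (t, lon, lat): bilinear in space, linear in time.

    Accepts scalars or matching arrays of lon/lat with a single time.
    Raises :class:`OutOfDomainError` for points outside the grid bounds.
    """
    scalar = np.isscalar(lon) or (np.ndim(lon) == 0)
    lons = wrap_lon(np.atleast_1d(np.asarray(lon, dtype=float)))
    lats = np.atleast_1d(np.asarray(lat, dtype=float))
    ts = pd.Timestamp(t)
    eps = _AXIS_RTOL
    if (
        np.any(lons < grid.lon[0] - eps)
        or np.any(lons > grid.lon[-1] + eps)
        or np.any(lats < grid.lat[0] - eps)
        or np.any(lats > grid.lat[-1] + eps)
    ):
        raise OutOfDomainError("query point outside spatial grid bounds")
    if ts < grid.time[0] or ts > grid.time[-1]:
        raise OutOfDomainError(f"time {ts} outside [{grid.time[0]}, {grid.time[-1]}]")
    lons = np.clip(lons, grid.lon[0], grid.lon[-1])
    lats = np.clip(lats, grid.lat[0], grid.lat[-1])
    k = int(np.clip(grid.time.searchsorted(ts, side="right") - 1, 0, len(grid.time) - 1))
    if k == len(grid.time) - 1 or ts == grid.time[k]:
        out = _bilinear_slice(grid.values[k], grid, lons, lats)
    else:
        w = (ts - grid.time[k]) / (grid.time[k + 1] - grid.time[k])
        a = _bilinear_slice(grid.values[k], grid, lons, lats)
        b = _bilinear_slice(grid.values[k + 1], grid, lons, lats)
        out = (1.0 - w) * a + w * b
    return float(out[0]) if scalar else out
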
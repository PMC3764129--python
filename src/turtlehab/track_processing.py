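"""Argos track cleaning: speed filter, kernel smoothing, spike removal.

The pipeline applied to every raw track is

1. velocity filter — iteratively drop any fix reached at more than
   10 km/h from the previous retained fix;
2. first Epanechnikov (local-linear) smoothing pass with a 2-day window
   centred on each fix;
3. spike removal — drop the 5% of fixes with the largest great-circle
   discrepancy between observed and smoothed position;
4. resampling of the surviving observed fixes to a 3-hourly lattice;
5. second Epanechnikov pass on the resampled series.

Tracks spanning fewer than 10 days, or with inter-fix gaps larger than
3 degrees of longitude or latitude, are flagged for exclusion rather
than interpolated across.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from turtlehab.geo import haversine_km, unwrap_lon, wrap_lon
from turtlehab.io_formats import TrackTable

__all__ = [
    "ProcessedTrack",
    "fix_speeds",
    "velocity_filter",
    "kernel_smooth",
    "spike_removal",
    "resample",
    "process_track",
    "process_tracks",
]

#: defaults of the cleaning pipeline
VMAX_KMH = 10.0
WINDOW_DAYS = 2.0
SPIKE_FRAC = 0.05
RESAMPLE_HOURS = 3.0
MIN_TRACK_DAYS = 10.0
GAP_DEG = 3.0


@dataclass
class ProcessedTrack:
    """A cleaned track on a regular 3-hour lattice, with removal counts."""

    id: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    n_raw: int
    n_removed_speed: int
    n_removed_spike: int
    discard: bool = False
    gap_flag: bool = False
    scl_release: float | None = None
    release_date: pd.Timestamp | None = None

    def __len__(self) -> int:
        return len(self.times)


def _as_track_frame(track) -> pd.DataFrame:
    """Accept a single-id TrackTable or a fixes DataFrame."""
    if isinstance(track, TrackTable):
        ids = track.track_ids()
        if len(ids) != 1:
            raise ValueError("expected a single track; got a table with several ids")
        return track.get_track(ids[0])
    return track.reset_index(drop=True)


def fix_speeds(track) -> np.ndarray:
    """Speed of each inter-fix segment in km/h (great-circle / elapsed)."""
    trk = _as_track_frame(track)
    if len(trk) < 2:
        raise ValueError("need at least 2 fixes to compute speeds")
    lon = trk["lon"].to_numpy()
    lat = trk["lat"].to_numpy()
    t = trk["t"].to_numpy()
    dist = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    hours = (t[1:] - t[:-1]) / np.timedelta64(1, "h")
    if np.any((hours <= 0) & (dist > 0)):
        raise ValueError("zero elapsed time between distinct fixes")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dist == 0, 0.0, dist / hours)


def velocity_filter(track, vmax: float = VMAX_KMH) -> pd.DataFrame:
    """Drop fixes implying speeds above vmax, re-joining the neighbours.

    The later fix of an offending segment is removed and speeds are
    recomputed from the previous retained fix, so the output never
    contains a segment faster than vmax; the first fix is always kept.
    """
    trk = _as_track_frame(track)
    lon = trk["lon"].to_numpy()
    lat = trk["lat"].to_numpy()
    t = trk["t"].to_numpy()
    keep = [0]
    for i in range(1, len(trk)):
        j = keep[-1]
        d = haversine_km(lon[j], lat[j], lon[i], lat[i])
        h = (t[i] - t[j]) / np.timedelta64(1, "h")
        if h <= 0:
            if d > 0:
                raise ValueError("zero elapsed time between distinct fixes")
            continue
        if d / h <= vmax:
            keep.append(i)
    return trk.iloc[keep].reset_index(drop=True)


def _epanechnikov_local_linear(t_days, y, eval_days, half_window_days):
    """Local-linear regression with Epanechnikov weights w = 1 - (tau/h)^2."""
    out = np.empty(eval_days.size)
    for m, te in enumerate(eval_days):
        tau = t_days - te
        w = 1.0 - (tau / half_window_days) ** 2
        sel = w > 0
        if sel.sum() >= 3:
            ws, ts, ys = w[sel], tau[sel], y[sel]
            s0 = ws.sum()
            s1 = (ws * ts).sum()
            s2 = (ws * ts * ts).sum()
            b0 = (ws * ys).sum()
            b1 = (ws * ts * ys).sum()
            den = s0 * s2 - s1 * s1
            if den > 1e-12 * max(s0 * s2, 1e-300):
                out[m] = (s2 * b0 - s1 * b1) / den
                continue
            out[m] = b0 / s0
        else:
            out[m] = y[np.argmin(np.abs(tau))]  # sparse window: nearest fix
    return out


def kernel_smooth(track, eval_times, window_days: float = WINDOW_DAYS):
    """Epanechnikov-weighted local-linear smoothing of lon(t) and lat(t).

    The window spans ``window_days`` centred on each evaluation time
    (half-window h = window/2); windows with fewer than 3 fixes fall
    back to the nearest fix.  Longitudes are unwrapped before smoothing
    and rewrapped after.  Returns (lon, lat) arrays at ``eval_times``.
    """
    trk = _as_track_frame(track)
    eval_times = pd.DatetimeIndex(eval_times)
    if len(eval_times) == 0:
        raise ValueError("eval_times is empty")
    t0 = trk["t"].iloc[0]
    t_days = (trk["t"] - t0).dt.total_seconds().to_numpy() / 86400.0
    e_days = (eval_times - t0).total_seconds() / 86400.0
    e_days = np.asarray(e_days, dtype=float)
    h = window_days / 2.0
    lon_u = unwrap_lon(trk["lon"].to_numpy())
    lat = trk["lat"].to_numpy()
    sm_lon = _epanechnikov_local_linear(t_days, lon_u, e_days, h)
    sm_lat = _epanechnikov_local_linear(t_days, lat, e_days, h)
    return wrap_lon(sm_lon), sm_lat


def spike_removal(track, frac: float = SPIKE_FRAC, window_days: float = WINDOW_DAYS) -> pd.DataFrame:
    """Remove the ceil(frac * n) fixes farthest from their smoothed position.

    Discrepancy is the great-circle distance between each observed fix
    and the first-pass smoothed position at that fix's time; ties are
    broken by removing the earlier fix first.
    """
    trk = _as_track_frame(track)
    n = len(trk)
    n_remove = math.ceil(frac * n)
    if n_remove == 0:
        return trk
    sm_lon, sm_lat = kernel_smooth(trk, trk["t"], window_days=window_days)
    disc = haversine_km(trk["lon"].to_numpy(), trk["lat"].to_numpy(), sm_lon, sm_lat)
    # stable sort on -disc keeps earlier index first among ties
    order = np.argsort(-disc, kind="stable")
    drop = set(order[:n_remove].tolist())
    keep = [i for i in range(n) if i not in drop]
    return trk.iloc[keep].reset_index(drop=True)


def resample(track, dt_hours: float = RESAMPLE_HOURS) -> pd.DataFrame:
    """Linearly resample a track onto a regular lattice every dt_hours.

    The lattice starts at the first fix time rounded up to the next
    whole ``dt_hours`` boundary (UTC) and runs through the last fix.
    """
    trk = _as_track_frame(track)
    t0, t1 = trk["t"].iloc[0], trk["t"].iloc[-1]
    step = pd.Timedelta(hours=dt_hours)
    start = t0.ceil(step)
    if t1 - start < pd.Timedelta(0) or len(trk) < 2:
        raise ValueError(f"track too short to resample at {dt_hours} h")
    times = pd.date_range(start, t1, freq=step)
    if len(times) == 0:
        raise ValueError(f"track too short to resample at {dt_hours} h")
    t_s = (trk["t"] - t0).dt.total_seconds().to_numpy()
    e_s = (times - t0).total_seconds()
    lon_u = unwrap_lon(trk["lon"].to_numpy())
    lon = wrap_lon(np.interp(e_s, t_s, lon_u))
    lat = np.interp(e_s, t_s, trk["lat"].to_numpy())
    return pd.DataFrame({"id": trk["id"].iloc[0], "t": times, "lon": lon, "lat": lat})


def process_track(
    track,
    vmax: float = VMAX_KMH,
    window_days: float = WINDOW_DAYS,
    spike_frac: float = SPIKE_FRAC,
    dt_hours: float = RESAMPLE_HOURS,
    min_days: float = MIN_TRACK_DAYS,
    gap_deg: float = GAP_DEG,
    scl_release: float | None = None,
    release_date=None,
) -> ProcessedTrack:
    """Full cleaning pipeline for one track.

    velocity_filter -> Epanechnikov pass 1 (at fix times, inside
    spike_removal) -> spike_removal -> 3-hourly resample -> Epanechnikov
    pass 2 (at lattice times).  Tracks spanning less than ``min_days``
    are flagged ``discard``; gaps over ``gap_deg`` degrees set
    ``gap_flag``.
    """
    trk = _as_track_frame(track)
    tid = str(trk["id"].iloc[0])
    n_raw = len(trk)
    try:
        filtered = velocity_filter(trk, vmax=vmax)
    except ValueError as err:
        raise ValueError(f"velocity_filter failed for track {tid}: {err}") from err
    n_removed_speed = n_raw - len(filtered)
    try:
        despiked = spike_removal(filtered, frac=spike_frac, window_days=window_days)
    except ValueError as err:
        raise ValueError(f"spike_removal failed for track {tid}: {err}") from err
    n_removed_spike = len(filtered) - len(despiked)
    try:
        lattice = resample(despiked, dt_hours=dt_hours)
        sm_lon, sm_lat = kernel_smooth(lattice, lattice["t"], window_days=window_days)
    except ValueError as err:
        raise ValueError(f"resample failed for track {tid}: {err}") from err

    span_days = (despiked["t"].iloc[-1] - despiked["t"].iloc[0]).total_seconds() / 86400.0
    lon_u = unwrap_lon(despiked["lon"].to_numpy())
    gaps = np.maximum(
        np.abs(np.diff(lon_u)), np.abs(np.diff(despiked["lat"].to_numpy()))
    )
    return ProcessedTrack(
        id=tid,
        times=pd.DatetimeIndex(lattice["t"]),
        lon=sm_lon,
        lat=sm_lat,
        n_raw=n_raw,
        n_removed_speed=n_removed_speed,
        n_removed_spike=n_removed_spike,
        discard=span_days < min_days,
        gap_flag=bool(gaps.size and np.max(gaps) > gap_deg),
        scl_release=scl_release,
        release_date=pd.Timestamp(release_date) if release_date is not None else None,
    )


def process_tracks(table: TrackTable, **kwargs) -> list[ProcessedTrack]:
    """Run :func:`process_track` on every id of a TrackTable."""
    out = []
    for tid in table.track_ids():
        meta = table.meta.loc[tid] if tid in table.meta.index else None
        out.append(
            process_track(
                table.get_track(tid),
                scl_release=(float(meta["scl_release"]) if meta is not None and "scl_release" in meta else None),
                release_date=(meta["release_date"] if meta is not None and "release_date" in meta else None),
                **kwargs,
            )
        )
    return out
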
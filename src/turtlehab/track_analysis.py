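"""Behavioural quantities derived from processed tracks.

Observed velocity Vg is decomposed into current Vc and swimming
velocity V = Vg - Vc by sampling gridded surface currents along the
track.  Body size grows along the track following an empirical CCL
growth curve; swimming statistics are summarised as a monthly 90th
percentile "maximum sustainable speed" (MSS), in km/h and body lengths
per second, and as per-size-class Gaussian temperature preferences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from turtlehab.geo import KM_PER_DEG
from turtlehab.io_formats import GridField, OutOfDomainError, TrackTable, sample_field
from turtlehab.track_processing import ProcessedTrack

__all__ = [
    "annotate_track",
    "grow",
    "ccl_from_scl",
    "scl_from_ccl",
    "growth_rate",
    "sst_preference_by_size",
    "mss_monthly",
    "ks_two_sample",
    "longitude_band_fraction",
    "mean_latitude_vs_isotherm",
    "DEFAULT_SIZE_CLASSES",
]

#: SCL (cm) size-class edges used throughout: <30, 30-40, 40-60, >=60
DEFAULT_SIZE_CLASSES = ((0.0, 30.0), (30.0, 40.0), (40.0, 60.0), (60.0, np.inf))

#: CCL above which the growth curve crosses zero: 10**(21.5/10.6)
CCL_GROWTH_ZERO = 10.0 ** (21.5 / 10.6)


def scl_from_ccl(ccl):
    """Straight from curved carapace length: SCL = 0.369 + 0.932 * CCL (cm)."""
    return 0.369 + 0.932 * np.asarray(ccl, dtype=float)


def ccl_from_scl(scl):
    """Invert the SCL/CCL relation."""
    return (np.asarray(scl, dtype=float) - 0.369) / 0.932


def growth_rate(ccl):
    """CCL growth rate in cm/yr: -10.6 * log10(CCL) + 21.5, floored at 0."""
    ccl = np.asarray(ccl, dtype=float)
    if np.any(ccl <= 0):
        raise ValueError("CCL must be positive")
    return np.maximum(0.0, -10.6 * np.log10(ccl) + 21.5)


def grow(ccl0: float, dates) -> tuple[np.ndarray, np.ndarray]:
    """Integrate carapace growth from ``dates[0]``: returns (CCL, SCL) in cm.

    Explicit Euler with a daily step on dCCL/dt = growth_rate / 365.25;
    evaluated at the requested dates by interpolation on the daily grid.
    Growth is clamped at zero above the curve's zero crossing (~107 cm).
    """
    if ccl0 <= 0:
        raise ValueError("initial CCL must be positive")
    if ccl0 > CCL_GROWTH_ZERO:
        warnings.warn(f"CCL {ccl0:.1f} beyond growth-curve zero ({CCL_GROWTH_ZERO:.1f} cm); growth clamped at 0")
    dates = pd.DatetimeIndex(dates)
    days = (dates - dates[0]).total_seconds() / 86400.0
    days = np.asarray(days, dtype=float)
    n_days = int(np.ceil(days.max())) if days.size else 0
    daily = np.empty(n_days + 1)
    daily[0] = ccl0
    for d in range(n_days):
        daily[d + 1] = daily[d] + growth_rate(daily[d]) / 365.25
    ccl = np.interp(days, np.arange(n_days + 1), daily)
    return ccl, scl_from_ccl(ccl)


def annotate_track(
    track: ProcessedTrack,
    fields: dict[str, GridField],
    temperature_var: str = "temp30m",
) -> pd.DataFrame:
    """Sample environment along a processed track and derive swimming velocity.

    Observed velocity (vg_x, vg_y, m/s) comes from centred finite
    differences of position on the 3-h lattice (one-sided at the ends)
    with a cos-latitude zonal metric; swimming velocity is v = vg - vc
    with the current vc sampled from the forcing.  ``speed`` is |v| in
    km/h.  Size columns (ccl, scl) are filled when the track carries a
    release size.  Out-of-domain lattice points are dropped (a warning
    reports how many).
    """
    t = track.times
    lon = np.asarray(track.lon, dtype=float)
    lat = np.asarray(track.lat, dtype=float)
    n = len(t)
    if n < 2:
        raise ValueError("need at least 2 lattice points")
    sec = (t - t[0]).total_seconds()
    sec = np.asarray(sec, dtype=float)

    # centred differences in metres (cos-lat zonal scaling)
    lon_u = np.degrees(np.unwrap(np.radians(lon)))
    vg_x = np.empty(n)
    vg_y = np.empty(n)
    m_per_deg = KM_PER_DEG * 1000.0
    for m in range(n):
        a, b = (m, m + 1) if m == 0 else ((m - 1, m) if m == n - 1 else (m - 1, m + 1))
        dt = sec[b] - sec[a]
        vg_x[m] = (lon_u[b] - lon_u[a]) * m_per_deg * np.cos(np.radians(lat[m])) / dt
        vg_y[m] = (lat[b] - lat[a]) * m_per_deg / dt

    sst = np.full(n, np.nan)
    u_c = np.full(n, np.nan)
    v_c = np.full(n, np.nan)
    n_dropped = 0
    for m in range(n):
        try:
            sst[m] = sample_field(fields[temperature_var], t[m], lon[m], lat[m])
            u_c[m] = sample_field(fields["u"], t[m], lon[m], lat[m])
            v_c[m] = sample_field(fields["v"], t[m], lon[m], lat[m])
        except OutOfDomainError:
            n_dropped += 1
    if n_dropped:
        warnings.warn(f"track {track.id}: {n_dropped} lattice points outside field domain dropped")

    v_x = vg_x - u_c
    v_y = vg_y - v_c
    speed = np.hypot(v_x, v_y) * 3.6  # m/s -> km/h
    rec = pd.DataFrame(
        {
            "id": track.id,
            "t": t,
            "lon": lon,
            "lat": lat,
            "sst": sst,
            "u_c": u_c,
            "v_c": v_c,
            "vg_x": vg_x,
            "vg_y": vg_y,
            "v_x": v_x,
            "v_y": v_y,
            "speed": speed,
        }
    )
    if track.scl_release is not None:
        ccl, scl = grow(float(ccl_from_scl(track.scl_release)), t)
        rec["ccl"] = ccl
        rec["scl"] = scl
    else:
        rec["ccl"] = np.nan
        rec["scl"] = np.nan
    return rec.dropna(subset=["sst", "u_c", "v_c"]).reset_index(drop=True)


def sst_preference_by_size(
    records: pd.DataFrame,
    classes=DEFAULT_SIZE_CLASSES,
    lon_min: float = 180.0,
) -> pd.DataFrame:
    """Per-size-class mean and sd of along-track SST (Gaussian preference).

    Restricted to records at longitude >= ``lon_min`` (degrees east) to
    keep distinct current regimes out of the comparison.  Classes with
    fewer than 2 records are omitted with a warning; zero-sd classes
    are flagged degenerate.
    """
    sub = records[records["lon"] >= lon_min]
    rows = []
    for lo, hi in classes:
        grp = sub[(sub["scl"] >= lo) & (sub["scl"] < hi)]
        label = f"[{lo:g}, {hi:g})"
        if len(grp) < 2:
            warnings.warn(f"size class {label}: fewer than 2 records, omitted")
            continue
        sd = float(grp["sst"].std(ddof=1))
        rows.append(
            {
                "size_class": label,
                "scl_lo": lo,
                "scl_hi": hi,
                "mean_sst": float(grp["sst"].mean()),
                "sd_sst": sd,
                "n_obs": len(grp),
                "degenerate": sd == 0.0,
            }
        )
    return pd.DataFrame(rows)


def mss_monthly(records: pd.DataFrame, percentile: float = 90.0, min_records: int = 10) -> pd.DataFrame:
    """Monthly maximum sustainable speed per animal.

    MSS is the ``percentile``-th percentile (linear interpolation
    between closest ranks) of the animal's current-corrected speed in a
    calendar month, reported in km/h and in body lengths per second
    (dividing the m/s speed by the monthly mean SCL in metres).  Months
    with fewer than ``min_records`` speeds are skipped.
    """
    rec = records.copy()
    rec["month"] = pd.PeriodIndex(rec["t"], freq="M")
    rows = []
    for (tid, month), grp in rec.groupby(["id", "month"], sort=True):
        if len(grp) < min_records:
            continue
        mss_kmh = float(np.percentile(grp["speed"].to_numpy(), percentile))
        scl_cm = float(grp["scl"].mean())
        mss_bls = (mss_kmh / 3.6) / (scl_cm / 100.0) if np.isfinite(scl_cm) and scl_cm > 0 else np.nan
        rows.append(
            {"id": tid, "month": month, "mss_kmh": mss_kmh, "mss_bls": mss_bls, "scl_cm": scl_cm, "n": len(grp)}
        )
    return pd.DataFrame(rows)


def ks_two_sample(a, b) -> dict:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the empirical CDFs; the p-value
    uses the asymptotic Kolmogorov distribution with effective sample
    size n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    D = float(np.max(np.abs(fa - fb)))
    ne = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(ne) * D))
    return {"D": D, "p": p}


def _position_at(track_fixes: pd.DataFrame, when: pd.Timestamp):
    t_s = (track_fixes["t"] - track_fixes["t"].iloc[0]).dt.total_seconds().to_numpy()
    w_s = (when - track_fixes["t"].iloc[0]).total_seconds()
    lon = np.interp(w_s, t_s, np.degrees(np.unwrap(np.radians(track_fixes["lon"].to_numpy()))))
    lat = np.interp(w_s, t_s, track_fixes["lat"].to_numpy())
    return lon % 360.0, lat


def longitude_band_fraction(tracks: TrackTable, horizon_days: float, band=(180.0, 200.0)) -> float:
    """Fraction of tracks in a longitude band after a horizon.

    Only tracks with at least ``horizon_days`` of data qualify; each
    qualifying track's position at release + horizon (interpolated
    between fixes) is tested against [band_lo, band_hi).
    """
    lo, hi = band
    n_ok = 0
    n_in = 0
    for tid in tracks.track_ids():
        trk = tracks.get_track(tid)
        span = (trk["t"].iloc[-1] - trk["t"].iloc[0]).total_seconds() / 86400.0
        if span < horizon_days:
            continue
        when = trk["t"].iloc[0] + pd.Timedelta(days=horizon_days)
        lon, _ = _position_at(trk, when)
        n_ok += 1
        if lo <= lon < hi:
            n_in += 1
    if n_ok == 0:
        raise ValueError(f"no track has {horizon_days} days of data")
    return n_in / n_ok


def mean_latitude_vs_isotherm(
    tracks: TrackTable,
    sst_field: GridField,
    iso: float = 17.0,
    lon0: float = 190.0,
) -> pd.DataFrame:
    """Mean track latitude vs the latitude of an SST isotherm, per time step.

    For each forcing time step: (i) the mean latitude over all fixes
    falling in that step's interval; (ii) the latitude where SST crosses
    ``iso`` on the ``lon0`` meridian (linear interpolation between
    bracketing grid nodes; the northernmost crossing if several; NaN
    when there is none).
    """
    if not (sst_field.lon[0] <= lon0 % 360.0 <= sst_field.lon[-1]):
        raise ValueError(f"meridian {lon0} outside field domain")
    times = sst_field.time
    fx = (lon0 % 360.0 - sst_field.lon[0]) / sst_field.lon_step
    i = int(np.clip(np.floor(fx), 0, sst_field.lon.size - 2))
    w = fx - i
    rows = []
    fixes = tracks.fixes
    step = sst_field.time_step
    for k, tk in enumerate(times):
        profile = (1 - w) * sst_field.values[k, :, i] + w * sst_field.values[k, :, i + 1]
        iso_lat = np.nan
        diff = profile - iso
        for j in range(len(profile) - 2, -1, -1):  # northernmost crossing first
            if np.isfinite(diff[j]) and np.isfinite(diff[j + 1]) and diff[j] * diff[j + 1] <= 0 and diff[j] != diff[j + 1]:
                frac = diff[j] / (diff[j] - diff[j + 1])
                iso_lat = sst_field.lat[j] + frac * sst_field.lat_step
                break
        hi = tk + step if len(times) > 1 else tk + pd.Timedelta(days=6)
        in_step = fixes[(fixes["t"] >= tk) & (fixes["t"] < hi)]
        rows.append(
            {
                "time": tk,
                "mean_track_lat": float(in_step["lat"].mean()) if len(in_step) else np.nan,
                "isotherm_lat": iso_lat,
            }
        )
    return pd.DataFrame(rows)
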
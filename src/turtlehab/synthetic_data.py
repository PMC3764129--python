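"""Synthetic ocean forcing and individual-based tracks with known truth.

The forcing generator emulates the gross structure of North Pacific
reanalysis products on a regular grid with a 6-day time step: a
meridional temperature gradient, a sinusoidal seasonal cycle peaking in
early September, westward-propagating mesoscale eddies, a zonal jet,
and a prey proxy built from a lagged, smoothed latitude/temperature
productivity transform.

Ground-truth tracks are produced by the stochastic (Lagrangian)
counterpart of the Eulerian movement model, sharing the taxis and
diffusivity operators of :mod:`turtlehab.movement_model`, so parameter-
recovery tests are well posed.  The Ito drift correction grad(D) is
included so the particle ensemble solves the same Fokker-Planck
equation as the density solver (flux-form diffusion div(D grad rho)).

Argos degradation thins fixes to ~2.6 per day and adds isotropic
Gaussian position noise plus rare large spikes — the artefacts the
track-processing pipeline must remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from turtlehab.geo import KM_PER_DEG
from turtlehab.habitat_model import HabitatParams, habitat_index
from turtlehab.io_formats import GridField, TrackTable, _bilinear_slice
from turtlehab.movement_model import (
    SimConfig,
    _habitat_gradient,
    _slice_index,
    diffusivity,
    taxis_velocity,
)

__all__ = [
    "ForcingSpec",
    "ArgosNoiseSpec",
    "make_forcing",
    "simulate_individuals",
    "degrade_to_argos",
    "make_drifters",
]

DEG_M = KM_PER_DEG * 1000.0

#: day of year of the Northern-Hemisphere SST maximum (~mid September)
_SEASON_PEAK_DOY = 258.0


@dataclass
class ForcingSpec:
    """Recipe for one synthetic forcing set (all randomness from ``seed``)."""

    lon_min: float = 150.0
    lon_max: float = 210.0
    lat_min: float = 15.0
    lat_max: float = 45.0
    grid_step: float = 0.5
    time_start: str = "2005-01-01"
    time_end: str = "2006-01-01"
    time_step_days: float = 6.0
    sst_south: float = 26.0
    sst_north: float = 8.0
    seasonal_amp: float = 2.0
    n_eddies: int = 4
    eddy_radius_deg: float = 2.0
    eddy_temp_amp: float = 1.0
    eddy_vel_amp: float = 0.2
    eddy_drift_km_day: float = 3.0
    jet_speed: float = 0.3
    jet_lat: float | None = None
    prey_lag_days: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        span = pd.Timestamp(self.time_end) - pd.Timestamp(self.time_start)
        if span < pd.Timedelta(days=self.time_step_days):
            raise ValueError("time_span must cover at least 2 forcing steps")


@dataclass
class ArgosNoiseSpec:
    """Argos-like degradation: irregular sampling, noise, rare spikes."""

    mean_fixes_per_day: float = 2.6
    sigma_km: float = 1.5
    spike_prob: float = 0.02
    spike_km: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.spike_prob <= 1.0):
            raise ValueError("spike_prob must be in [0, 1]")
        if self.sigma_km < 0 or self.spike_km < 0:
            raise ValueError("noise scales must be nonnegative")


def make_forcing(spec: ForcingSpec) -> dict[str, GridField]:
    """Generate temp30m, u, v and prey fields from a ForcingSpec.

    Deterministic given ``spec.seed``; returns a dict of GridFields on a
    shared regular grid (no land).
    """
    rng = np.random.default_rng(spec.seed)
    lon = np.arange(spec.lon_min, spec.lon_max + 1e-9, spec.grid_step)
    lat = np.arange(spec.lat_min, spec.lat_max + 1e-9, spec.grid_step)
    time = pd.date_range(spec.time_start, spec.time_end, freq=pd.Timedelta(days=spec.time_step_days))
    LON, LAT = np.meshgrid(lon, lat)

    lat_frac = (LAT - spec.lat_min) / max(spec.lat_max - spec.lat_min, 1e-12)
    base_T = spec.sst_south + (spec.sst_north - spec.sst_south) * lat_frac
    doy = np.array([t.dayofyear + t.hour / 24.0 for t in time])
    season = spec.seasonal_amp * np.cos(2.0 * np.pi * (doy - _SEASON_PEAK_DOY) / 365.25)

    # eddies: Gaussian streamfunction anomalies drifting westward
    n_eddies = spec.n_eddies
    lon_span = spec.lon_max - spec.lon_min
    lat_span = spec.lat_max - spec.lat_min
    if n_eddies > 0 and (lon_span < spec.eddy_radius_deg or lat_span < spec.eddy_radius_deg):
        warnings.warn("domain smaller than one eddy radius; eddies suppressed")
        n_eddies = 0
    e_lon0 = rng.uniform(spec.lon_min, spec.lon_max, n_eddies)
    e_lat0 = rng.uniform(spec.lat_min, spec.lat_max, n_eddies)
    e_sign = rng.choice([-1.0, 1.0], n_eddies)

    jet_lat = spec.jet_lat if spec.jet_lat is not None else 0.5 * (spec.lat_min + spec.lat_max)
    jet = spec.jet_speed * np.exp(-(((LAT - jet_lat) / 3.0) ** 2))

    T = np.empty((len(time), len(lat), len(lon)))
    U = np.empty_like(T)
    V = np.empty_like(T)
    R = spec.eddy_radius_deg
    drift_deg_day = spec.eddy_drift_km_day / KM_PER_DEG
    for k, t in enumerate(time):
        days = (t - time[0]).total_seconds() / 86400.0
        Tk = base_T + season[k]
        Uk = jet.copy()
        Vk = np.zeros_like(jet)
        for m in range(n_eddies):
            clon = spec.lon_min + (e_lon0[m] - spec.lon_min - drift_deg_day * days) % lon_span
            dx = LON - clon
            dy = LAT - e_lat0[m]
            g = np.exp(-(dx**2 + dy**2) / (2.0 * R**2))
            Tk = Tk + e_sign[m] * spec.eddy_temp_amp * g
            # velocity = curl of streamfunction psi = A * g  (rotational)
            amp = e_sign[m] * spec.eddy_vel_amp * np.e**0.5 * R  # peak speed ~ eddy_vel_amp
            Uk = Uk + amp * (dy / R**2) * g
            Vk = Vk - amp * (dx / R**2) * g
        T[k] = Tk
        U[k] = Uk
        V[k] = Vk

    # prey: lagged, smoothed productivity proxy, higher at cool/high latitudes
    lag_steps = max(0, int(round(spec.prey_lag_days / spec.time_step_days)))
    P = np.empty_like(T)
    for k in range(len(time)):
        Tl = T[max(0, k - lag_steps)]
        prod = (0.5 + 0.5 * lat_frac) * np.clip(1.0 + 0.02 * (18.0 - Tl), 0.2, None)
        P[k] = gaussian_filter(prod, sigma=2.0, mode="nearest")
    P = np.clip(P, 0.0, None)

    def _mk(name, vals, units):
        return GridField(name=name, lon=lon, lat=lat, time=time, values=vals, units=units)

    return {
        "temp30m": _mk("temp30m", T, "degC"),
        "u": _mk("u", U, "m s-1"),
        "v": _mk("v", V, "m s-1"),
        "prey": _mk("prey", P, "relative"),
    }


def _grad_fields(values: np.ndarray, grid: GridField):
    """Per-slice spatial gradient (per metre) of a (time,lat,lon) array."""
    gx = np.empty_like(values)
    gy = np.empty_like(values)
    for k in range(values.shape[0]):
        gx[k], gy[k] = _habitat_gradient(values[k], grid.lat, grid.lon_step, grid.lat_step)
    return gx, gy


def simulate_individuals(
    fields: dict[str, GridField],
    params: HabitatParams,
    release_lon: float,
    release_lat: float,
    release_date,
    n: int = 100,
    dt_hours: float = 3.0,
    duration_days: float = 90.0,
    mode: str = "active",
    seed: int = 0,
    config: SimConfig | None = None,
) -> TrackTable:
    """Euler-Maruyama individual-based simulation of n turtles.

    Uses exactly the taxis and diffusivity operators of the Eulerian
    solver:  dX = (u_currents + u_taxis + grad D) dt + sqrt(2D) dW.
    ``mode='passive'`` zeroes the taxis and holds D at the background
    floor.  Positions are kept off land by rejection with retry and
    reflected at the domain boundary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("active", "passive"):
        raise ValueError("mode must be 'active' or 'passive'")
    if config is None:
        config = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    temp = fields["temp30m"]
    u_c, v_c = fields["u"], fields["v"]
    release_lon = release_lon % 360.0

    hab = habitat_index(temp, fields["prey"], params)
    if mode == "active":
        ut_f, vt_f = taxis_velocity(hab, params, config)
        D_f = diffusivity(hab, params, config)
        ut_all, vt_all, D_all = ut_f.values, vt_f.values, D_f.values
        gDx, gDy = _grad_fields(D_all, temp)
    else:
        zeros = np.zeros_like(temp.values)
        ut_all = vt_all = zeros
        D_all = np.full_like(temp.values, config.background_diffusivity)
        D_all[np.isnan(temp.values)] = np.nan
        gDx = gDy = zeros

    wet = ~temp.land_mask
    i0 = int(np.clip(round((release_lon - temp.lon[0]) / temp.lon_step), 0, temp.lon.size - 1))
    j0 = int(np.clip(round((release_lat - temp.lat[0]) / temp.lat_step), 0, temp.lat.size - 1))
    if not wet[j0, i0]:
        raise ValueError("release position is on land")

    dt = dt_hours * 3600.0
    n_steps = int(round(duration_days * 24.0 / dt_hours))
    t0 = pd.Timestamp(release_date)
    times = pd.DatetimeIndex([t0 + pd.Timedelta(seconds=dt * k) for k in range(n_steps + 1)])

    lons = np.full(n, float(release_lon))
    lats = np.full(n, float(release_lat))
    lon_lo, lon_hi = temp.lon[0], temp.lon[-1]
    lat_lo, lat_hi = temp.lat[0], temp.lat[-1]

    out_lon = np.empty((n_steps + 1, n))
    out_lat = np.empty((n_steps + 1, n))
    out_lon[0] = lons
    out_lat[0] = lats

    def _on_land(lo, la):
        ii = np.clip(np.round((lo - temp.lon[0]) / temp.lon_step).astype(int), 0, temp.lon.size - 1)
        jj = np.clip(np.round((la - temp.lat[0]) / temp.lat_step).astype(int), 0, temp.lat.size - 1)
        return ~wet[jj, ii]

    for k in range(n_steps):
        mid = times[k] + pd.Timedelta(seconds=dt / 2)
        s = _slice_index(temp.time, mid)
        uc = _bilinear_slice(u_c.values[_slice_index(u_c.time, mid)], temp, lons, lats)
        vc = _bilinear_slice(v_c.values[_slice_index(v_c.time, mid)], temp, lons, lats)
        ut = _bilinear_slice(ut_all[s], temp, lons, lats)
        vt = _bilinear_slice(vt_all[s], temp, lons, lats)
        D = np.maximum(_bilinear_slice(D_all[s], temp, lons, lats), 0.0)
        dDx = _bilinear_slice(gDx[s], temp, lons, lats)
        dDy = _bilinear_slice(gDy[s], temp, lons, lats)
        drift_x = (uc + ut + dDx) * dt
        drift_y = (vc + vt + dDy) * dt
        sig = np.sqrt(2.0 * D * dt)
        new_lon, new_lat = lons.copy(), lats.copy()
        pending = np.arange(n)
        for _ in range(10):  # rejection with retry for land
            noise = rng.standard_normal((2, pending.size))
            dx_m = drift_x[pending] + sig[pending] * noise[0]
            dy_m = drift_y[pending] + sig[pending] * noise[1]
            cand_lat = lats[pending] + dy_m / DEG_M
            cand_lon = lons[pending] + dx_m / (DEG_M * np.cos(np.radians(lats[pending])))
            # reflect at the domain boundary (no-flux analogue)
            cand_lat = np.where(cand_lat < lat_lo, 2 * lat_lo - cand_lat, cand_lat)
            cand_lat = np.where(cand_lat > lat_hi, 2 * lat_hi - cand_lat, cand_lat)
            cand_lon = np.where(cand_lon < lon_lo, 2 * lon_lo - cand_lon, cand_lon)
            cand_lon = np.where(cand_lon > lon_hi, 2 * lon_hi - cand_lon, cand_lon)
            cand_lat = np.clip(cand_lat, lat_lo, lat_hi)
            cand_lon = np.clip(cand_lon, lon_lo, lon_hi)
            ok = ~_on_land(cand_lon, cand_lat)
            new_lon[pending[ok]] = cand_lon[ok]
            new_lat[pending[ok]] = cand_lat[ok]
            pending = pending[~ok]
            if pending.size == 0:
                break
        lons, lats = new_lon, new_lat
        out_lon[k + 1] = lons
        out_lat[k + 1] = lats

    ids = [f"sim{m:04d}" for m in range(n)]
    fixes = pd.DataFrame(
        {
            "id": np.repeat(ids, n_steps + 1),
            "t": np.tile(times, n),
            "lon": out_lon.T.ravel(),
            "lat": out_lat.T.ravel(),
        }
    )
    meta = pd.DataFrame(
        {"scl_release": params.scl, "release_date": t0}, index=pd.Index(ids, name="id")
    )
    return TrackTable(fixes=fixes, meta=meta)


def degrade_to_argos(tracks: TrackTable, noise: ArgosNoiseSpec) -> TrackTable:
    """Thin regularly sampled tracks and add Argos-like location errors.

    Fix times survive with probability rate*dt (Poisson-like schedule at
    ``mean_fixes_per_day``); each surviving fix gets isotropic Gaussian
    noise of scale ``sigma_km`` and, with probability ``spike_prob``, a
    large displacement of roughly ``spike_km``.  The first fix of every
    track is always kept.  Deterministic given ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    out = []
    for tid in tracks.track_ids():
        trk = tracks.get_track(tid)
        t = trk["t"].to_numpy()
        if len(t) < 2:
            out.append(trk)
            continue
        dt_days = (t[1] - t[0]) / np.timedelta64(1, "D")
        p_keep = min(1.0, noise.mean_fixes_per_day * dt_days)
        keep = rng.random(len(t)) < p_keep
        keep[0] = True
        sub = trk[keep].copy()
        m = len(sub)
        lat = sub["lat"].to_numpy()
        dn = rng.standard_normal((2, m)) * noise.sigma_km
        spikes = rng.random(m) < noise.spike_prob
        ang = rng.uniform(0, 2 * np.pi, m)
        mag = noise.spike_km * rng.uniform(0.8, 1.5, m)
        dx_km = dn[0] + spikes * mag * np.cos(ang)
        dy_km = dn[1] + spikes * mag * np.sin(ang)
        sub["lat"] = lat + dy_km / KM_PER_DEG
        sub["lon"] = sub["lon"].to_numpy() + dx_km / (KM_PER_DEG * np.cos(np.radians(lat)))
        out.append(sub)
    fixes = pd.concat(out, ignore_index=True)
    return TrackTable(fixes=fixes, meta=tracks.meta.copy())


def make_drifters(
    fields: dict[str, GridField],
    release_lon: float,
    release_lat: float,
    release_date,
    n: int = 100,
    seed: int = 0,
    dt_hours: float = 3.0,
    duration_days: float = 90.0,
    config: SimConfig | None = None,
) -> TrackTable:
    """Passive surface drifters: the null model for swimming-speed tests."""
    return simulate_individuals(
        fields,
        HabitatParams(),
        release_lon,
        release_lat,
        release_date,
        n=n,
        dt_hours=dt_hours,
        duration_days=duration_days,
        mode="passive",
        seed=seed,
        config=config,
    )
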
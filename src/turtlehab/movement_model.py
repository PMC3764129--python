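"""Eulerian advection-diffusion movement model for a turtle cohort.

The density rho of a cohort (individuals per grid cell) evolves under

    d rho / dt = -div[(u_c + u_t) rho] + div[D grad rho]

where u_c is the ocean current, u_t a habitat taxis directed up the
gradient of the feeding-habitat index H_a, and D a diffusivity that is
low in good habitat (individuals linger) and high in poor habitat
(individuals escape).  Both taxis speed and diffusivity scale with the
cohort's maximum sustainable speed, itself proportional to body length.

Functional forms
----------------
* taxis speed  = v_max * (1 - H_a) * |g| / (|g| + K)   along  g = grad H_a
* diffusivity  D = max(D_bg, D_max * (1 - gamma * H_a)),
  D_max = f_D * v_max^2 * dt_forcing

so taxis saturates at v_max for strong gradients, vanishes both in flat
habitat and at the habitat optimum, and diffusion drops by a factor
(1 - gamma) between worst and best habitat.

Numerics: first-order upwind advection and flux-form centred diffusion,
explicit in time with CFL-limited substepping; no-flux boundaries at
land and at the domain edge, so total population is conserved exactly
(to round-off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

from turtlehab.geo import KM_PER_DEG
from turtlehab.habitat_model import HabitatField, HabitatParams
from turtlehab.io_formats import GridField, TrackTable

__all__ = [
    "SimConfig",
    "DensityField",
    "v_max",
    "taxis_velocity",
    "diffusivity",
    "step_density",
    "simulate_density",
    "density_track_agreement",
]

#: metres per degree of latitude
DEG_M = KM_PER_DEG * 1000.0

_DEFAULT_FORCING_STEP = pd.Timedelta(days=6)


@dataclass
class SimConfig:
    """Numerical constants of the movement model.

    d_max_factor : dimensionless
        Scales the maximum diffusivity: D_max = d_max_factor * v_max^2 *
        dt_forcing.
    taxis_half_gradient : habitat units per degree
        Habitat-gradient magnitude at which taxis reaches half of its
        ceiling (saturation constant K).
    habitat_diffusion_slope : dimensionless in [0, 1]
        gamma: fractional reduction of diffusivity at H_a = 1.
    cfl_safety : in (0, 1]
        Courant-number ceiling used when choosing substeps.
    background_diffusivity : m^2/s
        Floor on D; also the diffusivity of passive drift.
    n_release : count
        Size of the virtual release batch.
    """

    d_max_factor: float = 0.25
    taxis_half_gradient: float = 0.05
    habitat_diffusion_slope: float = 0.9
    cfl_safety: float = 0.5
    background_diffusivity: float = 100.0
    seed: int = 0
    n_release: int = 2000

    def __post_init__(self):
        if not (0.0 < self.cfl_safety <= 1.0):
            raise ValueError("cfl_safety must be in (0, 1]")
        if not (0.0 <= self.habitat_diffusion_slope <= 1.0):
            raise ValueError("habitat_diffusion_slope must be in [0, 1]")
        for name in ("d_max_factor", "taxis_half_gradient", "background_diffusivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DensityField:
    """Per-cell population density through time from the Eulerian solver."""

    lon: np.ndarray
    lat: np.ndarray
    time: pd.DatetimeIndex
    values: np.ndarray  # (time, lat, lon), individuals per cell
    release_total: float

    def total(self, k: int = -1) -> float:
        """Spatial sum of density at snapshot k (NaN-safe over land)."""
        return float(np.nansum(self.values[k]))


def v_max(params: HabitatParams) -> float:
    """Maximum sustainable speed in m/s: MSS (bl/s) times body length (m)."""
    return params.mss * params.scl / 100.0


def _habitat_gradient(h: np.ndarray, lat: np.ndarray, lon_step: float, lat_step: float):
    """Centred-difference gradient of one habitat slice, per metre.

    One-sided at edges and next to land; zero where no wet neighbour
    exists in a direction.
    """
    ny, nx = h.shape
    dx_m = lon_step * DEG_M * np.cos(np.radians(lat))[:, None]  # (ny, 1)
    dy_m = lat_step * DEG_M

    def _axis_grad(arr, axis, step):
        fwd = np.full_like(arr, np.nan)
        bwd = np.full_like(arr, np.nan)
        sl_lo = [slice(None)] * 2
        sl_hi = [slice(None)] * 2
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        diff = arr[tuple(sl_hi)] - arr[tuple(sl_lo)]
        fwd[tuple(sl_lo)] = diff
        bwd[tuple(sl_hi)] = diff
        both = ~np.isnan(fwd) & ~np.isnan(bwd)
        g = np.where(both, (np.where(np.isnan(fwd), 0, fwd) + np.where(np.isnan(bwd), 0, bwd)) / 2.0,
                     np.where(~np.isnan(fwd), fwd, np.where(~np.isnan(bwd), bwd, 0.0)))
        return g / step

    gx = _axis_grad(h, 1, dx_m)
    gy = _axis_grad(h, 0, dy_m)
    land = np.isnan(h)
    gx[land] = np.nan
    gy[land] = np.nan
    return gx, gy


def taxis_velocity(
    habitat: HabitatField, params: HabitatParams, config: SimConfig
) -> Tuple[GridField, GridField]:
    """Habitat-gradient taxis velocity fields (u_t, v_t) in m/s.

    Direction follows grad H_a; magnitude is v_max * (1 - H_a) *
    |g|/(|g| + K) with |g| measured in habitat units per degree, so the
    speed saturates at v_max in strong gradients and vanishes both in
    flat habitat and at the habitat optimum.
    """
    h_a = habitat.h_a
    vmax = v_max(params)
    K = config.taxis_half_gradient
    ut = np.zeros_like(h_a.values)
    vt = np.zeros_like(h_a.values)
    for k in range(h_a.values.shape[0]):
        gx, gy = _habitat_gradient(h_a.values[k], h_a.lat, h_a.lon_step, h_a.lat_step)
        gmag_m = np.hypot(gx, gy)
        gmag_deg = gmag_m * DEG_M  # habitat units per degree
        with np.errstate(invalid="ignore", divide="ignore"):
            speed = vmax * (1.0 - h_a.values[k]) * gmag_deg / (gmag_deg + K)
            scale = np.where(gmag_m > 0, speed / gmag_m, 0.0)
        ut[k] = scale * gx
        vt[k] = scale * gy
    return (
        h_a.with_values(ut, name="u_taxis", units="m s-1"),
        h_a.with_values(vt, name="v_taxis", units="m s-1"),
    )


def diffusivity(habitat: HabitatField, params: HabitatParams, config: SimConfig) -> GridField:
    """Habitat-modulated diffusivity field D in m^2/s (decreasing in H_a)."""
    h_a = habitat.h_a
    dt_forcing = h_a.time_step if len(h_a.time) > 1 else _DEFAULT_FORCING_STEP
    d_max = config.d_max_factor * v_max(params) ** 2 * dt_forcing.total_seconds()
    D = np.maximum(config.background_diffusivity, d_max * (1.0 - config.habitat_diffusion_slope * h_a.values))
    D[np.isnan(h_a.values)] = np.nan
    return h_a.with_values(D, name="diffusivity", units="m2 s-1")


# ---------------------------------------------------------------------------
# Solver


def _cell_geometry(lon: np.ndarray, lat: np.ndarray):
    """dx_m (ny,), dy_m, area (ny,), dx at meridional faces (ny-1,)."""
    lon_step = lon[1] - lon[0]
    lat_step = lat[1] - lat[0]
    dx_m = lon_step * DEG_M * np.cos(np.radians(lat))  # zonal cell width per row
    dy_m = lat_step * DEG_M
    area = dx_m * dy_m
    lat_face = 0.5 * (lat[:-1] + lat[1:])
    dx_face = lon_step * DEG_M * np.cos(np.radians(lat_face))  # width of meridional faces
    return dx_m, dy_m, area, dx_face


def step_density(
    rho: np.ndarray,
    currents: Tuple[np.ndarray, np.ndarray],
    u_taxis: np.ndarray,
    v_taxis: np.ndarray,
    D: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    config: SimConfig,
    dt: float,
) -> np.ndarray:
    """Advance one density slice (individuals/cell) by dt seconds.

    Upwind advection with velocity (u_c + u_t, v_c + v_t) and flux-form
    diffusion with spatially varying D, substepped so that per-cell
    outflow never exceeds ``cfl_safety`` of its content (nonnegativity)
    and the explicit diffusion limit holds.  No-flux at land and domain
    boundaries.
    """
    u_c, v_c = currents
    wet = ~np.isnan(D)
    for name, arr in (("currents u", u_c), ("currents v", v_c), ("diffusivity", D)):
        bad = ~np.isfinite(np.where(wet, arr, 0.0))
        if bad.any():
            j, i = np.argwhere(bad)[0]
            raise ValueError(f"NaN in forcing field {name} at wet cell (lat={lat[j]}, lon={lon[i]})")
    u = np.where(wet, u_c + u_taxis, 0.0)
    v = np.where(wet, v_c + v_taxis, 0.0)
    Dw = np.where(wet, D, 0.0)

    dx_m, dy_m, area, dx_face = _cell_geometry(lon, lat)
    dx2d = np.broadcast_to(dx_m[:, None], rho.shape)

    # combined Courant + diffusion number per cell -> number of substeps
    courant = (
        np.abs(u) * dt / dx2d
        + np.abs(v) * dt / dy_m
        + 2.0 * Dw * dt * (1.0 / dx2d**2 + 1.0 / dy_m**2)
    )
    n_sub = max(1, int(np.ceil(np.nanmax(courant) / config.cfl_safety)))
    dts = dt / n_sub

    N = np.where(wet, rho, 0.0).astype(float)
    wet_x = wet[:, :-1] & wet[:, 1:]   # open zonal faces
    wet_y = wet[:-1, :] & wet[1:, :]   # open meridional faces
    u_face = np.where(wet_x, 0.5 * (u[:, :-1] + u[:, 1:]), 0.0)
    v_face = np.where(wet_y, 0.5 * (v[:-1, :] + v[1:, :]), 0.0)
    D_face_x = np.where(wet_x, 0.5 * (Dw[:, :-1] + Dw[:, 1:]), 0.0)
    D_face_y = np.where(wet_y, 0.5 * (Dw[:-1, :] + Dw[1:, :]), 0.0)

    for _ in range(n_sub):
        c = N / area[:, None]  # concentration, individuals / m^2
        # zonal faces: flux (individuals/s) positive eastward
        c_up_x = np.where(u_face >= 0, c[:, :-1], c[:, 1:])
        Fx = u_face * c_up_x * dy_m
        Fx += -D_face_x * (c[:, 1:] - c[:, :-1]) / dx2d[:, :-1] * dy_m
        # meridional faces: positive northward
        c_up_y = np.where(v_face >= 0, c[:-1, :], c[1:, :])
        Fy = v_face * c_up_y * dx_face[:, None]
        Fy += -D_face_y * (c[1:, :] - c[:-1, :]) / dy_m * dx_face[:, None]
        dN = np.zeros_like(N)
        dN[:, :-1] -= Fx * dts
        dN[:, 1:] += Fx * dts
        dN[:-1, :] -= Fy * dts
        dN[1:, :] += Fy * dts
        N += dN
    N[~wet] = np.nan
    return N


def _slice_index(time_axis: pd.DatetimeIndex, t: pd.Timestamp) -> int:
    """Forcing slice whose interval contains t (piecewise-constant forcing)."""
    k = int(np.clip(time_axis.searchsorted(t, side="right") - 1, 0, len(time_axis) - 1))
    return k


def simulate_density(
    release_lon: float,
    release_lat: float,
    release_date,
    duration_days: float,
    currents: Tuple[GridField, GridField],
    habitat: HabitatField,
    params: HabitatParams,
    config: Optional[SimConfig] = None,
    mode: str = "active",
) -> DensityField:
    """Simulate a virtual release as an Eulerian density through time.

    ``config.n_release`` individuals start in the grid cell containing
    the release point; snapshots are stored at every forcing time step.
    ``mode='passive'`` switches active swimming off: taxis is zero and
    diffusivity drops to the background floor, leaving pure drift in the
    ocean currents.
    """
    if config is None:
        config = SimConfig()
    if mode not in ("active", "passive"):
        raise ValueError("mode must be 'active' or 'passive'")
    h_a = habitat.h_a
    u_c, v_c = currents
    i = int(np.clip(round((release_lon % 360.0 - h_a.lon[0]) / h_a.lon_step), 0, h_a.lon.size - 1))
    j = int(np.clip(round((release_lat - h_a.lat[0]) / h_a.lat_step), 0, h_a.lat.size - 1))
    if h_a.land_mask[j, i]:
        raise ValueError(f"release cell (lat={h_a.lat[j]}, lon={h_a.lon[i]}) is on land")

    t0 = pd.Timestamp(release_date)
    dt_forcing = h_a.time_step if len(h_a.time) > 1 else _DEFAULT_FORCING_STEP
    n_steps = int(np.ceil(pd.Timedelta(days=duration_days) / dt_forcing))
    snap_times = pd.DatetimeIndex([t0 + k * dt_forcing for k in range(n_steps + 1)])

    if mode == "active":
        ut_f, vt_f = taxis_velocity(habitat, params, config)
        D_f = diffusivity(habitat, params, config)
        ut_all, vt_all, D_all = ut_f.values, vt_f.values, D_f.values
    else:
        zeros = np.zeros_like(h_a.values)
        ut_all = vt_all = zeros
        D_all = np.where(np.isnan(h_a.values), np.nan, config.background_diffusivity)

    rho = np.full(h_a.values.shape[1:], np.nan)
    rho[~h_a.land_mask] = 0.0
    rho[j, i] = float(config.n_release)

    out = np.empty((n_steps + 1,) + rho.shape)
    out[0] = rho
    for k in range(n_steps):
        mid = snap_times[k] + dt_forcing / 2
        s = _slice_index(h_a.time, mid)
        rho = step_density(
            rho,
            (u_c.values[_slice_index(u_c.time, mid)], v_c.values[_slice_index(v_c.time, mid)]),
            ut_all[s],
            vt_all[s],
            D_all[s],
            h_a.lon,
            h_a.lat,
            config,
            dt_forcing.total_seconds(),
        )
        out[k + 1] = rho
    return DensityField(
        lon=h_a.lon, lat=h_a.lat, time=snap_times, values=out, release_total=float(config.n_release)
    )


# ---------------------------------------------------------------------------
# Track agreement


def _iter_positions(tracks) -> Iterable[Tuple[pd.Timestamp, float, float]]:
    if isinstance(tracks, TrackTable):
        for _, row in tracks.fixes.iterrows():
            yield pd.Timestamp(row["t"]), float(row["lon"]), float(row["lat"])
        return
    for trk in np.atleast_1d(tracks):
        for t, lo, la in zip(trk.times, trk.lon, trk.lat):
            yield pd.Timestamp(t), float(lo), float(la)


def density_track_agreement(
    density: DensityField, tracks, top_q: float = 0.25
) -> dict:
    """Score how well observed positions fall in high simulated density.

    For each observed position within the simulation span, looks up the
    density in its cell at the nearest snapshot and ranks it among all
    wet cells at that snapshot.  Returns the mean percentile rank (50
    for a uniform density) and the fraction of observations inside the
    top ``top_q`` density region.
    """
    lon_step = density.lon[1] - density.lon[0]
    lat_step = density.lat[1] - density.lat[0]
    percentiles = []
    in_top = []
    for t, lo, la in _iter_positions(tracks):
        if t < density.time[0] or t > density.time[-1]:
            continue
        k = int(np.argmin(np.abs(density.time - t)))
        i = int(np.clip(round((lo % 360.0 - density.lon[0]) / lon_step), 0, density.lon.size - 1))
        j = int(np.clip(round((la - density.lat[0]) / lat_step), 0, density.lat.size - 1))
        slab = density.values[k]
        wet = slab[np.isfinite(slab)]
        val = slab[j, i]
        if not np.isfinite(val) or wet.size == 0:
            continue
        rank = (np.sum(wet < val) + 0.5 * np.sum(wet == val)) / wet.size
        percentiles.append(100.0 * rank)
        in_top.append(val >= np.quantile(wet, 1.0 - top_q))
    if not percentiles:
        return {"mean_percentile": np.nan, "top_q_coverage": np.nan, "n_obs": 0}
    return {
        "mean_percentile": float(np.mean(percentiles)),
        "top_q_coverage": float(np.mean(in_top)),
        "n_obs": len(percentiles),
    }
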
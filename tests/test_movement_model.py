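"""Advection-diffusion solver: taxis, diffusivity, conservation, limits."""

import numpy as np
import pandas as pd
import pytest

from turtlehab.habitat_model import HabitatParams, habitat_index
from turtlehab.io_formats import GridField, TrackTable
from turtlehab.movement_model import (
    DEG_M,
    DensityField,
    SimConfig,
    density_track_agreement,
    diffusivity,
    simulate_density,
    step_density,
    taxis_velocity,
    v_max,
)


def _uniform_fields(value=17.0, prey=1.0, u=0.0, v=0.0, lat0=20.0, lat1=40.0):
    lon = np.arange(170.0, 190.0 + 1e-9, 0.5)
    lat = np.arange(lat0, lat1 + 1e-9, 0.5)
    time = pd.date_range("2005-01-01", "2005-07-01", freq="6D")
    shape = (len(time), len(lat), len(lon))

    def _mk(name, val):
        return GridField(name=name, lon=lon, lat=lat, time=time, values=np.full(shape, float(val)))

    return {"temp30m": _mk("temp30m", value), "u": _mk("u", u), "v": _mk("v", v), "prey": _mk("prey", prey)}


class TestVmax:
    def test_thirty_cm_cohort(self):
        assert v_max(HabitatParams(mss=1.1, scl=30.0)) == pytest.approx(0.33)

    def test_thirtyfive_cm_cohort(self):
        assert v_max(HabitatParams(mss=0.9, scl=34.7)) == pytest.approx(0.3123)

    def test_linear_in_body_length(self):
        assert v_max(HabitatParams(mss=1.0, scl=60.0)) == pytest.approx(
            2 * v_max(HabitatParams(mss=1.0, scl=30.0))
        )


class TestTaxisVelocity:
    def test_uniform_habitat_zero_taxis(self, cohort_params, sim_config):
        f = _uniform_fields(17.0)
        hab = habitat_index(f["temp30m"], f["prey"], cohort_params)
        ut, vt = taxis_velocity(hab, cohort_params, sim_config)
        assert np.allclose(ut.values, 0.0) and np.allclose(vt.values, 0.0)

    def test_speed_bounded_by_vmax(self, small_habitat, cohort_params, sim_config):
        ut, vt = taxis_velocity(small_habitat, cohort_params, sim_config)
        speed = np.hypot(ut.values, vt.values)
        assert np.nanmax(speed) <= v_max(cohort_params) + 1e-12

    def test_linear_ramp_analytic_magnitude(self, cohort_params, sim_config):
        # habitat rising northward at b units/degree: taxis points north with
        # magnitude v_max * (1 - h) * b / (b + K)
        f = _uniform_fields(17.0)
        temp = f["temp30m"]
        b = 0.02  # habitat units per degree of latitude
        ramp = 0.2 + b * (temp.lat - temp.lat[0])
        h = np.broadcast_to(ramp[None, :, None], temp.values.shape).copy()
        hab = habitat_index(temp, f["prey"], HabitatParams(prey_ref=1.0))
        hab.h_a = temp.with_values(h, name="h_a")
        ut, vt = taxis_velocity(hab, cohort_params, sim_config)
        k, j, i = 0, 20, 20  # interior cell
        expected = (
            v_max(cohort_params)
            * (1.0 - h[k, j, i])
            * b
            / (b + sim_config.taxis_half_gradient)
        )
        assert ut.values[k, j, i] == pytest.approx(0.0, abs=1e-15)
        assert vt.values[k, j, i] == pytest.approx(expected, rel=1e-9)
        assert vt.values[k, j, i] > 0  # up-ramp


class TestDiffusivity:
    def test_best_worst_habitat_ratio(self, cohort_params):
        cfg = SimConfig(background_diffusivity=1e-6)
        f = _uniform_fields(17.0)
        temp = f["temp30m"]
        hab = habitat_index(temp, f["prey"], cohort_params)
        hab.h_a = temp.with_values(np.zeros_like(temp.values), name="h_a")
        d0 = diffusivity(hab, cohort_params, cfg).values[0, 0, 0]
        hab.h_a = temp.with_values(np.ones_like(temp.values), name="h_a")
        d1 = diffusivity(hab, cohort_params, cfg).values[0, 0, 0]
        assert d1 / d0 == pytest.approx(1.0 - cfg.habitat_diffusion_slope, rel=1e-12)

    def test_uniform_habitat_uniform_d(self, cohort_params, sim_config):
        f = _uniform_fields(17.0)
        hab = habitat_index(f["temp30m"], f["prey"], cohort_params)
        D = diffusivity(hab, cohort_params, sim_config).values
        assert np.ptp(D) == 0.0

    def test_anticorrelated_with_habitat(self, small_habitat, cohort_params, sim_config):
        D = diffusivity(small_habitat, cohort_params, sim_config).values
        wet = ~np.isnan(D)
        r = np.corrcoef(D[wet].ravel(), small_habitat.h_a.values[wet].ravel())[0, 1]
        assert r < 0.0


class TestStepDensity:
    def _grid(self, nx=81, ny=81, step=0.05, lat0=28.0, lon0=178.0):
        return lon0 + step * np.arange(nx), lat0 + step * np.arange(ny)

    def test_zero_velocity_zero_d_identity(self):
        lon, lat = self._grid(nx=21, ny=21, step=0.5)
        rng = np.random.default_rng(0)
        rho = rng.uniform(0, 5, (21, 21))
        zeros = np.zeros_like(rho)
        out = step_density(rho, (zeros, zeros), zeros, zeros, zeros, lon, lat, SimConfig(), 86400.0)
        np.testing.assert_allclose(out, rho)

    def test_uniform_zonal_advection_moves_centroid(self):
        lon, lat = self._grid(nx=61, ny=21, step=0.25, lat0=29.0)
        rho = np.zeros((21, 61))
        rho[10, 10:14] = 5.0
        u = np.full_like(rho, 0.2)
        zeros = np.zeros_like(rho)
        dt = 3 * 86400.0
        out = step_density(rho, (u, zeros), zeros, zeros, zeros, lon, lat, SimConfig(), dt)
        dx_deg = 0.2 * dt / (DEG_M * np.cos(np.radians(30.0)))
        c0 = (rho * lon[None, :]).sum() / rho.sum()
        c1 = (out * lon[None, :]).sum() / out.sum()
        assert c1 - c0 == pytest.approx(dx_deg, abs=0.25)
        assert out.sum() == pytest.approx(rho.sum(), rel=1e-12)

    def test_point_release_matches_heat_kernel(self):
        lon, lat = self._grid()
        ny = nx = 81
        rho = np.zeros((ny, nx))
        j0 = i0 = 40
        N = 2000.0
        rho[j0, i0] = N
        D0 = 300.0
        D = np.full_like(rho, D0)
        zeros = np.zeros_like(rho)
        t = 6 * 86400.0
        out = step_density(rho, (zeros, zeros), zeros, zeros, D, lon, lat, SimConfig(), t)
        dx_m = 0.05 * DEG_M * np.cos(np.radians(lat))
        area = dx_m[:, None] * (0.05 * DEG_M)
        X = (lon[None, :] - lon[i0]) * DEG_M * np.cos(np.radians(lat))[:, None]
        Y = (lat[:, None] - lat[j0]) * DEG_M
        G = np.exp(-(X**2 + Y**2) / (4 * D0 * t)) / (4 * np.pi * D0 * t)
        expected = N * G * area
        assert np.abs(out - expected).sum() / N < 0.05

    def test_nan_in_forcing_names_cell(self):
        lon, lat = self._grid(nx=5, ny=5, step=0.5)
        rho = np.ones((5, 5))
        u = np.zeros_like(rho)
        u[2, 3] = np.nan
        zeros = np.zeros_like(rho)
        with pytest.raises(ValueError, match="lat"):
            step_density(rho, (u, zeros), zeros, zeros, np.full_like(rho, 10.0), lon, lat, SimConfig(), 3600.0)

    def test_nonnegativity_with_strong_gradients(self):
        lon, lat = self._grid(nx=31, ny=31, step=0.5)
        rng = np.random.default_rng(1)
        rho = np.zeros((31, 31))
        rho[15, 15] = 2000.0
        u = rng.normal(0, 0.4, rho.shape)
        v = rng.normal(0, 0.4, rho.shape)
        D = rng.uniform(10, 5000, rho.shape)
        out = rho
        for _ in range(5):
            out = step_density(out, (u, v), np.zeros_like(rho), np.zeros_like(rho), D, lon, lat, SimConfig(), 6 * 86400.0)
        assert out.min() >= 0.0
        assert out.sum() == pytest.approx(2000.0, rel=1e-9)


class TestSimulateDensity:
    def test_mass_conserved_over_year(self, small_forcing, small_habitat, cohort_params, sim_config):
        dens = simulate_density(
            180.0, 30.0, "2005-01-01", 170.0, (small_forcing["u"], small_forcing["v"]),
            small_habitat, cohort_params, sim_config, mode="active",
        )
        for k in range(len(dens.time)):
            assert dens.total(k) == pytest.approx(2000.0, rel=1e-6)
        assert np.nanmin(dens.values) >= 0.0

    def test_active_density_climbs_static_habitat_bump(self, cohort_params):
        f = _uniform_fields(17.0)
        temp = f["temp30m"]
        LON, LAT = np.meshgrid(temp.lon, temp.lat)
        bump = 0.2 + 0.8 * np.exp(-(((LON - 185.0) ** 2 + (LAT - 35.0) ** 2) / 18.0))
        h = np.broadcast_to(bump[None], temp.values.shape).copy()
        hab = habitat_index(temp, f["prey"], HabitatParams(prey_ref=1.0))
        hab.h_a = temp.with_values(h, name="h_a")
        cfg = SimConfig(n_release=2000)
        dens = simulate_density(175.0, 25.0, "2005-01-01", 120.0, (f["u"], f["v"]), hab, cohort_params, cfg)

        def centroid_dist(k):
            w = np.nan_to_num(dens.values[k])
            clon = (w * dens.lon[None, :]).sum() / w.sum()
            clat = (w * dens.lat[:, None]).sum() / w.sum()
            return np.hypot(clon - 185.0, clat - 35.0)

        dists = [centroid_dist(k) for k in range(0, len(dens.time), 5)]
        assert dists[-1] < dists[0]
        assert all(b <= a + 0.2 for a, b in zip(dists, dists[1:]))  # mostly decreasing

    def test_passive_equals_active_in_uniform_habitat(self, cohort_params):
        f = _uniform_fields(17.0, u=0.1)
        hab = habitat_index(f["temp30m"], f["prey"], cohort_params)
        # uniform optimal habitat: active D collapses to D_max*(1-gamma);
        # set the passive background to the same value
        cfg_a = SimConfig(n_release=2000)
        D_active = float(np.nanmax(diffusivity(hab, cohort_params, cfg_a).values))
        cfg_p = SimConfig(n_release=2000, background_diffusivity=D_active)
        a = simulate_density(180.0, 30.0, "2005-01-01", 60.0, (f["u"], f["v"]), hab, cohort_params, cfg_a, mode="active")
        p = simulate_density(180.0, 30.0, "2005-01-01", 60.0, (f["u"], f["v"]), hab, cohort_params, cfg_p, mode="passive")
        np.testing.assert_allclose(a.values[-1], p.values[-1], rtol=1e-9, atol=1e-12)

    def test_release_on_land_rejected(self, cohort_params, sim_config):
        f = _uniform_fields(17.0)
        hab = habitat_index(f["temp30m"], f["prey"], cohort_params)
        hab.h_a.values[:, 20, 20] = np.nan
        hab.h_a.land_mask[20, 20] = True
        with pytest.raises(ValueError, match="land"):
            simulate_density(
                float(hab.h_a.lon[20]), float(hab.h_a.lat[20]), "2005-01-01", 30.0,
                (f["u"], f["v"]), hab, cohort_params, sim_config,
            )


class TestDensityTrackAgreement:
    def _density(self, values):
        values = np.asarray(values, dtype=float)
        nt, ny, nx = values.shape
        return DensityField(
            lon=180.0 + np.arange(nx),
            lat=25.0 + np.arange(ny),
            time=pd.date_range("2005-01-01", periods=nt, freq="6D"),
            values=values,
            release_total=float(values[0].sum()),
        )

    def _tracks(self, lons, lats, t):
        return TrackTable(
            fixes=pd.DataFrame(
                {"id": [f"t{k}" for k in range(len(lons))], "t": t, "lon": lons, "lat": lats}
            )
        )

    def test_uniform_density_mean_percentile_fifty(self):
        dens = self._density(np.ones((2, 9, 9)))
        rng = np.random.default_rng(2)
        lons = rng.uniform(180, 188, 40)
        lats = rng.uniform(25, 33, 40)
        out = density_track_agreement(dens, self._tracks(lons, lats, dens.time[0]))
        assert out["mean_percentile"] == pytest.approx(50.0, abs=1.0)

    def test_positions_on_argmax_cells_cover_top_quarter(self):
        vals = np.ones((1, 9, 9))
        vals[0, 4, 6] = 100.0
        dens = self._density(vals)
        out = density_track_agreement(dens, self._tracks([186.0], [29.0], dens.time[0]))
        assert out["top_q_coverage"] == 1.0
        assert out["mean_percentile"] > 99.0

    def test_sampling_from_density_scores_above_half(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 1.0, (1, 9, 9)) ** 4  # peaked
        dens = self._density(vals)
        p = vals[0].ravel() / vals[0].sum()
        idx = rng.choice(81, size=300, p=p)
        lats = 25.0 + idx // 9
        lons = 180.0 + idx % 9
        out = density_track_agreement(dens, self._tracks(lons, lats, dens.time[0]))
        assert out["mean_percentile"] > 50.0
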
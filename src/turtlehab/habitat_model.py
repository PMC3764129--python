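"""Feeding-habitat index for a single size cohort.

The habitat H_a of a cohort combines a Gaussian temperature-preference
index Θ (1 at the optimal temperature, falling off with the cohort's
thermal tolerance) with a saturating prey-accessibility term, as a
product on the unit interval: H_a = Θ · f_prey, with 1 the optimal
habitat.  Hot spots are cells where H_a exceeds a threshold (0.8 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union
import warnings

import numpy as np

from turtlehab.io_formats import GridField

__all__ = [
    "HabitatParams",
    "HabitatField",
    "temperature_preference",
    "prey_accessibility",
    "habitat_index",
    "hot_spots",
]

#: SCL (cm) -> CCL (cm) and back; carapace lengths are linearly related.
SCL_FROM_CCL = (0.369, 0.932)


@dataclass(frozen=True)
class HabitatParams:
    """Parameters defining one simulated cohort.

    t_opt, t_sd : °C
        Mean and spread of the Gaussian temperature preference.  The
        defaults (17.0, 1.5) describe ~30 cm juvenile loggerheads in the
        North Pacific.
    mss : body lengths / second
        Maximum sustainable swimming speed.
    scl : cm
        Straight carapace length of the cohort.
    prey_ref : optional
        Prey concentration at which accessibility saturates; defaults to
        the 95th percentile of the prey field over the whole domain-time.
    """

    t_opt: float = 17.0
    t_sd: float = 1.5
    mss: float = 1.1
    scl: float = 30.0
    prey_ref: Optional[float] = None

    def __post_init__(self):
        if self.t_sd <= 0:
            raise ValueError("t_sd must be positive")
        if self.mss <= 0 or self.scl <= 0:
            raise ValueError("mss and scl must be positive")


@dataclass
class HabitatField:
    """Habitat index H_a with its two factors, on a common grid."""

    h_a: GridField
    theta: GridField
    f_prey: GridField


def _as_values(field: Union[GridField, np.ndarray, float]) -> np.ndarray:
    if isinstance(field, GridField):
        return field.values
    return np.asarray(field, dtype=float)


def _like(template: Union[GridField, np.ndarray, float], values, name: str, units: str = ""):
    if isinstance(template, GridField):
        return template.with_values(values, name=name, units=units)
    out = np.asarray(values, dtype=float)
    return float(out) if np.ndim(template) == 0 else out


def temperature_preference(temperature, t_opt: float = 17.0, t_sd: float = 1.5):
    """Gaussian-shape temperature preference index in (0, 1].

    theta = exp(-(T - t_opt)^2 / (2 t_sd^2)); exactly 1 at T = t_opt.
    Accepts a GridField, array or scalar and returns the same kind.
    """
    if t_sd <= 0:
        raise ValueError("t_sd must be positive")
    T = _as_values(temperature)
    theta = np.exp(-((T - t_opt) ** 2) / (2.0 * t_sd**2))
    return _like(temperature, theta, "theta")


def prey_accessibility(prey, prey_ref: Optional[float] = None):
    """Saturating prey term: f_prey = min(P / prey_ref, 1).

    ``prey_ref`` defaults to the 95th percentile of the prey values over
    the whole domain and time span (ignoring land).
    """
    P = _as_values(prey)
    if np.any(P[np.isfinite(P)] < 0):
        raise ValueError("prey concentrations must be nonnegative")
    if prey_ref is None:
        finite = P[np.isfinite(P)]
        prey_ref = float(np.percentile(finite, 95)) if finite.size else 0.0
    if prey_ref <= 0:
        warnings.warn("prey field is all zero; accessibility is zero everywhere")
        f = np.zeros_like(P)
        f[~np.isfinite(P)] = np.nan
    else:
        f = np.minimum(P / prey_ref, 1.0)
    return _like(prey, f, "f_prey")


def habitat_index(temperature: GridField, prey: GridField, params: HabitatParams) -> HabitatField:
    """Feeding-habitat index H_a = Θ(T) · f_prey(P) per cell and time."""
    if (
        temperature.values.shape != prey.values.shape
        or not np.allclose(temperature.lon, prey.lon)
        or not np.allclose(temperature.lat, prey.lat)
    ):
        raise ValueError("temperature and prey fields must share grid and time axes")
    theta = temperature_preference(temperature, params.t_opt, params.t_sd)
    f_prey = prey_accessibility(prey, params.prey_ref)
    h_a = temperature.with_values(theta.values * f_prey.values, name="h_a")
    return HabitatField(h_a=h_a, theta=theta, f_prey=f_prey)


def hot_spots(habitat: HabitatField, threshold: float = 0.8) -> GridField:
    """Boolean hot-spot mask: cells with H_a strictly above the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        mask = (habitat.h_a.values > threshold).astype(float)
    mask[np.isnan(habitat.h_a.values)] = np.nan
    return habitat.h_a.with_values(mask, name="hot_spot", units="")
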
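"""Synthetic inputs for the dispersal pipeline.

Two generators stand in for the external data sources:

* :func:`generate_flow_field` builds hourly surface current and
  temperature fields on a regular lon/lat grid with the statistical
  character of two contrasting coastal release sites — a *dynamic* site
  with strong semidiurnal tidal currents (speeds 0.01-2.4 m/s) and a
  *quiet* site with weak flow (0.01-0.6 m/s).  The velocity is the sum of
  a steady residual current, a spatially uniform rotating semidiurnal
  tide (period 12.42 h) whose amplitude follows a spring-neap envelope
  (period 14.8 d), and a weak steady divergence-free eddy field derived
  from a random smooth streamfunction (correlation length >= 10 grid
  cells) so that spatial interpolation is meaningful.

* :func:`generate_decay_series` emulates a tank decay experiment:
  temperature treatments x biological replicates (tanks) x technical
  replicates sampled at fixed times, with a multiplicative lognormal
  measurement noise of chosen coefficient of variation and a systematic
  between-tank level offset.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .decay_models import (
    FirstOrderParams,
    SecondOrderParams,
    TemperatureDecayLaw,
    eval_first_order,
    eval_second_order,
)

__all__ = [
    "SiteProfile",
    "FieldGridSpec",
    "DecaySeriesDesign",
    "DYNAMIC_SITE",
    "QUIET_SITE",
    "generate_flow_field",
    "generate_decay_series",
    "make_delayed_truth",
    "default_decay_design",
    "save_flow_field",
    "load_flow_field",
    "EARTH_RADIUS_M",
    "SEMIDIURNAL_PERIOD_H",
    "SPRING_NEAP_PERIOD_H",
]

EARTH_RADIUS_M = 6_371_000.0
SEMIDIURNAL_PERIOD_H = 12.42        # principal lunar semidiurnal constituent
SPRING_NEAP_PERIOD_H = 14.8 * 24.0  # spring-neap amplitude modulation


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteProfile:
    """Statistical character of a release site's surface flow."""

    name: str
    center_lon: float
    center_lat: float
    tidal_amplitude: float          # m/s, mean rotary tide amplitude
    residual_speed: float           # m/s, steady background current
    springneap_modulation: float    # fractional amplitude modulation in [0, 1]
    temperature_mean: float         # degC, uniform field temperature
    temperature_seasonal_offset: float = 0.0  # degC added for "summer" months
    eddy_speed: float = 0.0         # m/s, steady smooth eddy perturbation
    speed_min: float = 0.0          # m/s, declared envelope
    speed_max: float = math.inf

    def __post_init__(self) -> None:
        if self.tidal_amplitude < 0 or self.residual_speed < 0:
            raise ValueError("speeds must be >= 0")
        if not 0.0 <= self.springneap_modulation <= 1.0:
            raise ValueError("springneap_modulation must be in [0, 1]")


#: Strong tidal currents (observed range 0.01-2.4 m/s).
DYNAMIC_SITE = SiteProfile(
    name="dynamic", center_lon=-5.05, center_lat=48.05,
    tidal_amplitude=1.1, residual_speed=0.04, springneap_modulation=0.9,
    temperature_mean=12.0, eddy_speed=0.02, speed_min=0.01, speed_max=2.4,
)

#: Weak flows only (observed range 0.01-0.6 m/s).
QUIET_SITE = SiteProfile(
    name="quiet", center_lon=-4.51, center_lat=47.68,
    tidal_amplitude=0.25, residual_speed=0.02, springneap_modulation=0.8,
    temperature_mean=12.0, eddy_speed=0.01, speed_min=0.01, speed_max=0.6,
)


@dataclass(frozen=True)
class FieldGridSpec:
    """Regular lon/lat grid with hourly (or coarser) time steps."""

    lon0: float
    lat0: float
    nx: int
    ny: int
    spacing_m: float
    time_start: pd.Timestamp
    time_end: pd.Timestamp
    cadence_h: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("nx and ny must be >= 2")
        if self.spacing_m <= 0:
            raise ValueError("spacing_m must be > 0")
        span_h = (pd.Timestamp(self.time_end)
                  - pd.Timestamp(self.time_start)) / pd.Timedelta(hours=1)
        if span_h < 0:
            raise ValueError("time_end must not precede time_start")
        n = span_h / self.cadence_h
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cadence_h must divide the time span")

    @property
    def dlat(self) -> float:
        return math.degrees(self.spacing_m / EARTH_RADIUS_M)

    @property
    def dlon(self) -> float:
        lat_mid = self.lat0 + 0.5 * (self.ny - 1) * self.dlat
        return math.degrees(
            self.spacing_m / (EARTH_RADIUS_M * math.cos(math.radians(lat_mid)))
        )

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.nx)

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(self.ny)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.time_start, self.time_end,
                             freq=pd.Timedelta(hours=self.cadence_h))

    @classmethod
    def centered_on(cls, lon: float, lat: float, half_width_km: float,
                    spacing_m: float, time_start, time_end,
                    cadence_h: float = 1.0) -> "FieldGridSpec":
        """Grid covering ``half_width_km`` on each side of a point."""
        n = 2 * int(math.ceil(half_width_km * 1000.0 / spacing_m)) + 1
        dlat = math.degrees(spacing_m / EARTH_RADIUS_M)
        dlon = math.degrees(
            spacing_m / (EARTH_RADIUS_M * math.cos(math.radians(lat)))
        )
        return cls(lon0=lon - dlon * (n // 2), lat0=lat - dlat * (n // 2),
                   nx=n, ny=n, spacing_m=spacing_m,
                   time_start=pd.Timestamp(time_start),
                   time_end=pd.Timestamp(time_end), cadence_h=cadence_h)


class GridSizingError(ValueError):
    """The grid does not cover the required dispersal footprint."""


# --------------------------------------------------------------------------
# flow-field generator
# --------------------------------------------------------------------------

def generate_flow_field(profile: SiteProfile, grid: FieldGridSpec, seed: int,
                        min_footprint_km: float = 30.0) -> xr.Dataset:
    """Hourly u, v (m/s) and temperature (degC) fields for one site.

    The tidal component rotates anticlockwise with constant modulus, so
    it is divergence-free by construction; the eddy component derives
    from a streamfunction and is therefore divergence-free as well.  The
    speed series at the site centre is validated against the profile's
    declared envelope.

    ``min_footprint_km`` is the dispersal footprint the grid must cover
    on each side of the site centre (a :class:`GridSizingError` is raised
    otherwise); pass 0 to disable for idealized test grids.
    """
    half_x_km = 0.5 * (grid.nx - 1) * grid.spacing_m / 1000.0
    half_y_km = 0.5 * (grid.ny - 1) * grid.spacing_m / 1000.0
    if min(half_x_km, half_y_km) < min_footprint_km:
        raise GridSizingError(
            f"grid covers only +/-{min(half_x_km, half_y_km):.1f} km; "
            f">= {min_footprint_km} km around the release point required"
        )
    lons, lats = grid.lons, grid.lats
    if not (lons[0] <= profile.center_lon <= lons[-1]
            and lats[0] <= profile.center_lat <= lats[-1]):
        raise GridSizingError("site centre lies outside the grid")

    rng = np.random.default_rng(seed)
    times = grid.times
    t_h = ((times - times[0]) / pd.Timedelta(hours=1)).to_numpy(float)

    # rotating semidiurnal tide with spring-neap envelope (spatially uniform)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    sn_phase0 = rng.uniform(0.0, 2.0 * np.pi)
    omega = 2.0 * np.pi / SEMIDIURNAL_PERIOD_H
    omega_sn = 2.0 * np.pi / SPRING_NEAP_PERIOD_H
    amp = profile.tidal_amplitude * (
        1.0 - profile.springneap_modulation * np.cos(omega_sn * t_h + sn_phase0)
    )
    tide_u = amp * np.cos(omega * t_h + phase0)
    tide_v = amp * np.sin(omega * t_h + phase0)

    # steady residual current in a seeded random direction
    res_dir = rng.uniform(0.0, 2.0 * np.pi)
    res_u = profile.residual_speed * math.cos(res_dir)
    res_v = profile.residual_speed * math.sin(res_dir)

    # steady divergence-free eddy field from a random smooth streamfunction:
    # psi = sum_j a_j sin(kx x + ky y + phi), u = -dpsi/dy, v = dpsi/dx
    x_m = (np.arange(grid.nx) * grid.spacing_m)[None, :]
    y_m = (np.arange(grid.ny) * grid.spacing_m)[:, None]
    eddy_u = np.zeros((grid.ny, grid.nx))
    eddy_v = np.zeros((grid.ny, grid.nx))
    n_modes = 3
    for _ in range(n_modes):
        wavelength = rng.uniform(10.0, 20.0) * grid.spacing_m  # >= 10 cells
        angle = rng.uniform(0.0, 2.0 * np.pi)
        kx = 2.0 * np.pi / wavelength * math.cos(angle)
        ky = 2.0 * np.pi / wavelength * math.sin(angle)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        a = profile.eddy_speed / n_modes / math.hypot(kx, ky)
        c = np.cos(kx * x_m + ky * y_m + phi)
        eddy_u += -a * ky * c
        eddy_v += a * kx * c

    u = (tide_u[:, None, None] + res_u + eddy_u[None, :, :]).astype(np.float32)
    v = (tide_v[:, None, None] + res_v + eddy_v[None, :, :]).astype(np.float32)
    temp = np.full_like(
        u, profile.temperature_mean + profile.temperature_seasonal_offset
    )

    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), u,
                  {"units": "m s-1", "long_name": "eastward surface velocity"}),
            "v": (("time", "lat", "lon"), v,
                  {"units": "m s-1", "long_name": "northward surface velocity"}),
            "temp": (("time", "lat", "lon"), temp,
                     {"units": "degC", "long_name": "sea surface temperature"}),
        },
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"spacing_m": grid.spacing_m, "site": profile.name, "seed": seed},
    )

    # validate the site-centre speed series against the declared envelope
    iy = int(np.argmin(np.abs(lats - profile.center_lat)))
    ix = int(np.argmin(np.abs(lons - profile.center_lon)))
    speed = np.hypot(u[:, iy, ix], v[:, iy, ix])
    if (profile.tidal_amplitude > 0 or profile.residual_speed > 0) and (
            speed.min() < profile.speed_min or speed.max() > profile.speed_max):
        raise ValueError(
            f"generated speeds [{speed.min():.3f}, {speed.max():.3f}] m/s leave "
            f"the declared envelope [{profile.speed_min}, {profile.speed_max}]"
        )
    return ds


def save_flow_field(ds: xr.Dataset, path) -> None:
    """Write a flow field as netCDF (classic format via the scipy engine)."""
    enc = {k: {"dtype": "float32"} for k in ("u", "v", "temp")}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def load_flow_field(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    return ds.load()


# --------------------------------------------------------------------------
# decay-series generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecaySeriesDesign:
    """Design of a tank decay experiment.

    ``truth`` is the underlying noiseless concentration model: a single
    parameter set applied to every temperature, or a mapping from
    temperature to a parameter set (so the decay rate can follow the
    temperature law).
    """

    temperatures: tuple[float, ...] = (13.0, 20.0, 27.0)
    n_bio_replicates: int = 2
    n_tech_replicates: int = 3
    sample_times_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 23.0, 26.0)
    replicate_offset: float = 2.0   # tank A / tank B concentration ratio
    noise_cv: float = 0.3           # CV of multiplicative lognormal noise
    truth: object = None            # params or {temperature: params}

    def __post_init__(self) -> None:
        times = np.asarray(self.sample_times_h, float)
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times_h must start at 0 and be "
                             "strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicate_offset <= 0:
            raise ValueError("replicate_offset must be > 0")
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise ValueError("replicate counts must be >= 1")


def make_delayed_truth(c0: float = 100.0, k_decay: float = 0.1,
                       k_release: float = 0.5,
                       detectable_fraction: float = 0.1) -> SecondOrderParams:
    """Second-order parameters encoding a delayed decay curve.

    Only ``detectable_fraction`` of the eventually-released pool is
    measurable at t = 0 (concentration c0); the remainder becomes
    detectable at rate ``k_release`` (the negative fast component) while
    the whole pool decays at ``k_decay``, producing a several-fold rise
    over the first hours before the exponential decline.
    """
    if not 0 < detectable_fraction <= 1:
        raise ValueError("detectable_fraction must be in (0, 1]")
    c02 = c0 / detectable_fraction
    return SecondOrderParams(C01=c0 - c02, C02=c02,
                             k1=k_release, k2=k_decay)


def default_decay_design(noise_cv: float = 0.3,
                         law: TemperatureDecayLaw | None = None
                         ) -> DecaySeriesDesign:
    """The emulated experiment: 3 temperatures x 2 tanks x 3 technical
    replicates at 8 sampling times, delayed-decay truth whose second-phase
    rate follows the temperature law, 2x tank-A level offset."""
    law = law or TemperatureDecayLaw()
    truth = {T: make_delayed_truth(c0=100.0, k_decay=law(T))
             for T in (13.0, 20.0, 27.0)}
    return DecaySeriesDesign(noise_cv=noise_cv, truth=truth)


def _truth_for(design: DecaySeriesDesign, temperature: float):
    truth = design.truth
    if truth is None:
        raise ValueError("design.truth is not set")
    if isinstance(truth, Mapping):
        truth = truth[temperature]
    return truth


def _eval_truth(params, t: np.ndarray) -> np.ndarray:
    if isinstance(params, FirstOrderParams):
        return np.asarray(eval_first_order(params, t), float)
    if isinstance(params, SecondOrderParams):
        return np.asarray(eval_second_order(params, t), float)
    if callable(params):
        return np.asarray(params(t), float)
    raise TypeError(f"unsupported truth model: {type(params)!r}")


def generate_decay_series(design: DecaySeriesDesign, seed: int) -> pd.DataFrame:
    """Simulate one run of the tank experiment.

    Returns a tidy table with columns ``temperature_C``, ``bio_replicate``
    (tank letter), ``tech_replicate``, ``time_h`` and
    ``concentration_copies_per_uL``.  Tank multipliers are symmetric in
    log space (first/last tank ratio equals ``replicate_offset``, the
    across-tank geometric mean follows the truth curve), and the noise is
    multiplicative lognormal with unit mean and the design's CV.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(design.sample_times_h, float)
    sigma2 = math.log(1.0 + design.noise_cv ** 2)
    sigma = math.sqrt(sigma2)

    n_bio = design.n_bio_replicates
    tank_names = [chr(ord("A") + i) for i in range(n_bio)]
    exponents = (np.linspace(0.5, -0.5, n_bio) if n_bio > 1
                 else np.zeros(1))
    tank_mult = design.replicate_offset ** exponents

    rows = []
    for T in design.temperatures:
        base = _eval_truth(_truth_for(design, T), times)
        if np.any(base < 0):
            raise ValueError(
                f"truth model yields negative concentrations at {T} degC"
            )
        for tank, mult in zip(tank_names, tank_mult):
            for tech in range(1, design.n_tech_replicates + 1):
                noise = np.exp(rng.normal(-0.5 * sigma2, sigma, size=len(times))
                               ) if design.noise_cv > 0 else np.ones(len(times))
                conc = base * mult * noise
                for t, c in zip(times, conc):
                    rows.append((T, tank, tech, t, c))
    return pd.DataFrame(
        rows,
        columns=["temperature_C", "bio_replicate", "tech_replicate",
                 "time_h", "concentration_copies_per_uL"],
    )
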
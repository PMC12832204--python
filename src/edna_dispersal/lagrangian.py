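"""Surface Lagrangian particle tracking with decay-scenario engines.

Particles released at a point are advected by a gridded velocity field
(classical 4th-order Runge-Kutta, fixed time step), perturbed by a
random-walk model of unresolved motion (horizontal diffusivity K, per-axis
Gaussian displacement of standard deviation sqrt(2 K dt)), and subjected
to one of four per-particle fate scenarios:

* ``no_decay``      - particles persist for the whole run;
* ``exponential``   - per-step Bernoulli survival with probability
  exp(-k(T) dt), k(T) from the temperature law;
* ``biphasic``      - the release is split into a fast-decaying (rate
  0.50 /h, 70%) and a slow-decaying (0.013 /h, 30%) group, each keeping
  its constant rate for the whole run;
* ``delayed``       - during the first 6 h, 20% of the living particles
  are duplicated in place each hour (threefold increase by hour 6, no
  decay draws); afterwards all particles decay exponentially.

Positions are recorded hourly; a particle is alive while it has neither
decayed nor left the flow-field domain.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .decay_models import TemperatureDecayLaw

__all__ = [
    "SimulationConfig",
    "DecayScenarioSpec",
    "ReleaseEvent",
    "ParticleState",
    "FlowFieldInterpolator",
    "OutOfDomainError",
    "interpolate_velocity",
    "rk4_step",
    "diffusion_step",
    "build_release_schedule",
    "survival_probability",
    "apply_decay_step",
    "assign_biphasic_groups",
    "apply_delayed_division",
    "run_event",
    "run_events",
    "EARTH_RADIUS_M",
]

EARTH_RADIUS_M = 6_371_000.0
_DEG = 180.0 / math.pi


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings of a tracking run."""

    diffusivity_K: float = 1.0      # m^2/s
    timestep_s: float = 180.0       # RK4 / random-walk step
    tracking_horizon_h: float = 24.0
    n_particles: int = 10_000
    record_cadence_h: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusivity_K < 0:
            raise ValueError("diffusivity_K must be >= 0")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        steps = self.record_cadence_h * 3600.0 / self.timestep_s
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("timestep must divide the record cadence")


@dataclass(frozen=True)
class DecayScenarioSpec:
    """Per-particle fate rules for one decay scenario."""

    kind: str                                   # exponential|biphasic|delayed|no_decay
    law: TemperatureDecayLaw = TemperatureDecayLaw()
    biphasic_fractions: tuple[float, float] = (0.7, 0.3)
    biphasic_rates: tuple[float, float] = (0.50, 0.013)   # 1/h, fast then slow
    division_fraction_per_h: float = 0.20
    division_duration_h: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "biphasic", "delayed", "no_decay"):
            raise ValueError(f"unknown scenario kind: {self.kind!r}")
        if abs(sum(self.biphasic_fractions) - 1.0) > 1e-12:
            raise ValueError("biphasic fractions must sum to 1")
        if any(r < 0 for r in self.biphasic_rates):
            raise ValueError("biphasic rates must be >= 0")
        if not 0.0 <= self.division_fraction_per_h <= 1.0:
            raise ValueError("division fraction must be in [0, 1]")


@dataclass(frozen=True)
class ReleaseEvent:
    """One release of a particle batch under one scenario.

    ``release_key`` identifies the (site, time) release independent of the
    scenario; it is the blocking unit of the downstream variance
    decomposition and the seed of the shared transport noise, so that the
    four scenarios of one release see identical currents and diffusion.
    """

    event_id: str
    site: str
    release_lon: float
    release_lat: float
    release_time: pd.Timestamp
    scenario: DecayScenarioSpec

    @property
    def release_key(self) -> str:
        return f"{self.site}:{self.release_time.isoformat()}"


class OutOfDomainError(ValueError):
    """A queried position/time lies outside the gridded field."""


# --------------------------------------------------------------------------
# field interpolation
# --------------------------------------------------------------------------

class FlowFieldInterpolator:
    """Bilinear-in-space, linear-in-time interpolation of u, v and temp.

    Wraps the flow-field dataset produced by the synthetic generator
    (dims time/lat/lon, variables u, v in m/s and temp in degC on a
    regular grid).  Queries outside the grid return a False entry in the
    ``inside`` mask rather than raising.
    """

    def __init__(self, ds: xr.Dataset):
        self.lon = ds["lon"].to_numpy().astype(float)
        self.lat = ds["lat"].to_numpy().astype(float)
        times = pd.DatetimeIndex(ds["time"].to_numpy())
        self.t0 = times[0]
        self.t_h = ((times - self.t0) / pd.Timedelta(hours=1)).to_numpy(float)
        self.u = ds["u"].to_numpy().astype(float)
        self.v = ds["v"].to_numpy().astype(float)
        self.temp = ds["temp"].to_numpy().astype(float) if "temp" in ds else None
        for axis, name in ((self.lon, "lon"), (self.lat, "lat"),
                           (self.t_h, "time")):
            d = np.diff(axis)
            if len(d) and not np.allclose(d, d[0], rtol=1e-6):
                raise ValueError(f"{name} axis must be regularly spaced")

    def hours_since_start(self, when: pd.Timestamp) -> float:
        return (pd.Timestamp(when) - self.t0) / pd.Timedelta(hours=1)

    def covers(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        return (self.hours_since_start(start) >= -1e-9
                and self.hours_since_start(end) <= self.t_h[-1] + 1e-9)

    @staticmethod
    def _axis_indices(coord: np.ndarray, axis: np.ndarray):
        """Cell index, in-cell weight and inside mask for one regular axis."""
        step = axis[1] - axis[0]
        pos = (coord - axis[0]) / step
        i = np.clip(pos.astype(np.int64), 0, len(axis) - 2)
        w = pos - i
        inside = (pos >= 0.0) & (pos <= len(axis) - 1)
        return i, w, inside

    def _locate(self, lon, lat, t_hours: float):
        lon = np.atleast_1d(np.asarray(lon, float))
        lat = np.atleast_1d(np.asarray(lat, float))
        ix, wx, in_x = self._axis_indices(lon, self.lon)
        iy, wy, in_y = self._axis_indices(lat, self.lat)
        nt = len(self.t_h)
        if nt > 1:
            pos_t = (t_hours - self.t_h[0]) / (self.t_h[1] - self.t_h[0])
            it = min(max(int(pos_t), 0), nt - 2)
            wt = pos_t - it
        else:
            pos_t, it, wt = 0.0, 0, 0.0
        inside = in_x & in_y & (-1e-9 <= pos_t <= nt - 1 + 1e-9)
        # flat indices of the 4 surrounding nodes and their bilinear weights
        ny, nx = len(self.lat), len(self.lon)
        base = iy * nx + ix
        flat = (base, base + 1, base + nx, base + nx + 1)
        w = ((1 - wx) * (1 - wy), wx * (1 - wy), (1 - wx) * wy, wx * wy)
        return flat, w, it, wt, inside

    def _gather(self, grid3d: np.ndarray, flat, w, it: int, wt: float):
        out = None
        for k, w_t in ((it, 1.0 - wt), (it + 1, wt)):
            if w_t == 0.0:
                continue
            plane = grid3d[k].ravel()
            f = (plane[flat[0]] * w[0] + plane[flat[1]] * w[1]
                 + plane[flat[2]] * w[2] + plane[flat[3]] * w[3])
            out = w_t * f if out is None else out + w_t * f
        return out

    def velocity(self, lon, lat, t_hours: float):
        """(u, v, inside) at positions (deg) and time (h since field start)."""
        flat, w, it, wt, inside = self._locate(lon, lat, t_hours)
        u = self._gather(self.u, flat, w, it, wt)
        v = self._gather(self.v, flat, w, it, wt)
        return u, v, inside

    def temperature(self, lon, lat, t_hours: float):
        if self.temp is None:
            raise ValueError("field has no temperature variable")
        flat, w, it, wt, _ = self._locate(lon, lat, t_hours)
        return self._gather(self.temp, flat, w, it, wt)


def interpolate_velocity(field: xr.Dataset | FlowFieldInterpolator,
                         lon, lat, time) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated (u, v) in m/s; raises OutOfDomainError outside the grid."""
    interp = (field if isinstance(field, FlowFieldInterpolator)
              else FlowFieldInterpolator(field))
    t_h = (interp.hours_since_start(time)
           if isinstance(time, (pd.Timestamp, str, np.datetime64))
           else float(time))
    u, v, inside = interp.velocity(lon, lat, t_h)
    if not np.all(inside):
        raise OutOfDomainError("query outside the flow-field grid")
    scalar = np.isscalar(lon) or np.ndim(lon) == 0
    return (float(u[0]), float(v[0])) if scalar else (u, v)


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def _mps_to_deg(u, v, lat):
    """Convert metric velocities to degrees/second at the given latitude."""
    dlat = v / EARTH_RADIUS_M * _DEG
    dlon = u / (EARTH_RADIUS_M * np.cos(np.radians(lat))) * _DEG
    return dlon, dlat


VelocityFn = Callable[[np.ndarray, np.ndarray, float],
                      tuple[np.ndarray, np.ndarray, np.ndarray]]


def rk4_step(lon, lat, velocity: VelocityFn, t_h: float, dt_s: float):
    """One classical RK4 step of dx/dt = u(x, t), dy/dt = v(x, t).

    ``velocity`` maps (lon, lat, hours) to (u, v, inside); the metric
    velocities are converted to angular rates at each stage's latitude.
    Returns (lon, lat, ok) where ok is False for particles whose RK4
    stages left the domain (their position is unchanged).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    lon = np.atleast_1d(np.asarray(lon, float))
    lat = np.atleast_1d(np.asarray(lat, float))
    dt_h = dt_s / 3600.0
    ok = np.ones(lon.shape, bool)

    def f(lo, la, th):
        u, v, inside = velocity(lo, la, th)
        dlon, dlat = _mps_to_deg(u, v, la)
        return dlon, dlat, inside

    k1x, k1y, in1 = f(lon, lat, t_h)
    k2x, k2y, in2 = f(lon + 0.5 * dt_s * k1x, lat + 0.5 * dt_s * k1y,
                      t_h + 0.5 * dt_h)
    k3x, k3y, in3 = f(lon + 0.5 * dt_s * k2x, lat + 0.5 * dt_s * k2y,
                      t_h + 0.5 * dt_h)
    k4x, k4y, in4 = f(lon + dt_s * k3x, lat + dt_s * k3y, t_h + dt_h)
    ok &= in1 & in2 & in3 & in4

    new_lon = lon + dt_s / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_lat = lat + dt_s / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    new_lon = np.where(ok, new_lon, lon)
    new_lat = np.where(ok, new_lat, lat)
    return new_lon, new_lat, ok


def diffusion_step(lon, lat, K: float, dt_s: float,
                   rng: np.random.Generator):
    """Random-walk displacement: per-axis N(0, 2 K dt) metres."""
    if K < 0:
        raise ValueError("K must be >= 0")
    lon = np.atleast_1d(np.asarray(lon, float))
    lat = np.atleast_1d(np.asarray(lat, float))
    if K == 0:
        return lon.copy(), lat.copy()
    sigma_m = math.sqrt(2.0 * K * dt_s)
    disp = rng.normal(0.0, sigma_m, size=(lon.size, 2))
    dlon, dlat = _mps_to_deg(disp[:, 0], disp[:, 1], lat)
    return lon + dlon, lat + dlat


# --------------------------------------------------------------------------
# release schedule
# --------------------------------------------------------------------------

def build_release_schedule(months: Sequence[tuple[int, int]], cadence_h: float,
                           sites: Sequence, scenarios: Sequence[DecayScenarioSpec],
                           ) -> list[ReleaseEvent]:
    """One event per (release time, site, scenario).

    Releases run at fixed cadence from the first hour of each listed
    (year, month) through its last; e.g. a 2-h cadence over January and
    September gives 372 + 360 = 732 release times per site and scenario.
    ``sites`` entries need ``name``, ``center_lon``, ``center_lat``
    attributes (a SiteProfile qualifies).
    """
    if 24.0 % cadence_h != 0:
        raise ValueError("cadence_h must divide 24")
    times: list[pd.Timestamp] = []
    for year, month in months:
        if not 1 <= int(month) <= 12:
            raise ValueError(f"unknown month: {month}")
        start = pd.Timestamp(year=int(year), month=int(month), day=1)
        end = start + pd.offsets.MonthBegin(1)
        t = start
        while t < end:
            times.append(t)
            t += pd.Timedelta(hours=cadence_h)

    events = []
    for site in sites:
        for scen in scenarios:
            for t in times:
                eid = f"{site.name}:{scen.kind}:{t.strftime('%Y%m%dT%H%M')}"
                events.append(ReleaseEvent(
                    event_id=eid, site=site.name,
                    release_lon=site.center_lon, release_lat=site.center_lat,
                    release_time=t, scenario=scen,
                ))
    return events


# --------------------------------------------------------------------------
# fate engines
# --------------------------------------------------------------------------

def survival_probability(k_per_h: float, dt_h: float) -> float:
    """Per-step survival probability exp(-k dt), the Bernoulli parameter
    consistent with continuous first-order decay (semigroup property:
    two steps of dt compose to one step of 2 dt)."""
    if k_per_h < 0:
        raise ValueError("k must be >= 0")
    if dt_h <= 0:
        raise ValueError("dt must be > 0")
    return math.exp(-k_per_h * dt_h)


@dataclass
class ParticleState:
    """Mutable per-particle arrays of one release event."""

    lon: np.ndarray
    lat: np.ndarray
    alive: np.ndarray                 # bool
    group: np.ndarray                 # int, biphasic group (0 fast, 1 slow, -1 none)
    parent: np.ndarray                # int id of parent, -1 for originals
    ids: np.ndarray                   # int, stable particle ids

    @classmethod
    def point_release(cls, lon: float, lat: float, n: int) -> "ParticleState":
        return cls(lon=np.full(n, lon, float), lat=np.full(n, lat, float),
                   alive=np.ones(n, bool), group=np.full(n, -1, int),
                   parent=np.full(n, -1, int), ids=np.arange(n, dtype=int))

    @property
    def n(self) -> int:
        return self.lon.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())


def assign_biphasic_groups(particles: ParticleState,
                           fractions: tuple[float, float] = (0.7, 0.3),
                           rng: np.random.Generator | None = None,
                           ) -> ParticleState:
    """Exact-count random split into fast (group 0) and slow (group 1).

    round(f_fast * N) particles get the fast rate; membership is a seeded
    random permutation, counts are deterministic.
    """
    if abs(sum(fractions) - 1.0) > 1e-12:
        raise ValueError("fractions must sum to 1")
    rng = rng or np.random.default_rng()
    n = particles.n
    n_fast = int(round(fractions[0] * n))
    groups = np.ones(n, int)
    groups[:n_fast] = 0
    particles.group = rng.permutation(groups)
    return particles


def apply_decay_step(particles: ParticleState, scenario: DecayScenarioSpec,
                     temperature, dt_h: float,
                     hours_since_release: float,
                     rng: np.random.Generator) -> ParticleState:
    """One survival draw per living particle for one timestep.

    ``temperature`` may be a scalar or a per-particle array (degC); dead
    particles are never resurrected.
    """
    if scenario.kind == "no_decay":
        return particles
    if scenario.kind == "delayed" and (
            hours_since_release < scenario.division_duration_h):
        return particles  # growth phase: division only, no decay draws

    alive_idx = np.flatnonzero(particles.alive)
    if alive_idx.size == 0:
        return particles
    if scenario.kind == "biphasic":
        g = particles.group[alive_idx]
        if np.any(g < 0):
            raise RuntimeError("biphasic particle without group assignment")
        rates = np.asarray(scenario.biphasic_rates)[g]
    else:  # exponential, or delayed after the growth phase
        T = np.asarray(temperature, float)
        T_alive = T[alive_idx] if T.ndim else T
        rates = scenario.law.a * np.exp(scenario.law.b * T_alive)
    p_survive = np.exp(-rates * dt_h)
    died = rng.random(alive_idx.size) >= p_survive
    particles.alive[alive_idx[died]] = False
    return particles


def apply_delayed_division(particles: ParticleState,
                           hours_since_release: float,
                           fraction: float = 0.20, duration_h: float = 6.0,
                           rng: np.random.Generator | None = None,
                           ) -> ParticleState:
    """Hourly in-place duplication during the delayed growth phase.

    At each whole hour 1..duration, round(fraction * N_alive) living
    particles chosen uniformly without replacement are duplicated at
    their exact positions (children get fresh ids, parent recorded, and
    follow their own dynamics afterwards).  Six divisions at 20% per hour
    triple the particle count.  No-op after the growth phase.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if hours_since_release < 1.0 or hours_since_release > duration_h:
        return particles
    rng = rng or np.random.default_rng()
    alive_idx = np.flatnonzero(particles.alive)
    n_div = int(round(fraction * alive_idx.size))
    if n_div == 0:
        return particles
    chosen = rng.choice(alive_idx, size=n_div, replace=False)
    next_id = int(particles.ids.max()) + 1 if particles.n else 0
    particles.lon = np.concatenate([particles.lon, particles.lon[chosen]])
    particles.lat = np.concatenate([particles.lat, particles.lat[chosen]])
    particles.alive = np.concatenate([particles.alive, np.ones(n_div, bool)])
    particles.group = np.concatenate([particles.group, particles.group[chosen]])
    particles.parent = np.concatenate([particles.parent, particles.ids[chosen]])
    particles.ids = np.concatenate(
        [particles.ids, np.arange(next_id, next_id + n_div, dtype=int)]
    )
    return particles


# --------------------------------------------------------------------------
# event driver
# --------------------------------------------------------------------------

def _stream(master_seed: int, label: str) -> np.random.Generator:
    """Deterministic child RNG from (master seed, stable label hash)."""
    h = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master_seed, h]))


def run_event(event: ReleaseEvent, field: xr.Dataset | FlowFieldInterpolator,
              cfg: SimulationConfig) -> pd.DataFrame:
    """Track one release event and record hourly particle states.

    Per timestep: RK4 advection, then random-walk diffusion, then a decay
    draw; on whole-hour boundaries within the growth phase the delayed
    scenario duplicates particles.  Particles leaving the grid are marked
    dead and keep their last in-domain position.  Two independent seeded
    streams drive the run: transport noise keyed by the release (shared
    across scenarios of the same release, so scenario contrasts are
    paired) and fate draws keyed by the full event id.
    """
    interp = (field if isinstance(field, FlowFieldInterpolator)
              else FlowFieldInterpolator(field))
    t_end = event.release_time + pd.Timedelta(hours=cfg.tracking_horizon_h)
    if not interp.covers(event.release_time, t_end):
        raise ValueError("flow field does not cover the tracking horizon")

    rng_transport = _stream(cfg.seed, "transport:" + event.release_key)
    rng_fate = _stream(cfg.seed, "fate:" + event.event_id)
    scen = event.scenario

    particles = ParticleState.point_release(
        event.release_lon, event.release_lat, cfg.n_particles
    )
    if scen.kind == "biphasic":
        assign_biphasic_groups(particles, scen.biphasic_fractions, rng_fate)

    dt_s = cfg.timestep_s
    dt_h = dt_s / 3600.0
    n_steps = int(round(cfg.tracking_horizon_h * 3600.0 / dt_s))
    record_every = int(round(cfg.record_cadence_h * 3600.0 / dt_s))
    t0_h = interp.hours_since_start(event.release_time)

    records = []

    def record(hour: float) -> None:
        records.append(pd.DataFrame({
            "event_id": event.event_id,
            "release_key": event.release_key,
            "site": event.site,
            "scenario": scen.kind,
            "particle_id": particles.ids,
            "parent_id": particles.parent,
            "decay_group": particles.group,
            "hour": hour,
            "lon": particles.lon.copy(),
            "lat": particles.lat.copy(),
            "alive": particles.alive.copy(),
        }))

    record(0.0)
    for step in range(1, n_steps + 1):
        t_h = t0_h + (step - 1) * dt_h
        elapsed_h = step * dt_h

        # advection (alive only) -- exiting particles die at their last position
        alive = particles.alive
        if alive.any():
            new_lon, new_lat, ok = rk4_step(
                particles.lon[alive], particles.lat[alive],
                interp.velocity, t_h, dt_s,
            )
            idx = np.flatnonzero(alive)
            particles.lon[idx] = new_lon
            particles.lat[idx] = new_lat
            particles.alive[idx[~ok]] = False

        # diffusion: draws are generated for the full array (dead included)
        # to keep the transport stream aligned across scenarios
        d_lon, d_lat = diffusion_step(
            particles.lon, particles.lat, cfg.diffusivity_K, dt_s,
            rng_transport,
        )
        still = particles.alive
        particles.lon[still] = d_lon[still]
        particles.lat[still] = d_lat[still]

        # exit check after diffusion
        if still.any():
            _, _, inside = interp.velocity(
                particles.lon[still], particles.lat[still], t_h + dt_h
            )
            idx = np.flatnonzero(still)
            particles.alive[idx[~inside]] = False

        # decay draw for this step (temperature sampled at living particles)
        temp = None
        if scen.kind in ("exponential", "delayed") and particles.alive.any():
            temp = np.zeros(particles.n)
            idx = np.flatnonzero(particles.alive)
            temp[idx] = interp.temperature(
                particles.lon[idx], particles.lat[idx], t_h + dt_h
            )
        apply_decay_step(particles, scen, temp, dt_h,
                         hours_since_release=elapsed_h - dt_h, rng=rng_fate)

        # division on whole-hour boundaries during the growth phase
        if scen.kind == "delayed" and abs(elapsed_h - round(elapsed_h)) < 1e-9:
            apply_delayed_division(
                particles, round(elapsed_h), scen.division_fraction_per_h,
                scen.division_duration_h, rng_fate,
            )

        if step % record_every == 0:
            record(elapsed_h * 1.0)

    return pd.concat(records, ignore_index=True)


def run_events(events: Iterable[ReleaseEvent],
               fields: xr.Dataset | FlowFieldInterpolator | dict,
               cfg: SimulationConfig) -> pd.DataFrame:
    """Run several events; ``fields`` may be one field or a per-site dict."""
    tables = []
    for ev in events:
        field = fields[ev.site] if isinstance(fields, dict) else fields
        tables.append(run_event(ev, field, cfg))
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)
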
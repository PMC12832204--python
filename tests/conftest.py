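"""Shared fixtures: idealized flow fields and synthetic-site fields."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import edna_dispersal as ed

T0 = pd.Timestamp("2018-01-01")


def make_uniform_field(u=0.0, v=0.0, *, temp=12.0, half_width_km=40.0,
                       spacing_m=4000.0, hours=30, lon0=-4.51, lat0=47.68):
    """Constant-velocity, constant-temperature field centred on (lon0, lat0)."""
    n = 2 * int(np.ceil(half_width_km * 1000 / spacing_m)) + 1
    dlat = np.degrees(spacing_m / ed.lagrangian.EARTH_RADIUS_M)
    dlon = np.degrees(spacing_m / (ed.lagrangian.EARTH_RADIUS_M
                                   * np.cos(np.radians(lat0))))
    lats = lat0 + dlat * (np.arange(n) - n // 2)
    lons = lon0 + dlon * (np.arange(n) - n // 2)
    times = pd.date_range(T0, periods=hours + 1, freq="1h")
    shape = (len(times), n, n)
    return xr.Dataset(
        {
            "u": (("time", "lat", "lon"), np.full(shape, float(u))),
            "v": (("time", "lat", "lon"), np.full(shape, float(v))),
            "temp": (("time", "lat", "lon"), np.full(shape, float(temp))),
        },
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"spacing_m": spacing_m, "site": "idealized"},
    )


def make_release(field, scenario_kind, *, site="idealized", when=T0,
                 index=0) -> ed.ReleaseEvent:
    """Release at the grid centre of an idealized field."""
    lon = float(field["lon"][len(field["lon"]) // 2])
    lat = float(field["lat"][len(field["lat"]) // 2])
    when = pd.Timestamp(when)
    return ed.ReleaseEvent(
        event_id=f"{site}:{scenario_kind}:{when.strftime('%Y%m%dT%H%M')}:{index}",
        site=site, release_lon=lon, release_lat=lat, release_time=when,
        scenario=ed.DecayScenarioSpec(kind=scenario_kind),
    )


@pytest.fixture(scope="session")
def still_water():
    """Zero-flow field (u = v = 0) for pure-diffusion and decay checks."""
    return make_uniform_field(0.0, 0.0)


@pytest.fixture(scope="session")
def quiet_field():
    """Short synthetic quiet-site field at 500 m spacing."""
    grid = ed.FieldGridSpec.centered_on(
        ed.QUIET_SITE.center_lon, ed.QUIET_SITE.center_lat,
        half_width_km=16.0, spacing_m=500.0,
        time_start=T0, time_end=T0 + pd.Timedelta(hours=48),
    )
    return ed.generate_flow_field(ed.QUIET_SITE, grid, seed=11,
                                  min_footprint_km=15.0)
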
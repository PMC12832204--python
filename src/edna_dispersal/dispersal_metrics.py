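"""Event-based dispersal metrics for particle plumes.

For every (scenario, release event, hour) the hourly particle snapshot is
summarized by six metrics: the number of particles alive, their centre of
mass (arithmetic mean of longitudes and latitudes), the great-circle
distance of that centre from the release point (km), the dispersion (mean
squared great-circle distance of the particles from the centre of mass,
km^2), the convex-hull area enclosing the particles (km^2, computed on a
local tangent-plane projection), and the particle density inside the hull
(particles/km^2).

Hours with no living particle, or a degenerate (zero-area) hull for the
density, carry NaN sentinels rather than being dropped.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "EARTH_RADIUS_KM",
    "center_of_mass",
    "haversine_km",
    "mean_distance",
    "dispersion",
    "convex_hull_area",
    "density",
    "relative_density",
    "compute_metrics_table",
    "METRIC_COLUMNS",
]

EARTH_RADIUS_KM = 6371.0

#: names of the metric value columns in a metrics table
METRIC_COLUMNS = ("n_alive", "com_lon", "com_lat", "mean_distance_km",
                  "dispersion_km2", "hull_area_km2", "density_per_km2")


def center_of_mass(lons, lats) -> tuple[float, float]:
    """Arithmetic mean position (per-axis mean of lon and lat in degrees)."""
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    if lons.size == 0:
        return (math.nan, math.nan)
    return float(lons.mean()), float(lats.mean())


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (Earth radius 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = (np.sin(0.5 * dlat) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(0.5 * dlon) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def mean_distance(release_point: tuple[float, float],
                  com: tuple[float, float]) -> float:
    """Distance (km) between the release location and the centre of mass."""
    if any(math.isnan(c) for c in com):
        return math.nan
    return float(haversine_km(release_point[0], release_point[1],
                              com[0], com[1]))


def dispersion(lons, lats, com: tuple[float, float] | None = None) -> float:
    """Mean squared great-circle distance (km^2) from the centre of mass."""
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    if lons.size == 0:
        return math.nan
    if com is None:
        com = center_of_mass(lons, lats)
    r = haversine_km(lons, lats, com[0], com[1])
    return float(np.mean(np.square(r)))


def _tangent_plane_km(lons, lats, origin: tuple[float, float]) -> np.ndarray:
    """Local equirectangular projection about ``origin`` in km."""
    kx = EARTH_RADIUS_KM * math.cos(math.radians(origin[1])) * math.pi / 180.0
    ky = EARTH_RADIUS_KM * math.pi / 180.0
    x = (np.asarray(lons, float) - origin[0]) * kx
    y = (np.asarray(lats, float) - origin[1]) * ky
    return np.column_stack([x, y])


def convex_hull_area(lons, lats) -> float:
    """Area (km^2) of the convex envelope of the particle positions.

    Positions are projected onto a local tangent plane about their centre
    of mass (adequate for plumes below ~50 km); fewer than three distinct
    non-collinear points give area 0.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    if lons.size == 0:
        return math.nan
    pts = _tangent_plane_km(lons, lats, center_of_mass(lons, lats))
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        return 0.0
    # rank check: collinear clouds (up to rounding) have zero area
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # degenerate input


def density(n_alive: int, hull_area_km2: float) -> float:
    """Particles per km^2 inside the hull; NaN when the hull has no area."""
    if n_alive < 0:
        raise ValueError("n_alive must be >= 0")
    if not hull_area_km2 > 0:
        return math.nan
    return n_alive / hull_area_km2


def compute_metrics_table(trajectories: pd.DataFrame,
                          release_points: Mapping[str, tuple[float, float]]
                          ) -> pd.DataFrame:
    """All six metrics per (scenario, event, hour) from a trajectory table.

    ``trajectories`` must carry event_id, scenario, hour, lon, lat, alive
    (site and release_key are propagated when present);
    ``release_points`` maps event_id to the (lon, lat) release location.
    Every event must report a contiguous hourly record; zero-alive hours
    yield sentinel rows.  Only living particles enter the metrics.
    """
    required = {"event_id", "scenario", "hour", "lon", "lat", "alive"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")

    carry = [c for c in ("site", "release_key") if c in trajectories.columns]
    rows = []
    for (scen, eid), ev in trajectories.groupby(["scenario", "event_id"],
                                                sort=False):
        hours = np.sort(ev["hour"].unique())
        expect = np.arange(hours.min(), hours.max() + 1)
        if len(hours) != len(expect) or not np.allclose(hours, expect):
            raise ValueError(f"event {eid}: non-contiguous hourly record")
        if eid not in release_points:
            raise ValueError(f"no release point for event {eid}")
        x0y0 = release_points[eid]
        extra = {c: ev[c].iloc[0] for c in carry}
        for hour, snap in ev.groupby("hour"):
            live = snap[snap["alive"]]
            lons = live["lon"].to_numpy()
            lats = live["lat"].to_numpy()
            n = len(live)
            com = center_of_mass(lons, lats)
            area = convex_hull_area(lons, lats) if n else math.nan
            rows.append({
                "scenario": scen, "event_id": eid, "hour": float(hour),
                **extra,
                "n_alive": n,
                "com_lon": com[0], "com_lat": com[1],
                "mean_distance_km": mean_distance(x0y0, com),
                "dispersion_km2": dispersion(lons, lats, com) if n else math.nan,
                "hull_area_km2": area,
                "density_per_km2": density(n, area) if n else math.nan,
            })
    return pd.DataFrame(rows)


def relative_density(metrics: pd.DataFrame, scenario: str,
                     reference_scenario: str) -> pd.DataFrame:
    """Per-hour density of one scenario relative to a reference scenario.

    Each event's density under ``scenario`` is divided by the across-event
    median density of ``reference_scenario`` at the same hour; the result
    summarizes those ratios as the median and the 20%-80% percentile band.
    Hours where the reference median is zero or undefined are NaN.
    """
    for s in (scenario, reference_scenario):
        if s not in set(metrics["scenario"]):
            raise ValueError(f"scenario {s!r} not present in metrics table")
    ref = (metrics[metrics["scenario"] == reference_scenario]
           .groupby("hour")["density_per_km2"].median())
    scen = metrics[metrics["scenario"] == scenario]

    out = []
    for hour, grp in scen.groupby("hour"):
        ref_med = ref.get(hour, math.nan)
        if not ref_med > 0:
            out.append({"hour": hour, "median": math.nan,
                        "p20": math.nan, "p80": math.nan})
            continue
        ratio = grp["density_per_km2"].to_numpy() / ref_med
        ratio = ratio[np.isfinite(ratio)]
        if ratio.size == 0:
            out.append({"hour": hour, "median": math.nan,
                        "p20": math.nan, "p80": math.nan})
            continue
        out.append({"hour": hour,
                    "median": float(np.median(ratio)),
                    "p20": float(np.percentile(ratio, 20)),
                    "p80": float(np.percentile(ratio, 80))})
    return pd.DataFrame(out).sort_values("hour", ignore_index=True)
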
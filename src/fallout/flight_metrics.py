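"""Per-flight summary variables from a GPS track, sunset time and rasters.

For each flight the nine summary variables of the analysis are computed:
timing after apparent sunset, duration, cumulative path length L, straight
(start-to-end) length S, tortuosity T = 1 − S/L (0 straight, 1 fully
convoluted), mean ground speed until the bird first rests on the sea surface,
mean and maximum radiance along the track, and the colony/grounding radiance
ratio (single-pixel values; below 1 when the grounding site is brighter than
the colony).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import exposure_geo, geo
from .io_formats import RasterGrid, RescueRecord, Track
from .solar import SunsetSpec, apparent_sunset  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

geodesic_distance = geo.geodesic_distance  # module-level re-export

REST_SPEED_KMH = 5.0  # segment speed below this, over sea, counts as a rest


@dataclass
class FlightSummary:
    """The per-flight summary variables (one row of the flight table)."""

    bird_id: str
    group: str
    timing_min: float
    duration_min: float
    length_m: float
    straight_length_m: float
    tortuosity: float
    speed_kmh: float
    max_radiance: float
    mean_radiance: float
    colony_grounding_ratio: float

    def __post_init__(self):
        if not 0.0 <= self.tortuosity <= 1.0 + 1e-12:
            raise ValueError(f"tortuosity {self.tortuosity} outside [0, 1]")
        if self.straight_length_m > self.length_m * (1 + 1e-12):
            raise ValueError("straight length exceeds path length")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.speed_kmh < 0:
            raise ValueError("speed must be non-negative")


def path_length_m(track: Track) -> float:
    """Cumulative geodesic length of the track polyline, metres."""
    return float(
        sum(
            geo.geodesic_distance(f1.lon, f1.lat, f2.lon, f2.lat)
            for f1, f2 in zip(track.fixes, track.fixes[1:])
        )
    )


def _first_rest_index(track: Track, dem: RasterGrid | None, rest_speed_kmh: float) -> int:
    """Index of the first fix where the bird rests on the sea surface.

    A rest is the first fix over sea whose incoming segment speed falls below
    ``rest_speed_kmh``.  Returns the last index when no rest is detected (or
    when no DEM is supplied to identify sea).
    """
    if dem is None:
        return len(track.fixes) - 1
    sea = exposure_geo.sea_mask(dem)
    for i in range(1, len(track.fixes)):
        f1, f2 = track.fixes[i - 1], track.fixes[i]
        dt_h = (f2.time - f1.time).total_seconds() / 3600.0
        if dt_h <= 0:
            continue
        v_kmh = geo.geodesic_distance(f1.lon, f1.lat, f2.lon, f2.lat) / 1000.0 / dt_h
        try:
            r, c = exposure_geo.cell_index(dem, f2.lon, f2.lat)
            over_sea = bool(sea[r, c])
        except ValueError:
            over_sea = False
        if over_sea and v_kmh < rest_speed_kmh:
            return i
    return len(track.fixes) - 1


def summarize_flight(
    track: Track,
    sunset: SunsetSpec,
    radiance: RasterGrid,
    colony: tuple[float, float],
    dem: RasterGrid | None = None,
    rest_speed_kmh: float = REST_SPEED_KMH,
) -> FlightSummary:
    """Compute the flight summary for one track.

    ``colony`` is the (lon, lat) of the nest colony; the departure fix is the
    first fix of the track and the grounding/landing is the last.  Speed is
    the mean ground speed over the segment ending at the first on-water rest;
    the radiance mean/max come from the distinct raster cells the track
    traverses.  Negative timing (pre-sunset departure) is kept and logged.
    """
    first, last = track.fixes[0], track.fixes[-1]
    length = path_length_m(track)
    if length == 0:
        raise ValueError(f"track {track.bird_id!r} has zero path length; tortuosity undefined")
    straight = float(geo.geodesic_distance(first.lon, first.lat, last.lon, last.lat))
    tortuosity = 1.0 - straight / length
    timing_min = (first.time - sunset.sunset_utc).total_seconds() / 60.0
    if timing_min < 0:
        log.warning("track %r departed %.1f min before sunset", track.bird_id, -timing_min)
    duration_min = (last.time - first.time).total_seconds() / 60.0

    rest_i = _first_rest_index(track, dem, rest_speed_kmh)
    rest_track = track.fixes[: rest_i + 1]
    seg_len_m = float(
        sum(
            geo.geodesic_distance(f1.lon, f1.lat, f2.lon, f2.lat)
            for f1, f2 in zip(rest_track, rest_track[1:])
        )
    )
    seg_h = (rest_track[-1].time - rest_track[0].time).total_seconds() / 3600.0
    speed_kmh = (seg_len_m / 1000.0) / seg_h if seg_h > 0 else 0.0

    exposure = exposure_geo.sample_track(radiance, track)
    rad_colony = exposure_geo.sample_point(radiance, colony[0], colony[1])
    try:
        rad_ground = exposure_geo.sample_point(radiance, last.lon, last.lat)
    except ValueError:
        rad_ground = float("nan")  # flight ended beyond the mapped extent
    if rad_ground and not np.isnan(rad_ground) and not np.isnan(rad_colony):
        ratio = rad_colony / rad_ground
    else:
        log.warning("track %r: colony/grounding ratio undefined (zero or nodata radiance)", track.bird_id)
        ratio = float("nan")

    return FlightSummary(
        bird_id=track.bird_id,
        group=track.group,
        timing_min=timing_min,
        duration_min=duration_min,
        length_m=length,
        straight_length_m=straight,
        tortuosity=max(0.0, min(1.0, tortuosity)),
        speed_kmh=speed_kmh,
        max_radiance=exposure.max_radiance,
        mean_radiance=exposure.mean_radiance,
        colony_grounding_ratio=ratio,
    )


def straight_distance_colony_to_rescue(colony: tuple[float, float], rescue: RescueRecord) -> float:
    """Straight geodesic distance (m) from the colony centre to a rescue point.

    This is the only flight-distance measure available for band-only birds
    that carried no GPS.
    """
    return float(geo.geodesic_distance(colony[0], colony[1], rescue.lon, rescue.lat))
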
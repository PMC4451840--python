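"""Raster covariate extraction for points, tracks and colony buffers.

Light-pollution exposure follows the satellite-imagery conventions of the
analysis: a colony's exposure is the single radiance pixel intersecting its
centre; a flight's exposure is the mean/max over the distinct cells its
polyline traverses; colony-scale exposure is the mean/max over cells whose
centres fall within a 3-km buffer.  Burrows are grouped into colonies by
single-linkage clustering with a 1-km threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import geo
from .io_formats import BurrowRecord, RasterGrid, Track

log = logging.getLogger(__name__)

BUFFER_RADIUS_M = 3000.0
COLONY_LINK_THRESHOLD_M = 1000.0


@dataclass
class ColonyRecord:
    """A burrow cluster with counts and raster-derived covariates.

    Covariates are None until :func:`attach_covariates` fills them from the
    DEM and radiance rasters.
    """

    colony_id: str
    centre_lon: float
    centre_lat: float
    n_banded: int
    n_recovered: int
    elevation_m: float | None = None
    distance_to_sea_m: float | None = None
    radiance_at_colony: float | None = None
    radiance_mean_3km: float | None = None
    radiance_max_3km: float | None = None
    member_burrows: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.n_recovered <= self.n_banded:
            raise ValueError(f"colony {self.colony_id!r}: invalid counts")


@dataclass(frozen=True)
class TrackExposure:
    """Mean and maximum radiance over the cells a track traverses."""

    mean_radiance: float
    max_radiance: float
    n_cells: int

    def __post_init__(self):
        if self.max_radiance < self.mean_radiance:
            raise ValueError("max radiance below mean radiance")


# ---------------------------------------------------------------------------
# point sampling


def cell_index(grid: RasterGrid, lon: float, lat: float) -> tuple[int, int]:
    """(row, col) of the cell containing a point, half-open convention.

    Cells are [x, x+cell) in lon and (y−cell, y] in lat, so a point on a
    shared corner belongs to the cell to its lower-right (south-east).
    """
    # floor realises the half-open convention: a point on a vertical edge
    # x0+i*c falls in column i, one on a horizontal edge y0-k*c in row k.
    # Fractional indices within 1e-9 of an integer are snapped first so that
    # points constructed to lie on an edge are not thrown off by float noise.
    def _idx(q: float) -> int:
        qr = round(q)
        if abs(q - qr) < 1e-9:
            return int(qr)
        return math.floor(q)

    col = _idx((lon - grid.x_origin) / grid.cell_size)
    row = _idx((grid.y_origin - lat) / grid.cell_size)
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise ValueError(f"point ({lon}, {lat}) outside raster extent")
    return row, col


def sample_point(grid: RasterGrid, lon: float, lat: float) -> float:
    """Value of the cell containing the point; NaN if that cell is nodata."""
    row, col = cell_index(grid, lon, lat)
    v = grid.values[row, col]
    return float("nan") if v == grid.nodata else float(v)


# ---------------------------------------------------------------------------
# track sampling


def _segment_cells(grid: RasterGrid, lon1, lat1, lon2, lat2) -> set[tuple[int, int]]:
    """Distinct cells crossed by one segment, by exact gridline subdivision."""
    c = grid.cell_size
    # parameter values where the segment crosses vertical/horizontal gridlines
    ts = {0.0, 1.0}
    if lon2 != lon1:
        first = math.floor((min(lon1, lon2) - grid.x_origin) / c) + 1
        last = math.floor((max(lon1, lon2) - grid.x_origin) / c)
        for i in range(first, last + 1):
            x = grid.x_origin + i * c
            ts.add((x - lon1) / (lon2 - lon1))
    if lat2 != lat1:
        first = math.floor((grid.y_origin - max(lat1, lat2)) / c) + 1
        last = math.floor((grid.y_origin - min(lat1, lat2)) / c)
        for j in range(first, last + 1):
            y = grid.y_origin - j * c
            ts.add((y - lat1) / (lat2 - lat1))
    ts = sorted(t for t in ts if 0.0 <= t <= 1.0)
    cells: set[tuple[int, int]] = set()
    for t1, t2 in zip(ts, ts[1:]):
        tm = 0.5 * (t1 + t2)
        lon = lon1 + tm * (lon2 - lon1)
        lat = lat1 + tm * (lat2 - lat1)
        try:
            cells.add(cell_index(grid, lon, lat))
        except ValueError:
            continue  # sub-segment outside the raster
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        try:
            cells.add(cell_index(grid, lon, lat))
        except ValueError:
            continue
    return cells


def traversed_cells(grid: RasterGrid, track: Track) -> set[tuple[int, int]]:
    """Distinct cells crossed by the track polyline (endpoints included)."""
    cells: set[tuple[int, int]] = set()
    for f1, f2 in zip(track.fixes, track.fixes[1:]):
        cells |= _segment_cells(grid, f1.lon, f1.lat, f2.lon, f2.lat)
    return cells


def sample_track(grid: RasterGrid, track: Track) -> TrackExposure:
    """Mean/max radiance over the distinct cells the polyline traverses.

    Each traversed cell counts once regardless of dwell length; nodata cells
    are excluded.  Raises if no valid cell is touched.
    """
    cells = traversed_cells(grid, track)
    vals = [grid.values[r, c] for r, c in cells]
    vals = [v for v in vals if v != grid.nodata]
    if not vals:
        raise ValueError("track traverses no valid raster cells")
    return TrackExposure(mean_radiance=float(np.mean(vals)), max_radiance=float(np.max(vals)), n_cells=len(vals))


# ---------------------------------------------------------------------------
# buffers and distance to sea


def buffer_stats(grid: RasterGrid, lon: float, lat: float, radius_m: float) -> tuple[float, float]:
    """(mean, max) over cells whose centre lies within ``radius_m`` of the point.

    The cell containing the point is always included, so a radius smaller
    than half a cell degenerates to that single cell.  Nodata excluded.
    """
    if radius_m <= 0:
        raise ValueError("radius must be > 0")
    clon, clat = grid.centres()
    d = geo.geodesic_distance(lon, lat, clon, clat)
    sel = d <= radius_m
    try:
        r0, c0 = cell_index(grid, lon, lat)
        sel[r0, c0] = True
    except ValueError:
        pass
    vals = grid.values[sel & ~grid.mask]
    if vals.size == 0:
        raise ValueError("no valid cells within the buffer")
    return float(vals.mean()), float(vals.max())


def sea_mask(dem: RasterGrid) -> np.ndarray:
    """Sea = nodata or elevation <= 0."""
    return dem.mask | (dem.values <= 0)


def distance_to_sea(dem: RasterGrid, lon: float, lat: float) -> float:
    """Minimum distance (m) from the point to the centre of any sea cell."""
    sea = sea_mask(dem)
    try:
        r0, c0 = cell_index(dem, lon, lat)
        if sea[r0, c0]:
            log.warning("distance_to_sea called for a point over sea; returning 0")
            return 0.0
    except ValueError:
        pass
    if not sea.any():
        raise ValueError("DEM contains no sea cells")
    rows, cols = np.nonzero(sea)
    slon, slat = dem.cell_centre(rows, cols)
    return float(geo.geodesic_distance(lon, lat, slon, slat).min())


# ---------------------------------------------------------------------------
# burrow clustering


def cluster_burrows(
    burrows: list[BurrowRecord], threshold_m: float = COLONY_LINK_THRESHOLD_M
) -> list[ColonyRecord]:
    """Single-linkage clustering of burrows into colonies.

    Two burrows share a colony iff a chain of pairwise links of at most
    ``threshold_m`` connects them (so chains longer than the threshold still
    merge — deliberate single-linkage chaining).  Counts are summed per
    colony; the centre is the centroid of member burrows.  The partition is
    invariant to input order; colonies are labelled in order of their
    westernmost-then-southernmost member for determinism.
    """
    if not burrows:
        raise ValueError("need at least one burrow")
    n = len(burrows)
    lons = np.array([b.lon for b in burrows])
    lats = np.array([b.lat for b in burrows])
    d = geo.geodesic_distance(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    adj = coo_matrix(d <= threshold_m)
    n_comp, labels = connected_components(adj, directed=False)
    colonies = []
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        members = [burrows[i] for i in idx]
        colonies.append(
            ColonyRecord(
                colony_id="",
                centre_lon=float(lons[idx].mean()),
                centre_lat=float(lats[idx].mean()),
                n_banded=sum(b.n_banded for b in members),
                n_recovered=sum(b.n_recovered for b in members),
                member_burrows=sorted(b.burrow_id for b in members),
            )
        )
    colonies.sort(key=lambda c: (c.centre_lon, c.centre_lat))
    for i, c in enumerate(colonies, start=1):
        c.colony_id = f"colony_{i:02d}"
    return colonies


def attach_covariates(
    colonies: list[ColonyRecord],
    dem: RasterGrid,
    radiance: RasterGrid,
    buffer_radius_m: float = BUFFER_RADIUS_M,
) -> list[ColonyRecord]:
    """Fill each colony's DEM and radiance covariates in place (and return)."""
    for c in colonies:
        c.elevation_m = sample_point(dem, c.centre_lon, c.centre_lat)
        c.distance_to_sea_m = distance_to_sea(dem, c.centre_lon, c.centre_lat)
        c.radiance_at_colony = sample_point(radiance, c.centre_lon, c.centre_lat)
        c.radiance_mean_3km, c.radiance_max_3km = buffer_stats(
            radiance, c.centre_lon, c.centre_lat, buffer_radius_m
        )
    return colonies
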
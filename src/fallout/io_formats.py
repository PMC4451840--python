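"""Readers and writers for every external format the pipeline touches.

Tracks come in as GPX 1.1 or as a fixed-dialect CSV
(``bird_id,time,lon,lat,altitude`` plus an optional ``group`` column); rasters
as ESRI ASCII grids; burrow/rescue tables as CSV.  All timestamps are parsed
as ISO-8601 and held in UTC; coordinates are WGS84 lon/lat degrees.  GeoTIFF
input is detected and rejected with an explicit message — the text-grid
format carries the same information for this pipeline.
"""

from __future__ import annotations

import csv
import logging

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

GROUPS = ("first_flight", "second_flight")
RADIANCE_KIND = "radiance_nW_sr_cm2"
ELEVATION_KIND = "elevation_m"

TRACK_CSV_HEADER = ["bird_id", "time", "lon", "lat", "altitude"]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Fix:
    """One GPS position: UTC time, WGS84 lon/lat, device altitude (m, optional)."""

    time: datetime
    lon: float
    lat: float
    altitude: float | None = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.time.tzinfo is None:
            object.__setattr__(self, "time", self.time.replace(tzinfo=timezone.utc))
        else:
            object.__setattr__(self, "time", self.time.astimezone(timezone.utc))


@dataclass
class Track:
    """One bird's flight: time-ordered fixes at a nominal sampling interval."""

    bird_id: str
    group: str
    fixes: list[Fix]
    nominal_interval_s: float = 30.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if len(self.fixes) < 2:
            raise ValueError(f"track {self.bird_id!r} has fewer than 2 fixes")
        times = [f.time for f in self.fixes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"track {self.bird_id!r} times not strictly increasing")


@dataclass
class RasterGrid:
    """Row-major georeferenced cell grid in WGS84 degrees.

    ``(x_origin, y_origin)`` is the outer (north-west) corner of cell (0, 0);
    rows run southward.  Cells are half-open: [x, x+cell) in longitude and
    (y−cell, y] in latitude, so boundary points belong to exactly one cell.
    """

    x_origin: float
    y_origin: float
    cell_size: float
    n_rows: int
    n_cols: int
    values: np.ndarray
    nodata: float = -9999.0
    kind: str = RADIANCE_KIND

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float).reshape(self.n_rows, self.n_cols)
        if self.kind == RADIANCE_KIND:
            valid = self.values != self.nodata
            if np.any(self.values[valid] < 0):
                raise ValueError("radiance values must be >= 0 where not nodata")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self.values == self.nodata

    @property
    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def cell_centre(self, row, col):
        """Lon/lat of a cell centre (broadcastable over row/col arrays)."""
        lon = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def centres(self):
        """Lon and lat arrays of every cell centre, each shaped (n_rows, n_cols)."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_centre(rows, cols)


@dataclass(frozen=True)
class BurrowRecord:
    """One monitored nest burrow with banding and recovery counts."""

    burrow_id: str
    lon: float
    lat: float
    n_banded: int
    n_recovered: int

    def __post_init__(self):
        if not 0 <= self.n_recovered <= self.n_banded:
            raise ValueError(
                f"burrow {self.burrow_id!r}: need 0 <= n_recovered ({self.n_recovered}) "
                f"<= n_banded ({self.n_banded})"
            )


@dataclass(frozen=True)
class RescueRecord:
    """Where and when one grounded bird was found."""

    bird_id: str
    lon: float
    lat: float
    found_time: datetime


# ---------------------------------------------------------------------------
# time parsing


def parse_utc(text: str) -> datetime:
    """Parse an ISO-8601 timestamp; naive values are taken as UTC."""
    t = datetime.fromisoformat(text.strip().replace("Z", "+00:00"))
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def _iso(t: datetime) -> str:
    return t.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


# ---------------------------------------------------------------------------
# tracks


def read_tracks(path, dialect: str = None) -> list[Track]:
    """Read tracks from GPX 1.1 or dialect CSV; one Track per bird.

    Fixes are sorted by time, duplicate timestamps within a bird collapse to
    the first occurrence, and birds with fewer than 2 usable fixes are
    excluded with a logged warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if dialect == "gpx":
        raw = _read_gpx(path)
    elif dialect == "csv":
        raw = _read_track_csv(path)
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")

    tracks: list[Track] = []
    for bird_id, (group, interval, fixes) in raw.items():
        fixes.sort(key=lambda f: f.time)
        seen, unique = set(), []
        for f in fixes:
            if f.time not in seen:
                seen.add(f.time)
                unique.append(f)
        if len(unique) < 2:
            log.warning("track %r has <2 usable fixes; excluded", bird_id)
            continue
        tracks.append(Track(bird_id=bird_id, group=group, fixes=unique, nominal_interval_s=interval))
    return tracks


def _read_track_csv(path: Path) -> dict:
    raw: dict = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = set(TRACK_CSV_HEADER)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: CSV header must contain {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                alt_text = (row["altitude"] or "").strip()
                fix = Fix(
                    time=parse_utc(row["time"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    altitude=float(alt_text) if alt_text else None,
                )
                group = (row.get("group") or "first_flight").strip()
                interval = float(row.get("interval_s") or 30.0)
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
            entry = raw.setdefault(row["bird_id"], (group, interval, []))
            entry[2].append(fix)
    return raw


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_gpx(path: Path) -> dict:
    tree = ET.parse(path)
    raw: dict = {}
    n_unnamed = 0
    for trk in (e for e in tree.getroot().iter() if _localname(e.tag) == "trk"):
        name = None
        group = "first_flight"
        for child in trk:
            if _localname(child.tag) == "name":
                name = (child.text or "").strip()
            if _localname(child.tag) == "type":
                t = (child.text or "").strip()
                if t in GROUPS:
                    group = t
        if not name:
            n_unnamed += 1
            name = f"track_{n_unnamed}"
        fixes = []
        for pt in (e for e in trk.iter() if _localname(e.tag) == "trkpt"):
            time_el = next((c for c in pt if _localname(c.tag) == "time"), None)
            ele_el = next((c for c in pt if _localname(c.tag) == "ele"), None)
            if time_el is None or time_el.text is None:
                raise ValueError(f"{path}: trkpt without <time> in track {name!r}")
            fixes.append(
                Fix(
                    time=parse_utc(time_el.text),
                    lon=float(pt.attrib["lon"]),
                    lat=float(pt.attrib["lat"]),
                    altitude=float(ele_el.text) if ele_el is not None and ele_el.text else None,
                )
            )
        raw[name] = (group, 30.0, fixes)
    return raw


def write_tracks(tracks: list[Track], path, dialect: str = None) -> None:
    """Write tracks as dialect CSV or GPX 1.1."""
    path = Path(path)
    if dialect is None:
        dialect = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(TRACK_CSV_HEADER + ["group", "interval_s"])
            for tr in tracks:
                for f in tr.fixes:
                    w.writerow(
                        [
                            tr.bird_id,
                            _iso(f.time),
                            repr(f.lon),
                            repr(f.lat),
                            "" if f.altitude is None else repr(f.altitude),
                            tr.group,
                            repr(tr.nominal_interval_s),
                        ]
                    )
    elif dialect == "gpx":
        root = ET.Element("gpx", {"version": "1.1", "creator": "fallout", "xmlns": "http://www.topografix.com/GPX/1/1"})
        for tr in tracks:
            trk = ET.SubElement(root, "trk")
            ET.SubElement(trk, "name").text = tr.bird_id
            ET.SubElement(trk, "type").text = tr.group
            seg = ET.SubElement(trk, "trkseg")
            for f in tr.fixes:
                pt = ET.SubElement(seg, "trkpt", {"lat": repr(f.lat), "lon": repr(f.lon)})
                if f.altitude is not None:
                    ET.SubElement(pt, "ele").text = repr(f.altitude)
                ET.SubElement(pt, "time").text = _iso(f.time)
        ET.indent(root)
        ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)

_TIFF_MAGICS = (b"II*\x00", b"MM\x00*", b"II+\x00", b"MM\x00+")


def read_raster(path, kind: str = RADIANCE_KIND) -> RasterGrid:
    """Read an ESRI ASCII grid.  GeoTIFF input is detected and refused."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic in _TIFF_MAGICS:
        raise ValueError(f"{path}: detected format GeoTIFF; only ESRI ASCII grids are supported")
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="ascii") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise ValueError(f"{path}: detected format is not an ESRI ASCII grid: {exc}") from exc
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: ESRI ASCII header missing {req}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.array([v for r in rows for v in r], dtype=float)
    if values.size != n_rows * n_cols:
        raise ValueError(f"{path}: expected {n_rows * n_cols} values, found {values.size}")
    cell = header["cellsize"]
    return RasterGrid(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        values=values,
        nodata=header.get("nodata_value", -9999.0),
        kind=kind,
    )


def write_raster(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid; values use repr so the round trip is exact."""
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {repr(grid.x_origin)}\n")
        fh.write(f"yllcorner {repr(grid.y_origin - grid.n_rows * grid.cell_size)}\n")
        fh.write(f"cellsize {repr(grid.cell_size)}\n")
        fh.write(f"NODATA_value {repr(grid.nodata)}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# tables

BURROW_HEADER = ["burrow_id", "lon", "lat", "n_banded", "n_recovered"]
RESCUE_HEADER = ["bird_id", "lon", "lat", "found_time"]


def read_burrow_table(path) -> list[BurrowRecord]:
    """Read the burrow CSV; validates 0 <= n_recovered <= n_banded per row."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(BURROW_HEADER).issubset(reader.fieldnames):
            raise ValueError(f"{path}: CSV header must contain {BURROW_HEADER}")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    BurrowRecord(
                        burrow_id=row["burrow_id"],
                        lon=float(row["lon"]),
                        lat=float(row["lat"]),
                        n_banded=int(row["n_banded"]),
                        n_recovered=int(row["n_recovered"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out


def write_burrow_table(records: list[BurrowRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BURROW_HEADER)
        for r in records:
            w.writerow([r.burrow_id, repr(r.lon), repr(r.lat), r.n_banded, r.n_recovered])


def read_rescue_table(path) -> list[RescueRecord]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(RESCUE_HEADER).issubset(reader.fieldnames):
            raise ValueError(f"{path}: CSV header must contain {RESCUE_HEADER}")
        for i, row in enumerate(reader, start=2):
            try:
                lon, lat = float(row["lon"]), float(row["lat"])
                if not (-180 <= lon <= 180 and -90 <= lat <= 90):
                    raise ValueError(f"invalid coordinates ({lon}, {lat})")
                out.append(
                    RescueRecord(
                        bird_id=row["bird_id"],
                        lon=lon,
                        lat=lat,
                        found_time=parse_utc(row["found_time"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out


def write_rescue_table(records: list[RescueRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESCUE_HEADER)
        for r in records:
            w.writerow([r.bird_id, repr(r.lon), repr(r.lat), _iso(r.found_time)])
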
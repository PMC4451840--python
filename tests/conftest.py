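"""Shared fixtures: small deterministic rasters and a session-scoped island."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from fallout.io_formats import Fix, RasterGrid, Track
from fallout.synthetic_nightscape import FlightModelConfig, NightscapeConfig, make_island, place_colonies


def make_grid(values, x_origin=0.0, y_origin=1.0, cell_size=0.1, nodata=-9999.0, kind="radiance_nW_sr_cm2"):
    values = np.asarray(values, dtype=float)
    return RasterGrid(
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_size,
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        values=values,
        nodata=nodata,
        kind=kind,
    )


def make_track(points, bird_id="b1", group="first_flight", interval_s=30.0, t0=None):
    """Track from a list of (lon, lat) pairs at a fixed interval."""
    t0 = t0 or datetime(2013, 10, 25, 20, 0, tzinfo=timezone.utc)
    fixes = [
        Fix(time=t0 + timedelta(seconds=i * interval_s), lon=lon, lat=lat, altitude=100.0)
        for i, (lon, lat) in enumerate(points)
    ]
    return Track(bird_id=bird_id, group=group, fixes=fixes, nominal_interval_s=interval_s)


@pytest.fixture(scope="session")
def small_island():
    """A coarse, fast island for geometry tests (6 km radius, 100 m cells)."""
    cfg = NightscapeConfig(island_radius_m=6000, dem_cell_m=100, n_lights=10, seed=42)
    dem, radiance = make_island(cfg)
    return cfg, dem, radiance


@pytest.fixture(scope="session")
def default_island():
    """The full default nightscape used for cohort-level calibration checks."""
    cfg = NightscapeConfig(seed=20131025)
    dem, radiance = make_island(cfg)
    return cfg, dem, radiance


@pytest.fixture(scope="session")
def default_colonies(default_island):
    cfg, dem, _ = default_island
    return place_colonies(dem, 17, seed=20131025)


@pytest.fixture()
def flight_config():
    return FlightModelConfig()
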
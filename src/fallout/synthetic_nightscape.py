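"""Synthetic island nightscape and fledgling maiden-flight simulator.

Generates a mountainous volcanic island (noisy radial-cone DEM with 25-m
cells, peak 3,718 m), a nocturnal radiance raster built from a coastal ring
of Gaussian point lights on a dark background (clipped at 103.6 nW/(sr·cm²)),
and breeding colonies at elevations below 1,000 m a.s.l.  Fledgling flights
are biased correlated random walks: each 30-s step mixes the previous heading
(directional persistence), the seaward bearing (steepest DEM descent) and the
bearing to the perceptually brightest light — inverse-square apparent
brightness, so bright cities attract from farther — with a per-step grounding
hazard that grows linearly with radiance above the 18 nW/(sr·cm²) grounding
threshold.  Departure times follow a zero-truncated normal with the
observed 161.2 ± 153.8 min after-sunset law.  Colony-level grounding outcomes
are binomial draws from a logit-linear model in colony distance-to-sea and
elevation.

Every generator is deterministic under a fixed seed; each simulated bird gets
its own RNG stream derived from (seed, bird index), so enlarging a cohort
never perturbs earlier birds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np
from scipy.ndimage import distance_transform_edt, maximum_filter
from scipy.special import expit
from scipy.stats import truncnorm

from . import geo
from .exposure_geo import ColonyRecord, sea_mask
from .io_formats import ELEVATION_KIND, RADIANCE_KIND, BurrowRecord, Fix, RasterGrid, Track

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class NightscapeConfig:
    """Island geometry and light-field parameters."""

    centre_lon: float = -16.5
    centre_lat: float = 28.3
    island_radius_m: float = 20000.0
    peak_elevation_m: float = 3718.0
    dem_cell_m: float = 25.0
    n_lights: int = 30
    light_intensity_max: float = 103.6
    light_kernel_sigma_m: float = 500.0
    background_radiance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("island_radius_m", "peak_elevation_m", "dem_cell_m", "light_kernel_sigma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.light_intensity_max < 0 or self.background_radiance < 0:
            raise ValueError("radiances must be >= 0")
        if self.n_lights < 0:
            raise ValueError("n_lights must be >= 0")


@dataclass
class FlightModelConfig:
    """Biased-correlated-random-walk parameters for one fledgling flight."""

    cruise_speed_kmh: float = 44.79
    step_interval_s: float = 30.0
    persistence: float = 0.7
    light_attraction_weight: float = 2.0
    seaward_weight: float = 1.0
    grounding_radiance_threshold: float = 18.0
    grounding_hazard_scale: float = 0.25
    departure_mean_min: float = 161.2
    departure_sd_min: float = 153.8
    sensing_radius_m: float = 16000.0
    escape_distance_m: float = 1000.0
    max_steps: int = 10000
    heading_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if self.light_attraction_weight < 0 or self.seaward_weight < 0:
            raise ValueError("direction weights must be >= 0")
        if not 0.0 <= self.grounding_hazard_scale:
            raise ValueError("grounding_hazard_scale must be >= 0")
        if self.departure_sd_min < 0:
            raise ValueError("departure SD must be >= 0")


@dataclass
class GroundingModelConfig:
    """Logit-linear colony grounding-rate model (per-metre slopes)."""

    beta0: float = -4.0
    beta_distance_per_m: float = 0.0004
    beta_elevation_per_m: float = 0.0036


@dataclass(frozen=True)
class ColonySite:
    """A placed colony centre on the synthetic island."""

    site_id: str
    lon: float
    lat: float
    elevation_m: float


@dataclass(frozen=True)
class FlightOutcome:
    """End state of one simulated maiden flight."""

    status: str  # "reached_sea" | "grounded"
    lon: float
    lat: float
    truncated: bool = False


# ---------------------------------------------------------------------------
# island generation


def make_island(config: NightscapeConfig) -> tuple[RasterGrid, RasterGrid]:
    """Build the DEM and radiance rasters for a synthetic island.

    The DEM is a radial cone (coast at 0, configured peak at the centre) with
    smooth multiplicative Gaussian-bump noise that vanishes at the coastline;
    sea cells are nodata.  Radiance is background plus a sum of Gaussian
    kernels centred on point lights placed in a coastal ring, clipped at the
    configured maximum; it is defined over land and sea alike.
    """
    rng = np.random.default_rng(config.seed)
    lat0, lon0 = config.centre_lat, config.centre_lon
    cell_deg = math.degrees(config.dem_cell_m / geo.meridional_radius(lat0))
    half = int(math.ceil(1.15 * config.island_radius_m / config.dem_cell_m)) + 1
    n = 2 * half
    x_origin = lon0 - half * cell_deg
    y_origin = lat0 + half * cell_deg

    grid = RasterGrid(
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_deg,
        n_rows=n,
        n_cols=n,
        values=np.zeros((n, n)),
        kind=ELEVATION_KIND,
    )
    clon, clat = grid.centres()
    east, north = geo.local_offsets_m(lon0, lat0, clon, clat)
    r = np.hypot(east, north)

    base = config.peak_elevation_m * (1.0 - r / config.island_radius_m)
    noise = np.zeros_like(base)
    for _ in range(12):
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, 0.8) * config.island_radius_m
        bx, by = rad * math.sin(ang), rad * math.cos(ang)
        sig = rng.uniform(0.08, 0.2) * config.island_radius_m
        amp = rng.uniform(-0.12, 0.12)
        noise += amp * np.exp(-((east - bx) ** 2 + (north - by) ** 2) / (2 * sig * sig))
    land = r < config.island_radius_m
    elev = np.where(land, np.maximum(base * (1.0 + noise), 0.001), -9999.0)
    dem = RasterGrid(
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_deg,
        n_rows=n,
        n_cols=n,
        values=elev,
        nodata=-9999.0,
        kind=ELEVATION_KIND,
    )

    radiance_vals = np.full((n, n), config.background_radiance)
    for _ in range(config.n_lights):
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0.93, 0.99) * config.island_radius_m
        lx, ly = rad * math.sin(ang), rad * math.cos(ang)
        amp = rng.uniform(0.3, 1.0) * config.light_intensity_max
        d2 = (east - lx) ** 2 + (north - ly) ** 2
        radiance_vals += amp * np.exp(-d2 / (2 * config.light_kernel_sigma_m**2))
    radiance_vals = np.clip(radiance_vals, 0.0, config.light_intensity_max)
    radiance = RasterGrid(
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_deg,
        n_rows=n,
        n_cols=n,
        values=radiance_vals,
        nodata=-9999.0,
        kind=RADIANCE_KIND,
    )
    return dem, radiance


def place_colonies(
    dem: RasterGrid, n_colonies: int, max_elevation_m: float = 1000.0, seed: int = 0
) -> list[ColonySite]:
    """Place colony centres on land cells with elevation in (0, max_elevation_m]."""
    rng = np.random.default_rng(seed)
    land = ~sea_mask(dem)
    eligible = land & (dem.values > 0) & (dem.values <= max_elevation_m)
    rows, cols = np.nonzero(eligible)
    if rows.size == 0:
        raise ValueError("no cells eligible for colony placement")
    if n_colonies == 0:
        return []
    idx = rng.choice(rows.size, size=min(n_colonies, rows.size), replace=False)
    sites = []
    for k, i in enumerate(sorted(idx), start=1):
        lon, lat = dem.cell_centre(rows[i], cols[i])
        sites.append(
            ColonySite(site_id=f"site_{k:03d}", lon=float(lon), lat=float(lat), elevation_m=float(dem.values[rows[i], cols[i]]))
        )
    return sites


# ---------------------------------------------------------------------------
# departures


def simulate_departure(config: FlightModelConfig, sunset: datetime, n: int) -> list[datetime]:
    """Draw n burrow-departure times from the zero-truncated normal law."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if config.departure_sd_min < 0:
        raise ValueError("departure SD must be >= 0")
    rng = np.random.default_rng(config.seed)
    if config.departure_sd_min == 0:
        offsets = np.full(n, config.departure_mean_min)
    else:
        a = (0.0 - config.departure_mean_min) / config.departure_sd_min
        offsets = truncnorm.rvs(
            a, np.inf, loc=config.departure_mean_min, scale=config.departure_sd_min, size=n, random_state=rng
        )
    return [sunset + timedelta(minutes=float(o)) for o in offsets]


def departure_offset_moments(config: FlightModelConfig) -> tuple[float, float]:
    """Mean and SD (minutes) of the truncated departure-offset law."""
    a = (0.0 - config.departure_mean_min) / config.departure_sd_min
    dist = truncnorm(a, np.inf, loc=config.departure_mean_min, scale=config.departure_sd_min)
    return float(dist.mean()), float(dist.std())


# ---------------------------------------------------------------------------
# flight simulation


class _FlightContext:
    """Precomputed raster fields shared by all flights over one nightscape."""

    def __init__(self, dem: RasterGrid, radiance: RasterGrid, config: FlightModelConfig):
        self.dem = dem
        self.radiance = radiance
        self.config = config
        self.sea = sea_mask(dem)
        lat0 = dem.y_origin - 0.5 * dem.n_rows * dem.cell_size
        self.dy_m = math.radians(dem.cell_size) * geo.meridional_radius(lat0)
        self.dx_m = (
            math.radians(dem.cell_size)
            * geo.prime_vertical_radius(lat0)
            * math.cos(math.radians(lat0))
        )
        # distance (m) from each sea cell to the nearest land cell
        self.dist_to_land = distance_transform_edt(self.sea, sampling=(self.dy_m, self.dx_m))
        elev0 = np.where(self.sea, 0.0, dem.values)
        d_row, d_col = np.gradient(elev0)
        self.grad_north = -d_row / self.dy_m  # rows run southward
        self.grad_east = d_col / self.dx_m
        # light candidates: local radiance maxima above the grounding threshold
        peaks = (radiance.values >= config.grounding_radiance_threshold) & (
            radiance.values == maximum_filter(radiance.values, size=5)
        )
        rows, cols = np.nonzero(peaks)
        self.light_lon, self.light_lat = radiance.cell_centre(rows, cols)
        self.light_rad = radiance.values[rows, cols]
        # fallback seaward direction on flat ground: radially outward
        land_rows, land_cols = np.nonzero(~self.sea)
        llon, llat = dem.cell_centre(land_rows, land_cols)
        self.centroid = (float(np.mean(llon)), float(np.mean(llat)))

    def cell(self, lon, lat):
        col = math.floor((lon - self.dem.x_origin) / self.dem.cell_size)
        row = math.floor((self.dem.y_origin - lat) / self.dem.cell_size)
        if 0 <= row < self.dem.n_rows and 0 <= col < self.dem.n_cols:
            return row, col
        return None

    def seaward_bearing(self, row, col, lon, lat, heading):
        ge, gn = self.grad_east[row, col], self.grad_north[row, col]
        if math.hypot(ge, gn) < 1e-9:
            if self.sea[row, col]:
                return heading  # over flat sea: keep going
            return float(geo.initial_bearing(self.centroid[0], self.centroid[1], lon, lat))
        return math.atan2(-ge, -gn)

    def brightest_light_bearing(self, lon, lat):
        """Bearing to, and perceived brightness of, the most salient light.

        Salience follows the inverse-square law — apparent brightness is the
        source radiance divided by squared distance (in km, floored at one
        cell) — so a bright city captures birds from proportionally farther
        away than a dim village, which is the behaviour inferred from the
        attraction-radius/intensity relationship.  Lights beyond the sensing
        radius are invisible.  Returns (bearing, perceived) or None.
        """
        if self.light_rad.size == 0:
            return None
        d = geo.geodesic_distance(lon, lat, self.light_lon, self.light_lat)
        in_range = d <= self.config.sensing_radius_m
        if not np.any(in_range):
            return None
        d_km = np.maximum(d / 1000.0, self.dy_m / 1000.0)
        perceived = np.where(in_range, self.light_rad / d_km**2, -np.inf)
        i = int(np.argmax(perceived))
        bearing = float(geo.initial_bearing(lon, lat, self.light_lon[i], self.light_lat[i]))
        return bearing, float(perceived[i])


def simulate_flight(
    start: tuple[float, float],
    dem: RasterGrid,
    radiance: RasterGrid,
    config: FlightModelConfig,
    rng: np.random.Generator,
    *,
    bird_id: str = "sim",
    group: str = "first_flight",
    departure: datetime | None = None,
    context: _FlightContext | None = None,
) -> tuple[Track, FlightOutcome]:
    """Simulate one maiden flight from a colony centre.

    Per step the heading is a weighted circular mixture of the previous
    heading, the seaward (steepest-descent) bearing and the bearing to the
    perceptually brightest light within the sensing radius; the light weight
    scales with the target's inverse-square apparent brightness normalised by
    the grounding threshold at 1 km (clamped at 1), so bright cities attract
    from proportionally farther than dim villages.
    Grounding is a Bernoulli event per step with probability
    ``hazard_scale × max(0, radiance − threshold)/threshold``, clamped to 1,
    evaluated over land.  The flight ends at grounding, or over sea once the
    bird is farther than the escape distance from land, or at the hard step
    cap (logged, treated as having reached the sea).
    """
    if context is None:
        context = _FlightContext(dem, radiance, config)
    if departure is None:
        departure = datetime(2013, 10, 25, 20, 0, tzinfo=timezone.utc)
    lon, lat = float(start[0]), float(start[1])
    cell = context.cell(lon, lat)
    if cell is None or context.sea[cell]:
        raise ValueError("flight must start on land")

    step_m = config.cruise_speed_kmh / 3.6 * config.step_interval_s
    noise_sd = config.heading_noise_sd * (1.0 - config.persistence)
    heading = context.seaward_bearing(cell[0], cell[1], lon, lat, 0.0)

    def fix(lon, lat, k):
        c = context.cell(lon, lat)
        alt = 0.0
        if c is not None and not context.sea[c]:
            alt = float(max(dem.values[c], 0.0))
        return Fix(time=departure + timedelta(seconds=k * config.step_interval_s), lon=lon, lat=lat, altitude=alt)

    fixes = [fix(lon, lat, 0)]
    outcome = None
    for k in range(1, config.max_steps + 1):
        # steer
        cell = context.cell(lon, lat)
        if cell is not None:
            sea_b = context.seaward_bearing(cell[0], cell[1], lon, lat, heading)
        else:
            sea_b = heading
        target = context.brightest_light_bearing(lon, lat) if config.light_attraction_weight > 0 else None
        vx = config.persistence * math.sin(heading) + config.seaward_weight * math.sin(sea_b)
        vy = config.persistence * math.cos(heading) + config.seaward_weight * math.cos(sea_b)
        if target is not None:
            light_b, perceived = target
            # attraction saturates once the light appears as bright as the
            # grounding threshold does at 1 km
            w_light = config.light_attraction_weight * min(
                1.0, perceived / config.grounding_radiance_threshold
            )
            vx += w_light * math.sin(light_b)
            vy += w_light * math.cos(light_b)
        if math.hypot(vx, vy) > 1e-12:
            heading = math.atan2(vx, vy)
        if noise_sd > 0:
            heading += rng.normal(0.0, noise_sd)
        # move
        lon, lat = geo.destination(lon, lat, heading, step_m)
        fixes.append(fix(lon, lat, k))
        cell = context.cell(lon, lat)
        if cell is None:
            outcome = FlightOutcome("reached_sea", lon, lat)
            break
        if context.sea[cell]:
            if context.dist_to_land[cell] > config.escape_distance_m:
                outcome = FlightOutcome("reached_sea", lon, lat)
                break
            continue
        local_rad = radiance.values[cell]
        if local_rad == radiance.nodata:
            local_rad = 0.0
        p_ground = min(
            1.0,
            config.grounding_hazard_scale
            * max(0.0, local_rad - config.grounding_radiance_threshold)
            / config.grounding_radiance_threshold,
        )
        if p_ground > 0 and rng.random() < p_ground:
            outcome = FlightOutcome("grounded", lon, lat)
            break
    if outcome is None:
        log.warning("flight %r exceeded %d steps; truncated as reached_sea", bird_id, config.max_steps)
        outcome = FlightOutcome("reached_sea", lon, lat, truncated=True)
    track = Track(bird_id=bird_id, group=group, fixes=fixes, nominal_interval_s=config.step_interval_s)
    return track, outcome


def simulate_cohort(
    starts: list[ColonySite],
    dem: RasterGrid,
    radiance: RasterGrid,
    config: FlightModelConfig,
    n_birds: int,
    seed: int,
    sunset: datetime | None = None,
    group: str = "first_flight",
) -> list[tuple[Track, FlightOutcome, ColonySite]]:
    """Simulate a cohort of maiden flights, one RNG stream per bird.

    Birds are assigned to colony sites round-robin; departure times are drawn
    from the truncated-normal law relative to ``sunset``.
    """
    if not starts:
        raise ValueError("need at least one start site")
    if sunset is None:
        sunset = datetime(2013, 10, 25, 18, 30, tzinfo=timezone.utc)
    context = _FlightContext(dem, radiance, config)
    dep_cfg = FlightModelConfig(**{**config.__dict__, "seed": seed})
    departures = simulate_departure(dep_cfg, sunset, n_birds)
    out = []
    for i in range(n_birds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        site = starts[i % len(starts)]
        track, outcome = simulate_flight(
            (site.lon, site.lat),
            dem,
            radiance,
            config,
            rng,
            bird_id=f"{group}_{i:04d}",
            group=group,
            departure=departures[i],
            context=context,
        )
        out.append((track, outcome, site))
    return out


# ---------------------------------------------------------------------------
# colony outcomes


def simulate_colony_outcomes(
    colonies: list[ColonyRecord],
    grounding_model: GroundingModelConfig,
    n_banded,
    rng: np.random.Generator,
) -> list[BurrowRecord]:
    """Draw binomial recovery counts per colony from the logit-linear model.

    ``n_banded`` is an int (same for every colony) or a per-colony sequence.
    Each colony needs ``distance_to_sea_m`` and ``elevation_m`` attached.
    """
    if np.isscalar(n_banded):
        n_banded = [int(n_banded)] * len(colonies)
    if len(n_banded) != len(colonies):
        raise ValueError("n_banded length must match colonies")
    out = []
    for colony, nb in zip(colonies, n_banded):
        if colony.distance_to_sea_m is None or colony.elevation_m is None:
            raise ValueError(f"colony {colony.colony_id!r} lacks covariates")
        eta = (
            grounding_model.beta0
            + grounding_model.beta_distance_per_m * colony.distance_to_sea_m
            + grounding_model.beta_elevation_per_m * colony.elevation_m
        )
        p = float(expit(eta))
        if not 1e-9 < p < 1.0 - 1e-9:
            raise ValueError(f"colony {colony.colony_id!r}: grounding probability {p} outside (0, 1)")
        rec = int(rng.binomial(nb, p)) if nb > 0 else 0
        out.append(
            BurrowRecord(
                burrow_id=colony.colony_id,
                lon=colony.centre_lon,
                lat=colony.centre_lat,
                n_banded=int(nb),
                n_recovered=rec,
            )
        )
    return out
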
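"""End-to-end orchestration: nightscape → exposure → metrics → inference.

A single INI config (key=value sections) drives either a fully synthetic
scenario or a set of real input files, through a fixed stage order:
simulate (synthetic only) → exposure extraction → flight metrics →
randomisation/correlation tests → grounding-rate GLM table → population
back-calculation.  Outputs are plain CSV/ASCII-grid/JSON files plus a
manifest recording the seed and config hash; identical config+seed gives
byte-identical outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date as date_cls
from pathlib import Path

import numpy as np

from . import __version__, exposure_geo, flight_metrics, geo, stats_inference, synthetic_nightscape
from .io_formats import (
    BurrowRecord,
    RescueRecord,
    read_burrow_table,
    read_raster,
    read_tracks,
    write_burrow_table,
    write_raster,
    write_rescue_table,
    write_tracks,
)
from .solar import apparent_sunset

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "bird_id",
    "group",
    "timing_min",
    "duration_min",
    "length_m",
    "straight_length_m",
    "tortuosity",
    "speed_kmh",
    "max_radiance",
    "mean_radiance",
    "colony_grounding_ratio",
    "outcome",
    "colony_distance_m",
    "radiance_differential",
]

COLONY_COLUMNS = [
    "colony_id",
    "centre_lon",
    "centre_lat",
    "n_banded",
    "n_recovered",
    "elevation_m",
    "distance_to_sea_m",
    "radiance_at_colony",
    "radiance_mean_3km",
    "radiance_max_3km",
]


@dataclass
class ScenarioConfig:
    """Synthetic-scenario block of a run config."""

    island_radius_m: float = 20000.0
    dem_cell_m: float = 25.0
    n_lights: int = 40
    n_colonies: int = 17
    n_gps_first: int = 12
    n_gps_second: int = 20
    n_banded_per_colony: int = 16
    burrows_per_colony: int = 3
    second_flight_persistence: float = 0.5
    rescued_annual_min: int = 863
    rescued_annual_max: int = 1751
    breeding_success: float = 0.75
    date: str = "2013-10-25"


@dataclass
class RunConfig:
    """Top-level run configuration: exactly one of scenario or real inputs."""

    seed: int = 0
    out_dir: str = "fallout_run"
    buffer_radius_km: float = 3.0
    exhaustive_limit: int = stats_inference.EXHAUSTIVE_LIMIT
    n_iterations: int = stats_inference.DEFAULT_ITERATIONS
    scenario: ScenarioConfig | None = None
    inputs: dict | None = None

    def __post_init__(self):
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("config must define exactly one of a synthetic scenario or real inputs")


def load_config(path) -> RunConfig:
    """Parse an INI run config (sections [run], and [scenario] or [inputs])."""
    cp = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        cp.read_file(fh)
    run = cp["run"] if cp.has_section("run") else {}
    kwargs = dict(
        seed=int(run.get("seed", 0)),
        out_dir=run.get("out_dir", "fallout_run"),
        buffer_radius_km=float(run.get("buffer_radius_km", 3.0)),
        exhaustive_limit=int(run.get("exhaustive_limit", stats_inference.EXHAUSTIVE_LIMIT)),
        n_iterations=int(run.get("n_iterations", stats_inference.DEFAULT_ITERATIONS)),
    )
    if cp.has_section("scenario"):
        sc = ScenarioConfig()
        for key, value in cp["scenario"].items():
            if not hasattr(sc, key):
                raise ValueError(f"unknown scenario key {key!r}")
            current = getattr(sc, key)
            setattr(sc, key, type(current)(value))
        kwargs["scenario"] = sc
    if cp.has_section("inputs"):
        kwargs["inputs"] = dict(cp["inputs"])
    return RunConfig(**kwargs)


def _config_hash(config: RunConfig) -> str:
    text = json.dumps(
        {
            "seed": config.seed,
            "buffer_radius_km": config.buffer_radius_km,
            "exhaustive_limit": config.exhaustive_limit,
            "n_iterations": config.n_iterations,
            "scenario": None if config.scenario is None else vars(config.scenario),
            "inputs": config.inputs,
        },
        sort_keys=True,
    )
    return hashlib.sha256(text.encode()).hexdigest()


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _write_csv(path, header, rows):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def write_colony_table(colonies, path):
    _write_csv(
        path,
        COLONY_COLUMNS,
        [[getattr(c, col) for col in COLONY_COLUMNS] for c in colonies],
    )


def run_all(config: RunConfig) -> dict:
    """Execute every pipeline stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    if config.scenario is not None:
        stage_results = _run_synthetic(config, out, outputs)
    else:
        raise NotImplementedError(
            "real-input runs: use the stage commands (exposure/metrics/test/glm) individually"
        )
    import pandas, scipy, statsmodels  # noqa: PLC0415

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "fallout": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "outputs": sorted(outputs),
        "results": stage_results,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_synthetic(config: RunConfig, out: Path, outputs: list[str]) -> dict:
    sc = config.scenario
    seed = config.seed
    log.info("stage simulate: building nightscape")
    night_cfg = synthetic_nightscape.NightscapeConfig(
        island_radius_m=sc.island_radius_m, dem_cell_m=sc.dem_cell_m, n_lights=sc.n_lights, seed=seed
    )
    dem, radiance = synthetic_nightscape.make_island(night_cfg)
    write_raster(dem, out / "dem.asc")
    write_raster(radiance, out / "radiance.asc")
    outputs += ["dem.asc", "radiance.asc"]

    sites = synthetic_nightscape.place_colonies(dem, sc.n_colonies, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)

    # burrows scattered tightly around each colony centre, banded counts split
    burrows = []
    for site in sites:
        per = np.full(sc.burrows_per_colony, sc.n_banded_per_colony // sc.burrows_per_colony)
        per[: sc.n_banded_per_colony % sc.burrows_per_colony] += 1
        sea = exposure_geo.sea_mask(dem)
        for j in range(sc.burrows_per_colony):
            # scatter burrows near the colony centre but keep them on land,
            # so cluster centroids stay inside the DEM's land mask
            blon, blat = site.lon, site.lat
            for _ in range(20):
                cand = geo.destination(site.lon, site.lat, rng.uniform(0, 2 * np.pi), rng.uniform(0, 150.0))
                try:
                    r_c, c_c = exposure_geo.cell_index(dem, float(cand[0]), float(cand[1]))
                except ValueError:
                    continue
                if not sea[r_c, c_c]:
                    blon, blat = cand
                    break
            burrows.append(
                BurrowRecord(
                    burrow_id=f"{site.site_id}_b{j}",
                    lon=float(blon),
                    lat=float(blat),
                    n_banded=int(per[j]),
                    n_recovered=0,
                )
            )

    log.info("stage exposure: clustering burrows, attaching covariates")
    colonies = exposure_geo.cluster_burrows(burrows)
    exposure_geo.attach_covariates(colonies, dem, radiance, config.buffer_radius_km * 1000.0)

    grounding_cfg = synthetic_nightscape.GroundingModelConfig()
    draws = synthetic_nightscape.simulate_colony_outcomes(
        colonies, grounding_cfg, [c.n_banded for c in colonies], rng
    )
    # recovery counts live at colony resolution; burrow rows keep banding only
    for colony, draw in zip(colonies, draws):
        colony.n_recovered = draw.n_recovered
    write_burrow_table(burrows, out / "burrows.csv")
    write_colony_table(colonies, out / "colonies.csv")
    outputs += ["burrows.csv", "colonies.csv"]

    log.info("stage simulate: flying GPS cohorts")
    d = date_cls.fromisoformat(sc.date)
    sunset = apparent_sunset(d, night_cfg.centre_lon, night_cfg.centre_lat)
    flight_cfg = synthetic_nightscape.FlightModelConfig()
    second_cfg = synthetic_nightscape.FlightModelConfig(persistence=sc.second_flight_persistence)
    release_sites = sites[:2] if len(sites) >= 2 else sites
    cohorts = synthetic_nightscape.simulate_cohort(
        sites, dem, radiance, flight_cfg, sc.n_gps_first, seed + 10, sunset.sunset_utc, "first_flight"
    ) + synthetic_nightscape.simulate_cohort(
        release_sites, dem, radiance, second_cfg, sc.n_gps_second, seed + 20, sunset.sunset_utc, "second_flight"
    )

    tracks = [t for t, _, _ in cohorts]
    write_tracks(tracks, out / "tracks.csv")
    write_tracks(tracks, out / "tracks.gpx")
    rescues = [
        RescueRecord(bird_id=t.bird_id, lon=o.lon, lat=o.lat, found_time=t.fixes[-1].time)
        for t, o, _ in cohorts
        if o.status == "grounded"
    ]
    write_rescue_table(rescues, out / "rescues.csv")
    outputs += ["tracks.csv", "tracks.gpx", "rescues.csv"]

    log.info("stage metrics: summarising flights")
    summary_rows = []
    summaries = []
    for track, outcome, site in cohorts:
        s = flight_metrics.summarize_flight(track, sunset, radiance, (site.lon, site.lat), dem=dem)
        dist = flight_metrics.geodesic_distance(site.lon, site.lat, outcome.lon, outcome.lat)
        rad_site = exposure_geo.sample_point(radiance, site.lon, site.lat)
        rad_end = exposure_geo.sample_point(radiance, outcome.lon, outcome.lat) if outcome.status == "grounded" else float("nan")
        diff = rad_end - rad_site
        summaries.append((s, outcome, float(dist), float(diff)))
        summary_rows.append([getattr(s, c) for c in SUMMARY_COLUMNS[:11]] + [outcome.status, float(dist), float(diff)])
    _write_csv(out / "summaries.csv", SUMMARY_COLUMNS, summary_rows)
    outputs.append("summaries.csv")

    log.info("stage tests: randomisation and correlation inference")
    tests: dict = {}
    for var in ("tortuosity", "speed_kmh", "length_m"):
        g1 = [getattr(s, var) for s, o, _, _ in summaries if s.group == "first_flight"]
        g2 = [getattr(s, var) for s, o, _, _ in summaries if s.group == "second_flight"]
        if g1 and g2:
            r = stats_inference.randomisation_test(
                g1, g2, exhaustive_limit=config.exhaustive_limit, n_iterations=config.n_iterations, seed=seed + 30
            )
            tests[f"randomisation_{var}"] = {
                "statistic": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
            }
    grounded = [(dist, diff) for s, o, dist, diff in summaries if o.status == "grounded"]
    if len(grounded) >= 3 and np.ptp([g[1] for g in grounded]) > 0:
        sp = stats_inference.spearman_mc_test(
            [g[0] for g in grounded], [g[1] for g in grounded], tail="greater",
            n_iterations=config.n_iterations, seed=seed + 31,
        )
        tests["spearman_distance_vs_light"] = {"rho": sp.rho, "p_value": sp.p_value, "n": sp.n}

    log.info("stage glm: grounding-rate candidate models")
    fits = []
    glm_errors = {}
    for cov in ("none",) + stats_inference.GLM_COVARIATES:
        try:
            fits.append(stats_inference.fit_binomial_logit(colonies, cov))
        except ValueError as exc:
            glm_errors[cov] = str(exc)
    table = stats_inference.rank_models(fits)
    with open(out / "glm_table.csv", "w", encoding="utf-8", newline="") as fh:
        table.to_csv(fh, index=False, float_format="%.10g")
    outputs.append("glm_table.csv")
    try:
        tests["vif"] = stats_inference.vif(colonies)
    except ValueError as exc:
        glm_errors["vif"] = str(exc)
    if glm_errors:
        tests["glm_errors"] = glm_errors

    log.info("stage popsize: population back-calculation")
    total_banded = sum(c.n_banded for c in colonies)
    total_recovered = sum(c.n_recovered for c in colonies)
    rate = stats_inference.pooled_recovery_rate(total_recovered, total_banded)
    pop = {}
    if 0 < rate <= 1:
        for label, rescued in (("min", sc.rescued_annual_min), ("max", sc.rescued_annual_max)):
            est = stats_inference.estimate_population(rescued, rate, sc.breeding_success)
            pop[label] = {"rescued": est.rescued, "pairs": est.pairs, "pairs_raw": est.pairs_raw}
    results = {
        "tests": tests,
        "recovery_rate": rate,
        "population": pop,
        "n_grounded_gps": sum(1 for _, o, _ in cohorts if o.status == "grounded"),
        "n_tracks": len(tracks),
    }
    with open(out / "tests.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    outputs.append("tests.json")
    return results
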
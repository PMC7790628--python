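"""End-to-end pipeline: simulate/load -> covariates -> density -> GAM -> importance.

Configuration is a YAML document (seeds explicit and mandatory for every
stochastic stage); each run writes a report bundle whose artifacts carry
the config hash and seed so every output is reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density as dens
from . import importance as imp
from . import landcover as lc
from . import selection as sel
from . import synthetic as syn
from . import terrain
from .grid import CovariateStack, Grid, read_ascii_grid, read_geojson, write_ascii_grid

logger = logging.getLogger("bharal")

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult",
           "run_pipeline", "run_sensitivity", "build_covariate_stack",
           "configure_logging"]


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    lg = logging.getLogger("bharal")
    if not lg.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        lg.addHandler(h)
    lg.setLevel(level)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration.

    ``mode="synthetic"`` generates all inputs from the landscape module;
    ``mode="files"`` reads DEM/NDVI rasters (.asc), transects (GeoJSON),
    observations (CSV) and features (GeoJSON) from ``paths``.
    """

    mode: str = "synthetic"
    seed: int = 0
    season: str = "spring"
    output_dir: str = "bharal_run"
    paths: dict[str, str] = field(default_factory=dict)

    # synthetic-mode scene (scaled-down defaults for a desk run)
    extent_m: float = 6000.0
    cell_size_m: float = 30.0
    n_transects: int = 8
    transect_target_length_m: float = 2100.0
    true_density_ind_per_km2: float = 7.0

    # analysis parameters
    radii_m: tuple[float, float] = (1000.0, 1500.0)
    livestock_buffer_m: float = 500.0
    cliff_threshold_deg: float = 45.0
    cliff_min_area_m2: float = 90.0
    stream_drainage_km2: float = 0.5
    n_candidates: int = 50_000
    pa_multiplier: int = 100
    groupsize_alpha: float = 0.05
    exclude_forest: bool = True
    gam_df: int = 8
    gam_alpha: object = "auto"
    importance_reps: int = 100
    viewshed_line_of_sight: bool = True

    def validate(self) -> None:
        if self.mode not in {"synthetic", "files"}:
            raise PipelineError("config", f"unknown mode {self.mode!r}")
        if any(r <= 0 for r in self.radii_m):
            raise PipelineError("config", "radii must be positive")
        if self.mode == "files":
            for key in ("dem", "transects", "observations"):
                if key not in self.paths:
                    raise PipelineError("config", f"missing path {key!r}")
                if not Path(self.paths[key]).exists():
                    raise PipelineError("config",
                                        f"path {key!r} does not exist: "
                                        f"{self.paths[key]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "radii_m" in doc:
            doc["radii_m"] = tuple(doc["radii_m"])
        return cls(**doc)

    def to_yaml(self) -> str:
        doc = asdict(self)
        doc["radii_m"] = list(self.radii_m)
        return yaml.safe_dump(doc, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    stack: CovariateStack
    transects: syn.TransectSet
    observations: pd.DataFrame
    densities: dict[float, dens.DensityEstimate]
    fit: sel.GamFit
    frame: sel.ModelFrame
    importance: imp.ImportanceTable
    groupsize_model: sel.GroupSizeModel
    rate: sel.ExponentialRate


def build_covariate_stack(dem: Grid, ndvi: Grid, features: syn.FeatureSet,
                          livestock_buffer_m: float = 500.0,
                          cliff_threshold_deg: float = 45.0,
                          cliff_min_area_m2: float = 90.0,
                          stream_drainage_km2: float = 0.5) -> CovariateStack:
    """Derive the full covariate stack from DEM, NDVI and feature layers."""
    slope = terrain.horn_slope(dem)
    aspect = terrain.horn_aspect(dem)
    stack = CovariateStack({
        "elevation": dem,
        "slope_deg": slope,
        "tri_m": terrain.riley_tri(dem),
        "aspect_deg": aspect,
        "south_deviation_deg": terrain.south_deviation(aspect),
        "ndvi": ndvi,
    })
    cliffs = terrain.detect_cliffs(slope, cliff_threshold_deg, cliff_min_area_m2)
    stack.add("dist_cliff_m", terrain.distance_surface(cliffs, dem))
    filled = terrain.fill_sinks(dem)
    accum = terrain.flow_accumulation(terrain.d8_flow_direction(filled))
    streams = terrain.extract_streams(
        accum, terrain.stream_threshold_cells(stream_drainage_km2, dem.cell_size))
    stack.add("dist_stream_m", terrain.distance_surface(streams, dem))
    stack.add("dist_settlement_m",
              terrain.distance_surface(features.settlements, dem))
    stack.add("dist_trail_m", terrain.distance_surface(features.trails, dem))
    stack.add("livestock_presence",
              terrain.livestock_presence(features.livestock, livestock_buffer_m,
                                         dem))
    return stack


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag stage and re-raise
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    if config.mode == "synthetic":
        lscfg = syn.LandscapeConfig(
            extent_m=(config.extent_m, config.extent_m),
            cell_size_m=config.cell_size_m, seed=config.seed)
        dem = syn.generate_dem(lscfg)
        ndvi = syn.generate_ndvi(dem, lscfg)
        transects = syn.place_transects(dem, config.n_transects,
                                        config.transect_target_length_m,
                                        seed=config.seed + 1)
        features = syn.place_features(dem, seed=config.seed + 2)
        truth = syn.PopulationTruth(
            true_density_ind_per_km2=config.true_density_ind_per_km2)
        groups = syn.simulate_population(dem, ndvi, truth, seed=config.seed + 3)
        det = syn.DetectionModel()
        obs = syn.simulate_survey(groups, transects, dem, det,
                                  seed=config.seed + 4, season=config.season)
        return dem, ndvi, transects, features, obs
    dem = read_ascii_grid(config.paths["dem"])
    ndvi = (read_ascii_grid(config.paths["ndvi"])
            if "ndvi" in config.paths else dem.like(np.zeros(dem.shape)))
    geoms, _ = read_geojson(config.paths["transects"])
    transects = syn.TransectSet([g for g in geoms if g.geom_type == "LineString"])
    obs = pd.read_csv(config.paths["observations"])
    features = syn.FeatureSet([], [], [])
    if "features" in config.paths:
        geoms, props = read_geojson(config.paths["features"])
        features = syn.FeatureSet(
            [g for g, p in zip(geoms, props) if p.get("layer") == "settlement"],
            [g for g, p in zip(geoms, props) if p.get("layer") == "trail"],
            [g for g, p in zip(geoms, props) if p.get("layer") == "livestock"])
    return dem, ndvi, transects, features, obs


def run_pipeline(config: PipelineConfig, write_outputs: bool = True
                 ) -> PipelineResult:
    """Run covariates -> density -> habitat selection -> importance."""
    config.validate()
    dem, ndvi, transects, features, obs = _load_inputs(config)

    stack = _stage("covariates")(build_covariate_stack)(
        dem, ndvi, features, config.livestock_buffer_m,
        config.cliff_threshold_deg, config.cliff_min_area_m2,
        config.stream_drainage_km2)

    @_stage("density")
    def _density():
        vs = {r: dens.transect_viewshed(
                dem, transects, r,
                assume_visible=not config.viewshed_line_of_sight)
              for r in config.radii_m}
        return vs, dens.minimum_density(obs, vs, season=config.season)

    viewsheds, densities = _density()

    @_stage("landcover")
    def _forest_mask() -> Grid:
        # forest class from NDVI calibration when possible, else a fixed
        # NDVI threshold at the top of the forest band
        if config.mode == "synthetic":
            pts = syn.generate_calibration_points(dem, ndvi, seed=config.seed + 20)
            counts = pts["landcover"].value_counts()
            if counts.get("forest", 0) >= 3:
                ranges = lc.calibrate_ndvi_classes(pts)
                classes, legend = lc.classify_ndvi(
                    ndvi, ranges, priority=["forest", "grassland",
                                            "shrubland", "barren"])
                code = {v: k for k, v in legend.items()}["forest"]
                return ndvi.like(
                    (np.asarray(classes.values) == code).astype(float))
        vals = (np.asarray(ndvi.values, dtype=float) >= 0.55).astype(float)
        return ndvi.like(vals)

    forest = _forest_mask()

    @_stage("habitat_selection")
    def _habsel():
        rate = sel.fit_exponential_rate(obs["distance_m"], config.season)
        vs_max = viewsheds[max(config.radii_m)]
        pa = sel.generate_pseudo_absences(vs_max, transects, len(obs), rate,
                                          config.n_candidates,
                                          config.pa_multiplier,
                                          seed=config.seed + 10)
        pa, gs_model = sel.attribute_group_sizes(pa, obs,
                                                 config.groupsize_alpha,
                                                 seed=config.seed + 11)
        from .studies import RETAIN_PRIORITY

        # raw circular aspect never enters the model; its south-deviation
        # transform does
        covs = [c for c in stack.names if c != "aspect_deg"]
        frame = sel.build_model_frame(obs, pa, stack,
                                      exclude_forest=config.exclude_forest,
                                      forest_mask=forest, covariates=covs)
        screen = sel.screen_collinearity(frame.data[frame.covariates],
                                         retain_priority=RETAIN_PRIORITY)
        retained = screen.retained
        frame = sel.ModelFrame(
            frame.data[["presence", "weight"] + retained], retained,
            frame.n_presence, frame.n_pseudo_absence, frame.n_dropped_forest)
        fit = sel.fit_habitat_gam(frame, df=config.gam_df,
                                  alpha=config.gam_alpha)
        return rate, gs_model, frame, fit

    rate, gs_model, frame, fit = _habsel()

    importance = _stage("importance")(imp.permutation_importance)(
        fit, frame, config.importance_reps, seed=config.seed + 12)

    result = PipelineResult(config, stack, transects, obs, densities, fit,
                            frame, importance, gs_model, rate)
    if write_outputs:
        _stage("report")(_write_outputs)(result, dem, ndvi)
    return result


def _write_outputs(result: PipelineResult, dem: Grid, ndvi: Grid) -> None:
    cfg = result.config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(dem, out / "dem.asc")
    write_ascii_grid(ndvi, out / "ndvi.asc")
    result.transects.save(out / "transects.geojson")
    result.observations.to_csv(out / "observations.csv", index=False)
    dens_rows = [{"season": d.season, "buffer_radius_m": d.buffer_radius_m,
                  "individuals": d.individuals_counted,
                  "visible_area_km2": d.visible_area_km2,
                  "density_ind_per_km2": d.density_ind_per_km2,
                  "density_rounded": d.density_rounded}
                 for d in result.densities.values()]
    pd.DataFrame(dens_rows).to_csv(out / "density.csv", index=False)
    result.fit.summary_frame().to_csv(out / "model_summary.csv", index=False)
    result.importance.table.to_csv(out / "importance.csv", index=False)
    fig = imp.plot_importance(result.importance)
    fig.savefig(out / "importance.png", dpi=120)
    report = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "config": yaml.safe_load(cfg.to_yaml()),
        "n_observations": int(len(result.observations)),
        "exponential_rate_per_m": float(result.rate.rate_per_m),
        "groupsize_strategy": result.groupsize_model.strategy,
        "deviance_explained": float(result.fit.deviance_explained),
        "r2_adjusted": float(result.fit.r2_adjusted),
        "n_model_rows": result.fit.n,
    }
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    logger.info("report bundle written to %s (config %s)", out, cfg.config_hash)


def run_sensitivity(config: PipelineConfig, variants: dict[str, dict]
                    ) -> pd.DataFrame:
    """Re-run the pipeline under variant parameters and tabulate shifts.

    ``variants`` maps a variant name to config-field overrides (e.g.
    livestock buffer width, forest inclusion, an alternative
    pseudo-absence seed).  Returns a table of standardized-importance and
    deviance-explained differences against the base run.
    """
    base = run_pipeline(config, write_outputs=False)
    base_imp = base.importance.table.set_index("variable")["standardized"]
    rows = []
    for name, overrides in variants.items():
        vcfg = replace(config, **overrides)
        vres = run_pipeline(vcfg, write_outputs=False)
        vimp = vres.importance.table.set_index("variable")["standardized"]
        common = base_imp.index.intersection(vimp.index)
        rows.append({
            "variant": name,
            "deviance_explained": vres.fit.deviance_explained,
            "delta_deviance_explained": (vres.fit.deviance_explained
                                         - base.fit.deviance_explained),
            "max_abs_importance_shift": float(
                (vimp[common] - base_imp[common]).abs().max()),
            "top_variable": vres.importance.top(),
        })
    return pd.DataFrame(rows)
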
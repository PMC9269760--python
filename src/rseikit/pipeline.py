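"""End-to-end pipeline: indicators -> normalization -> SPCA -> RSEI ->
grading -> reports.

`run_on_scene` executes every stage on a synthetic scene (or any object
exposing the same band/thermal surface); `run_pipeline` drives it from a
:class:`PipelineConfig`, writing the RSEI and class rasters as GeoTIFF and
the summary/PCA/correlation/grade tables as fixed-column CSV (floats at 4
decimals) into the output directory. All randomness flows from the single
config seed; per-stage seeds are derived from it deterministically.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import aod as aod_mod
from . import engine, indices, salinity as salinity_mod, scene as scene_mod
from .raster import RasterGrid, write_raster

__all__ = ["PipelineConfig", "PipelineResult", "run_on_scene", "run_pipeline"]

log = logging.getLogger("rseikit")


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic run."""

    scene: scene_mod.SceneConfig = field(default_factory=scene_mod.SceneConfig)
    layers: tuple[str, ...] = (
        "greenness", "wetness", "dryness", "heat", "salinity", "aod"
    )
    lower_percentile: float = 2.0
    upper_percentile: float = 98.0
    change_threshold: float = 0.1
    n_soil_samples: int = 10
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scene_raw = raw.pop("scene", {})
        lst_raw = scene_raw.pop("lst_params", None)
        if lst_raw is not None:
            scene_raw["lst_params"] = indices.LSTParams(**lst_raw)
        for key in ("salinity_range", "aod_field", "lst_range", "geometry"):
            if key in scene_raw:
                scene_raw[key] = tuple(scene_raw[key])
        if "layers" in raw:
            raw["layers"] = tuple(raw["layers"])
        return cls(scene=scene_mod.SceneConfig(**scene_raw), **raw)


@dataclass
class PipelineResult:
    scene: scene_mod.SyntheticScene
    indicator_rasters: dict[str, RasterGrid]
    stack: engine.NormalizedIndexStack
    pca: engine.PCAResult
    rsei: RasterGrid
    grade_table: object
    class_raster: RasterGrid
    summary_table: object
    correlation_matrix: object
    correlation_means: object


def _derive_seed(seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def compute_indicators(
    sc: scene_mod.SyntheticScene,
    layers: tuple[str, ...],
    n_soil_samples: int = 10,
    seed: int = 0,
) -> dict[str, RasterGrid]:
    """Raw (pre-normalization) indicator rasters for the requested layers."""
    roles = sc.band_roles()
    out: dict[str, RasterGrid] = {}
    if "greenness" in layers:
        out["greenness"] = indices.ndvi(roles["red"], roles["nir"])
        log.info("greenness: NDVI computed")
    if "wetness" in layers:
        out["wetness"] = indices.wetness(roles, indices.SENTINEL2_WETNESS)
        log.info("wetness: tasseled-cap component computed")
    if "dryness" in layers:
        out["dryness"] = indices.bare_soil_index(roles)
        log.info("dryness: bare soil index computed")
    if "heat" in layers:
        thermal = sc.thermal_radiance
        if thermal.pixel_size != roles["red"].pixel_size:
            thermal = indices.resample(
                thermal, roles["red"].pixel_size[0], method="bilinear"
            )
        out["heat"] = indices.lst(thermal, sc.lst_params)
        log.info("heat: single-channel LST computed")
    if "aod" in layers:
        toa_ndvi = indices.ndvi(sc.toa["red"], sc.toa["nir"])
        cfg = aod_mod.DDVConfig(
            ndvi_threshold=sc.config.ndvi_threshold, k_ratio=sc.config.k_ratio
        )
        dark = aod_mod.detect_dark(toa_ndvi, cfg.ndvi_threshold)
        sparse, disc = aod_mod.retrieve_aod(
            sc.toa["red"], sc.toa["blue"], dark, sc.geometry, sc.lut, cfg
        )
        out["aod"] = aod_mod.fill_aod(sparse, cfg, discrepancy=disc).tau
        log.info("aod: DDV retrieval on %d dark pixels", int(dark.sum()))
    if "salinity" in layers:
        samples = scene_mod.sample_soil(
            sc, n_soil_samples, seed=_derive_seed(seed, "soil")
        )
        diag = salinity_mod.band_diagnostics(samples)
        bands = salinity_mod.select_bands(diag, min(5, len(samples.bands)))
        model = salinity_mod.fit_linear(samples, bands)
        out["salinity"] = salinity_mod.predict_linear_map(model, sc.reflectance)
        log.info("salinity: linear inversion on bands %s", bands)
    return out


def run_on_scene(
    sc: scene_mod.SyntheticScene,
    layers: tuple[str, ...] = (
        "greenness", "wetness", "dryness", "heat", "salinity", "aod"
    ),
    lower: float = 2.0,
    upper: float = 98.0,
    n_soil_samples: int = 10,
    seed: int = 0,
    mask_water: bool = True,
) -> PipelineResult:
    """Execute indicators -> normalization -> SPCA -> RSEI -> grading.

    Water pixels are masked out of the indicator stack by default: open
    water carries extreme wetness/dryness/heat values that hijack the first
    principal component and distort the ecological score of the land
    surface, so RSEI is conventionally evaluated over land only.
    """
    raw = compute_indicators(sc, layers, n_soil_samples, seed)
    if mask_water and sc.water_mask.any():
        masked = {}
        for name, g in raw.items():
            vals = g.values.astype(float).copy()
            vals[sc.water_mask] = np.nan
            masked[name] = g.like(vals)
        raw = masked
    normalized = {
        name: engine.percentile_normalize(g, lower, upper)
        for name, g in raw.items()
    }
    stack = engine.NormalizedIndexStack(normalized)
    pca = engine.run_spca(stack)
    rsei = engine.compose_rsei(stack, pca)
    grade_table, class_raster = engine.grade(rsei)
    summary_table = engine.summary(stack, rsei)
    corr, corr_means = engine.correlation_report(stack, rsei)
    log.info("RSEI composed; mean %.3f", float(np.nanmean(rsei.values)))
    return PipelineResult(
        scene=sc,
        indicator_rasters=raw,
        stack=stack,
        pca=pca,
        rsei=rsei,
        grade_table=grade_table,
        class_raster=class_raster,
        summary_table=summary_table,
        correlation_matrix=corr,
        correlation_means=corr_means,
    )


def _write_reports(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_raster(result.rsei, out_dir / "rsei.tif")
    write_raster(result.class_raster, out_dir / "rsei_classes.tif")
    for name, g in result.indicator_rasters.items():
        write_raster(g, out_dir / f"indicator_{name}.tif")
    fmt = "%.4f"
    result.summary_table.to_csv(out_dir / "summary.csv", index=False,
                                float_format=fmt)
    result.pca.to_frame().to_csv(out_dir / "pca.csv", float_format=fmt)
    result.correlation_matrix.to_csv(out_dir / "correlation.csv",
                                     float_format=fmt)
    result.grade_table.to_csv(out_dir / "grades.csv", index=False,
                              float_format=fmt)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Drive the full run from a config; writes reports if out_dir set."""
    sc = scene_mod.make_scene(config.scene)
    result = run_on_scene(
        sc,
        layers=config.layers,
        lower=config.lower_percentile,
        upper=config.upper_percentile,
        n_soil_samples=config.n_soil_samples,
        seed=config.seed,
    )
    if config.out_dir:
        _write_reports(result, Path(config.out_dir))
    return result
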
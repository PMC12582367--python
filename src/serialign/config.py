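"""Declarative pipeline configuration and end-to-end orchestration.

One :class:`PipelineConfig` drives the whole run:
load → downscale/normalize → rigid fit → B-spline fit (or mesh sweep) →
QC exports → clipping → cell transformation → panel merge.  Every unstated
numeric default of the other modules surfaces here.  The run writes a
manifest (config hash, seed, versions, per-stage metrics) sufficient to
reproduce the outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .errors import ArgumentError

log = logging.getLogger("serialign")


class PipelineConfig(BaseModel):
    """All inputs and knobs of one alignment run."""

    slide1_image: str
    slide2_image: str
    slide1_cells: str | None = None
    slide2_cells: str | None = None
    channel_index: int = 0  # DAPI channel by convention
    pyramid_level: int = 0
    base_spacing: float | None = None  # µm/px of the level-0 scan; None = from file/0.5
    downscale_factor: int = 32
    brightness_low: float = 0.01
    brightness_high: float = 0.99
    pre_flip: str = "none"  # none | horizontal | vertical (applied to slide 2)
    mesh_sizes: list[int] = Field(default_factory=lambda: [8])  # sweep list
    mesh_size: int = 8  # chosen mesh for the final transform
    sampling_fraction: float = 0.1
    max_iterations: int = 100
    gradient_tolerance: float = 1e-5
    rotation_search_deg: float = 15.0
    regions_file: str | None = None
    overlay_alpha: float = 0.5
    output_dir: str = "serialign_out"
    seed: int = 0

    @field_validator("downscale_factor")
    @classmethod
    def _factor_ge_1(cls, v):
        if v < 1:
            raise ValueError("downscale_factor must be >= 1")
        return v

    @field_validator("mesh_sizes")
    @classmethod
    def _meshes_ge_1(cls, v):
        if not v or any(m < 1 for m in v):
            raise ValueError("mesh_sizes must be non-empty, each >= 1")
        return v

    @field_validator("pre_flip")
    @classmethod
    def _flip_ok(cls, v):
        if v not in ("none", "horizontal", "vertical"):
            raise ValueError("pre_flip must be none|horizontal|vertical")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def validate_paths(self) -> None:
        for name in ("slide1_image", "slide2_image", "slide1_cells",
                     "slide2_cells", "regions_file"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ArgumentError(f"config field {name}: path does not exist: {value}")

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full alignment and integration; returns the run manifest."""
    from . import __version__, cells as cells_mod, imaging, qc, registration, transforms

    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
        "status": "partial",
    }
    t_start = time.time()

    def stage(name):
        log.info("stage %s: start", name)
        return time.time()

    def done(name, t0, **metrics):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **metrics}
        log.info("stage %s: done in %.1fs %s", name, time.time() - t0, metrics or "")

    try:
        # -- load + preprocess ------------------------------------------------
        t0 = stage("preprocess")
        imgs = []
        for path in (config.slide1_image, config.slide2_image):
            img = imaging.load_channel(path, config.channel_index,
                                       config.pyramid_level, config.base_spacing)
            img = imaging.downscale(img, config.downscale_factor)
            img = imaging.normalize_brightness(img, config.brightness_low,
                                               config.brightness_high)
            imgs.append(img)
        fixed, moving = imgs
        if config.pre_flip != "none":
            moving = imaging.flip(moving, config.pre_flip)
        done("preprocess", t0, fixed_px=[fixed.width, fixed.height],
             moving_px=[moving.width, moving.height])

        # -- registration -----------------------------------------------------
        settings = registration.OptimizerSettings(
            sampling_fraction=config.sampling_fraction,
            max_iterations=config.max_iterations,
            gradient_tolerance=config.gradient_tolerance,
            rotation_search_deg=config.rotation_search_deg,
            seed=config.seed,
        )
        t0 = stage("fit_rigid")
        rigid, rigid_report = registration.fit_rigid(fixed, moving, settings)
        done("fit_rigid", t0, metric=rigid_report.final_metric,
             converged=rigid_report.converged)

        sweep_meshes = sorted(set(config.mesh_sizes) | {config.mesh_size})
        composite = None
        if len(sweep_meshes) > 1:
            t0 = stage("mesh_sweep")
            rows = []
            for mesh in sweep_meshes:
                comp_m, rep_m = registration.fit_bspline(fixed, moving, rigid,
                                                         mesh, settings)
                rows.append({"mesh_size": mesh,
                             "final_correlation": rep_m.final_correlation,
                             "elapsed_seconds": rep_m.elapsed_seconds})
                if mesh == config.mesh_size:
                    composite, bspline_report = comp_m, rep_m
            with open(out / "sweep.json", "w") as fh:
                json.dump(rows, fh, indent=1)
            done("mesh_sweep", t0, rows=len(rows))
        else:
            t0 = stage("fit_bspline")
            composite, bspline_report = registration.fit_bspline(
                fixed, moving, rigid, config.mesh_size, settings)
            done("fit_bspline", t0)
        manifest["final_metric"] = bspline_report.final_metric
        manifest["final_correlation"] = bspline_report.final_correlation
        transforms.save_transform(composite, out / "transform.json")

        # -- QC exports -------------------------------------------------------
        t0 = stage("qc")
        resampled = registration.resample(moving, composite, fixed)
        overlay = imaging.blend_overlay(fixed, resampled, config.overlay_alpha)
        imaging.save_png(overlay.pixels, out / "overlay.png")
        jac = qc.jacobian_map(composite, fixed)
        imaging.save_png(jac.values, out / "jacobian.png")
        grid_img = qc.deformation_grid_render(composite, fixed, resampled=resampled)
        imaging.save_png(grid_img.pixels, out / "deformation_grid.png")
        done("qc", t0, jacobian_mean=float(jac.values.mean()))

        # -- clipping + integration -------------------------------------------
        regions = (cells_mod.load_regions_geojson(config.regions_file)
                   if config.regions_file else [])
        if config.slide1_cells and config.slide2_cells:
            t0 = stage("integrate")
            c1 = cells_mod.read_cell_table(config.slide1_cells)
            c2 = cells_mod.read_cell_table(config.slide2_cells)
            c1t = cells_mod.transform_cells(c1, composite)
            merged, summary = cells_mod.merge_panels(c1t, c2, regions)
            cells_mod.write_cell_table(merged, out / "merged_cells.csv")
            with open(out / "merge_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1)
            raster_r = qc.raster_correlation(c1t, c2) if len(merged) else None
            manifest["merge"] = summary
            manifest["raster_correlation_after"] = raster_r
            done("integrate", t0, merged=summary["n_merged"])
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["elapsed_seconds"] = round(time.time() - t_start, 3)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    manifest["status"] = "complete"
    manifest["elapsed_seconds"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _versions() -> dict:
    import numpy
    import SimpleITK

    from . import __version__

    return {
        "serialign": __version__,
        "numpy": numpy.__version__,
        "simpleitk": SimpleITK.__version__,
    }
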
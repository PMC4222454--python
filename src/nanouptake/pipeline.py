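"""End-to-end orchestration: reconstruction → detection → classification → report.

The whole analysis path is deterministic given its inputs and configuration;
every stage logs the object counts it produced, and the report's provenance
block records the input paths, the configuration, and the calibration I₁.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationResult
from .cell_reconstruction import (
    ReconstructionParams,
    build_regions,
    make_cell_mask,
    smooth_membrane,
)
from .classification_counting import summarize_cell
from .io_formats import (
    AnalysisReport,
    read_stack,
    write_overlay,
    write_region_mask,
    write_report,
)
from .particle_detection import DetectionParams, detect_objects, subtract_background

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("nanouptake")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def _from_dict(cls, values: dict, block: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {block!r}: {sorted(unknown)}")
    return cls(**values)


@dataclass
class RunConfig:
    """Full configuration of one quantification run."""

    membrane_path: str = ""
    particle_path: str = ""
    calibration_path: str = ""
    output_dir: str = "."
    voxel_size_override: tuple[float, float, float] | None = None
    cell_bbox: tuple[int, int, int, int, int, int] | None = None  # z0 z1 y0 y1 x0 x1
    reconstruction: ReconstructionParams = field(default_factory=ReconstructionParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    overlay_colors: dict = field(default_factory=dict)
    write_overlay_stack: bool = True
    write_region_masks: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        rec = _from_dict(
            ReconstructionParams, raw.pop("reconstruction", {}), "reconstruction"
        )
        det = _from_dict(DetectionParams, raw.pop("detection", {}), "detection")
        for key in ("voxel_size_override", "cell_bbox"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(reconstruction=rec, detection=det, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _crop(grid, bbox):
    z0, z1, y0, y1, x0, x1 = bbox
    return grid.with_data(grid.data[z0:z1, y0:y1, x0:x1])


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis of one cell and write its outputs.

    Stages: read stacks → reconstruct cell regions → subtract background &
    detect objects → classify & count → write report (+ overlay). Errors are
    re-raised as :class:`PipelineError` tagged with the failing stage.
    """
    logging.basicConfig(level=config.log_level)
    stage = "read"
    try:
        membrane = read_stack(
            config.membrane_path, "membrane", config.voxel_size_override
        )
        particles = read_stack(
            config.particle_path, "particles", config.voxel_size_override
        )
        cal = CalibrationResult.from_json(config.calibration_path)
        if config.cell_bbox is not None:
            membrane = _crop(membrane, config.cell_bbox)
            particles = _crop(particles, config.cell_bbox)
        log.info("read: membrane %s, particles %s", membrane.shape, particles.shape)

        stage = "reconstruction"
        smoothed = smooth_membrane(membrane, config.reconstruction)
        mask = make_cell_mask(smoothed, config.reconstruction)
        regions = build_regions(
            mask, config.reconstruction.shell_width_um, membrane.voxel_size
        )
        log.info("reconstruction: cell volume %d voxels", int(mask.sum()))

        stage = "detection"
        residual = subtract_background(particles, config.detection)
        objects = detect_objects(residual, config.detection)
        log.info("detection: %d objects", len(objects))

        stage = "counting"
        result = summarize_cell(objects, regions, cal, grid=particles)
        log.info("counting: totals %s", result.totals)

        stage = "report"
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        provenance = {
            "membrane_path": str(config.membrane_path),
            "particle_path": str(config.particle_path),
            "calibration_path": str(config.calibration_path),
            "calibration_i1": cal.i1_mean,
            "config_hash": config.digest(),
        }
        report = result.to_report(provenance)
        write_report(report, out / "per_object.csv")
        if config.write_overlay_stack:
            write_overlay(
                membrane, objects, regions, out / "overlay.tif",
                colors=config.overlay_colors or None,
            )
        if config.write_region_masks:
            write_region_mask(regions, out / "regions.tif")
        return report
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"[{stage}] {exc}") from exc
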
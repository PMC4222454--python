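"""Image-stack and report I/O.

Stacks are held as :class:`VoxelGrid`: a 3D intensity array indexed
``(z, y, x)`` together with physical voxel sizes in micrometres. Intensities
are kept in native camera units ("pixel intensities") — no rescaling on load —
so that calibration constants and cell measurements share units.

Physical convention: voxel indices are 0-based; the physical coordinate of a
voxel is ``index * voxel_size``, taken at voxel centers, with the origin at
the center of voxel (0, 0, 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGrid",
    "AnalysisReport",
    "read_stack",
    "write_stack",
    "write_report",
    "read_report",
    "write_overlay",
    "write_region_mask",
]

#: region label → 8-bit code used in exported mask TIFFs
REGION_MASK_CODES = {"extracellular": 0, "membrane": 85, "intracellular": 170}

#: default overlay colors (RGB, 0–255) per region label
DEFAULT_OVERLAY_COLORS = {
    "membrane_stain": (0, 255, 255),   # cyan shell
    "intracellular": (255, 0, 0),      # red
    "membrane": (255, 255, 0),         # yellow
    "extracellular": (128, 128, 128),  # gray
}


@dataclass(frozen=True)
class VoxelGrid:
    """One channel's 3D intensity stack with physical voxel sizes.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``; non-negative, finite intensities.
    voxel_size
        ``(dz, dy, dx)`` in µm. Pixels must be square (``dy == dx``).
    channel_name
        Free-text channel identifier (e.g. ``"membrane"``, ``"particles"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) stack, got ndim={data.ndim}")
        if data.shape[0] < 3:
            raise ValueError(
                f"need at least 3 z planes for 3D reconstruction, got {data.shape[0]}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("stack contains non-finite intensities")
        if data.size and data.min() < 0:
            raise ValueError("stack contains negative intensities")
        dz, dy, dx = self.voxel_size
        if not (dz > 0 and dy > 0 and dx > 0):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if not np.isclose(dy, dx, rtol=1e-6):
            raise ValueError(f"non-square pixels (dy={dy}, dx={dx}) are not supported")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", (float(dz), float(dy), float(dx)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) of the stack in µm (voxel-center span + 1 voxel)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.voxel_size))

    def with_data(self, data: np.ndarray, channel_name: str | None = None) -> "VoxelGrid":
        """Same geometry, new intensities."""
        return VoxelGrid(
            data,
            self.voxel_size,
            self.channel_name if channel_name is None else channel_name,
        )


@dataclass
class AnalysisReport:
    """Final per-cell analysis: one row per detected object plus totals.

    ``per_object`` columns: object_id, x_um, y_um, z_um, region_label,
    integrated_intensity, n_particles. ``per_cell`` keys: n_intracellular,
    n_membrane, n_extracellular, n_total.
    """

    per_object: pd.DataFrame
    per_cell: dict
    provenance: dict = field(default_factory=dict)

    COLUMNS = (
        "object_id",
        "x_um",
        "y_um",
        "z_um",
        "region_label",
        "integrated_intensity",
        "n_particles",
    )

    def validate(self) -> None:
        missing = set(self.COLUMNS) - set(self.per_object.columns)
        if missing:
            raise ValueError(f"per_object table missing columns: {sorted(missing)}")
        totals = self.per_cell
        if totals["n_total"] != (
            totals["n_intracellular"] + totals["n_membrane"] + totals["n_extracellular"]
        ):
            raise ValueError("per-cell totals do not sum to n_total")
        for label, key in (
            ("intracellular", "n_intracellular"),
            ("membrane", "n_membrane"),
            ("extracellular", "n_extracellular"),
        ):
            rows = self.per_object[self.per_object["region_label"] == label]
            if int(rows["n_particles"].sum()) != int(totals[key]):
                raise ValueError(f"per-cell total {key} inconsistent with object table")


def _parse_ome_voxel_size(ome_xml: str) -> tuple[float, float, float] | None:
    try:
        meta = tifffile.xml2dict(ome_xml)
        pixels = meta["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
    except (KeyError, TypeError, IndexError):
        return None

    def one(axis: str) -> float | None:
        v = pixels.get(f"PhysicalSize{axis}")
        if v is None:
            return None
        unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
        scale = {"µm": 1.0, "um": 1.0, "micron": 1.0, "nm": 1e-3, "mm": 1e3}.get(unit)
        if scale is None:
            return None
        return float(v) * scale

    dz, dy, dx = one("Z"), one("Y"), one("X")
    if None in (dz, dy, dx):
        return None
    return (dz, dy, dx)


def _parse_imagej_voxel_size(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tif.imagej_metadata or {}
    dz = meta.get("spacing")
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    dx = xres[1] / xres[0] if xres[0] else None
    dy = yres[1] / yres[0] if yres[0] else None
    if dz is None or dx is None or dy is None:
        return None
    return (float(dz), float(dy), float(dx))


def read_stack(
    path: str | Path,
    expected_channel: str = "",
    voxel_size_override: tuple[float, float, float] | None = None,
) -> VoxelGrid:
    """Read a multi-page TIFF / OME-TIFF as a :class:`VoxelGrid`.

    Voxel sizes come from OME metadata when present, else ImageJ-style
    metadata (``spacing`` + resolution tags); a ``voxel_size_override``
    always wins, with a warning if it disagrees with file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_size = None
        if tif.ome_metadata:
            meta_size = _parse_ome_voxel_size(tif.ome_metadata)
        if meta_size is None:
            meta_size = _parse_imagej_voxel_size(tif)
    data = np.squeeze(data)
    if data.ndim == 2:
        raise ValueError(f"{path} is a single 2D image; a z-stack is required")
    if data.ndim != 3:
        raise ValueError(f"{path}: cannot interpret array of shape {data.shape} as (z, y, x)")

    if voxel_size_override is not None:
        if meta_size is not None and not np.allclose(
            voxel_size_override, meta_size, rtol=1e-6
        ):
            warnings.warn(
                f"voxel-size override {voxel_size_override} differs from file "
                f"metadata {meta_size}; using the override",
                stacklevel=2,
            )
        voxel_size = voxel_size_override
    elif meta_size is not None:
        voxel_size = meta_size
    else:
        raise ValueError(
            f"{path} carries no voxel-size metadata; supply voxel_size_override "
            "(silent wrong-scale geometry is worse than an error)"
        )
    return VoxelGrid(data, voxel_size, channel_name=expected_channel)


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` as OME-TIFF with physical voxel sizes."""
    dz, dy, dx = grid.voxel_size
    tifffile.imwrite(
        Path(path),
        grid.data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
        },
    )


def write_report(report: AnalysisReport, path: str | Path) -> None:
    """Write the per-object table as CSV and the per-cell summary as JSON.

    ``path`` is the CSV path; the JSON sidecar gets the same stem with a
    ``.json`` suffix. Floats are written with full precision so that a
    read-back reproduces every numeric field exactly.
    """
    report.validate()
    path = Path(path)
    df = report.per_object.loc[:, list(AnalysisReport.COLUMNS)]
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".json")
    payload = {"per_cell": report.per_cell, "provenance": report.provenance}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_report(path: str | Path) -> AnalysisReport:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        df = df.astype(
            {
                "object_id": int,
                "x_um": float,
                "y_um": float,
                "z_um": float,
                "region_label": str,
                "integrated_intensity": float,
                "n_particles": int,
            },
            errors="ignore",
        )
    payload = json.loads(path.with_suffix(".json").read_text())
    return AnalysisReport(
        per_object=df,
        per_cell=payload["per_cell"],
        provenance=payload.get("provenance", {}),
    )


def _normalize_u8(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros(data.shape, dtype=np.uint8)
    return ((data - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def write_overlay(
    membrane: VoxelGrid,
    objects,
    regions,
    path: str | Path,
    colors: dict | None = None,
) -> np.ndarray:
    """Write an RGB stack: membrane shell in cyan, objects colored by region.

    Intracellular objects default to red (configurable, e.g. magenta),
    membrane-associated to yellow, extracellular to gray. Only voxels
    belonging to the shell or to object masks are colored; everything else
    stays black. Returns the RGB array that was written.
    """
    cmap = dict(DEFAULT_OVERLAY_COLORS)
    if colors:
        cmap.update(colors)
    rgb = np.zeros(membrane.shape + (3,), dtype=np.uint8)
    shell_intensity = _normalize_u8(membrane.data)
    shell_color = np.asarray(cmap["membrane_stain"], dtype=np.float64) / 255.0
    shell = regions.membrane_shell
    for c in range(3):
        rgb[..., c][shell] = (shell_intensity[shell] * shell_color[c]).astype(np.uint8)
    for obj in objects:
        if obj.voxel_indices is None:
            continue
        color = cmap.get(obj.region_label)
        if color is None:
            continue
        zz, yy, xx = obj.voxel_indices
        rgb[zz, yy, xx] = color
    tifffile.imwrite(Path(path), rgb, photometric="rgb")
    return rgb


def write_region_mask(regions, path: str | Path) -> None:
    """Export the three-region partition as an 8-bit TIFF (0/85/170 coding)."""
    out = np.zeros(regions.membrane_shell.shape, dtype=np.uint8)
    out[regions.membrane_shell] = REGION_MASK_CODES["membrane"]
    out[regions.intracellular] = REGION_MASK_CODES["intracellular"]
    tifffile.imwrite(Path(path), out)
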
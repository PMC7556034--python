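"""Readers, writers and run configuration.

CSV is the interchange format throughout (particle tables, area samples,
Lab coordinates, force curves, fit summaries); JSON holds structured fit
reports. Every CSV written here carries a header row whose column names
carry the units (mm2, N, N_mm).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .colordiff import LabColor
from .heavytail import FitReport
from .imaging import ImageGray, ParticleSet, rgb_to_gray
from .texture import ForceCurve

__all__ = [
    "RunConfig",
    "load_config",
    "read_image",
    "write_particles_csv",
    "read_areas_csv",
    "read_lab_csv",
    "read_force_curves",
    "reports_to_json",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a full pipeline run.

    Exactly one of ``dpi`` / ``pixel_pitch_um`` may be set explicitly;
    with neither, 400 dpi (63.5 um pitch) is assumed. ``roi_diameter_mm``
    of None disables the circular ROI.
    """

    dpi: float | None = None
    pixel_pitch_um: float | None = None
    roi_diameter_mm: float | None = None
    min_size_px: int = 2
    connectivity: int = 8
    polarity: str = "dark_foreground"
    min_tail_size: int = 10
    significance: float = 0.05
    k_L: float = 1.0
    k_C: float = 1.0
    k_H: float = 1.0
    contact_threshold_N: float = 0.05
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.dpi is not None and self.pixel_pitch_um is not None:
            raise ValueError("set exactly one of dpi / pixel_pitch_um, not both")
        if self.dpi is not None and not self.dpi > 0:
            raise ValueError("dpi must be positive")
        if self.pixel_pitch_um is not None and not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.roi_diameter_mm is not None and not self.roi_diameter_mm > 0:
            raise ValueError("roi_diameter_mm must be positive")
        if self.min_size_px < 0:
            raise ValueError("min_size_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.polarity not in ("dark_foreground", "light_foreground"):
            raise ValueError("polarity must be dark_foreground or light_foreground")
        if self.min_tail_size < 2:
            raise ValueError("min_tail_size must be >= 2")
        if not 0 < self.significance < 1:
            raise ValueError("significance must lie in (0, 1)")
        if self.contact_threshold_N < 0:
            raise ValueError("contact_threshold_N must be >= 0")

    @property
    def pitch_um(self) -> float:
        """Effective pixel pitch in micrometers (25400/dpi when dpi-based)."""
        if self.pixel_pitch_um is not None:
            return self.pixel_pitch_um
        dpi = self.dpi if self.dpi is not None else 400.0
        return 25400.0 / dpi


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config file; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def read_image(path: str | Path, pixel_pitch_um: float) -> ImageGray:
    """Read an 8-bit PNG/TIFF/JPEG as a calibrated grayscale image."""
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            arr = np.asarray(im.convert("RGB"))
            return rgb_to_gray(arr, pixel_pitch_um=pixel_pitch_um)
        arr = np.asarray(im.convert("L"))
    return ImageGray(arr, pixel_pitch_um)


def write_particles_csv(path: str | Path, particle_sets: Iterable[ParticleSet]) -> None:
    rows = [
        {
            "image_id": ps.image_id,
            "label": p.label,
            "area_px": p.area_px,
            "area_mm2": p.area_mm2,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
        }
        for ps in particle_sets
        for p in ps.particles
    ]
    pd.DataFrame(rows, columns=["image_id", "label", "area_px", "area_mm2",
                                "centroid_row", "centroid_col"]).to_csv(path, index=False)


def read_areas_csv(path: str | Path, area_column: str = "area_mm2",
                   group_column: str | None = None) -> pd.DataFrame:
    """Read an area table (e.g. a particle CSV); keeps id/group columns."""
    df = pd.read_csv(path)
    if area_column not in df.columns:
        raise ValueError(f"{path}: missing column {area_column!r}")
    if group_column is not None and group_column not in df.columns:
        raise ValueError(f"{path}: missing group column {group_column!r}")
    return df


def read_lab_csv(path: str | Path) -> dict[str, LabColor]:
    """Read named CIELAB coordinates from columns name, L, a, b."""
    df = pd.read_csv(path)
    required = {"name", "L", "a", "b"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: Lab CSV needs columns {sorted(required)}")
    if df["name"].duplicated().any():
        raise ValueError(f"{path}: duplicate color names")
    return {str(r["name"]): LabColor(float(r.L), float(r.a), float(r.b))
            for _, r in df.iterrows()}


def read_force_curves(path: str | Path) -> list[ForceCurve]:
    """Read puncture curves from CSV.

    Either one curve per file (columns distance_mm, force_N) or long
    format with an extra curve_id column.
    """
    df = pd.read_csv(path)
    if not {"distance_mm", "force_N"}.issubset(df.columns):
        raise ValueError(f"{path}: force CSV needs columns distance_mm, force_N")
    if "curve_id" in df.columns:
        return [ForceCurve(g["distance_mm"].to_numpy(), g["force_N"].to_numpy(),
                           curve_id=str(cid))
                for cid, g in df.groupby("curve_id", sort=False)]
    return [ForceCurve(df["distance_mm"].to_numpy(), df["force_N"].to_numpy(),
                       curve_id=Path(path).stem)]


def _report_dict(r: FitReport) -> dict[str, Any]:
    return {
        "sample_id": r.sample_id,
        "group": r.group,
        "n": r.n,
        "total_area_mm2": r.total_area_mm2,
        "lognormal": dataclasses.asdict(r.lognormal),
        "powerlaw": dataclasses.asdict(r.powerlaw),
    }


def reports_to_json(path: str | Path, reports: Iterable[FitReport],
                    meta: Mapping[str, Any] | None = None) -> None:
    """Write fit reports (plus optional run metadata) as JSON."""
    payload = {"meta": dict(meta or {}), "reports": [_report_dict(r) for r in reports]}
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
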
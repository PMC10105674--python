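"""Domain containers shared across the pipeline.

JSON-facing records (annotations, perfusion records, configuration) are
pydantic models so schema violations fail with field-level messages;
array-bearing containers (micrographs, masks) are plain dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from shapely.geometry import Polygon

from .geometry import GeometryError, validate_polygon

Polarity = Literal["brightfield_dark_label", "fluorescence_bright_label"]

SCHEMA_VERSION = 1


@dataclass
class Micrograph:
    """2-D grayscale intensity raster with explicit signal polarity.

    ``polarity`` states whether label darkens (brightfield DAB) or brightens
    (fluorescence) pixels relative to background; it is never inferred from
    the data.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    polarity: Polarity = "brightfield_dark_label"
    pixel_scale: Optional[float] = None  # physical length per pixel, optional

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("micrograph must be a 2-D array")
        hi = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > hi:
            raise ValueError(f"intensities outside [0, {hi}] for bit depth {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


class CellAnnotation(BaseModel):
    """Manually circumscribed cell with nucleus and apico-basal axis.

    Coordinates are 0-based pixel coordinates, x = column, y = row.  The axis
    is directed from the apical (lumen-side) edge to the basolateral edge.
    """

    model_config = ConfigDict(frozen=True)

    cell_id: str
    polygon: list[tuple[float, float]]
    nucleus: list[tuple[float, float]]
    axis: tuple[tuple[float, float], tuple[float, float]]
    animal_id: str = "unknown"
    segment: Literal["CCD", "CNT"] = "CCD"
    group: str = "unknown"

    @field_validator("polygon", "nucleus")
    @classmethod
    def _simple_polygon(cls, v):
        validate_polygon(v)
        return v

    @model_validator(mode="after")
    def _nucleus_inside_cell(self):
        cell = Polygon(self.polygon)
        nuc = Polygon(self.nucleus)
        if not cell.covers(nuc):
            raise ValueError(f"cell {self.cell_id}: nucleus polygon not contained in cell polygon")
        a, b = np.asarray(self.axis[0]), np.asarray(self.axis[1])
        if np.allclose(a, b):
            raise ValueError(f"cell {self.cell_id}: degenerate apico-basal axis")
        return self


class AnnotationFile(BaseModel):
    """On-disk annotation schema: one background ROI plus annotated cells."""

    schema_version: int = SCHEMA_VERSION
    background: list[tuple[float, float]]
    cells: list[CellAnnotation]

    @field_validator("background")
    @classmethod
    def _valid_bg(cls, v):
        validate_polygon(v)
        return v


@dataclass
class CellIntensityResult:
    """Per-cell immunolabel quantification (areas in pixels, label in a.u.)."""

    cell_id: str
    animal_id: str
    segment: str
    group: str
    cell_area_px: int
    nuclear_area_px: int
    cytoplasmic_area_px: int
    net_label_cell: float
    net_label_cytoplasm: float
    redistribution_ratio: float  # NaN when total label is not positive
    cell_height_px: float
    zonal_profile: np.ndarray = field(default_factory=lambda: np.array([]))


class GoldCellRecord(BaseModel):
    """Immunogold EM cell profile: traced apical membrane, cell outline and
    gold particle coordinates, all in pixels at ``scale_nm_per_px``."""

    model_config = ConfigDict(frozen=True)

    cell_id: str
    apical_polyline: list[tuple[float, float]]
    cell_polygon: list[tuple[float, float]]
    particles: list[tuple[float, float]] = Field(default_factory=list)
    scale_nm_per_px: float = Field(gt=0)
    cell_type: Literal["type_B", "non_A_non_B"] = "type_B"
    animal_id: str = "unknown"
    group: str = "unknown"

    @field_validator("cell_polygon")
    @classmethod
    def _simple(cls, v):
        validate_polygon(v)
        return v

    @field_validator("apical_polyline")
    @classmethod
    def _polyline(cls, v):
        arr = np.asarray(v, dtype=float)
        if len(arr) < 2 or np.allclose(arr, arr[0]):
            raise ValueError("apical polyline needs >= 2 distinct vertices")
        return v

    @field_validator("particles")
    @classmethod
    def _finite(cls, v):
        if v and not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValueError("particle coordinates must be finite")
        return v


@dataclass
class GoldCellMetrics:
    """Per-cell immunogold morphometry (Au = gold particles)."""

    cell_id: str
    animal_id: str
    group: str
    cell_type: str
    boundary_length_mm: float
    apical_au: int
    cytoplasmic_au: int
    discarded_au: int
    total_au: int
    apical_to_cytoplasmic_ratio: float  # NaN when cytoplasmic_au == 0
    au_per_mm_boundary: float


class CalibrationCurve(BaseModel):
    """Stern-Volmer quenching calibration: F0 / F = 1 + K_sv [Cl-]."""

    F0: float = Field(gt=0)
    K_sv: float = Field(gt=0)  # 1/mM
    residual_sd: float = Field(ge=0)


class Collection(BaseModel):
    collected_F: float = Field(gt=0)
    rate_nl_min: float = Field(gt=0)
    duration_min: float = Field(default=1.0, gt=0)


class PerfusionRecord(BaseModel):
    """One perfused-tubule experiment: calibration standards, perfusate and
    collected-sample fluorescence, collection rates and tubule length."""

    tubule_id: str = "t1"
    standards: list[tuple[float, float]]  # (Cl mM, fluorescence a.u.)
    perfusate_F: float = Field(gt=0)
    collections: list[Collection]
    tubule_length_mm: float = Field(gt=0)
    animal_id: str = "unknown"
    group: str = "unknown"

    @field_validator("standards")
    @classmethod
    def _standards(cls, v):
        if len(v) < 3:
            raise ValueError("need >= 3 calibration standards")
        return v


@dataclass
class FluxEstimate:
    """Net transepithelial Cl- flux, pmol/min per mm tubule (positive = absorption)."""

    tubule_id: str
    animal_id: str
    group: str
    per_collection: np.ndarray
    mean: float
    se: float
    perfusate_cl_mM: float
    flags: list[str] = field(default_factory=list)


class BlotLane(BaseModel):
    """One immunoblot lane: target band density plus loading references."""

    lane_id: str
    animal_id: str = "unknown"
    group: str = "unknown"
    band_density: float = Field(ge=0)
    coomassie_density: float = Field(gt=0)
    actin_density: Optional[float] = Field(default=None, ge=0)


__all__ = [
    "AnnotationFile",
    "BlotLane",
    "CalibrationCurve",
    "CellAnnotation",
    "CellIntensityResult",
    "Collection",
    "FluxEstimate",
    "GeometryError",
    "GoldCellMetrics",
    "GoldCellRecord",
    "Micrograph",
    "PerfusionRecord",
    "Polarity",
    "SCHEMA_VERSION",
]
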
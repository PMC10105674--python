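"""Synthetic data generators with known ground truth.

Each generator emulates the statistical structure one analysis stage assumes
— not realistic histology:

* ``synth_micrograph`` — a brightfield DAB-style scene: one annotated cell
  whose label darkens pixels below a uniform background, with an apically
  graded axial label profile (uniform / linear / exponential) whose apical
  band fraction has a closed form, plus an unlabeled background ROI.
* ``synth_gold_cell`` — homogeneous Poisson gold point patterns: a linear
  density (particles per µm) along the apical membrane trace and an areal
  density (particles per µm²) in the cytoplasm.
* ``synth_perfusion`` — an isolated perfused tubule read out by SPQ
  fluorimetry: collected [Cl-] from the flux balance, Stern-Volmer quenching,
  multiplicative (CV) fluorimeter noise.
* ``synth_blot`` — immunoblot lanes with lognormal loading variation and
  multiplicative densitometry noise.

A single integer seed fully determines every artifact; generators never touch
global random state.  All noise models are simple stand-ins (the real raw
data were never deposited) and are labeled as such in the truth sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from shapely.geometry import LineString, Polygon

from .geometry import polygon_mask, polyline_length, validate_polygon
from .types import BlotLane, CellAnnotation, Collection, GoldCellRecord, Micrograph, PerfusionRecord

__all__ = [
    "SynthImageTruth",
    "SynthGoldTruth",
    "SynthPerfusionTruth",
    "SynthMicrograph",
    "SynthGoldCell",
    "SynthPerfusion",
    "SynthBlot",
    "synth_micrograph",
    "synth_gold_cell",
    "synth_perfusion",
    "synth_blot",
]


# ---------------------------------------------------------------------------
# micrographs


class SynthImageTruth(BaseModel):
    """Ground truth for one synthetic brightfield micrograph.

    The label's axial density runs from the apical (t = 0) to the basolateral
    (t = 1) end of the cell; ``apical_fraction_true`` is the closed-form
    fraction of total label in the most apical ``apical_fraction`` of cell
    height.  ``label_total`` is the integrated net label over the cytoplasm
    (cell minus nucleus) of the noiseless image, in intensity a.u.
    """

    model_config = ConfigDict(frozen=True)

    background_level: float = Field(default=200.0, gt=0)
    label_total: float = Field(default=1.0e5, ge=0)
    gradient_shape: Literal["uniform", "linear", "exponential"] = "linear"
    shape_param: float = Field(default=0.3, gt=0)  # exponential decay length, axial units
    apical_fraction: float = Field(default=0.10, gt=0, le=1)
    noise_sd: float = Field(default=0.0, ge=0)
    seed: int = 0
    # scene geometry (pixels); cell is an axis-aligned rectangle, apex at top
    image_shape: tuple[int, int] = (128, 168)
    cell_rect: tuple[int, int, int, int] = (60, 10, 100, 110)  # x0, y0, x1, y1
    nucleus_rect: tuple[int, int, int, int] = (68, 60, 92, 86)
    background_rect: tuple[int, int, int, int] = (8, 10, 52, 110)
    bit_depth: int = 8

    @model_validator(mode="after")
    def _geometry_in_frame(self):
        h, w = self.image_shape
        for name, (x0, y0, x1, y1) in (
            ("cell", self.cell_rect),
            ("nucleus", self.nucleus_rect),
            ("background ROI", self.background_rect),
        ):
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"{name} rectangle {x0, y0, x1, y1} exceeds the image frame")
        cx0, cy0, cx1, cy1 = self.cell_rect
        nx0, ny0, nx1, ny1 = self.nucleus_rect
        if not (cx0 < nx0 and nx1 < cx1 and cy0 < ny0 and ny1 < cy1):
            raise ValueError("nucleus rectangle must lie strictly inside the cell rectangle")
        return self

    @property
    def apical_fraction_true(self) -> float:
        """Closed-form fraction of label in the apical band for this shape."""
        f = self.apical_fraction
        if self.gradient_shape == "uniform":
            return f
        if self.gradient_shape == "linear":  # density 0 at base, max at apex
            return 1.0 - (1.0 - f) ** 2
        tau = self.shape_param
        return float((1.0 - np.exp(-f / tau)) / (1.0 - np.exp(-1.0 / tau)))

    def axial_density(self, t: np.ndarray) -> np.ndarray:
        """Unnormalized label density at axial position t in [0, 1] (0 = apex)."""
        if self.gradient_shape == "uniform":
            return np.ones_like(t)
        if self.gradient_shape == "linear":
            return 1.0 - t
        return np.exp(-t / self.shape_param)


def _rect_polygon(rect) -> list[tuple[float, float]]:
    x0, y0, x1, y1 = rect
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


@dataclass
class SynthMicrograph:
    image: Micrograph
    annotation: CellAnnotation
    background_roi: list[tuple[float, float]]
    truth: SynthImageTruth
    apical_fraction_true: float
    label_total: float


def synth_micrograph(truth: SynthImageTruth) -> SynthMicrograph:
    """Render a brightfield micrograph with a single labeled, annotated cell.

    Label is encoded as ``background_level - amplitude * density(t)`` (darker
    = more label, DAB convention) over the whole cell including the nucleus;
    the amplitude is set so the noiseless cytoplasmic net label integrates to
    exactly ``truth.label_total``.  Additive Gaussian pixel noise of SD
    ``noise_sd`` is applied everywhere, and pixels are clipped to the bit
    depth's range.
    """
    h, w = truth.image_shape
    cell_poly = _rect_polygon(truth.cell_rect)
    nuc_poly = _rect_polygon(truth.nucleus_rect)
    bg_poly = _rect_polygon(truth.background_rect)
    x0, y0, x1, y1 = truth.cell_rect
    apex = ((x0 + x1) / 2.0, float(y0))
    base = ((x0 + x1) / 2.0, float(y1))

    img = np.full((h, w), truth.background_level, dtype=float)
    cell_mask = polygon_mask(cell_poly, (h, w))
    nuc_mask = polygon_mask(nuc_poly, (h, w))
    if truth.label_total > 0:
        rows, cols = np.nonzero(cell_mask)
        t = (rows + 0.5 - y0) / (y1 - y0)
        dens = truth.axial_density(t)
        cyto = ~nuc_mask[rows, cols]
        denom = float(dens[cyto].sum())
        if denom <= 0:
            raise ValueError("cytoplasm carries no label density")
        amp = truth.label_total / denom
        if amp * dens.max() > truth.background_level:
            raise ValueError(
                "label_total too large for the dynamic range: peak label "
                f"{amp * dens.max():.1f} exceeds background {truth.background_level}"
            )
        img[rows, cols] -= amp * dens
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 2**truth.bit_depth - 1)

    ann = CellAnnotation(
        cell_id=f"synth-{truth.seed}",
        polygon=cell_poly,
        nucleus=nuc_poly,
        axis=(apex, base),
        animal_id="synthetic",
        segment="CCD",
        group="synthetic",
    )
    return SynthMicrograph(
        image=Micrograph(pixels=img, bit_depth=truth.bit_depth, polarity="brightfield_dark_label"),
        annotation=ann,
        background_roi=bg_poly,
        truth=truth,
        apical_fraction_true=truth.apical_fraction_true,
        label_total=truth.label_total,
    )


# ---------------------------------------------------------------------------
# immunogold point patterns


class SynthGoldTruth(BaseModel):
    """Poisson ground truth for one immunogold cell profile.

    ``lambda_membrane`` is a linear density (Au per µm of traced membrane),
    ``lambda_cytoplasm`` an areal density (Au per µm² of cell profile).
    Membrane particles are jittered perpendicular to the trace by at most
    half the association threshold, and cytoplasmic particles keep at least
    twice the threshold clear of the trace, so classification at the default
    threshold is unambiguous.
    """

    model_config = ConfigDict(frozen=True)

    lambda_membrane: float = Field(default=12.0, ge=0)  # Au / µm
    lambda_cytoplasm: float = Field(default=2.5, ge=0)  # Au / µm²
    scale_nm_per_px: float = Field(default=4.0, gt=0)
    membrane_threshold_nm: float = Field(default=25.0, gt=0)
    cell_polygon: Optional[list[tuple[float, float]]] = None  # px; default 800x800 square
    apical_polyline: Optional[list[tuple[float, float]]] = None  # px; default top edge
    cell_type: Literal["type_B", "non_A_non_B"] = "non_A_non_B"
    seed: int = 0

    @model_validator(mode="after")
    def _geometry(self):
        if self.cell_polygon is not None:
            validate_polygon(self.cell_polygon)
        if self.apical_polyline is not None:
            polyline_length(self.apical_polyline)
        return self

    def resolved_geometry(self):
        poly = self.cell_polygon or [(100.0, 100.0), (900.0, 100.0), (900.0, 900.0), (100.0, 900.0)]
        line = self.apical_polyline or [(100.0, 100.0), (900.0, 100.0)]
        return poly, line


@dataclass
class SynthGoldCell:
    record: GoldCellRecord
    truth: SynthGoldTruth
    true_membrane_count: int
    true_cytoplasm_count: int
    boundary_length_um: float
    cell_area_um2: float


def synth_gold_cell(truth: SynthGoldTruth) -> SynthGoldCell:
    """Draw one Poisson gold point pattern on a cell profile.

    Membrane count ~ Poisson(lambda_membrane x boundary length); positions
    uniform along the trace's arc length with bounded perpendicular jitter.
    Cytoplasm count ~ Poisson(lambda_cytoplasm x profile area); positions
    uniform in the polygon, re-drawn while they fall within twice the
    association threshold of the trace.
    """
    rng = np.random.default_rng(truth.seed)
    poly_v, line_v = truth.resolved_geometry()
    nm_per_px = truth.scale_nm_per_px
    line = np.asarray(line_v, dtype=float)
    length_px = polyline_length(line_v)
    length_um = length_px * nm_per_px / 1000.0
    shp_poly = Polygon(poly_v)
    area_um2 = shp_poly.area * (nm_per_px / 1000.0) ** 2

    particles: list[tuple[float, float]] = []

    n_mem = int(rng.poisson(truth.lambda_membrane * length_um))
    if n_mem > 0:
        seg = np.diff(line, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        u = rng.uniform(0.0, cum[-1], size=n_mem)
        idx = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(seg) - 1)
        frac = (u - cum[idx]) / seg_len[idx]
        pos = line[idx] + frac[:, None] * seg[idx]
        tang = seg[idx] / seg_len[idx, None]
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        jitter_px = truth.membrane_threshold_nm / 2.0 / nm_per_px
        pos = pos + rng.uniform(-jitter_px, jitter_px, size=n_mem)[:, None] * normal
        particles.extend(map(tuple, pos))

    n_cyt = int(rng.poisson(truth.lambda_cytoplasm * area_um2))
    if n_cyt > 0:
        import shapely

        shp_line = LineString(line_v)
        clear_px = 2.0 * truth.membrane_threshold_nm / nm_per_px
        minx, miny, maxx, maxy = shp_poly.bounds
        kept = np.empty((0, 2))
        while len(kept) < n_cyt:
            cand = rng.uniform((minx, miny), (maxx, maxy), size=(4 * n_cyt, 2))
            cand_pts = shapely.points(cand)
            ok = shapely.covers(shp_poly, cand_pts) & (
                shapely.distance(cand_pts, shp_line) > clear_px
            )
            kept = np.vstack([kept, cand[ok]])
        particles.extend(map(tuple, kept[:n_cyt]))

    record = GoldCellRecord(
        cell_id=f"synth-{truth.seed}",
        apical_polyline=[tuple(v) for v in line_v],
        cell_polygon=[tuple(v) for v in poly_v],
        particles=particles,
        scale_nm_per_px=nm_per_px,
        cell_type=truth.cell_type,
        animal_id="synthetic",
        group="synthetic",
    )
    return SynthGoldCell(
        record=record,
        truth=truth,
        true_membrane_count=n_mem,
        true_cytoplasm_count=n_cyt,
        boundary_length_um=length_um,
        cell_area_um2=area_um2,
    )


# ---------------------------------------------------------------------------
# microperfusion / SPQ fluorimetry


class SynthPerfusionTruth(BaseModel):
    """Ground truth for one simulated perfused tubule.

    Defaults follow the experimental conditions the analysis assumes: a
    perfusate of 129 mM Cl- (125 NaCl + 2 CaCl2), collection rates in the
    2-3 nl/min range, millimeter-scale tubules, and an SPQ quenching constant
    of 0.118 /mM.
    """

    model_config = ConfigDict(frozen=True)

    J_true: float = 25.0  # pmol/min/mm, positive = absorption
    C_perfusate: float = Field(default=129.0, gt=0)  # mM
    collection_rate: float = Field(default=2.5, ge=1.0, le=6.0)  # nl/min
    tubule_length: float = Field(default=1.0, gt=0)  # mm
    K_sv: float = Field(default=0.118, gt=0)  # 1/mM
    F0: float = Field(default=1000.0, gt=0)
    cv_noise: float = Field(default=0.02, ge=0, lt=0.3)
    seed: int = 0

    @model_validator(mode="after")
    def _collected_positive(self):
        if self.J_true * self.tubule_length / self.collection_rate >= self.C_perfusate:
            raise ValueError(
                "J_true x length / rate must stay below the perfusate Cl- concentration"
            )
        return self

    def quench(self, cl_mM: np.ndarray | float) -> np.ndarray | float:
        """Noiseless Stern-Volmer fluorescence at a given [Cl-]."""
        return self.F0 / (1.0 + self.K_sv * np.asarray(cl_mM, dtype=float))


@dataclass
class SynthPerfusion:
    record: PerfusionRecord
    truth: SynthPerfusionTruth
    collected_cl_true: float


def synth_perfusion(truth: SynthPerfusionTruth, n_collections: int = 4) -> SynthPerfusion:
    """Simulate one SPQ-read perfused tubule.

    Collected [Cl-] follows the flux balance C_c = C_p - J L / V_dot; all
    fluorescences (standards, perfusate, collections) carry multiplicative
    Gaussian noise with coefficient of variation ``cv_noise``.
    """
    if n_collections < 1:
        raise ValueError("need at least one collection")
    rng = np.random.default_rng(truth.seed)
    c_coll = truth.C_perfusate - truth.J_true * truth.tubule_length / truth.collection_rate

    levels = np.linspace(0.0, max(150.0, 1.2 * truth.C_perfusate), 7)
    f_std = np.asarray(truth.quench(levels), dtype=float)
    f_perf = float(truth.quench(truth.C_perfusate))
    f_coll = np.full(n_collections, float(truth.quench(c_coll)))
    if truth.cv_noise > 0:
        noisy = lambda f: np.maximum(f * (1.0 + rng.normal(0.0, truth.cv_noise, np.shape(f))), 1e-9)
        f_std = noisy(f_std)
        f_perf = float(noisy(f_perf))
        f_coll = noisy(f_coll)

    record = PerfusionRecord(
        tubule_id=f"synth-{truth.seed}",
        standards=list(zip(levels.tolist(), np.atleast_1d(f_std).tolist())),
        perfusate_F=f_perf,
        collections=[
            Collection(collected_F=float(f), rate_nl_min=truth.collection_rate, duration_min=5.0)
            for f in np.atleast_1d(f_coll)
        ],
        tubule_length_mm=truth.tubule_length,
        animal_id="synthetic",
        group="synthetic",
    )
    return SynthPerfusion(record=record, truth=truth, collected_cl_true=c_coll)


# ---------------------------------------------------------------------------
# immunoblots


def synth_blot(
    true_abundances: dict[str, list[float]],
    loading_cv: float = 0.2,
    seed: int = 0,
    density_cv: float = 0.05,
    coomassie_constant: float = 1000.0,
    band_gain: float = 500.0,
    with_actin: bool = True,
    actin_constant: float = 800.0,
) -> tuple[list[BlotLane], pd.DataFrame]:
    """Simulate an immunoblot lane table from per-group true abundances.

    Each lane gets a lognormal loading factor with coefficient of variation
    ``loading_cv`` (mean 1); band density = abundance x loading x gain,
    total-protein (Coomassie) density = loading x constant, each perturbed by
    multiplicative measurement noise with CV ``density_cv``.  With both CVs
    zero, Coomassie-normalized densities equal true abundances up to one
    global constant.
    """
    if loading_cv < 0 or density_cv < 0:
        raise ValueError("CVs must be >= 0")
    rng = np.random.default_rng(seed)
    lanes: list[BlotLane] = []
    if loading_cv > 0:
        sigma = float(np.sqrt(np.log1p(loading_cv**2)))
    else:
        sigma = 0.0

    def meas(x: float) -> float:
        if density_cv == 0:
            return x
        return max(x * (1.0 + rng.normal(0.0, density_cv)), 0.0)

    i = 0
    for group, values in true_abundances.items():
        for abundance in values:
            if abundance < 0:
                raise ValueError("abundances must be >= 0")
            load = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
            lanes.append(
                BlotLane(
                    lane_id=f"lane{i:02d}",
                    animal_id=f"a{i:02d}",
                    group=group,
                    band_density=meas(abundance * load * band_gain),
                    coomassie_density=max(meas(load * coomassie_constant), 1e-9),
                    actin_density=meas(load * actin_constant) if with_actin else None,
                )
            )
            i += 1
    truth = pd.DataFrame(
        [(g, v) for g, vals in true_abundances.items() for v in vals],
        columns=["group", "true_abundance"],
    )
    return lanes, truth
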
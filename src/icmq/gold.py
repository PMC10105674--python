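"""Immunogold morphometry: apical membrane boundary length, membrane vs
cytoplasmic particle classification, per-cell metrics and per-animal pooling.

A gold particle is scored as apical when its minimum distance to the traced
apical membrane polyline is at or below the membrane-association threshold
(default 25 nm, a conventional antibody-bridge distance for colloidal gold);
otherwise it is cytoplasmic if it lies inside the cell outline, else
discarded.  Precedence is apical > cytoplasmic so each particle is counted
exactly once.  Statistics downstream use the animal, not the cell, as the
experimental unit: raw per-cell metrics are pooled to one mean per animal.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict

import numpy as np
import pandas as pd

from .geometry import min_distance_to_polyline, points_in_polygon, polyline_length, validate_polygon
from .types import GoldCellMetrics, GoldCellRecord

DEFAULT_MEMBRANE_THRESHOLD_NM = 25.0
NM_PER_MM = 1e6

__all__ = [
    "DEFAULT_MEMBRANE_THRESHOLD_NM",
    "boundary_length",
    "classify_gold",
    "cell_gold_metrics",
    "pool_by_animal",
]


def boundary_length(polyline, scale_nm_per_px: float) -> float:
    """Traced apical membrane length in mm (Table-style convention: mm x 1e-2
    is just this value x 100)."""
    if scale_nm_per_px <= 0:
        raise ValueError("scale_nm_per_px must be > 0")
    return polyline_length(polyline) * scale_nm_per_px / NM_PER_MM


def classify_gold(
    record: GoldCellRecord, membrane_threshold_nm: float = DEFAULT_MEMBRANE_THRESHOLD_NM
) -> tuple[int, int, int]:
    """Count (apical, cytoplasmic, discarded) gold particles for one cell.

    Distances are computed in nm via the record's pixel scale; particles
    outside the cell outline and beyond the membrane threshold are discarded,
    never silently dropped from the total.
    """
    if membrane_threshold_nm < 0:
        raise ValueError("membrane threshold must be >= 0")
    validate_polygon(record.cell_polygon)
    if not record.particles:
        return 0, 0, 0
    pts = np.asarray(record.particles, dtype=float)
    dist_nm = min_distance_to_polyline(pts, record.apical_polyline) * record.scale_nm_per_px
    apical = dist_nm <= membrane_threshold_nm
    inside = points_in_polygon(pts, np.asarray(record.cell_polygon, dtype=float))
    cytoplasmic = ~apical & inside
    n_ap = int(apical.sum())
    n_cy = int(cytoplasmic.sum())
    return n_ap, n_cy, len(pts) - n_ap - n_cy


def cell_gold_metrics(
    record: GoldCellRecord, membrane_threshold_nm: float = DEFAULT_MEMBRANE_THRESHOLD_NM
) -> GoldCellMetrics:
    """Per-cell immunogold metrics mirroring the standard morphometry table:
    boundary length, apical and cytoplasmic Au counts, their ratio, and Au per
    mm of membrane.  The ratio is NaN (flagged undefined) when the cytoplasmic
    count is zero."""
    n_ap, n_cy, n_disc = classify_gold(record, membrane_threshold_nm)
    blen = boundary_length(record.apical_polyline, record.scale_nm_per_px)
    ratio = n_ap / n_cy if n_cy > 0 else float("nan")
    return GoldCellMetrics(
        cell_id=record.cell_id,
        animal_id=record.animal_id,
        group=record.group,
        cell_type=record.cell_type,
        boundary_length_mm=blen,
        apical_au=n_ap,
        cytoplasmic_au=n_cy,
        discarded_au=n_disc,
        total_au=n_ap + n_cy,
        apical_to_cytoplasmic_ratio=ratio,
        au_per_mm_boundary=n_ap / blen,
    )


def pool_by_animal(
    cells, min_cells: int = 5, by: tuple[str, ...] = ("animal_id", "group")
) -> tuple[pd.DataFrame, list[str]]:
    """Pool per-cell metrics to one arithmetic mean per animal.

    ``cells`` is a list of metric dataclasses (GoldCellMetrics or
    CellIntensityResult) or an equivalent DataFrame.  Animals contributing
    fewer than ``min_cells`` cells are flagged with a warning (the mean is
    still computed).  Returns ``(per-animal DataFrame, warnings)``; downstream
    n is the number of animals.
    """
    if isinstance(cells, pd.DataFrame):
        df = cells.copy()
    else:
        cells = list(cells)
        if not cells:
            raise ValueError("no cells to pool")
        df = pd.DataFrame([asdict(c) if not isinstance(c, dict) else c for c in cells])
    if df.empty:
        raise ValueError("no cells to pool")
    df = df.drop(columns=[c for c in ("zonal_profile",) if c in df.columns])
    keys = [k for k in by if k in df.columns]
    if "animal_id" not in keys:
        raise ValueError("records must carry an animal_id")
    numeric = df.select_dtypes(include=[np.number]).columns.tolist()
    grouped = df.groupby(keys, sort=True, dropna=False)
    pooled = grouped[numeric].mean().reset_index()
    pooled["n_cells"] = grouped.size().to_numpy()
    msgs = []
    for _, row in pooled.iterrows():
        if row["n_cells"] < min_cells:
            msg = (
                f"animal {row['animal_id']}: only {int(row['n_cells'])} cells pooled "
                f"(fewer than {min_cells})"
            )
            msgs.append(msg)
            warnings.warn(msg, stacklevel=2)
    return pooled, msgs
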
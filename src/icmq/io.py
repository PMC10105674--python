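"""File I/O: TIFF micrographs, annotation JSON, record CSV/JSON tables.

CSV dialect everywhere: UTF-8, comma separator, header row, '.' decimal.
Annotation JSON carries a ``schema_version`` field; validation errors surface
pydantic's field-level messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import AnnotationFile, BlotLane, Collection, GoldCellRecord, Micrograph, PerfusionRecord


def write_micrograph(path, img: Micrograph) -> None:
    tifffile.imwrite(str(path), img.pixels.astype(np.float32))


def read_micrograph(path, polarity: str = "brightfield_dark_label", bit_depth: int | None = None) -> Micrograph:
    """Read a grayscale TIFF.  Polarity is caller-supplied, never inferred."""
    arr = tifffile.imread(str(path)).astype(float)
    if bit_depth is None:
        bit_depth = 16 if arr.max() > 255 else 8
    return Micrograph(pixels=arr, bit_depth=bit_depth, polarity=polarity)  # type: ignore[arg-type]


def write_annotations(path, ann: AnnotationFile) -> None:
    Path(path).write_text(ann.model_dump_json(indent=2))


def read_annotations(path) -> AnnotationFile:
    """Read and validate an annotation file (background ROI + cells)."""
    return AnnotationFile.model_validate_json(Path(path).read_text())


def write_gold_record(path, rec: GoldCellRecord) -> None:
    Path(path).write_text(rec.model_dump_json(indent=2))


def read_gold_record(path) -> GoldCellRecord:
    return GoldCellRecord.model_validate_json(Path(path).read_text())


def read_gold_csvs(particles_csv, geometry_csv, scale_nm_per_px: float, **meta) -> list[GoldCellRecord]:
    """Assemble gold records from two CSVs.

    ``particles_csv``: cell_id,x,y.  ``geometry_csv``: cell_id,role,vertex_index,x,y
    with role in {membrane, cell}; vertices are ordered by vertex_index.
    """
    parts = pd.read_csv(particles_csv)
    geom = pd.read_csv(geometry_csv)
    records = []
    for cell_id, g in geom.groupby("cell_id", sort=True):
        g = g.sort_values("vertex_index")
        line = g[g["role"] == "membrane"][["x", "y"]].to_numpy(float)
        poly = g[g["role"] == "cell"][["x", "y"]].to_numpy(float)
        pts = parts[parts["cell_id"] == cell_id][["x", "y"]].to_numpy(float)
        records.append(
            GoldCellRecord(
                cell_id=str(cell_id),
                apical_polyline=[tuple(v) for v in line],
                cell_polygon=[tuple(v) for v in poly],
                particles=[tuple(v) for v in pts],
                scale_nm_per_px=scale_nm_per_px,
                **meta,
            )
        )
    return records


def read_perfusion_csvs(standards_csv, collections_csv) -> list[PerfusionRecord]:
    """Assemble perfusion records from a shared standards CSV (cl_mM,F) and a
    per-collection CSV (tubule_id,animal,group,perfusate_F,F,rate_nl_min,
    length_mm,duration_min)."""
    std = pd.read_csv(standards_csv)
    coll = pd.read_csv(collections_csv)
    standards = list(zip(std["cl_mM"].astype(float), std["F"].astype(float)))
    records = []
    for tid, g in coll.groupby("tubule_id", sort=True):
        records.append(
            PerfusionRecord(
                tubule_id=str(tid),
                standards=standards,
                perfusate_F=float(g["perfusate_F"].iloc[0]),
                collections=[
                    Collection(
                        collected_F=float(r["F"]),
                        rate_nl_min=float(r["rate_nl_min"]),
                        duration_min=float(r.get("duration_min", 1.0)),
                    )
                    for _, r in g.iterrows()
                ],
                tubule_length_mm=float(g["length_mm"].iloc[0]),
                animal_id=str(g["animal"].iloc[0]),
                group=str(g["group"].iloc[0]),
            )
        )
    return records


def read_blot_csv(path) -> list[BlotLane]:
    df = pd.read_csv(path)
    return [BlotLane(**{k: v for k, v in row.items() if pd.notna(v)}) for row in df.to_dict("records")]


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
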
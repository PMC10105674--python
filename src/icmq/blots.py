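"""Immunoblot densitometry: total-protein (Coomassie) normalization and
group-relative abundance.

Band densities are normalized lane-wise to the Coomassie total-protein signal
of the same lane, which cancels loading differences; normalized densities are
then expressed relative to the mean of a control group so the control maps to
1.0.  Actin densities, when present, are carried through as a loading
cross-check but never used as the normalization denominator.
"""

from __future__ import annotations

import pandas as pd

from .types import BlotLane

__all__ = ["normalize_lane", "relative_to_control", "lanes_to_frame"]


def normalize_lane(lane: BlotLane) -> float:
    """Band density normalized to the lane's Coomassie density (unitless)."""
    if lane.coomassie_density <= 0:
        raise ValueError(f"lane {lane.lane_id}: Coomassie density must be > 0")
    return lane.band_density / lane.coomassie_density


def lanes_to_frame(lanes) -> pd.DataFrame:
    """Tabulate BlotLane records with their Coomassie-normalized densities."""
    lanes = list(lanes)
    if not lanes:
        raise ValueError("no lanes")
    rows = []
    for lane in lanes:
        row = lane.model_dump()
        row["normalized_density"] = normalize_lane(lane)
        if lane.actin_density is not None:
            row["actin_normalized"] = lane.band_density / lane.actin_density if lane.actin_density > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def relative_to_control(lanes, control_group: str) -> pd.DataFrame:
    """Per-lane normalized densities relative to the control-group mean.

    The control group's mean relative density is 1.0 by construction.
    Accepts BlotLane records or a DataFrame with ``group`` and
    ``normalized_density`` columns.
    """
    df = lanes if isinstance(lanes, pd.DataFrame) else lanes_to_frame(lanes)
    ctrl = df.loc[df["group"] == control_group, "normalized_density"]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} has no lanes")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control group mean normalized density is zero")
    out = df.copy()
    out["relative_density"] = out["normalized_density"] / ctrl_mean
    return out
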
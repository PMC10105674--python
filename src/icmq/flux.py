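"""Net transepithelial Cl- flux from isolated perfused tubules.

Chloride in perfusate and collected fluid is read out with the collisionally
quenched fluorophore SPQ; quenching follows the Stern-Volmer relation
F0 / F = 1 + K_sv [Cl-].  With the tubule perfused and bathed in the same
solution, net water flux is taken as zero, so the flux is

    J_Cl = V_dot (C_perfusate - C_collected) / L   [pmol min^-1 mm^-1]

with the collection rate V_dot in nl/min, concentrations in mM and tubule
length L in mm (nl/min x mM = pmol/min).  Positive J_Cl is absorption.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .types import CalibrationCurve, FluxEstimate, PerfusionRecord

__all__ = [
    "stern_volmer_fit",
    "fluorescence_to_cl",
    "solution_cl_content",
    "compute_jcl",
    "estimate_flux",
]

# Cl- ions contributed per formula unit of the salts used in tubule solutions.
CL_PER_FORMULA = {
    "NaCl": 1,
    "KCl": 1,
    "NH4Cl": 1,
    "CholineCl": 1,
    "CaCl2": 2,
    "MgCl2": 2,
    "BaCl2": 2,
    "NaHCO3": 0,
    "KHCO3": 0,
    "K2HPO4": 0,
    "KH2PO4": 0,
    "Na2HPO4": 0,
    "MgSO4": 0,
    "Na2SO4": 0,
    "glucose": 0,
    "urea": 0,
    "HEPES": 0,
}


def solution_cl_content(composition) -> float:
    """Total Cl- (mM) of a solution given as (salt, mM) pairs or a dict."""
    items = composition.items() if isinstance(composition, dict) else composition
    total = 0.0
    for salt, mM in items:
        if salt not in CL_PER_FORMULA:
            raise KeyError(f"unknown salt {salt!r}; add it to CL_PER_FORMULA")
        if mM < 0:
            raise ValueError(f"negative concentration for {salt}")
        total += mM * CL_PER_FORMULA[salt]
    return total


def stern_volmer_fit(standards) -> CalibrationCurve:
    """Least-squares Stern-Volmer calibration from (Cl mM, F) standards.

    Fits F(C) = F0 / (1 + K_sv C) by nonlinear least squares, seeded from the
    linearisation 1/F = 1/F0 + (K_sv/F0) C.  Requires >= 3 standards at >= 2
    distinct Cl- levels including one at (or near) zero.
    """
    arr = np.asarray(list(standards), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (Cl_mM, F) standards")
    c, f = arr[:, 0], arr[:, 1]
    if np.any(f <= 0):
        raise ValueError("fluorescence standards must be positive")
    if len(np.unique(c)) < 2:
        raise ValueError("rank-deficient calibration: need >= 2 distinct Cl- levels")
    # linearised seed
    coef = np.polyfit(c, 1.0 / f, 1)
    f0_init = 1.0 / coef[1] if coef[1] > 0 else float(f.max())
    ksv_init = max(coef[0] * f0_init, 1e-6)

    def model(cc, f0, ksv):
        return f0 / (1.0 + ksv * cc)

    popt, _ = curve_fit(model, c, f, p0=[f0_init, ksv_init], maxfev=10000)
    f0, ksv = float(popt[0]), float(popt[1])
    resid = f - model(c, f0, ksv)
    dof = max(len(f) - 2, 1)
    return CalibrationCurve(F0=f0, K_sv=ksv, residual_sd=float(np.sqrt((resid**2).sum() / dof)))


def fluorescence_to_cl(F: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Invert the calibration: [Cl-] = (F0/F - 1) / K_sv.

    Returns ``(cl_mM, truncated)``; a fluorescence above F0 would give a
    negative concentration, which is truncated to 0 and flagged.
    """
    if F <= 0:
        raise ValueError("fluorescence must be positive")
    cl = (curve.F0 / F - 1.0) / curve.K_sv
    if cl < 0:
        return 0.0, True
    return float(cl), False


def compute_jcl(
    c_perfusate: float, c_collected: float, collection_rate: float, tubule_length: float
) -> float:
    """Net Cl- flux (pmol/min/mm) under the zero-water-flux assumption.

    Negative values mean net secretion and are returned signed.
    """
    if tubule_length <= 0:
        raise ValueError("tubule length must be > 0")
    if collection_rate <= 0:
        raise ValueError("collection rate must be > 0")
    if c_perfusate <= 0 or c_collected < 0:
        raise ValueError("concentrations must be positive (perfusate) / non-negative (collected)")
    return collection_rate * (c_perfusate - c_collected) / tubule_length


def estimate_flux(record: PerfusionRecord) -> FluxEstimate:
    """Calibrate, convert fluorescences to [Cl-] and summarize per-tubule flux.

    Per-collection J values are averaged (mean +/- SE over collections within
    the tubule); any truncated negative concentration is flagged in
    ``FluxEstimate.flags``.
    """
    if not record.collections:
        raise ValueError(f"tubule {record.tubule_id}: no collections")
    curve = stern_volmer_fit(record.standards)
    flags: list[str] = []
    c_perf, trunc = fluorescence_to_cl(record.perfusate_F, curve)
    if trunc:
        flags.append("perfusate concentration truncated at 0 mM")
    js = []
    for i, coll in enumerate(record.collections):
        c_coll, trunc = fluorescence_to_cl(coll.collected_F, curve)
        if trunc:
            flags.append(f"collection {i}: concentration truncated at 0 mM")
        js.append(compute_jcl(c_perf, c_coll, coll.rate_nl_min, record.tubule_length_mm))
    js = np.asarray(js, dtype=float)
    se = float(js.std(ddof=1) / np.sqrt(len(js))) if len(js) > 1 else 0.0
    return FluxEstimate(
        tubule_id=record.tubule_id,
        animal_id=record.animal_id,
        group=record.group,
        per_collection=js,
        mean=float(js.mean()),
        se=se,
        perfusate_cl_mM=c_perf,
        flags=flags,
    )
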
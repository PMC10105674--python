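"""Umbrella pipeline: generate/ingest data, quantify every stage, pool per
animal, compare groups, and write tables plus a machine-readable manifest.

Every tunable lives exactly once in :class:`RunConfig`.  The packaged fixture
set is produced deterministically from the config seed, so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, blots, flux, gold, intensity, stats, synthetic
from .types import BlotLane, GoldCellRecord, PerfusionRecord


class RunConfig(BaseModel):
    """All pipeline tunables, with their defaults.

    Fixture sizes mirror a small two-group study (control vs mutant) with the
    animal as experimental unit; ground-truth group effects are null for the
    image/gold/blot stages and a fixed absorptive flux for perfusion.
    """

    model_config = ConfigDict(frozen=True)

    out_dir: str = "icmq_run"
    seed: int = Field(default=0, ge=0)
    polarity: str = "brightfield_dark_label"
    clip_negative: bool = True
    n_zones: int = Field(default=10, ge=1)
    apical_fraction: float = Field(default=0.10, gt=0, le=1)
    apical_band: str = "height"  # or "area"
    membrane_threshold_nm: float = Field(default=25.0, gt=0)
    scale_nm_per_px: float = Field(default=4.0, gt=0)
    control_group: str = "control"
    groups: tuple[str, str] = ("control", "mutant")
    n_animals_per_group: int = Field(default=4, ge=2)
    cells_per_animal: int = Field(default=5, ge=1)
    tubules_per_group: int = Field(default=4, ge=1)
    lanes_per_group: int = Field(default=6, ge=2)
    image_noise_sd: float = Field(default=4.0, ge=0)
    perfusion_cv: float = Field(default=0.02, ge=0)
    blot_loading_cv: float = Field(default=0.2, ge=0)


def _synthesize(config: RunConfig):
    """Deterministic synthetic fixture set for every stage."""
    rng = np.random.default_rng(config.seed)
    ihc_cells = []
    gold_cells: list[GoldCellRecord] = []
    tubules: list[PerfusionRecord] = []
    for gi, group in enumerate(config.groups):
        for ai in range(config.n_animals_per_group):
            animal = f"{group}-m{ai + 1}"
            for ci in range(config.cells_per_animal):
                seed = int(rng.integers(0, 2**31 - 1))
                truth = synthetic.SynthImageTruth(
                    gradient_shape="linear", noise_sd=config.image_noise_sd, seed=seed
                )
                scene = synthetic.synth_micrograph(truth)
                ann = scene.annotation.model_copy(
                    update={"cell_id": f"{animal}-c{ci + 1}", "animal_id": animal, "group": group}
                )
                ihc_cells.append((scene.image, ann, scene.background_roi))
                gtruth = synthetic.SynthGoldTruth(
                    scale_nm_per_px=config.scale_nm_per_px,
                    membrane_threshold_nm=config.membrane_threshold_nm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                grec = synthetic.synth_gold_cell(gtruth).record.model_copy(
                    update={"cell_id": f"{animal}-g{ci + 1}", "animal_id": animal, "group": group}
                )
                gold_cells.append(grec)
        for ti in range(config.tubules_per_group):
            ptruth = synthetic.SynthPerfusionTruth(
                cv_noise=config.perfusion_cv, seed=int(rng.integers(0, 2**31 - 1))
            )
            prec = synthetic.synth_perfusion(ptruth).record.model_copy(
                update={
                    "tubule_id": f"{group}-t{ti + 1}",
                    "animal_id": f"{group}-m{ti % config.n_animals_per_group + 1}",
                    "group": group,
                }
            )
            tubules.append(prec)
    abundances = {g: [1.0] * config.lanes_per_group for g in config.groups}
    lanes, _ = synthetic.synth_blot(
        abundances, loading_cv=config.blot_loading_cv, seed=int(rng.integers(0, 2**31 - 1))
    )
    return ihc_cells, gold_cells, tubules, lanes


def quantify_ihc_cells(cells, config: RunConfig) -> pd.DataFrame:
    rows = []
    for img, ann, bg_roi in cells:
        bg = intensity.mean_background(img, bg_roi)
        res = intensity.quantify_cell(
            img,
            ann,
            bg,
            n_zones=config.n_zones,
            apical_fraction=config.apical_fraction,
            band=config.apical_band,
            clip_negative=config.clip_negative,
        )
        row = {
            "animal_id": res.animal_id,
            "segment": res.segment,
            "group": res.group,
            "cell_id": res.cell_id,
            "cell_area_px": res.cell_area_px,
            "nuclear_area_px": res.nuclear_area_px,
            "cytoplasmic_area_px": res.cytoplasmic_area_px,
            "net_label_cell": res.net_label_cytoplasm,
            "redistribution_ratio": res.redistribution_ratio,
            "cell_height_px": res.cell_height_px,
        }
        for z, v in enumerate(res.zonal_profile, start=1):
            row[f"zone_{z:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def quantify_gold_cells(records, config: RunConfig) -> pd.DataFrame:
    metrics = [gold.cell_gold_metrics(r, config.membrane_threshold_nm) for r in records]
    df = pd.DataFrame([m.__dict__ for m in metrics])
    return df


def quantify_flux(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        est = flux.estimate_flux(rec)
        rows.append(
            {
                "tubule_id": est.tubule_id,
                "animal_id": est.animal_id,
                "group": est.group,
                "jcl_pmol_min_mm": est.mean,
                "jcl_se": est.se,
                "n_collections": len(est.per_collection),
                "perfusate_cl_mM": est.perfusate_cl_mM,
                "flags": ";".join(est.flags),
            }
        )
    return pd.DataFrame(rows)


def quantify_blots(lanes: list[BlotLane], control_group: str) -> pd.DataFrame:
    return blots.relative_to_control(lanes, control_group)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on the packaged synthetic fixture set.

    Writes per-cell, per-animal, per-group tables and a run manifest under
    ``config.out_dir``; returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []
    stage = "synthesize"
    try:
        ihc_cells, gold_cells, tubules, lanes = _synthesize(config)

        stage = "quantify-ihc"
        ihc = quantify_ihc_cells(ihc_cells, config)
        ihc.to_csv(out / "ihc_per_cell.csv", index=False)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            ihc_animal, msgs = gold.pool_by_animal(ihc, min_cells=5)
        collected += msgs
        ihc_animal.to_csv(out / "ihc_per_animal.csv", index=False)

        stage = "quantify-gold"
        gdf = quantify_gold_cells(gold_cells, config)
        gdf.to_csv(out / "gold_per_cell.csv", index=False)
        gold_animal, msgs = gold.pool_by_animal(gdf, min_cells=5)
        collected += msgs
        gold_animal.to_csv(out / "gold_per_animal.csv", index=False)

        stage = "flux"
        fdf = quantify_flux(tubules)
        fdf.to_csv(out / "flux_per_tubule.csv", index=False)
        flux_animal, msgs = gold.pool_by_animal(
            fdf.drop(columns=["flags"]), min_cells=1
        )
        flux_animal.to_csv(out / "flux_per_animal.csv", index=False)

        stage = "blots"
        bdf = quantify_blots(lanes, config.control_group)
        bdf.to_csv(out / "blots_per_lane.csv", index=False)

        stage = "compare"
        comparisons = []
        for table, metric in (
            (ihc_animal, "net_label_cell"),
            (ihc_animal, "redistribution_ratio"),
            (gold_animal, "apical_au"),
            (gold_animal, "total_au"),
            (flux_animal, "jcl_pmol_min_mm"),
        ):
            cmp_res = stats.compare_groups(table, metric)
            comparisons.append(
                {
                    "metric": metric,
                    "test": cmp_res.test,
                    "statistic": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    "groups": ",".join(cmp_res.groups),
                    "means": ",".join(f"{cmp_res.means[g]:.6g}" for g in cmp_res.groups),
                    "significant": cmp_res.significant,
                }
            )
        cdf = pd.DataFrame(comparisons)
        cdf.to_csv(out / "group_comparisons.csv", index=False)
    except Exception as exc:  # annotate failures with the stage that broke
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    defaults = RunConfig()
    manifest = {
        "icmq_version": __version__,
        "python_version": platform.python_version(),
        "config": json.loads(config.model_dump_json()),
        "non_default_config": {
            k: v
            for k, v in json.loads(config.model_dump_json()).items()
            if getattr(defaults, k) != getattr(config, k)
        },
        "seed": config.seed,
        "warnings": collected,
        "tables": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
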
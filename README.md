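# icmq — intercalated-cell morphometry and quantification

`icmq` is a reusable, tested implementation of the quantification machinery
used in renal collecting-duct transport physiology: scoring apical
transporter immunolabel (such as the Cl⁻/HCO₃⁻ exchanger pendrin) in
intercalated cells, counting immunogold particles on the apical membrane
versus the cytoplasm, computing net transepithelial Cl⁻ flux in isolated
perfused tubules, normalizing immunoblot densitometry, and running the group
statistics these measurements feed — with the animal, not the cell, as the
experimental unit.

It is written for renal physiologists and imaging scientists who have
micrographs plus manual annotations (or particle coordinate tables, or
fluorimeter readings) and want deterministic, auditable numbers instead of
spreadsheet macros. Every stage ships with a synthetic-data generator with
known ground truth, so the whole pipeline can be validated end to end
without any raw data.

## What it computes

**Immunolabel intensity.** Net label at a pixel is the polarity-corrected
difference from background (for brightfield DAB, `background − pixel`).
Per cell: cytoplasmic label by the *whole-cell* method
(Σ net over cell − Σ over nucleus), a zonal *linear* profile along the
apico-basal axis, cell height, line profiles, and the **redistribution
ratio**

    r = (net label with axial position in the most apical 10 % of cell height)
        / (total net cell label)

which is 0.10 for uniformly distributed label and 1 − 0.9² = 0.19 for a
linear base-to-apex gradient.

**Immunogold morphometry.** Boundary length of the traced apical membrane,
particle classification (apical if within 25 nm of the trace, else
cytoplasmic if inside the cell outline, else discarded), per-cell counts and
apical:cytoplasmic ratios, pooled to per-animal means.

**Perfused-tubule Cl⁻ flux.** SPQ fluorescence is calibrated with the
Stern–Volmer relation F₀/F = 1 + K_sv[Cl⁻]; with symmetric perfusate and
bath (zero net water flux),

    J_Cl = V̇ (C_perfusate − C_collected) / L   [pmol·min⁻¹·mm⁻¹]

**Blot densitometry.** Band density normalized lane-wise to Coomassie
total-protein signal, expressed relative to a control group's mean.

**Statistics.** Per-animal mean ± SE; two groups by unpaired pooled-variance
t-test; ≥ 3 groups by one-way ANOVA with a Holm–Šídák step-down post-test;
α = 0.05.

See `docs/methods.md` for models, conventions, defaults and limitations.

## Worked example

Generate a synthetic brightfield scene with a linear base-to-apex label
gradient (2 % noise), quantify it, and compare with its ground truth:

```python
from icmq import intensity
from icmq.synthetic import SynthImageTruth, synth_micrograph

scene = synth_micrograph(SynthImageTruth(gradient_shape="linear", noise_sd=4.0, seed=42))
bg = intensity.mean_background(scene.image, scene.background_roi)
res = intensity.quantify_cell(scene.image, scene.annotation, bg)
print(f"label per cell {res.net_label_cytoplasm:.0f} a.u., "
      f"redistribution {res.redistribution_ratio:.3f}, height {res.cell_height_px:.0f} px")
```

prints

```
label per cell 100044 a.u., redistribution 0.191, height 100 px
```

against a generator truth of 100 000 a.u. and 0.19: the whole-cell method
recovers the integrated label to 0.04 % here, and the measured apical
fraction matches the analytic 1 − 0.9². A noiseless perfused tubule
(J_true = 25 pmol·min⁻¹·mm⁻¹, 129 mM perfusate from the standard
125 NaCl + 2 CaCl₂ recipe):

```python
from icmq import flux
from icmq.synthetic import SynthPerfusionTruth, synth_perfusion

est = flux.estimate_flux(synth_perfusion(SynthPerfusionTruth(J_true=25.0, cv_noise=0.0)).record)
print(f"perfusate {est.perfusate_cl_mM:.1f} mM, J_Cl {est.mean:.2f} pmol/min/mm")
```

```
perfusate 129.0 mM, J_Cl 25.00 pmol/min/mm
```

With realistic 2 % fluorimeter noise single tubules scatter widely (the
perfusate is measured once, so a 2 % fluorescence error is a few mM of
Cl⁻), but the estimator is unbiased: means over many tubules land on
J_true (see below).

## Command line

```sh
icmq synth image --seed 1 --out data/          # any of: image|gold|perfusion|blot
icmq quantify-ihc --images data --annotations data --out cells.csv
icmq quantify-gold --records data --threshold-nm 25 --out gold.csv
icmq flux --standards standards.csv --collections collections.csv --out flux.csv
icmq blots --lanes lanes.csv --control-group control --out rel.csv
icmq compare --table per_animal.csv --metric redistribution_ratio --by group
icmq run --seed 7 --out run7/                  # full pipeline on the packaged fixture set
```

`icmq run` writes per-cell, per-animal and per-group tables plus a
`manifest.json` recording the config, seed and collected warnings; re-running
with the same config and seed reproduces byte-identical tables.

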
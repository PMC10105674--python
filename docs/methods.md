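# Methods

`icmq` quantifies four kinds of renal-collecting-duct measurements — per-cell
immunolabel intensity in brightfield micrographs, immunogold particle
morphometry on electron-micrograph cell profiles, net transepithelial Cl⁻
flux in isolated perfused tubules, and immunoblot densitometry — and applies
group statistics with the animal as the experimental unit. Every stage has a
synthetic generator with known ground truth, so the whole pipeline is
testable without any raw imaging data.

## Immunolabel intensity (brightfield, DAB)

**Model.** A micrograph is a 2-D intensity raster with an explicit polarity
flag. DAB immunolabel is a dark deposit, so on brightfield images the net
label at a pixel is `background − pixel`; on fluorescence images it is
`pixel − background`. Background is the mean raw intensity inside an ROI
circumscribing cytoplasm of an unlabeled cell in the same image. Negative
net values (stray pixels brighter than background) are clipped to zero by
default; the clip is configurable (`clip_negative`) because either
convention is defensible and the choice only matters in nearly unlabeled
regions.

**Pixel membership** is defined once: a pixel belongs to a polygonal region
when its center `(col + 0.5, row + 0.5)` lies inside the polygon under the
even-odd rule, with 0-based x = column / y = row coordinates. This primitive
is deliberately small and is verified against exhaustive per-pixel
enumeration; every area and region sum in the package reduces to it.

**Whole-cell method.** Cytoplasmic net label = (sum of net intensity over
cell pixels) − (sum over nucleus pixels); cytoplasmic area = cell area −
nuclear area. The nucleus polygon must be geometrically contained in the
cell polygon (validated at annotation load).

**Linear method.** Each cell pixel is projected onto the directed
apico-basal axis (apical end = 0) and assigned to one of `n_zones`
(default 10) equal-length bins of normalized axial position; projections are
clipped to [0, 1] so the zone sums partition the whole-cell sum exactly.

**Redistribution ratio.** Label in the most apical band divided by total
cell label. The band is defined by axial position (`t ≤ fraction`,
default fraction 0.10) — i.e. by cell *height*, matching the cell-height
statistic measured on the same axis. An area-percentile definition
(`band="area"`: most-apical 10 % of pixels by count) is available because
the height convention is a design choice, not a measured fact. The ratio is
undefined (raised / NaN) when total net label is ≤ 0.

**Line profiles** sample `ceil(L) + 1` evenly spaced points along a directed
lumen-to-base line (step ≤ 1 px), read the containing pixel
(nearest-lower-integer indexing, deterministic) and subtract the
outside-cell background under the image's polarity.

## Immunogold morphometry

A cell record carries the traced apical-membrane polyline, the cell outline,
gold particle coordinates, and an nm/px scale supplied per record (print
magnification is not a pixel scale). Boundary length is the polyline's
Euclidean length × scale, reported in mm (1 mm = 10⁶ nm).

A particle is **apical** when its minimum distance to the membrane trace is
≤ 25 nm (default; configurable). 25 nm is a conventional antibody-bridge
distance between a colloidal-gold marker and its epitope in post-embedding
immunogold work. Otherwise the particle is **cytoplasmic** if inside the
cell outline, else **discarded**; precedence apical > cytoplasmic means
every particle is counted exactly once and
apical + cytoplasmic + discarded = total. Apical counts are therefore
non-decreasing in the threshold.

Per-cell metrics mirror the standard morphometry table: boundary length,
apical Au, cytoplasmic Au, total Au, apical:cytoplasmic ratio (NaN-flagged
when the cytoplasmic count is zero), and Au per mm of boundary. Raw per-cell
metrics are pooled to one arithmetic mean per animal; animals with fewer
than 5 cells trigger a warning (collected in the run manifest), never an
error, and downstream n is always the number of animals.

## Microperfusion Cl⁻ flux

Chloride is read out with SPQ, a collisionally quenched fluorophore, so
quenching follows the Stern–Volmer relation `F0/F = 1 + K_sv·[Cl⁻]`.
Calibration fits `F(C) = F0/(1 + K_sv·C)` to the standards by nonlinear
least squares (seeded from the linearisation `1/F` vs `C`); inversion is
`[Cl⁻] = (F0/F − 1)/K_sv`, with negative concentrations truncated to 0 and
flagged. With the tubule perfused and bathed in the same solution, net water
flux is taken as zero and

    J_Cl = V̇ · (C_perfusate − C_collected) / L    [pmol·min⁻¹·mm⁻¹]

with V̇ in nl/min, concentrations in mM, L in mm; positive J_Cl is
absorption, negative values (net secretion) are returned signed. J is exactly
linear in V̇ and in ΔC. Per-collection J values are averaged within a tubule
(mean ± SE); per-animal pooling then follows the n = animals rule.
`solution_cl_content` computes perfusate Cl⁻ stoichiometrically from the
salt recipe; the standard bicarbonate-buffered perfusate
(125 NaCl + 2 CaCl₂ among Cl-free salts) gives 129 mM.

## Blot densitometry

Band densities enter as numbers (band boxing happens upstream). Lane-wise
normalization divides the target band by the same lane's Coomassie
total-protein density, which cancels loading exactly in the absence of
measurement noise and makes normalized densities invariant to any common
rescaling. Group presentation divides by the control group's mean normalized
density, mapping the control to 1.0. Actin, when present, is carried through
as a loading cross-check only.

## Statistics

Values entering any test are per-animal pooled means. Two groups: two-sided
unpaired Student's t-test with pooled variance (Welch available by flag;
pooled is the default to match the classical "Student's" procedure). Three or
more: one-way ANOVA, followed by all-pairs t-tests with Holm–Šídák step-down
adjustment: sort raw p ascending, `adj_i = 1 − (1 − p_i)^(m − i + 1)`,
enforce monotone non-decreasing along the sorted order (ties therefore share
an adjusted value), return in input order. α = 0.05 throughout. Degenerate
inputs are resolved before delegating to scipy/statsmodels: identical
constant groups give (t = 0, p = 1); zero variance with distinct means gives
a flagged infinite statistic with p = 0.

## Synthetic generators — what they emulate, and what not

A single integer seed fully determines each artifact; generators never touch
global random state.

* **Micrographs** (`synth_micrograph`): one rectangular annotated cell
  (apex at top, 40 × 100 px) plus an unlabeled background region on a
  uniform background of 200 a.u. (8-bit scale). The axial label density is
  uniform, linear (0 at base, maximal at apex) or exponential with decay
  length τ; the closed-form apical-band fraction is recorded as ground
  truth — for the linear profile and a 10 % band it is 1 − 0.9² = 0.19.
  The painted amplitude is scaled so the noiseless cytoplasmic net label
  integrates exactly to `label_total` (default 10⁵ a.u.). Noise is additive
  Gaussian (default tests use SD 4 ≈ 2 % of the background swing). Not
  emulated: histology texture, RGB DAB color, segmentation error,
  multi-cell crowding — so passing recovery tests validates the arithmetic
  of the quantification, not robustness to real staining variability.
* **Gold patterns** (`synth_gold_cell`): homogeneous Poisson counts —
  membrane count ~ Poisson(λ_mem × boundary length), cytoplasm count ~
  Poisson(λ_cyt × profile area) — with membrane particles jittered at most
  half the association threshold off the trace and cytoplasmic particles
  kept at least twice the threshold away, so classification is unambiguous
  by construction. Defaults (λ_mem = 12 /µm, λ_cyt = 2.5 /µm², 3.2 µm
  trace, 10.2 µm² profile at 4 nm/px) give ≈ 38 apical and ≈ 26
  cytoplasmic particles per cell, the magnitude of a strongly labeled
  non-A, non-B intercalated cell. Real labeling is neither homogeneous nor
  unambiguous near the membrane; the generator validates counting and
  classification geometry only.
* **Perfusion records** (`synth_perfusion`): collected concentration from
  the flux balance C_c = C_p − J·L/V̇ (defaults J = 25 pmol·min⁻¹·mm⁻¹,
  C_p = 129 mM, V̇ = 2.5 nl/min within the experimental 2–3 nl/min range,
  L = 1 mm), converted to fluorescence with K_sv = 0.118 mM⁻¹ (standard
  aqueous SPQ value) and perturbed multiplicatively with CV `cv_noise`
  (default 2 %) on standards, perfusate and collections alike. Because the
  perfusate is measured once per tubule, a 2 % fluorescence error maps to a
  few-mM concentration error and per-tubule J estimates scatter widely
  (SD ≈ 25–30 % of J); the estimator is unbiased, so means over many
  tubules recover J. Drift, dye leakage and water flux are not modeled.
* **Blots** (`synth_blot`): per-lane lognormal loading factors (mean 1, CV
  `loading_cv`, default 0.2); band = abundance × loading × gain, Coomassie
  = loading × constant, actin = loading × constant. Both measured densities
  additionally carry multiplicative noise with CV `density_cv`
  (default 0.05) — without it, Coomassie normalization would cancel loading
  exactly and recovery simulations would be vacuous. All three noise models
  are stand-ins (the raw data's distributions are unknown) and are labeled
  as such in the `*.truth.json` sidecars.

## Numerical choices and degenerate inputs

* Even-odd membership uses half-open edge treatment in y; points exactly on
  a boundary resolve deterministically.
* Self-intersecting or zero-area polygons, degenerate axes/polylines, empty
  rasterized ROIs, zero Coomassie densities, rank-deficient calibrations and
  non-positive fluorescences are errors, not silent NaNs; undefined ratios
  (zero total label, zero cytoplasmic Au) are flagged NaN.
* Stern–Volmer fitting is a 2-parameter nonlinear least-squares problem with
  an exact linearised seed; on noiseless standards it recovers parameters to
  better than 10⁻⁶ relative error.
* CSV output is UTF-8/comma/'.'-decimal; identical config + seed reproduces
  byte-identical tables (the manifest stores no timestamps).

## Problem sizes

Default simulation sizes — 20 scenes for intensity recovery, 50 cells for
gold densities, 200 tubules for flux recovery, 200 replicates for blot
ratios, 2 000 datasets for null calibration — are chosen so each property is
resolved well inside its tolerance (e.g. 2 SE bands) while the full suite
and the acceptance script each run in seconds on one CPU.

## Known limitations

* Annotations are inputs: no segmentation, no nucleus detection, no color
  deconvolution; grayscale images assumed.
* The redistribution ratio's height-vs-area band convention and the
  negative-net clipping convention are package design choices; both are
  switchable, and both default to the convention that keeps the ratio in
  [0, 1] and monotone in apical labeling.
* Cell height is reported in pixels; mapping to physical units requires a
  pixel scale that micrograph metadata must supply.
* The immunogold area-normalized cytoplasmic density is computed but the
  table-style summary uses raw counts and ratios.
* No mixed models or sex-stratified analyses; group labels are carried as
  plain metadata.
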
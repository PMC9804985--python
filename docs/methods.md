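# Methods

## Scope and model

`isletquant` quantifies the endocrine compartment of pancreas sections from
2D microscopy. The analysis model is deliberately simple and transparent:

1. **Tissue** is the "pancreatic area examined": the smoothed sum of all
   fluorescence channels, thresholded, hole-filled, and size-filtered.
2. **Islets** are synaptophysin-positive regions *within tissue*; the
   threshold is computed over tissue pixels only, followed by morphological
   closing, hole filling, a minimum-area filter and clipping to tissue.
3. **β cells** are insulin-positive pixels *within the islet mask*; the
   threshold is computed over islet pixels only, so the result is invariant
   to everything outside islets.
4. The three read-outs are: islet % of tissue area, insulin-positive % of
   islet area, and the insulin signal integrated over islet pixels
   (reported raw and background-subtracted; background = median insulin
   intensity over tissue∖islet). Masks satisfy insulin ⊆ islet ⊆ tissue by
   construction, and this nesting is asserted in tests over randomized
   fields.
5. Per-animal values are tissue-area-weighted means over that animal's
   images (unweighted means by option). Missing values (an image or animal
   with no detected islet) are excluded with a logged warning — never
   imputed, never silently zeroed.

Brightfield double-stained IHC tiles are handled by optical-density colour
deconvolution: per-channel OD = −log₁₀((I+1)/256), per-stain amounts from
the inverse of a row-unit-norm stain matrix (haematoxylin, DAB, AP-magenta;
Ruifrok–Johnston vectors for H and DAB by default, overridable because real
kits vary). Negative unmixed amounts are clipped to zero. The synthetic IHC
renderer uses the exact inverse transform I = 256·10^(−OD) − 1, so the
noise-free render→deconvolve round trip is lossless (≤1e-6 OD; measured
~1e-16) while OD = 0 still maps to pure white.

## Statistics

Per-animal metrics are log₁₀-transformed (non-positive values raise an
error naming the animal; documented alternatives are exclusion or a fixed
offset, both recorded in the result notes). Variance homogeneity (Bartlett)
and per-group normality (Shapiro–Wilk) are tested at P > 0.05; a failed
gate is *reported*, not enforced, since real reuse must surface violations
rather than silently switch tests.

Group comparison is the two-sided single-step Dunnett many-to-one
procedure with pooled within-group variance (matching the homogeneity
gate). For treatment j,

    t_j = (x̄_j − x̄_c) / √(s²(1/n_j + 1/n_c)),  df = N − k,

and the adjusted p-value is P(max_k |T_k| ≥ |t_j|) under the joint null,
where (T_1..T_m) is multivariate t with the Dunnett correlation
ρ_ij = λ_i λ_j, λ_j = √(n_j/(n_j+n_c)). The tail probability is evaluated
through the factor representation T_j = (c_j X_j + λ_j X₀)/q,
q = √(χ²_df/df): a 160-node Gauss–Hermite rule integrates the shared
factor X₀ and adaptive quadrature (absolute tolerance 1e-12) integrates
the scale q over (0, q_max) with q_max at the 1−1e-13 chi quantile. This
reproduces the closed-form pooled t-test at m = 1 to ~1e-13 and matches
R `multcomp`'s single-step values to ~4e-9 and a 10⁶-draw Monte-Carlo
oracle to <1e-3. For m > 8 treatments a seeded Monte-Carlo fallback
(500k draws by default) replaces the quadrature.

Within `compare_cohort`, group samples are sorted before any computation so
results are *exactly* invariant to the order animals appear in the table.
No multiplicity correction is applied across metrics.

## Synthetic-cohort generator

The generator emulates a two-group comparative histology study with exact
ground truth. Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| frame | 2048×2048 px at 0.25 µm/px | ≈0.26 mm² field, plausible ×40 scan |
| islet area fraction (control) | 0.8 % of tissue | sparse endocrine compartment |
| islet radius | lognormal, median 30 µm, ln-sd 0.25 | multi-cell ovoid islets |
| β fraction of islet | 0.55 | control-like β-cell share |
| insulin / synaptophysin intensity | 180 / 140 (8-bit) | bright specific staining |
| tissue background / glass | 6 / 0 | autofluorescence vs bare glass |
| noise | Poisson gain 1.0 + Gaussian sd 2.0 | shot + read noise on 8-bit scale |
| between-animal spread | log₁₀ sd 0.25 (islet fraction), 0.10 (intensity), ±0.11 absolute (β fraction) | matches the coefficient of variation of the motivating study's groups |

Geometry: the tissue is a smooth radially-perturbed blob covering ≥60 % of
the frame; islets are non-overlapping random ellipses (axis ratio 1–2,
random rotation, 2 px separation margin) placed wholly inside tissue.
Because a single median islet can exceed a small target fraction at this
field size, the final ellipse is shrunk to close the remaining pixel
budget (with an iterative lattice-quantisation correction), so the
achieved fraction lands within ±10 % relative of the target whenever the
frame allows it; otherwise a placement error reports achieved vs requested.
The β-cell sub-region is one connected Eden-growth blob per islet at an
exact pixel count (β cells cluster in islet cores); an exact-count
spatially-random subset is available by option. Ground-truth fractions are
computed from the actual label maps, so they are consistent with the
rendered images to machine precision regardless of placement quantisation.

Between-animal draws are mean-preserving lognormal factors (islet fraction,
insulin intensity) and clipped Gaussian perturbations (β fraction);
per-animal seeds derive from (master_seed, crc32(group), animal index), so
adding a group never perturbs existing animals and every output is
bit-reproducible under a fixed master seed.

What the generator does **not** emulate: optical point-spread blur,
intensity gradients/vignetting, stitching artefacts, islet amyloid,
vasculature or innervation, autofluorescent debris, or 3D structure.
Staining contrast is high and uniform. Passing the recovery tests therefore
shows the pipeline is *correct* under its stated model — recovering known
geometry and intensities through segmentation, aggregation and statistics —
not that its default thresholds are tuned for any particular real scanner
or staining protocol; on real data the segmentation config (blur, threshold
method, size filters) is expected to need adjustment, which is why every
step is config-driven and echoed into the run's provenance.

## Numerical and design choices

- **Tissue threshold** default is `otsu_capped`: Otsu's criterion applied
  to values below the 85th percentile. With tissue covering 60–85 % of the
  frame, the dominant histogram mode is tissue background, where the
  triangle rule (and plain or multi-class Otsu) can place the cut above the
  tissue level; capping removes the bright minority classes (nuclei,
  islets) so the split falls between glass and tissue. Triangle, plain Otsu
  and fixed thresholds remain selectable.
- **Otsu threshold placement**: thresholds are returned at the upper *edge*
  of the background histogram bin, not its centre, so exact grey levels
  (common in noise-free synthetic data) classify to the intended side.
- **Otsu contrast guard** (`min_contrast_sd`, default 4): Otsu always
  returns a split, even on pure background noise (class separation ≈2.7
  background sds). A field is declared islet-free (or an islet
  insulin-free) when the foreground–background mean separation is below 4
  background sds; genuine staining in the model sits tens of sds above
  background. This makes "no islet in this field" a first-class, valid
  result rather than a noise artefact.
- **Monotonicity**: closing, hole filling, small-object removal and
  intersection are all increasing set operators, so raising a fixed
  threshold can only shrink the final mask — asserted by threshold sweeps
  in the tests.
- **Size filters in µm²** (min islet area 300 µm² by default, rejecting
  single stray positive cells; closing radius 2 µm), so configs are
  magnification-independent. Islets touching the frame border are kept by
  default (no exclusion rule is imposed); a config flag excludes them.
- **Primary intensity statistic** for group comparison is the
  background-subtracted mean insulin intensity per islet pixel: integrated
  intensity confounds islet area, which the area metric already captures.
  The raw integrated value is still computed and reported.
- **Problem sizes for repeated simulation studies** (type-I error, power,
  intensity-contrast recovery; `isletquant.experiments`): 256×256 px frames
  at 2.0 µm/px — the same 0.26 mm² physical field as the full-scale
  default, sampled more coarsely — with `min_islet_area` lowered to
  50 µm² so lower-tail animals (~130 µm² islets) stay detectable. At these
  conditions recovery of the islet fraction is accurate to ~0.0005 in
  log₁₀, so the calibration results are not limited by sampling density.
  The intensity-contrast experiment holds between-animal intensity and
  β-fraction spread at zero: it is a measurement-recovery check of the
  imposed 0.5× contrast, not a power study.
- **Calibration**: across 300 null cohorts the full simulate→segment→
  quantify→compare pipeline yields uniform p-values (KS P ≈ 0.7) and a
  rejection rate of ≈0.04 at nominal 0.05; power at the calibrated effect
  (0.8 % vs 0.3 %, n = 10 vs 9, log₁₀ sd 0.25) is ≈0.95.

## Known limitations

- No per-cell segmentation or counting; areas and intensities only.
- No mixed-effects modelling of the image-within-animal nesting; images are
  aggregated to one value per animal before testing, as in the motivating
  workflow.
- The automated DAB (IHC) quantification is an automated equivalent of
  slide-viewer measurements; no claim is made that it reproduces any
  particular manual annotation procedure.
- Whole-slide (pyramidal) images, 3D stacks and scanner-specific artefact
  correction are out of scope.
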
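# isletquant

Quantification of the pancreatic islet microenvironment from 2D microscopy,
built for comparative studies of diabetic and non-diabetic cohorts (the
motivating setting is feline diabetes mellitus, where reduced per-cell
insulin expression is thought to precede islet loss).

The package measures, per image and per animal:

- **islet area fraction** — synaptophysin-positive area as a percentage of
  the pancreatic tissue area examined (synaptophysin is a pan-neuroendocrine
  marker, so its stained area proxies total islet mass);
- **insulin-positive fraction of islet area** — the β-cell share of each
  islet;
- **insulin signal within islets** — the anti-insulin fluorescence signal
  integrated within masks of the synaptophysin-delineated islet areas,
  reported raw and background-subtracted (background = median insulin
  intensity over tissue outside islets).

Two imaging modalities are supported: three-channel immunofluorescence
(DAPI / synaptophysin / insulin, OME-TIFF) and brightfield double-stained
IHC (haematoxylin + DAB + AP-magenta), which is unmixed by optical-density
colour deconvolution: per-channel OD = −log₁₀((I+1)/256) and per-stain
amounts follow from the inverse of a unit-norm stain matrix (Beer–Lambert
linearity).

Group comparison follows the standard comparative-histology workflow:
per-animal metrics are log₁₀-transformed, gated by Bartlett (variance
homogeneity) and Shapiro–Wilk (normality) tests at P > 0.05, and each
non-control group is compared with the control by the two-sided single-step
**Dunnett test** at α = 0.05. The adjusted p-value is the tail probability
of max⁠ⱼ |Tⱼ| under the equicorrelated multivariate-t null
(ρᵢⱼ = λᵢλⱼ, λⱼ = √(nⱼ/(nⱼ+n_c))), evaluated by deterministic quadrature
over the factor representation; for one treatment group it reduces exactly
to the pooled two-sample t-test.

Because studies of this kind rarely deposit raw images, the package ships a
**synthetic-cohort generator** with exact ground truth (islet label maps,
β-cell masks, per-image fractions) that emulates the study conditions:
sparse islets at ~0.3–0.8 % of tissue area, β-cell sub-areas of ~47–55 % of
islet area, a multiplicative insulin-intensity deficit in the diseased
group, between-animal spread (log₁₀ sd 0.25), and Poisson + Gaussian
imaging noise. All validation and calibration claims are made against this
generator.

## Worked example

```python
import numpy as np
from isletquant import (CohortSpec, GroupSpec, generate_cohort,
                        RunConfig, run_pipeline)
from isletquant.experiments import sim_params
from isletquant.types import SegmentationConfig

spec = CohortSpec(
    groups=[GroupSpec("non_diabetic", 10, is_control=True),
            GroupSpec("diabetic", 9,
                      overrides={"islet_area_fraction_target": 0.003,
                                 "insulin_intensity": 90.0})],
    images_per_animal=2,
    base_params=sim_params(),   # 256 px frames, 2 µm/px, control target 0.8 %
    master_seed=1,
)
generate_cohort(spec, "cohort")
report = run_pipeline(RunConfig(
    manifest="cohort/manifest.csv", out_dir="results",
    segmentation=SegmentationConfig(min_islet_area=50.0)))
print(report.processed)
```

prints `38` (19 animals × 2 images, none flagged) and writes
`per_image_metrics.csv`, `per_animal.csv` and `stats_results.csv` into
`results/`. The stats table for this seed contains, per metric, the raw
group summaries and the Dunnett comparison:

```
metric                         treatment  t_value  p_adjusted  non_diabetic_raw_mean  diabetic_raw_mean
islet_area_pct_of_tissue       diabetic   -4.1089  0.0007      0.9244                 0.2050
insulin_pos_area_pct_of_islet  diabetic   -0.9121  0.3745      57.9903                54.6635
insulin_mean_bgsub             diabetic   -3.8381  0.0013      98.1860                52.7636
```

i.e. the generated islet-mass deficit and the halved insulin intensity are
recovered as significant while the (similar) β-cell fractions are not —
the same qualitative pattern the pipeline is designed to resolve. Per-seed
numbers vary with the between-animal spread; with this effect size the
islet-fraction comparison rejects in ≈95 % of cohorts.

The same steps are available from the shell:

```sh
isletquant simulate --spec spec.yaml --out cohort --seed 7
isletquant run-all  --config run.yaml
isletquant segment|quantify|stats|qc ...   # individual stages
```

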
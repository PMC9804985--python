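"""Simulation studies of the pipeline's own statistical behaviour.

These drivers run the full simulate -> segment -> quantify -> compare chain
in memory, many times, to measure ground-truth recovery, type-I error and
power under known conditions.  Problem sizes default to 256x256 px frames at
2.0 um/px — the same 0.26 mm^2 physical field as the generator's full-scale
default, sampled more coarsely — with ``min_islet_area`` lowered to 50 um^2
so the smallest simulated islets (lower tail of the between-animal spread)
remain detectable.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .quantification import aggregate_per_animal, metrics_to_frame, per_image_metrics
from .segmentation import segment_if_image
from .stats import compare_cohort
from .synthetic import CohortSpec, GeneratorParams, GroupSpec, iter_cohort
from .types import SegmentationConfig

logger = logging.getLogger(__name__)

#: frame used by the repeated-simulation studies (see module docstring)
SIM_FRAME = {"image_shape": (256, 256), "pixel_size": 2.0}

#: segmentation config matched to the simulation frame
SIM_SEG_CONFIG = SegmentationConfig(min_islet_area=50.0)


def sim_params(**overrides) -> GeneratorParams:
    """Generator parameters on the simulation-study frame."""
    return GeneratorParams(**{**SIM_FRAME, **overrides})


def measure_cohort(spec: CohortSpec,
                   cfg: SegmentationConfig | None = None) -> pd.DataFrame:
    """Generate, segment and quantify a cohort in memory.

    Returns the per-animal table (one row per animal) ready for
    :func:`isletquant.stats.compare_cohort`.
    """
    if cfg is None:
        cfg = SIM_SEG_CONFIG
    rows = []
    manifest_rows = []
    for item in iter_cohort(spec):
        masks = segment_if_image(item.image, cfg)
        rows.append(per_image_metrics(item.image, masks, item.image_id))
        manifest_rows.append({"image_path": item.image_id,
                              "animal_id": item.animal_id,
                              "group": item.group})
    metrics = metrics_to_frame(rows)
    manifest = pd.DataFrame(manifest_rows)
    return aggregate_per_animal(metrics, manifest)


def two_group_spec(control_params: GeneratorParams,
                   diabetic_overrides: dict, master_seed: int,
                   n_control: int = 10, n_diabetic: int = 9,
                   images_per_animal: int = 1) -> CohortSpec:
    """A study-shaped cohort: n=10 controls vs n=9 diabetics."""
    return CohortSpec(
        groups=[
            GroupSpec("non_diabetic", n_control, is_control=True),
            GroupSpec("diabetic", n_diabetic, overrides=diabetic_overrides),
        ],
        images_per_animal=images_per_animal,
        base_params=control_params,
        master_seed=master_seed,
    )


def rejection_rate(n_cohorts: int, seed: int, diabetic_overrides: dict,
                   metric: str = "islet_area_pct_of_tissue",
                   alpha: float = 0.05,
                   base_params: GeneratorParams | None = None,
                   cfg: SegmentationConfig | None = None) -> float:
    """Fraction of simulated cohorts whose Dunnett p falls below alpha.

    With empty ``diabetic_overrides`` both groups share one distribution and
    the rate estimates the type-I error; with a real group difference it
    estimates power.  Animals whose measurement is non-positive under the
    log10 transform are excluded (rare at the simulated conditions; counts
    are logged).
    """
    if base_params is None:
        base_params = sim_params()
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts) % (2**31)
    rejections = 0
    for i in range(n_cohorts):
        spec = two_group_spec(base_params, diabetic_overrides,
                              master_seed=int(seeds[i]))
        table = measure_cohort(spec, cfg)
        results = compare_cohort(table, [metric], control="non_diabetic",
                                 alpha=alpha, zero_policy="exclude")
        if not results:
            logger.warning("cohort %d produced no comparable metric", i)
            continue
        if results[0].comparisons[0].p_adjusted < alpha:
            rejections += 1
    return rejections / n_cohorts


def intensity_ratio(master_seed: int, intensity_factor: float = 0.5,
                    base_params: GeneratorParams | None = None,
                    cfg: SegmentationConfig | None = None) -> float:
    """Measured diabetic/control ratio of background-subtracted mean insulin
    intensity for a cohort generated with a known intensity contrast.

    This is a measurement-recovery check of the imposed contrast, so the
    between-animal spread of insulin intensity and beta fraction is held at
    zero; imaging noise stays at its default.
    """
    if base_params is None:
        base_params = sim_params(insulin_intensity_animal_sd=0.0,
                                 beta_fraction_animal_sd=0.0)
    overrides = {"insulin_intensity":
                 base_params.insulin_intensity * intensity_factor}
    spec = two_group_spec(base_params, overrides, master_seed=master_seed)
    table = measure_cohort(spec, cfg)
    means = table.groupby("group")["insulin_mean_bgsub"].mean()
    return float(means["diabetic"] / means["non_diabetic"])


def dunnett_null_max_abs_t(sizes: tuple[int, ...], n_draws: int,
                           rng: np.random.Generator,
                           chunk: int = 100_000) -> np.ndarray:
    """Monte-Carlo draws of max_j |T_j| under the joint Dunnett null.

    Simulates raw standard-normal samples for every group (control first) and
    recomputes the pooled-variance many-to-one t statistics from scratch on
    each draw — an oracle independent of any analytic tail evaluation.
    """
    sizes = tuple(int(s) for s in sizes)
    n_total = sum(sizes)
    df = n_total - len(sizes)
    bounds = np.cumsum((0,) + sizes)
    out = np.empty(n_draws)
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        data = rng.standard_normal((m, n_total))
        means, ssq = [], 0.0
        for g in range(len(sizes)):
            block = data[:, bounds[g]:bounds[g + 1]]
            mu = block.mean(axis=1)
            ssq = ssq + ((block - mu[:, None]) ** 2).sum(axis=1)
            means.append(mu)
        s2 = ssq / df
        max_abs = np.zeros(m)
        n0 = sizes[0]
        for g in range(1, len(sizes)):
            se = np.sqrt(s2 * (1.0 / sizes[g] + 1.0 / n0))
            np.maximum(max_abs, np.abs(means[g] - means[0]) / se, out=max_abs)
        out[done:done + m] = max_abs
        done += m
    return out


def islet_fraction_errors(n_images: int, targets: tuple[float, ...],
                          seed: int, noise: tuple[float, float],
                          params: GeneratorParams | None = None,
                          cfg: SegmentationConfig | None = None
                          ) -> pd.DataFrame:
    """Per-image islet-fraction and beta-fraction recovery errors.

    Generates ``n_images`` fields cycling through the target fractions and
    returns truth vs estimate per image (percent units).
    """
    if params is None:
        params = GeneratorParams()
    if cfg is None:
        cfg = SegmentationConfig()
    children = np.random.SeedSequence(seed).spawn(n_images)
    rows = []
    for i in range(n_images):
        p = replace(params, islet_area_fraction_target=targets[i % len(targets)],
                    noise_model=noise)
        rng = np.random.default_rng(children[i])
        from .synthetic import sample_islet_geometry, render_if_image

        gt = sample_islet_geometry(p, rng)
        img = render_if_image(gt, p, rng)
        masks = segment_if_image(img, cfg)
        m = per_image_metrics(img, masks, f"img{i:03d}")
        rows.append({
            "image_id": m.image_id,
            "target_pct": 100.0 * p.islet_area_fraction_target,
            "true_islet_pct": gt.true_islet_fraction,
            "est_islet_pct": m.islet_area_pct_of_tissue,
            "true_beta_pct": gt.true_beta_fraction_of_islet,
            "est_beta_pct": m.insulin_pos_area_pct_of_islet,
        })
    return pd.DataFrame(rows)
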
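"""Turning masks and channels into the study's read-outs.

Per image: islet fraction of tissue area, insulin-positive fraction of islet
area, and the insulin signal integrated within the islet mask (raw and
background-subtracted, where background is the median insulin intensity over
tissue outside islets).  Per animal: tissue-area-weighted means across that
animal's images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MultiChannelImage, MaskSet, IsletMetrics

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "tissue_area", "islet_area", "islet_area_pct_of_tissue",
    "insulin_pos_area_pct_of_islet", "insulin_integrated_intensity",
    "insulin_mean_intensity", "background_intensity",
    "insulin_integrated_bgsub", "insulin_mean_bgsub",
]

AREA_WEIGHTED = ("islet_area_pct_of_tissue", "insulin_pos_area_pct_of_islet",
                 "insulin_integrated_intensity", "insulin_mean_intensity",
                 "background_intensity", "insulin_integrated_bgsub",
                 "insulin_mean_bgsub")


def area_fraction(mask: np.ndarray, reference: np.ndarray) -> float:
    """Percentage of ``reference`` pixels covered by ``mask``.

    ``mask`` must be contained in ``reference``; a violation indicates an
    upstream bug and raises.
    """
    mask = np.asarray(mask, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    n_ref = int(reference.sum())
    if n_ref == 0:
        raise ValueError("reference mask is empty")
    if np.any(mask & ~reference):
        raise ValueError("mask is not contained in the reference mask")
    return 100.0 * int(mask.sum()) / n_ref


@dataclass(frozen=True)
class IntensityStats:
    integrated: float  # sum of insulin channel over islet pixels
    mean: float  # integrated / islet pixel count
    background: float  # median insulin over tissue \ islet
    integrated_bgsub: float
    mean_bgsub: float


def insulin_intensity_in_islets(img: MultiChannelImage, islet: np.ndarray,
                                tissue: np.ndarray) -> IntensityStats:
    """Integrate the insulin channel within the islet mask.

    Background is estimated as the median insulin intensity over tissue
    pixels outside the islet mask; statistics are reported raw and
    background-subtracted.  Raises on an empty islet mask: the caller records
    the metrics as missing, never as zero.
    """
    islet = np.asarray(islet, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    n = int(islet.sum())
    if n == 0:
        raise ValueError("islet mask is empty; intensity undefined")
    chan = img.channels["insulin"]
    integrated = float(chan[islet].sum())
    mean = integrated / n
    outside = tissue & ~islet
    background = float(np.median(chan[outside])) if outside.any() else 0.0
    return IntensityStats(
        integrated=integrated,
        mean=mean,
        background=background,
        integrated_bgsub=integrated - background * n,
        mean_bgsub=mean - background,
    )


def per_image_metrics(img: MultiChannelImage, masks: MaskSet,
                      image_id: str = "") -> IsletMetrics:
    """Assemble the full per-image read-out row from an image and its masks."""
    if masks.tissue.shape != img.shape:
        raise ValueError("masks and image do not share geometry")
    pa = img.pixel_area()
    tissue_area = float(masks.tissue.sum()) * pa
    islet_area = float(masks.islet.sum()) * pa
    islet_pct = area_fraction(masks.islet, masks.tissue)
    if masks.islet.any():
        stats = insulin_intensity_in_islets(img, masks.islet, masks.tissue)
        beta_pct = area_fraction(masks.insulin_positive, masks.islet)
        n = int(masks.islet.sum())
        assert abs(stats.integrated - stats.mean * n) <= 1e-6 * max(1.0, stats.integrated)
        return IsletMetrics(
            image_id=image_id,
            tissue_area=tissue_area,
            islet_area=islet_area,
            islet_area_pct_of_tissue=islet_pct,
            insulin_pos_area_pct_of_islet=beta_pct,
            insulin_integrated_intensity=stats.integrated,
            insulin_mean_intensity=stats.mean,
            background_intensity=stats.background,
            insulin_integrated_bgsub=stats.integrated_bgsub,
            insulin_mean_bgsub=stats.mean_bgsub,
            islet_found=True,
        )
    logger.warning("image %s: no islet detected; intensity metrics missing",
                   image_id or "<unnamed>")
    nan = float("nan")
    return IsletMetrics(
        image_id=image_id,
        tissue_area=tissue_area,
        islet_area=0.0,
        islet_area_pct_of_tissue=0.0,
        insulin_pos_area_pct_of_islet=nan,
        insulin_integrated_intensity=nan,
        insulin_mean_intensity=nan,
        background_intensity=nan,
        insulin_integrated_bgsub=nan,
        insulin_mean_bgsub=nan,
        islet_found=False,
    )


def metrics_to_frame(rows: list[IsletMetrics]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def aggregate_per_animal(metrics: pd.DataFrame, manifest: pd.DataFrame,
                         weighting: str = "tissue_area") -> pd.DataFrame:
    """Aggregate per-image rows to one row per animal.

    Percentages and intensities are tissue-area-weighted means by default
    (``weighting='none'`` gives unweighted means).  Intensity metrics average
    over islet-bearing images only; an animal whose every image lacked islets
    keeps NaN intensities (excluded downstream with a logged warning).
    Raises if a manifest animal has no analysable image.
    """
    if weighting not in ("tissue_area", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    lookup = manifest.drop_duplicates("image_path").set_index("image_path")
    merged = metrics.merge(
        lookup[["animal_id", "group"]], left_on="image_id", right_index=True,
        how="left")
    if merged["animal_id"].isna().any():
        bad = merged.loc[merged["animal_id"].isna(), "image_id"].tolist()
        raise ValueError(f"images missing from manifest: {bad}")

    missing_animals = sorted(
        set(manifest["animal_id"]) - set(merged["animal_id"]))
    if missing_animals:
        raise ValueError(
            f"animals with zero analysable images: {missing_animals}")

    rows = []
    for (animal, group), sub in sorted(merged.groupby(["animal_id", "group"],
                                                      sort=False)):
        w = sub["tissue_area"].to_numpy(dtype=float)
        if weighting == "none":
            w = np.ones_like(w)
        row = {"animal_id": animal, "group": group, "n_images": len(sub),
               "tissue_area": float(sub["tissue_area"].sum()),
               "islet_area": float(sub["islet_area"].sum())}
        for col in AREA_WEIGHTED:
            vals = sub[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.any() and w[ok].sum() > 0:
                row[col] = float(np.average(vals[ok], weights=w[ok]))
            else:
                row[col] = float("nan")
        if not np.isfinite(row["insulin_mean_intensity"]):
            logger.warning(
                "animal %s: no islet-bearing image; intensity metrics missing "
                "and the animal is excluded from intensity comparisons", animal)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("animal_id").reset_index(drop=True)
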
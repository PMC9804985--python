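"""Mask extraction: tissue, islet and insulin-positive regions from IF
fields, and DAB-positive regions from colour-deconvolved brightfield IHC.

Thresholds for islet and insulin masks are computed within their parent mask
only (Otsu by default) so the abundant empty glass never biases the
histogram.  All size filters work in um^2 via the pixel size, so one config
is valid across magnifications.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .types import (
    MultiChannelImage,
    MaskSet,
    SegmentationConfig,
    StainMatrix,
    NoTissueError,
)

logger = logging.getLogger(__name__)


def _remove_small(mask: np.ndarray, min_area_um2: float,
                  pixel_size: float) -> np.ndarray:
    min_px = int(np.ceil(min_area_um2 / pixel_size**2))
    if min_px <= 1:
        return mask
    # max_size semantics: components of size <= max_size are removed
    return morphology.remove_small_objects(mask, max_size=min_px - 1)


def _otsu_edge(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold placed at the upper edge of the background bin.

    skimage returns the background bin's centre, which misclassifies exact
    grey levels sitting on that centre (common in noise-free synthetic data);
    the bin edge keeps the whole background class strictly below threshold.
    """
    counts, edges = np.histogram(values, bins=nbins)
    p = counts.astype(np.float64) / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    denom = omega * (1.0 - omega)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(denom > 0, (mu_t * omega - mu) ** 2 / denom, 0.0)
    k = int(np.argmax(sigma_b[:-1]))
    return float(edges[k + 1])


def _threshold(values: np.ndarray, method: str, fixed: float) -> float:
    if method == "fixed":
        return fixed
    if values.size == 0 or values.min() == values.max():
        return np.inf  # degenerate histogram: nothing is foreground
    if method == "triangle":
        return float(filters.threshold_triangle(values))
    if method == "otsu":
        return _otsu_edge(values)
    if method == "otsu_capped":
        # Otsu restricted to values below the 85th percentile: bright
        # minority structures (nuclei, islets) are excluded so the split
        # falls between bare glass and tissue background even when tissue
        # dominates the histogram, where triangle and plain Otsu both fail
        cap = np.percentile(values, 85)
        low = values[values <= cap]
        if low.size == 0 or low.min() == low.max():
            return np.inf
        return _otsu_edge(low)
    raise ValueError(f"unknown threshold method {method!r}")


def _bimodal_contrast(values: np.ndarray, thr: float, min_sd: float) -> bool:
    """Whether an Otsu split reflects a real foreground class.

    Otsu always returns a threshold, even on pure background noise (where it
    simply halves the noise distribution).  A genuine stained class sits many
    background standard deviations above the background mean; splitting noise
    yields a class separation of only ~2.7 lower-class sds, so requiring
    ``mean(fore) - mean(back) >= min_sd * sd(back)`` separates the two cases.
    """
    if not np.isfinite(thr):
        return False
    back = values[values <= thr]
    fore = values[values > thr]
    if back.size < 2 or fore.size == 0:
        return False
    sd = back.std()
    if sd == 0:
        return True  # exact constant background: any excursion is signal
    return (fore.mean() - back.mean()) >= min_sd * sd


def compute_tissue_mask(img: MultiChannelImage,
                        cfg: SegmentationConfig) -> np.ndarray:
    """The 'pancreatic area examined': smoothed channel sum over threshold.

    Gaussian-blurs the sum of all channels at ``blur_sigma`` (um), thresholds
    (triangle by default), fills holes and drops components below
    ``min_tissue_area``.  Raises :class:`NoTissueError` when nothing remains.
    """
    s = img.channel_sum()
    sigma_px = cfg.blur_sigma / img.pixel_size
    if sigma_px > 0:
        s = ndi.gaussian_filter(s, sigma_px)
    thr = _threshold(s.ravel(), cfg.tissue_threshold_method,
                     cfg.tissue_fixed_threshold)
    mask = s > thr
    mask = ndi.binary_fill_holes(mask)
    mask = _remove_small(mask, cfg.min_tissue_area, img.pixel_size)
    if not mask.any():
        raise NoTissueError("no tissue detected in image")
    return mask


def _subtract_background(chan: np.ndarray, mask: np.ndarray,
                         cfg: SegmentationConfig, pixel_size: float) -> np.ndarray:
    if cfg.background_subtraction == "none":
        return chan
    if cfg.background_subtraction == "median":
        bg = np.median(chan[mask]) if mask.any() else 0.0
        return np.clip(chan - bg, 0.0, None)
    if cfg.background_subtraction == "rolling_ball":
        from skimage import restoration

        radius_px = max(cfg.background_radius / pixel_size, 1.0)
        bg = restoration.rolling_ball(chan, radius=radius_px)
        return np.clip(chan - bg, 0.0, None)
    raise ValueError(f"unknown background_subtraction {cfg.background_subtraction!r}")


def _cleanup(mask: np.ndarray, parent: np.ndarray, cfg: SegmentationConfig,
             pixel_size: float) -> np.ndarray:
    """Morphological closing, hole filling, size filter, clip to parent."""
    radius_px = cfg.closing_radius / pixel_size
    if radius_px >= 1:
        mask = morphology.closing(mask, morphology.disk(int(round(radius_px))))
    mask = ndi.binary_fill_holes(mask)
    mask = _remove_small(mask, cfg.min_islet_area, pixel_size)
    mask = mask & parent
    if cfg.exclude_border_islets and mask.any():
        mask = _drop_border_components(mask)
    return mask


def _drop_border_components(mask: np.ndarray) -> np.ndarray:
    labels, _ = ndi.label(mask)
    border = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    border = border[border != 0]
    if border.size:
        mask = mask & ~np.isin(labels, border)
    return mask


def compute_islet_mask(img: MultiChannelImage, tissue: np.ndarray,
                       cfg: SegmentationConfig) -> np.ndarray:
    """Synaptophysin-delineated islet mask within the tissue.

    The threshold is computed over tissue pixels only; an empty result is a
    valid outcome (a field with no islet) and is not an error.
    """
    tissue = np.asarray(tissue, dtype=bool)
    if not tissue.any():
        raise NoTissueError("tissue mask is empty")
    chan = _subtract_background(img.channels["synaptophysin"], tissue, cfg,
                                img.pixel_size)
    values = chan[tissue]
    thr = _threshold(values, cfg.islet_threshold_method,
                     cfg.islet_fixed_threshold)
    if (cfg.islet_threshold_method == "otsu"
            and not _bimodal_contrast(values, thr, cfg.min_contrast_sd)):
        return np.zeros_like(tissue)  # no islet in this field
    return _cleanup(chan > thr, tissue, cfg, img.pixel_size)


def compute_insulin_mask(img: MultiChannelImage, islet: np.ndarray,
                         cfg: SegmentationConfig) -> np.ndarray:
    """Insulin-positive pixels within the islet mask.

    The threshold depends on islet pixels only, so the result is invariant to
    anything outside the islets.  An empty islet mask yields an empty result.
    """
    islet = np.asarray(islet, dtype=bool)
    if not islet.any():
        logger.warning("insulin mask requested for an empty islet mask")
        return np.zeros_like(islet)
    chan = img.channels["insulin"]
    values = chan[islet]
    thr = _threshold(values, cfg.insulin_threshold_method,
                     cfg.insulin_fixed_threshold)
    if (cfg.insulin_threshold_method == "otsu"
            and not _bimodal_contrast(values, thr, cfg.min_contrast_sd)):
        return np.zeros_like(islet)
    return islet & (chan > thr)


def segment_if_image(img: MultiChannelImage,
                     cfg: SegmentationConfig | None = None) -> MaskSet:
    """Tissue -> islet -> insulin masks for one IF field."""
    if cfg is None:
        cfg = SegmentationConfig()
    tissue = compute_tissue_mask(img, cfg)
    islet = compute_islet_mask(img, tissue, cfg)
    insulin = compute_insulin_mask(img, islet, cfg)
    return MaskSet(tissue=tissue, islet=islet, insulin_positive=insulin,
                   config_used=cfg)


# ---------------------------------------------------------------------------
# brightfield IHC


def deconvolve_ihc(rgb: np.ndarray,
                   stains: StainMatrix | None = None) -> dict[str, np.ndarray]:
    """Unmix an RGB brightfield tile into per-stain OD channels.

    Per-channel OD is -log10((I + 1) / 256); per-stain amounts follow from
    the inverse stain matrix, with negative unmixed values clipped to 0.
    Accepts uint8 or float input on the 0..255 scale.
    """
    if stains is None:
        stains = StainMatrix.default()
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 RGB, got shape {rgb.shape}")
    od = -np.log10((rgb + 1.0) / 256.0)
    amounts = od @ stains.inverse()
    amounts = np.clip(amounts, 0.0, None)
    return {name: amounts[..., i] for i, name in enumerate(stains.names)}


def ihc_tissue_mask(od_maps: dict[str, np.ndarray], cfg: SegmentationConfig,
                    pixel_size: float, od_threshold: float = 0.04) -> np.ndarray:
    """Tissue on a brightfield tile: any stain uptake above a small OD floor.

    The haematoxylin counterstain washes the whole tissue, so total OD
    separates tissue from bare glass.
    """
    total = np.sum(list(od_maps.values()), axis=0)
    mask = ndi.binary_fill_holes(total > od_threshold)
    mask = _remove_small(mask, cfg.min_tissue_area, pixel_size)
    if not mask.any():
        raise NoTissueError("no tissue detected in IHC tile")
    return mask


def compute_dab_mask(dab_od: np.ndarray, tissue: np.ndarray,
                     cfg: SegmentationConfig, pixel_size: float) -> np.ndarray:
    """DAB-positive (synaptophysin) regions: OD threshold within tissue,
    then the same morphological cleanup as the IF islet mask."""
    tissue = np.asarray(tissue, dtype=bool)
    raw = (np.asarray(dab_od) >= cfg.dab_od_threshold) & tissue
    return _cleanup(raw, tissue, cfg, pixel_size)
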
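"""Synthetic cohorts of pancreas microscopy fields with exact ground truth.

The generator emulates the structure of a two-group (diabetic vs control)
histology study: sparse islets occupying a small fraction (~0.3-0.8%) of the
tissue area, an insulin-positive (beta-cell) sub-region of each islet of
roughly half the islet area, a multiplicative reduction of insulin intensity
in the diseased group, and shot + read noise on each fluorescence channel.
Ground truth (label maps, masks, per-image fractions) is exact by
construction, which makes the segmentation and statistics layers testable
against known answers.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
from skimage import draw as _draw

from .types import MultiChannelImage, StainMatrix, IF_CHANNELS

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


class PlacementError(RuntimeError):
    """Raised when islets cannot be placed to reach the requested area fraction."""

    def __init__(self, requested: float, achieved: float):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not reach requested islet area fraction {requested:.4%}; "
            f"achieved {achieved:.4%} (islets too large for the frame or "
            "placement attempts exhausted)"
        )


@dataclass
class GeneratorParams:
    """Conditions for one synthetic field (and per-animal draws in a cohort).

    Intensities are on the scale of ``bit_depth`` (arbitrary units, 0..255 for
    8 bit).  ``islet_radius_lognormal`` is (median radius in um, sigma of the
    natural-log radius).  ``noise_model`` is (poisson_gain, gaussian_sd): the
    Poisson gain converts intensity to expected photon counts (0 disables shot
    noise) and the Gaussian term is additive read noise; (0, 0) is noise-free.
    The ``*_animal_sd`` fields give between-animal spread used by cohort
    generation: log10-scale for islet fraction and insulin intensity
    (mean-preserving lognormal draws), absolute for the beta fraction.
    """

    image_shape: tuple[int, int] = (2048, 2048)
    pixel_size: float = 0.25  # um / pixel
    islet_area_fraction_target: float = 0.008  # fraction of tissue area
    islet_radius_lognormal: tuple[float, float] = (30.0, 0.25)
    beta_fraction: float = 0.55
    insulin_intensity: float = 180.0
    synaptophysin_intensity: float = 140.0
    background_level: float = 6.0  # tissue autofluorescence
    glass_level: float = 0.0  # outside tissue
    dapi_intensity: float = 120.0
    nuclei_density: float = 0.0015  # nuclei / um^2
    nucleus_radius: float = 3.5  # um
    tissue_frame_fraction: float = 0.75
    noise_model: tuple[float, float] = (1.0, 2.0)
    bit_depth: int = 8
    beta_mode: str = "blob"  # blob | bernoulli
    # between-animal variation (cohort level)
    islet_fraction_animal_sd: float = 0.25  # log10 scale
    insulin_intensity_animal_sd: float = 0.10  # log10 scale
    beta_fraction_animal_sd: float = 0.11  # absolute
    # brightfield IHC rendering
    ihc_nucleus_od: float = 0.65
    ihc_cytoplasm_od: float = 0.08
    ihc_dab_od: float = 0.80
    ihc_ap_od: float = 0.70
    macrophage_density: float = 2e-5  # dots / um^2
    macrophage_radius: float = 4.0  # um
    ihc_od_noise_sd: float = 0.01  # multiplicative (OD-scale) noise; 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.islet_area_fraction_target < 0.5):
            raise ValueError("islet_area_fraction_target must be in [0, 0.5)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not (0 <= self.beta_fraction <= 1):
            raise ValueError("beta_fraction must be in [0, 1]")
        if not (0.6 <= self.tissue_frame_fraction <= 0.85):
            raise ValueError("tissue_frame_fraction must be in [0.6, 0.85]")
        if self.beta_mode not in ("blob", "bernoulli"):
            raise ValueError(f"unknown beta_mode {self.beta_mode!r}")
        for name in ("insulin_intensity", "synaptophysin_intensity",
                     "background_level", "glass_level", "dapi_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        gain, sd = self.noise_model
        if gain < 0 or sd < 0:
            raise ValueError("noise_model components must be >= 0")

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2


@dataclass
class GroundTruth:
    """Exact geometry and intensities behind one synthetic field.

    ``true_islet_fraction`` and ``true_beta_fraction_of_islet`` are
    percentages computed from pixel counts of the stored maps (so they are
    consistent with the maps by construction); the beta fraction is NaN when
    the field contains no islet.
    """

    islet_label_map: np.ndarray  # int32, 0 = non-islet
    tissue_mask: np.ndarray  # bool
    beta_mask: np.ndarray  # bool
    true_islet_fraction: float  # % of tissue area
    true_beta_fraction_of_islet: float  # % of islet area (NaN if no islet)
    true_mean_insulin_intensity: float

    def validate(self) -> None:
        islet = self.islet_label_map > 0
        if np.any(islet & ~self.tissue_mask):
            raise AssertionError("islet outside tissue")
        if np.any(self.beta_mask & ~islet):
            raise AssertionError("beta mask outside islets")
        tp = int(self.tissue_mask.sum())
        ip = int(islet.sum())
        bp = int(self.beta_mask.sum())
        if tp == 0:
            raise AssertionError("empty tissue")
        if abs(self.true_islet_fraction - 100.0 * ip / tp) > 1e-9:
            raise AssertionError("true_islet_fraction inconsistent with maps")
        if ip > 0 and abs(self.true_beta_fraction_of_islet - 100.0 * bp / ip) > 1e-9:
            raise AssertionError("true_beta_fraction_of_islet inconsistent with maps")


def _tissue_blob(shape: tuple[int, int], frame_fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    """A smooth irregular blob covering ~frame_fraction of the frame."""
    rows, cols = shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    u = (np.arange(rows)[:, None] - r0) / rows
    v = (np.arange(cols)[None, :] - c0) / cols
    rad = np.hypot(u, v)
    theta = np.arctan2(u, v)
    base = math.sqrt(frame_fraction / math.pi)
    boundary = np.full(shape, base)
    for k in range(2, 6):
        eps = rng.uniform(0.0, 0.05)
        phi = rng.uniform(0.0, 2 * math.pi)
        boundary += base * eps * np.cos(k * theta + phi)
    return rad <= boundary


def _ellipse_axes(area_px: float, axis_ratio: float) -> tuple[float, float]:
    r = math.sqrt(area_px / math.pi)
    return r * math.sqrt(axis_ratio), r / math.sqrt(axis_ratio)


def _grow_blob(rr: np.ndarray, cc: np.ndarray, n_target: int,
               rng: np.random.Generator) -> np.ndarray:
    """Select a connected random blob of n_target pixels from a pixel set.

    Eden-style growth with a randomised frontier: beta cells cluster in islet
    cores rather than scattering, so the insulin-positive sub-region of each
    islet is one connected clump.  Returns a boolean selector over (rr, cc).
    """
    n = len(rr)
    if n_target >= n:
        return np.ones(n, dtype=bool)
    if n_target <= 0:
        return np.zeros(n, dtype=bool)
    rmin, cmin = rr.min(), cc.min()
    h, w = rr.max() - rmin + 1, cc.max() - cmin + 1
    local = np.full((h, w), -1, dtype=np.int64)  # map pixel -> index into rr
    local[rr - rmin, cc - cmin] = np.arange(n)
    selected = np.zeros(n, dtype=bool)
    in_frontier = np.zeros(n, dtype=bool)
    start = int(rng.integers(n))
    frontier = [start]
    in_frontier[start] = True
    count = 0
    lr = rr - rmin
    lc = cc - cmin
    while count < n_target and frontier:
        j = int(rng.integers(len(frontier)))
        frontier[j], frontier[-1] = frontier[-1], frontier[j]
        idx = frontier.pop()
        if selected[idx]:
            continue
        selected[idx] = True
        count += 1
        r, c = lr[idx], lc[idx]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w:
                nb = local[nr, nc]
                if nb >= 0 and not selected[nb] and not in_frontier[nb]:
                    in_frontier[nb] = True
                    frontier.append(nb)
    return selected


def sample_islet_geometry(params: GeneratorParams,
                          rng: np.random.Generator) -> GroundTruth:
    """Place elliptical islets in a tissue blob and carve beta-cell regions.

    Non-overlapping ellipses (axis ratio in [1, 2], random rotation) are
    placed fully inside the tissue until the islet pixel count reaches the
    requested fraction of tissue area; the final ellipse is shrunk to close
    the remaining gap, so the achieved fraction lands within +-10% relative
    of the target whenever the frame allows it.  A spatially clustered subset
    of each islet becomes the insulin-positive (beta) mask at the requested
    beta fraction.
    """
    shape = params.image_shape
    tissue = _tissue_blob(shape, params.tissue_frame_fraction, rng)
    label_map = np.zeros(shape, dtype=np.int32)
    tissue_px = int(tissue.sum())
    pa = params.pixel_area
    target_frac = params.islet_area_fraction_target

    if target_frac == 0:
        return GroundTruth(label_map, tissue, np.zeros(shape, dtype=bool),
                           0.0, float("nan"), params.insulin_intensity)

    target_px = target_frac * tissue_px
    min_area_px = max(4.0, min(28.0 / pa, target_px))  # ~radius-3um floor
    median_r, sigma = params.islet_radius_lognormal
    tissue_idx = np.flatnonzero(tissue)
    margin = 2.0  # px gap between islets keeps them separable

    placed = 0
    label = 0
    max_attempts = 400
    while target_px - placed >= min_area_px:
        remaining = target_px - placed
        r_um = float(rng.lognormal(math.log(median_r), sigma))
        area_px = min(math.pi * (r_um / params.pixel_size) ** 2, remaining)
        axis_ratio = float(rng.uniform(1.0, 2.0))
        rotation = float(rng.uniform(0.0, math.pi))
        a, b = _ellipse_axes(area_px, axis_ratio)
        shrink_to_fit = area_px == remaining

        placed_this = None
        for _ in range(max_attempts):
            flat = int(tissue_idx[rng.integers(len(tissue_idx))])
            r0, c0 = divmod(flat, shape[1])
            big = _draw.ellipse(r0, c0, a + margin, b + margin, rotation=rotation)
            br, bc = big
            if (br.min() < 0 or bc.min() < 0 or br.max() >= shape[0]
                    or bc.max() >= shape[1]):
                continue
            if not tissue[br, bc].all() or (label_map[br, bc] != 0).any():
                continue
            rr, cc = _draw.ellipse(r0, c0, a, b, rotation=rotation)
            if shrink_to_fit:
                # iterate a scale correction for lattice quantisation: small
                # ellipses gain/lose whole boundary pixels, so one rescale
                # can still miss the remaining-pixel budget
                aa, bb = a, b
                for _ in range(8):
                    if abs(len(rr) - remaining) <= max(2.0, 0.03 * remaining):
                        break
                    s = math.sqrt(remaining / len(rr))
                    aa, bb = max(aa * s, 1.0), max(bb * s, 1.0)
                    rr2, cc2 = _draw.ellipse(r0, c0, aa, bb, rotation=rotation)
                    if not (rr2.min() >= 0 and cc2.min() >= 0
                            and rr2.max() < shape[0] and cc2.max() < shape[1]
                            and tissue[rr2, cc2].all()
                            and not (label_map[rr2, cc2] != 0).any()):
                        break
                    if abs(len(rr2) - remaining) < abs(len(rr) - remaining):
                        rr, cc = rr2, cc2
            placed_this = (rr, cc)
            break
        if placed_this is None:
            raise PlacementError(target_frac, placed / tissue_px)
        rr, cc = placed_this
        label += 1
        label_map[rr, cc] = label
        placed += len(rr)

    achieved = placed / tissue_px
    tol_px = max(0.10 * target_px, 6.0)
    if abs(placed - target_px) > tol_px:
        raise PlacementError(target_frac, achieved)

    beta_mask = np.zeros(shape, dtype=bool)
    for lab in range(1, label + 1):
        rr, cc = np.nonzero(label_map == lab)
        n_beta = int(round(params.beta_fraction * len(rr)))
        if params.beta_mode == "blob":
            sel = _grow_blob(rr, cc, n_beta, rng)
        else:
            # spatially unclustered alternative: an exact-count random
            # subset, so the per-islet beta fraction contract still holds
            sel = np.zeros(len(rr), dtype=bool)
            sel[rng.permutation(len(rr))[:n_beta]] = True
        beta_mask[rr[sel], cc[sel]] = True

    islet_px = int((label_map > 0).sum())
    beta_px = int(beta_mask.sum())
    gt = GroundTruth(
        islet_label_map=label_map,
        tissue_mask=tissue,
        beta_mask=beta_mask,
        true_islet_fraction=100.0 * islet_px / tissue_px,
        true_beta_fraction_of_islet=(100.0 * beta_px / islet_px
                                     if islet_px else float("nan")),
        true_mean_insulin_intensity=params.insulin_intensity,
    )
    return gt


def _paint_disks(arr: np.ndarray, centres_flat: np.ndarray, radius_px: float,
                 value: float) -> None:
    """Set disks of ``radius_px`` around flat-index centres to ``value``.

    One disk template is broadcast over all centres; indices falling outside
    the frame are clipped to its edge (centres lie inside tissue, so only
    boundary-touching disks are affected).
    """
    if len(centres_flat) == 0:
        return
    rows, cols = arr.shape
    r = int(math.ceil(radius_px))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    inside = (dr**2 + dc**2) <= radius_px**2
    dr, dc = dr[inside], dc[inside]
    cr, cc = np.divmod(centres_flat.astype(np.int64), cols)
    rr = np.clip(cr[:, None] + dr[None, :], 0, rows - 1)
    cc = np.clip(cc[:, None] + dc[None, :], 0, cols - 1)
    arr[rr.ravel(), cc.ravel()] = value


def _apply_noise(chan: np.ndarray, gain: float, sd: float,
                 rng: np.random.Generator, max_value: float) -> np.ndarray:
    out = chan
    if gain > 0:
        out = rng.poisson(out * gain).astype(np.float64) / gain
    if sd > 0:
        out = out + rng.normal(0.0, sd, out.shape)
    return np.clip(out, 0.0, max_value)  # clip, never wrap


def render_if_image(gt: GroundTruth, params: GeneratorParams,
                    rng: np.random.Generator) -> MultiChannelImage:
    """Render the three-channel fluorescence field for a ground truth.

    Synaptophysin marks all islet pixels, insulin the beta sub-mask, and DAPI
    random nuclear disks within tissue; outside the tissue only the glass
    level remains.  Each channel passes through Poisson shot noise then
    additive Gaussian read noise and is clipped to the declared bit depth.
    """
    if gt.islet_label_map.shape != params.image_shape:
        raise ValueError("ground truth and params do not share geometry")
    shape = params.image_shape
    tissue = gt.tissue_mask
    islet = gt.islet_label_map > 0
    bg = np.where(tissue, params.background_level, params.glass_level)

    syn = np.where(islet, params.synaptophysin_intensity, bg)
    ins = np.where(gt.beta_mask, params.insulin_intensity, bg)

    dapi = bg.copy()
    area_um2 = tissue.sum() * params.pixel_area
    n_nuclei = int(round(params.nuclei_density * area_um2))
    if n_nuclei > 0 and params.dapi_intensity > 0:
        tissue_idx = np.flatnonzero(tissue)
        centres = tissue_idx[rng.integers(0, len(tissue_idx), size=n_nuclei)]
        r_px = max(params.nucleus_radius / params.pixel_size, 1.0)
        _paint_disks(dapi, centres, r_px, params.dapi_intensity)

    gain, sd = params.noise_model
    max_value = float(2**params.bit_depth - 1)
    channels = {
        "dapi": _apply_noise(dapi, gain, sd, rng, max_value),
        "synaptophysin": _apply_noise(syn, gain, sd, rng, max_value),
        "insulin": _apply_noise(ins, gain, sd, rng, max_value),
    }
    return MultiChannelImage(channels=channels, pixel_size=params.pixel_size,
                             bit_depth=params.bit_depth)


def stain_amount_maps(gt: GroundTruth, params: GeneratorParams,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-stain OD amount maps for a brightfield double-stained IHC tile.

    Haematoxylin sits on nuclei (plus a faint cytoplasmic wash over the
    tissue), DAB (the brown HRP chromogen, here read as synaptophysin) covers
    islet pixels, and sparse AP-magenta dots stand in for scattered
    macrophages.
    """
    shape = gt.islet_label_map.shape
    tissue = gt.tissue_mask
    haem = np.where(tissue, params.ihc_cytoplasm_od, 0.0)
    area_um2 = tissue.sum() * params.pixel_area
    tissue_idx = np.flatnonzero(tissue)

    n_nuclei = int(round(params.nuclei_density * area_um2))
    r_px = max(params.nucleus_radius / params.pixel_size, 1.0)
    _paint_disks(haem, tissue_idx[rng.integers(0, len(tissue_idx), size=n_nuclei)],
                 r_px, params.ihc_nucleus_od)

    dab = np.where(gt.islet_label_map > 0, params.ihc_dab_od, 0.0)

    ap = np.zeros(shape)
    n_mac = int(round(params.macrophage_density * area_um2))
    m_px = max(params.macrophage_radius / params.pixel_size, 1.0)
    _paint_disks(ap, tissue_idx[rng.integers(0, len(tissue_idx), size=n_mac)],
                 m_px, params.ihc_ap_od)
    return {"haematoxylin": haem, "dab": dab, "ap_magenta": ap}


def compose_ihc_rgb(amounts: dict[str, np.ndarray],
                    stains: StainMatrix) -> np.ndarray:
    """Beer-Lambert composition of per-stain OD maps into a float RGB tile.

    Transmitted intensity per channel is 256 * 10**(-OD) - 1 (clipped to
    [0, 255]), the exact inverse of the unmixing transform
    OD = -log10((I + 1) / 256), so a noise-free render/deconvolve round trip
    is lossless.
    """
    stack = np.stack([amounts[name] for name in stains.names], axis=-1)
    od_rgb = stack @ stains.vectors  # (..., 3)
    rgb = 256.0 * np.power(10.0, -od_rgb) - 1.0
    return np.clip(rgb, 0.0, 255.0)


def render_ihc_tile(gt: GroundTruth, params: GeneratorParams,
                    stains: StainMatrix | None = None,
                    rng: np.random.Generator | None = None,
                    quantize: bool = True) -> np.ndarray:
    """Render a brightfield IHC tile (uint8 RGB, or float when quantize=False).

    Small multiplicative noise (log-normal in intensity, i.e. Gaussian in OD)
    is applied when ``params.ihc_od_noise_sd`` > 0.
    """
    if stains is None:
        stains = StainMatrix.default()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    amounts = stain_amount_maps(gt, params, rng)
    rgb = compose_ihc_rgb(amounts, stains)
    if params.ihc_od_noise_sd > 0:
        factor = np.power(10.0, -rng.normal(0.0, params.ihc_od_noise_sd, rgb.shape))
        rgb = np.clip(rgb * factor, 0.0, 255.0)
    if quantize:
        return np.rint(rgb).astype(np.uint8)
    return rgb


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupSpec:
    """One study group: a name, its size, and parameter overrides."""

    name: str
    n_animals: int
    overrides: dict = field(default_factory=dict)
    is_control: bool = False


@dataclass
class CohortSpec:
    """A whole two-or-more-group cohort with deterministic per-animal seeds."""

    groups: list[GroupSpec]
    images_per_animal: int = 2
    base_params: GeneratorParams = field(default_factory=GeneratorParams)
    master_seed: int = 0
    modality: str = "if"  # if | ihc | both

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a cohort needs at least two groups")
        controls = [g for g in self.groups if g.is_control]
        if len(controls) != 1:
            raise ValueError("exactly one group must be flagged as control")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for g in self.groups:
            if g.n_animals < 2:
                raise ValueError(f"group {g.name!r} needs >= 2 animals")
        if self.images_per_animal < 1:
            raise ValueError("images_per_animal must be >= 1")
        if self.modality not in ("if", "ihc", "both"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def control_group(self) -> str:
        return next(g.name for g in self.groups if g.is_control)


def animal_seed_sequence(master_seed: int, group: str,
                         animal_index: int) -> np.random.SeedSequence:
    """Deterministic per-animal seed; adding a group never perturbs others."""
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(group.encode("utf-8")), int(animal_index)]
    )


def _draw_animal_params(base: GeneratorParams,
                        rng: np.random.Generator) -> GeneratorParams:
    """Between-animal biological variation around the group-level parameters.

    Islet fraction and insulin intensity get mean-preserving multiplicative
    log-normal factors (log10-scale sds from the params); the beta fraction
    gets an additive Gaussian perturbation clipped to [0.05, 0.95].
    """
    updates: dict = {}
    if base.islet_fraction_animal_sd > 0:
        s = base.islet_fraction_animal_sd * _LN10
        f = base.islet_area_fraction_target * math.exp(rng.normal(-s * s / 2, s))
        updates["islet_area_fraction_target"] = min(f, 0.45)
    if base.insulin_intensity_animal_sd > 0:
        s = base.insulin_intensity_animal_sd * _LN10
        updates["insulin_intensity"] = base.insulin_intensity * math.exp(
            rng.normal(-s * s / 2, s))
    if base.beta_fraction_animal_sd > 0:
        updates["beta_fraction"] = float(
            np.clip(rng.normal(base.beta_fraction, base.beta_fraction_animal_sd),
                    0.05, 0.95))
    return replace(base, **updates) if updates else base


@dataclass
class CohortImage:
    """One generated field with its provenance and ground truth."""

    group: str
    animal_id: str
    image_id: str
    params: GeneratorParams  # the per-animal parameter draw
    ground_truth: GroundTruth
    image: MultiChannelImage | None  # IF field (None for ihc-only cohorts)
    ihc_tile: np.ndarray | None  # uint8 RGB (None for if-only cohorts)


def iter_cohort(spec: CohortSpec,
                stains: StainMatrix | None = None) -> Iterator[CohortImage]:
    """Generate every field of a cohort in memory, deterministically."""
    for group in spec.groups:
        base = (replace(spec.base_params, **group.overrides)
                if group.overrides else spec.base_params)
        for a in range(group.n_animals):
            ss = animal_seed_sequence(spec.master_seed, group.name, a)
            animal_rng = np.random.default_rng(ss)
            aparams = _draw_animal_params(base, animal_rng)
            animal_id = f"{group.name}_{a + 1:02d}"
            for j, child in enumerate(ss.spawn(spec.images_per_animal)):
                rng = np.random.default_rng(child)
                gt = sample_islet_geometry(aparams, rng)
                img = (render_if_image(gt, aparams, rng)
                       if spec.modality in ("if", "both") else None)
                tile = (render_ihc_tile(gt, aparams, stains, rng)
                        if spec.modality in ("ihc", "both") else None)
                yield CohortImage(
                    group=group.name,
                    animal_id=animal_id,
                    image_id=f"{animal_id}_img{j + 1:02d}",
                    params=aparams,
                    ground_truth=gt,
                    image=img,
                    ihc_tile=tile,
                )


def generate_cohort(spec: CohortSpec, out_dir: str | Path,
                    stains: StainMatrix | None = None):
    """Write a cohort to disk: images, a manifest CSV and a ground-truth CSV.

    Returns the manifest as a DataFrame.  On any failure all files written so
    far are removed so a partial cohort never survives.
    """
    import pandas as pd

    from .io import write_if_image, write_rgb_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest_rows = []
    truth_rows = []
    try:
        for item in iter_cohort(spec, stains):
            if item.image is not None:
                path = out / f"{item.image_id}_if.ome.tif"
                write_if_image(path, item.image)
                written.append(path)
                manifest_rows.append(
                    {"image_path": path.name, "animal_id": item.animal_id,
                     "group": item.group, "modality": "if"})
                truth_rows.append(_truth_row(path.name, item))
            if item.ihc_tile is not None:
                path = out / f"{item.image_id}_ihc.png"
                write_rgb_png(path, item.ihc_tile)
                written.append(path)
                manifest_rows.append(
                    {"image_path": path.name, "animal_id": item.animal_id,
                     "group": item.group, "modality": "ihc"})
                truth_rows.append(_truth_row(path.name, item))
        manifest = pd.DataFrame(manifest_rows,
                                columns=["image_path", "animal_id", "group",
                                         "modality"])
        truth = pd.DataFrame(truth_rows)
        manifest.to_csv(out / "manifest.csv", index=False)
        written.append(out / "manifest.csv")
        truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.10g")
        written.append(out / "ground_truth.csv")
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        logger.error("cohort generation failed; removed %d partial outputs",
                     len(written))
        raise
    return manifest


def _truth_row(image_path: str, item: CohortImage) -> dict:
    gt = item.ground_truth
    return {
        "image_path": image_path,
        "animal_id": item.animal_id,
        "group": item.group,
        "true_islet_fraction_pct": gt.true_islet_fraction,
        "true_beta_fraction_of_islet_pct": gt.true_beta_fraction_of_islet,
        "true_mean_insulin_intensity": gt.true_mean_insulin_intensity,
    }
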
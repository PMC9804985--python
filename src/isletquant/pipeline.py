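"""Orchestration: manifest in, per-image metrics, per-animal table and group
statistics out, with per-image fault isolation and full determinism under a
fixed seed."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .io import read_if_image, read_manifest, write_mask_png, write_rgb_png
from .quantification import aggregate_per_animal, metrics_to_frame, per_image_metrics
from .segmentation import segment_if_image
from .stats import compare_cohort, results_to_frame
from .types import MaskSet, MultiChannelImage, SegmentationConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Source of truth for one pipeline run (YAML-serialisable)."""

    manifest: str
    out_dir: str
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    control_group: str = "non_diabetic"
    alpha: float = 0.05
    transform: str = "log10"
    zero_policy: str = "error"
    weighting: str = "tissue_area"
    metrics: tuple[str, ...] = ("islet_area_pct_of_tissue",
                                "insulin_pos_area_pct_of_islet",
                                "insulin_mean_bgsub")
    pixel_size: float | None = None  # override image metadata when set
    write_masks: bool = False
    write_qc: bool = False
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(segmentation=seg, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        return d


@dataclass
class RunReport:
    """Accounting of one run: processed + flagged + excluded = manifest rows."""

    processed: int
    flagged: int
    excluded: int
    n_manifest: int
    failures: dict[str, str]
    version: str = _version
    seed: int = 0

    def __post_init__(self) -> None:
        if self.processed + self.flagged + self.excluded != self.n_manifest:
            raise AssertionError("report accounting identity violated")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute segment -> quantify -> stats over a manifest.

    A failure on any single image flags that image and the run continues;
    an unreadable manifest or a fully empty cohort aborts.  All outputs
    (CSVs, JSON provenance, optional masks and QC overlays) land in
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    manifest_dir = Path(config.manifest).parent
    if_rows = manifest[manifest["modality"] == "if"]
    excluded = len(manifest) - len(if_rows)

    rows = []
    failures: dict[str, str] = {}
    for rec in if_rows.itertuples():
        path = manifest_dir / rec.image_path
        try:
            img = read_if_image(path, pixel_size=config.pixel_size)
            masks = segment_if_image(img, config.segmentation)
            rows.append(per_image_metrics(img, masks, rec.image_path))
            if config.write_masks:
                _write_masks(out, rec.image_path, masks)
            if config.write_qc:
                write_rgb_png(out / f"{Path(rec.image_path).stem}_qc.png",
                              render_qc_overlay(img, masks))
        except Exception as exc:  # per-image fault isolation
            logger.warning("image %s flagged: %s", rec.image_path, exc)
            failures[str(rec.image_path)] = str(exc)
    if not rows:
        raise RuntimeError("no image in the manifest could be analysed")

    metrics = metrics_to_frame(rows)
    analysed = manifest[manifest["image_path"].isin(metrics["image_id"])]
    per_animal = aggregate_per_animal(metrics, analysed,
                                      weighting=config.weighting)
    results = compare_cohort(per_animal, list(config.metrics),
                             control=config.control_group, alpha=config.alpha,
                             transform=config.transform,
                             zero_policy=config.zero_policy)

    float_fmt = "%.10g"
    metrics.to_csv(out / "per_image_metrics.csv", index=False,
                   float_format=float_fmt)
    per_animal.to_csv(out / "per_animal.csv", index=False,
                      float_format=float_fmt)
    results_to_frame(results).to_csv(out / "stats_results.csv", index=False,
                                     float_format=float_fmt)

    report = RunReport(processed=len(rows), flagged=len(failures),
                       excluded=excluded, n_manifest=len(manifest),
                       failures=failures, seed=config.master_seed)
    provenance = {
        "config": config.to_dict(),
        "report": dataclasses.asdict(report),
        "versions": {"isletquant": _version, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report


def _write_masks(out: Path, image_path: str, masks: MaskSet) -> None:
    stem = Path(image_path).stem
    write_mask_png(out / f"{stem}_tissue.png", masks.tissue)
    write_mask_png(out / f"{stem}_islet.png", masks.islet)
    write_mask_png(out / f"{stem}_insulin.png", masks.insulin_positive)


def _outline(mask: np.ndarray) -> np.ndarray:
    """Morphological boundary: mask minus its erosion."""
    from scipy import ndimage as ndi

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    return mask & ~ndi.binary_erosion(mask, border_value=0)


def render_qc_overlay(img: MultiChannelImage, masks: MaskSet) -> np.ndarray:
    """Composite RGB for visual QC: insulin gold, synaptophysin magenta,
    DAPI cyan, with islet outlines in white and insulin-positive outlines
    in red."""
    scale = img.max_value
    ins = np.clip(img.channels["insulin"] / scale, 0, 1)
    syn = np.clip(img.channels["synaptophysin"] / scale, 0, 1)
    dapi = np.clip(img.channels["dapi"] / scale, 0, 1)
    r = np.clip(ins + syn, 0, 1)
    g = np.clip(0.85 * ins + dapi, 0, 1)
    b = np.clip(syn + dapi, 0, 1)
    rgb = np.stack([r, g, b], axis=-1)
    islet_edge = _outline(masks.islet)
    ins_edge = _outline(masks.insulin_positive)
    rgb[islet_edge] = (1.0, 1.0, 1.0)
    rgb[ins_edge] = (1.0, 0.0, 0.0)
    return (rgb * 255).astype(np.uint8)
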
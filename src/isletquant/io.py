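"""Reading and writing the pipeline's file formats.

IF fields travel as OME-TIFF (axes CYX, named channels); IHC tiles as RGB
PNG/TIFF; masks as 0/255 8-bit PNG; manifests and metric tables as CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import MultiChannelImage, IF_CHANNELS

_SUFFIX_TO_CHANNEL = {"_dapi": "dapi", "_syn": "synaptophysin", "_ins": "insulin"}

MANIFEST_COLUMNS = ("image_path", "animal_id", "group")


def write_if_image(path: str | Path, img: MultiChannelImage) -> None:
    """Write a multichannel field as OME-TIFF with named channels.

    Intensities are rounded to the integer dtype implied by the bit depth.
    """
    names = list(img.channels)
    stack = np.stack([img.channels[n] for n in names])
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    stack = np.rint(np.clip(stack, 0, img.max_value)).astype(dtype)
    tifffile.imwrite(
        Path(path),
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": img.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": img.pixel_size,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_if_image(path: str | Path, pixel_size: float | None = None,
                  bit_depth: int | None = None) -> MultiChannelImage:
    """Read an OME-TIFF / multi-page TIFF field, or a per-channel TIFF triplet.

    Channel names come from OME metadata when present; a path ending in one of
    the suffixes ``_dapi/_syn/_ins`` (before the extension) is treated as one
    member of a single-channel triplet and its siblings are loaded too.
    Explicit ``pixel_size`` overrides file metadata.
    """
    path = Path(path)
    stem = path.name
    for suffix, _ in _SUFFIX_TO_CHANNEL.items():
        if suffix in stem:
            return _read_triplet(path, suffix, pixel_size, bit_depth)

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        names = None
        px = None
        if tif.ome_metadata:
            import re

            names = re.findall(r'Channel[^>]*Name="([^"]+)"', tif.ome_metadata)
            m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tif.ome_metadata)
            if m:
                px = float(m.group(1))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {arr.shape}")
    if arr.shape[0] > arr.shape[-1]:  # tolerate YXC layouts
        if arr.shape[-1] in (1, 3) and arr.shape[0] not in (1, 3):
            arr = np.moveaxis(arr, -1, 0)
    if not names or len(names) != arr.shape[0]:
        if arr.shape[0] == len(IF_CHANNELS):
            names = list(IF_CHANNELS)
        else:
            names = [f"ch{i}" for i in range(arr.shape[0])]
    if bit_depth is None:
        bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return MultiChannelImage(
        channels={n: arr[i] for i, n in enumerate(names)},
        pixel_size=pixel_size if pixel_size is not None else (px or 1.0),
        bit_depth=bit_depth,
    )


def _read_triplet(path: Path, suffix: str, pixel_size: float | None,
                  bit_depth: int | None) -> MultiChannelImage:
    channels = {}
    for suf, name in _SUFFIX_TO_CHANNEL.items():
        sibling = path.with_name(path.name.replace(suffix, suf))
        if not sibling.exists():
            raise FileNotFoundError(f"missing channel file {sibling}")
        channels[name] = tifffile.imread(sibling)
    itemsize = max(a.dtype.itemsize for a in channels.values())
    if bit_depth is None:
        bit_depth = 16 if itemsize > 1 else 8
    return MultiChannelImage(channels=channels,
                             pixel_size=pixel_size or 1.0, bit_depth=bit_depth)


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_rgb_image(path: str | Path) -> np.ndarray:
    """Read an RGB IHC tile (PNG or TIFF) as uint8 HxWx3."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path} is not an RGB image (shape {arr.shape})")
    return arr.astype(np.uint8)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (image_path, animal_id, group[, modality])."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {missing}")
    if "modality" not in df.columns:
        df["modality"] = "if"
    if df.empty:
        raise ValueError(f"manifest {path} is empty")
    return df
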
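"""Reading and writing masks, label maps, overlays and reports."""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.segmentation import find_boundaries

from .flow import PressureField
from .separation import InstanceLabelMap, SeparationCandidate

__all__ = [
    "read_mask",
    "write_mask",
    "read_label_map",
    "write_label_map",
    "write_overlay",
    "write_psi_maps",
    "instances_table",
]

_RASTER_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}

OVERLAY_BOUNDARY = (0, 255, 0)  # green instance boundaries
OVERLAY_LINE = (0, 0, 255)  # blue separation lines
OVERLAY_CENTROID = (255, 0, 0)  # red CG points


def read_mask(path) -> np.ndarray:
    """Load a raster file as a boolean object mask (nonzero -> object).

    RGB images are reduced by channel maximum before thresholding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    if path.suffix.lower() not in _RASTER_EXTS:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img.max(axis=-1)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"{path} is not a non-empty 2D image")
    return img > 0


def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_label_map(labels: InstanceLabelMap | np.ndarray, path) -> None:
    """Write instance labels as 16-bit unsigned TIFF (background 0)."""
    arr = labels.labels if isinstance(labels, InstanceLabelMap) else np.asarray(labels)
    if arr.max(initial=0) >= 65_536:
        raise ValueError(
            "more than 65535 labels; write the raw array as 32-bit instead"
        )
    tifffile.imwrite(os.fspath(path), arr.astype(np.uint16))


def read_label_map(path) -> InstanceLabelMap:
    return InstanceLabelMap.from_labels(tifffile.imread(os.fspath(path)).astype(np.int32))


def write_psi_maps(fields: dict, out_dir) -> list[Path]:
    """Debug dump of per-direction pressure maps as 32-bit float TIFFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for alpha, f in sorted(fields.items(), key=lambda kv: int(kv[0])):
        p = out_dir / f"psi_{int(alpha)}.tif"
        tifffile.imwrite(os.fspath(p), f.psi.astype(np.float32))
        written.append(p)
    return written


def write_overlay(
    original: np.ndarray,
    labels: InstanceLabelMap,
    lines: list[SeparationCandidate],
    path,
) -> None:
    """RGB PNG: green instance boundaries, blue separation lines, red centroids."""
    base = np.asarray(original)
    if base.shape[:2] != labels.labels.shape:
        raise ValueError(
            f"shape mismatch: image {base.shape[:2]} vs labels {labels.labels.shape}"
        )
    if base.ndim == 2:
        lo, hi = float(base.min()), float(base.max())
        gray = np.zeros_like(base, dtype=np.uint8) if hi == lo else (
            (base.astype(float) - lo) / (hi - lo) * 255
        ).astype(np.uint8)
        rgb = np.stack([gray] * 3, axis=-1)
    else:
        rgb = base[..., :3].astype(np.uint8).copy()

    rgb[find_boundaries(labels.labels, mode="outer")] = OVERLAY_BOUNDARY
    for cand in lines:
        for r, c in cand.line_pixels:
            rgb[r, c] = OVERLAY_LINE
    for r, c in labels.centroids:
        rgb[int(round(r)), int(round(c))] = OVERLAY_CENTROID
    iio.imwrite(Path(path), rgb)


def instances_table(labels: InstanceLabelMap) -> pd.DataFrame:
    """Per-instance table: label, area in pixels, centroid coordinates."""
    arr = labels.labels
    ids = np.unique(arr)
    ids = ids[ids > 0]
    rows = []
    for lab, (cr, cc) in zip(ids.tolist(), labels.centroids):
        rows.append(
            {
                "label": lab,
                "area_px": int(np.sum(arr == lab)),
                "centroid_row": cr,
                "centroid_col": cc,
            }
        )
    return pd.DataFrame(rows, columns=["label", "area_px", "centroid_row", "centroid_col"])
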
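"""ACCEPT-style image analysis of multichannel fluorescence cartridges.

Each channel (DNA/DAPI, cytokeratin, CD45) is segmented independently by
thresholding (triangle method with an optional absolute floor) and 8-connected
component labeling; per-object morphology and intensity features are then
measured.  The cytokeratin object defines the *event* footprint - both CTCs
and tdEVs are CK-positive by definition - and DNA/CD45 features are measured
on the overlapping object of the respective channel (all zeros when no object
overlaps).

Coordinates are 0-based (x right, y down); areas are reported in um^2 using
``pixel_size**2``, perimeters in um.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_triangle
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .config import EVENT_FEATURE_COLUMNS

__all__ = ["ImageStack", "segment_channel", "extract_features",
           "read_image_stack", "write_image_stack"]

CHANNEL_ORDER = ("dna", "ck", "cd45")


@dataclass
class ImageStack:
    """Co-registered 2-D rasters, one per fluorescence channel."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0  # um / pixel

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for c, a in self.channels.items():
            if a.ndim != 2:
                raise ValueError(f"channel {c!r} is not 2-D")
            if (np.asarray(a) < 0).any():
                raise ValueError(f"channel {c!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def segment_channel(raster: np.ndarray, method: str = "triangle",
                    abs_floor: float | None = None, min_pixels: int = 4) -> np.ndarray:
    """Threshold + 8-connected labeling of one channel.

    ``method`` is "triangle" (robust on sparse fluorescent fields) or
    "absolute" (threshold = ``abs_floor``).  With the triangle method,
    ``abs_floor`` acts as a lower bound on the threshold.  Components smaller
    than ``min_pixels`` are removed; labels are re-packed to 1..n in scan
    order.  Background is 0.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2 or raster.size == 0:
        raise ValueError("raster must be a nonempty 2-D array")
    if method == "triangle":
        thr = float(threshold_triangle(raster))
        if abs_floor is not None:
            thr = max(thr, abs_floor)
    elif method == "absolute":
        if abs_floor is None:
            raise ValueError("absolute method requires abs_floor")
        thr = float(abs_floor)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    mask = raster > thr
    labels = sk_label(mask, connectivity=2)  # 8-connected
    if min_pixels > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        kill = np.flatnonzero(sizes < min_pixels)
        labels[np.isin(labels, kill)] = 0
        # re-pack labels to consecutive 1..n
        remap = np.zeros(labels.max() + 1, dtype=labels.dtype)
        kept = np.unique(labels[labels > 0])
        remap[kept] = np.arange(1, kept.size + 1)
        labels = remap[labels]
    return labels


def _object_features(pixels_mask: np.ndarray, raster: np.ndarray, pixel_size: float) -> dict:
    """Morphology + intensity features of one object given its pixel mask."""
    props = regionprops(pixels_mask.astype(np.uint8), intensity_image=raster)[0]
    vals = raster[pixels_mask]
    return {
        "area": props.area * pixel_size ** 2,
        "perimeter": props.perimeter * pixel_size,
        "eccentricity": props.eccentricity,
        "mean_intensity": float(vals.mean()),
        "max_intensity": float(vals.max()),
        "total_intensity": float(vals.sum()),
        "sd_intensity": float(vals.std()),
    }


_ZERO_FEATURES = {k: 0.0 for k in ("area", "perimeter", "eccentricity", "mean_intensity",
                                   "max_intensity", "total_intensity", "sd_intensity")}


def extract_features(masks: dict[str, np.ndarray], stack: ImageStack,
                     sample_id: str = "sample") -> pd.DataFrame:
    """One EventFeatureRecord per cytokeratin object.

    For the DNA and CD45 channels the features are measured on the object of
    that channel's own mask that overlaps the CK footprint most (zeros when
    none overlaps).  ``overlap_dna_ck`` is the fraction of CK-object pixels
    that fall inside any DNA object.
    """
    for ch in CHANNEL_ORDER:
        if ch not in masks or ch not in stack.channels:
            raise ValueError(f"missing channel {ch!r} in masks or stack")
        if masks[ch].shape != stack.shape:
            raise ValueError(f"mask/stack shape mismatch for channel {ch!r}")

    ck_labels = masks["ck"]
    rows = []
    for idx, obj in enumerate(regionprops(ck_labels)):
        ck_mask = ck_labels == obj.label
        row: dict = {"event_id": f"{sample_id}-{idx:05d}", "sample_id": sample_id}
        feats = _object_features(ck_mask, stack.channels["ck"], stack.pixel_size)
        row.update({f"{k}_ck": v for k, v in feats.items()})

        for ch in ("dna", "cd45"):
            ch_labels = masks[ch]
            hit = ch_labels[ck_mask]
            hit = hit[hit > 0]
            if hit.size:
                match = np.bincount(hit).argmax()  # most-overlapping object
                ch_mask = ch_labels == match
                feats = _object_features(ch_mask, stack.channels[ch], stack.pixel_size)
            else:
                feats = _ZERO_FEATURES
            row.update({f"{k}_{ch}": v for k, v in feats.items()})

        dna_any = masks["dna"] > 0
        row["overlap_dna_ck"] = float(dna_any[ck_mask].sum() / ck_mask.sum())
        cy, cx = obj.centroid
        row["centroid_x"], row["centroid_y"] = float(cx), float(cy)
        rows.append(row)

    out = pd.DataFrame(rows, columns=_RECORD_COLUMNS())
    return out


def _RECORD_COLUMNS() -> list[str]:
    # EVENT_FEATURE_COLUMNS uses e.g. area_dna; _object_features emits area -> area_dna
    return list(EVENT_FEATURE_COLUMNS)


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    """Multipage TIFF, one page per channel in (DNA, CK, CD45) order, with a
    sidecar ``<path>.channels.txt`` recording the order and pixel size."""
    path = Path(path)
    pages = np.stack([np.asarray(stack.channels[c], dtype=np.float32) for c in CHANNEL_ORDER])
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".channels.txt")
    sidecar.write_text("\n".join([*CHANNEL_ORDER, f"pixel_size={stack.pixel_size}"]) + "\n")


def read_image_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] < 3:
        raise ValueError(f"{path}: expected >= 3 channel pages, got shape {pages.shape}")
    pixel_size = 1.0
    sidecar = path.with_suffix(path.suffix + ".channels.txt")
    order = list(CHANNEL_ORDER)
    if sidecar.exists():
        lines = [ln.strip() for ln in sidecar.read_text().splitlines() if ln.strip()]
        order = [ln for ln in lines if not ln.startswith("pixel_size=")]
        for ln in lines:
            if ln.startswith("pixel_size="):
                pixel_size = float(ln.split("=", 1)[1])
    channels = {c: pages[i].astype(float) for i, c in enumerate(order[:pages.shape[0]])}
    return ImageStack(channels=channels, pixel_size=pixel_size)
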
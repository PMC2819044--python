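"""Nuclear segmentation: contrast stretch, thresholding, cleaning, border handling.

The chain mirrors routine morphometric practice: stretch contrast inside the
ROI, threshold dark nuclei (Otsu on ROI pixels unless a manual level is
given), fill holes and drop specks, then suppress any nucleus cutting the
image frame so ROI and mean nuclear areas are measured on whole nuclei only.
Touching nuclei are deliberately not split: cluster splitting has no robust
automatic solution, and the synthetic generator keeps nuclei separable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border

from .image import EpitheliumImage

#: Default minimum component area (px^2) kept by mask cleaning, about one
#: sixth of the smallest reference mean nucleus area.
DEFAULT_MIN_AREA = 30

# 8-connectivity for nuclei, 4-connectivity for background holes: the
# standard dual pairing on a square grid.
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class NucleiLabelMap:
    """Labeled nuclei after cleaning and border suppression."""

    labels: np.ndarray  # int raster, 0 = background, 1..count = nuclei
    count: int
    mean_area: float | None  # px^2; None when count == 0

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def areas(self) -> np.ndarray:
        return np.bincount(self.labels.ravel())[1:]


def preprocess(img: EpitheliumImage) -> EpitheliumImage:
    """Linearly stretch ROI grey values so the 1st/99th percentiles map to 0/255.

    Pixels outside the ROI are untouched.  A (near-)constant ROI is returned
    unchanged with a warning.  Idempotent up to rounding.
    """
    grey = img.grey.astype(np.float64)
    vals = grey[img.roi]
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi - lo < 1e-12:
        warnings.warn(
            "ROI grey range is degenerate at the 1st/99th percentiles; "
            "image returned unchanged",
            stacklevel=2,
        )
        return img
    out = grey.copy()
    out[img.roi] = np.clip((vals - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return img.with_grey(np.rint(out).astype(np.uint8))


def threshold_nuclei(
    img: EpitheliumImage, manual_threshold: float | None = None
) -> np.ndarray:
    """Binary mask of ROI pixels darker than the threshold.

    The threshold is Otsu's criterion on ROI pixels unless
    ``manual_threshold`` is supplied.  Otsu's returned level belongs to the
    dark class, so the comparison is inclusive there; a manual threshold
    selects pixels strictly darker than the given level.
    """
    if not img.roi.any():
        raise ValueError("ROI is empty")
    if manual_threshold is None:
        vals = img.grey[img.roi]
        if vals.min() == vals.max():
            warnings.warn("constant ROI; empty nucleus mask", stacklevel=2)
            return np.zeros(img.shape, dtype=bool)
        return (img.grey <= threshold_otsu(vals)) & img.roi
    return (img.grey < manual_threshold) & img.roi


def clean_mask(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Fill interior holes and remove components smaller than ``min_area``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    filled = ndimage.binary_fill_holes(mask, structure=_STRUCT4)
    labels, n = ndimage.label(filled, structure=_STRUCT8)
    if n == 0:
        return filled
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def suppress_border_nuclei(mask: np.ndarray, roi: np.ndarray) -> NucleiLabelMap:
    """Remove frame-cutting components, label survivors, measure mean area.

    A 1-px frame is conceptually added around the image: any 8-connected
    component touching the outer frame is suppressed.  Survivors are labeled
    1..count in raster order.
    """
    mask = np.asarray(mask, dtype=bool) & np.asarray(roi, dtype=bool)
    interior = clear_border(mask)
    labels, count = ndimage.label(interior, structure=_STRUCT8)
    if count == 0:
        if mask.any():
            warnings.warn("all nuclei touched the frame and were suppressed",
                          stacklevel=2)
        return NucleiLabelMap(labels.astype(np.int32), 0, None)
    areas = np.bincount(labels.ravel())[1:]
    return NucleiLabelMap(labels.astype(np.int32), int(count), float(areas.mean()))


def measure_basic(
    nuclei: NucleiLabelMap, img: EpitheliumImage
) -> dict[str, float | None]:
    """Epithelium area A and mean nucleus area N, in px^2 and um^2."""
    a_px = float(img.roi.sum())
    n_px = nuclei.mean_area
    cal = img.pixel_area_um2
    return {
        "A": a_px,
        "N": n_px,
        "A_um2": a_px * cal,
        "N_um2": None if n_px is None else n_px * cal,
    }


def segment(
    img: EpitheliumImage,
    manual_threshold: float | None = None,
    min_area: int = DEFAULT_MIN_AREA,
) -> NucleiLabelMap:
    """Full segmentation chain: preprocess, threshold, clean, border-suppress."""
    pre = preprocess(img)
    mask = threshold_nuclei(pre, manual_threshold)
    mask = clean_mask(mask, min_area)
    return suppress_border_nuclei(mask, img.roi)
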
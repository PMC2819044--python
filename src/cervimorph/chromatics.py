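"""Chromaticism: the total and upper nuclei histogram values Hst and HstU.

The binary segmented nuclei are superimposed on the original grey image and
the result inverted, so nuclei carry their inverted grey (dark nucleus ->
high value) and everything else is zero.  Two normalizations of that
inverted superimposition are provided:

* ``"region"`` (pipeline default): mean over *all* region pixels.  This is
  an area-integrated stain measure — it grows with both nuclear darkness
  and nuclear density, and collapses when the region holds few nuclei
  (e.g. the upper epithelium of a high-grade lesion).
* ``"nuclei"``: mean over nucleus pixels only, a pure per-pixel darkness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .differentiation import DifferentiationResult
from .image import EpitheliumImage
from .segmentation import NucleiLabelMap

__all__ = ["ChromaticsResult", "nuclei_chromaticism", "measure_chromatics"]


@dataclass
class ChromaticsResult:
    Hst: float  # inverted-grey chromaticism over all nuclei / whole ROI
    HstU: float  # same, restricted to the upper (non-differentiated) region
    histogram: np.ndarray | None = None  # optional 256-bin inverted histogram


def nuclei_chromaticism(
    img: EpitheliumImage,
    nuclei: NucleiLabelMap,
    region: np.ndarray,
    normalize: str = "nuclei",
) -> float:
    """Chromaticism of the nuclei that fall inside ``region``.

    With ``normalize="nuclei"`` the value is the mean of (255 - grey) over
    pixels that are simultaneously nucleus and region (0 when the
    intersection is empty); with ``"region"`` the same inverted sum is
    divided by the region pixel count instead.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != img.shape:
        raise ValueError("region shape does not match the image")
    sel = nuclei.mask & region
    if normalize not in ("nuclei", "region"):
        raise ValueError("normalize must be 'nuclei' or 'region'")
    denom = float(sel.sum()) if normalize == "nuclei" else float(region.sum())
    if denom == 0 or not sel.any():
        return 0.0
    inv = 255.0 - img.grey[sel].astype(np.float64)
    return float(inv.sum() / denom)


def inverted_histogram(img: EpitheliumImage, nuclei: NucleiLabelMap,
                       region: np.ndarray) -> np.ndarray:
    """256-bin histogram of inverted grey over nuclei pixels in ``region``."""
    sel = nuclei.mask & np.asarray(region, dtype=bool)
    inv = 255 - img.grey[sel].astype(np.int64)
    return np.bincount(inv, minlength=256)


def measure_chromatics(
    img: EpitheliumImage,
    nuclei: NucleiLabelMap,
    diff: DifferentiationResult,
    normalize: str = "region",
    with_histogram: bool = False,
) -> ChromaticsResult:
    """Hst over the whole ROI and HstU over the upper region.

    Measured on the *original* grey image (not the contrast-stretched one),
    so the value reflects staining density rather than stretch parameters.
    """
    hst = nuclei_chromaticism(img, nuclei, img.roi, normalize)
    hstu = nuclei_chromaticism(img, nuclei, diff.upper_mask, normalize)
    hist = inverted_histogram(img, nuclei, img.roi) if with_histogram else None
    return ChromaticsResult(Hst=hst, HstU=hstu, histogram=hist)
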
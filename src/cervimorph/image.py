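"""Grayscale epithelium image with region-of-interest mask and calibration."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

#: Default pixel calibration in um^2 per pixel.  Computed from the reference
#: acquisition geometry: a 472 x 608 frame (286,976 px) imaging 0.066 mm^2
#: of slide gives 0.22998 um^2/px.  The alternative printed constant 0.22 is
#: exposed for users reproducing the original setup verbatim.
PIXEL_AREA_UM2 = 0.066e6 / 286_976
PIXEL_AREA_UM2_PRINTED = 0.22


@dataclass
class EpitheliumImage:
    """An 8-bit grayscale micrograph plus the epithelium ROI mask.

    The analysis convention is basal lamina at the image *bottom*; supply
    ``flip_vertical=True`` at load time for material oriented the other way.
    """

    grey: np.ndarray
    roi: np.ndarray
    pixel_area_um2: float = PIXEL_AREA_UM2

    def __post_init__(self) -> None:
        self.grey = np.asarray(self.grey)
        self.roi = np.asarray(self.roi).astype(bool)
        if self.grey.ndim != 2:
            raise ValueError("grey image must be 2-D")
        if self.grey.shape != self.roi.shape:
            raise ValueError(
                f"grey {self.grey.shape} and roi {self.roi.shape} shapes differ"
            )
        if not self.roi.any():
            raise ValueError("ROI mask has no foreground pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grey.shape

    @property
    def roi_area(self) -> int:
        return int(self.roi.sum())

    def with_grey(self, grey: np.ndarray) -> "EpitheliumImage":
        return replace(self, grey=grey)

    def flipped(self) -> "EpitheliumImage":
        return EpitheliumImage(
            self.grey[::-1].copy(), self.roi[::-1].copy(), self.pixel_area_um2
        )


def load_image(
    image_path: str | Path,
    roi_path: str | Path | None = None,
    pixel_area_um2: float = PIXEL_AREA_UM2,
    flip_vertical: bool = False,
) -> EpitheliumImage:
    """Read an 8-bit grayscale image (BMP/PNG/TIFF) and an optional ROI mask.

    Without an ROI file the full frame is taken as epithelium.  The mask is
    any image whose nonzero pixels mark the ROI.
    """
    grey = np.asarray(Image.open(image_path).convert("L"))
    if roi_path is None:
        roi = np.ones(grey.shape, dtype=bool)
    else:
        roi = np.asarray(Image.open(roi_path).convert("L")) > 0
        if roi.shape != grey.shape:
            raise ValueError(
                f"ROI {roi_path} shape {roi.shape} does not match "
                f"image {image_path} shape {grey.shape}"
            )
    img = EpitheliumImage(grey, roi, pixel_area_um2)
    return img.flipped() if flip_vertical else img


def save_grey(path: str | Path, grey: np.ndarray) -> None:
    """Write a 2-D uint8 array as an 8-bit grayscale PNG."""
    Image.fromarray(np.asarray(grey, dtype=np.uint8), mode="L").save(path)
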
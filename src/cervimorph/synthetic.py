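"""Seeded synthetic epithelium images with known ground truth.

The generator emulates the structure the grading pipeline exploits: a
rectangular epithelium ROI with the basal lamina at the image bottom, a
dense band of dark, nearly touching nuclei occupying the differentiated
fraction of the epithelium height, and a sparse population of nuclei in the
upper band.  Per-group targets (mean nucleus area, mean zone-of-influence
area, differentiated-area fraction, chromaticism) come from the reference
group statistics, so parameter recovery on generated images can be checked
against known values.

Placement uses a jittered lattice with an occupancy-grid overlap guard
rather than dart throwing: the dense band runs at a nucleus/zone packing of
~0.5, where random sequential placement jams before reaching the target
count, while a lattice reaches it deterministically and guarantees
non-overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image import EpitheliumImage
from .reference import GRADES, GROUP_MEANS

__all__ = [
    "GroupPreset",
    "GroundTruth",
    "make_preset",
    "generate_epithelium",
    "generate_three_disc_scene",
]

#: Upper-band lattice spacing (px) per grade.  Chosen once so that upper
#: nuclei stay clearly farther apart than the closing diameter (no spurious
#: merges into the basal block) while their count reproduces the reference
#: upper chromaticism; CIN3 keeps only a handful of upper nuclei, matching
#: the near-complete loss of the non-differentiated compartment.
_UPPER_SPACING = {"NORMAL": 65.0, "CIN1": 55.0, "CIN2": 55.0, "CIN3": 112.0}

_BACKGROUND_GREY = 235
_NOISE_SD = 4.0


@dataclass(frozen=True)
class GroupPreset:
    """Generative targets for one diagnostic group."""

    label: str
    mean_nucleus_area: float  # px^2
    sd_nucleus_area: float  # px^2, per-nucleus spread within an image
    mean_zone_area: float  # px^2, target ROI area per nucleus
    differentiation_fraction: float  # target D/A in [0, 1]
    nucleus_darkness: float  # inverted grey of basal-band nuclei
    upper_nucleus_darkness: float  # inverted grey of upper-band nuclei
    background_grey: int = _BACKGROUND_GREY
    upper_spacing: float = 65.0  # px, upper-band lattice pitch

    def __post_init__(self) -> None:
        if not self.mean_nucleus_area < self.mean_zone_area:
            raise ValueError("mean nucleus area must be below mean zone area")
        if not 0.0 <= self.differentiation_fraction <= 1.0:
            raise ValueError("differentiation fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually placed; the oracle for recovery tests."""

    nucleus_centers: np.ndarray  # (n, 2) float, (row, col)
    nucleus_areas: np.ndarray  # (n,) int, rasterized pixel counts
    roi_area: int
    true_differentiated_mask: np.ndarray  # bool raster, the basal band
    basal: np.ndarray  # (n,) bool, True for dense-band nuclei

    def __post_init__(self) -> None:
        if len(self.nucleus_centers) != len(self.nucleus_areas):
            raise ValueError("centers and areas must have equal length")

    def to_json(self) -> str:
        rows = np.flatnonzero(self.true_differentiated_mask.any(axis=1))
        return json.dumps(
            {
                "nucleus_centers": self.nucleus_centers.tolist(),
                "nucleus_areas": self.nucleus_areas.tolist(),
                "roi_area": self.roi_area,
                "basal": self.basal.astype(int).tolist(),
                "differentiated_rows": [int(rows.min()), int(rows.max())]
                if rows.size
                else None,
            }
        )


def make_preset(label: str) -> GroupPreset:
    """Shipped preset for one of NORMAL, CIN1, CIN2, CIN3.

    Nucleus and zone areas equal the reference group means; the
    differentiation fraction is the reference D/A quotient; nucleus darkness
    levels are derived in closed form so that the area-integrated
    chromaticism measured on generated images reproduces the reference
    Hst/HstU values.
    """
    if label not in GRADES:
        raise ValueError(f"unknown group label {label!r}; expected one of {GRADES}")
    m = GROUP_MEANS[label]
    n_area, v_area = m["N"], m["V"]
    frac = m["D"] / m["A"]
    s_u = _UPPER_SPACING[label]
    # Upper-band nuclei occupy N/s_u^2 of the upper region, so their
    # darkness must be HstU / (N / s_u^2) to integrate to the target.
    d_upper = m["HstU"] * s_u * s_u / n_area
    # Total chromaticism mixes both bands over the whole ROI:
    #   Hst = d_b * (N/V - N(1-f)/s_u^2) + d_u * N(1-f)/s_u^2
    upper_frac = n_area * (1.0 - frac) / (s_u * s_u)
    d_basal = (m["Hst"] - d_upper * upper_frac) / (n_area / v_area - upper_frac)
    d_upper = float(np.clip(d_upper, 20.0, 255.0))
    d_basal = float(np.clip(d_basal, 20.0, 255.0))
    return GroupPreset(
        label=label,
        mean_nucleus_area=n_area,
        sd_nucleus_area=0.15 * n_area,
        mean_zone_area=v_area,
        differentiation_fraction=frac,
        nucleus_darkness=d_basal,
        upper_nucleus_darkness=d_upper,
        upper_spacing=s_u,
    )


def _ellipse_pixels(
    cy: float, cx: float, area: float, ratio: float, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a rasterized ellipse of the given area."""
    a = math.sqrt(area / (math.pi * ratio))  # semi-major
    b = ratio * a
    r = int(math.ceil(a)) + 1
    yy, xx = np.mgrid[
        int(math.floor(cy)) - r : int(math.ceil(cy)) + r + 1,
        int(math.floor(cx)) - r : int(math.ceil(cx)) + r + 1,
    ]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


class _Placer:
    """Occupancy-grid placement of non-overlapping nuclei."""

    def __init__(self, shape: tuple[int, int], roi: np.ndarray, rng: np.random.Generator):
        self.occupied = np.zeros(shape, dtype=bool)
        self.roi = roi
        self.rng = rng
        self.centers: list[tuple[float, float]] = []
        self.areas: list[int] = []
        self.pixels: list[tuple[np.ndarray, np.ndarray]] = []

    def _fits(self, ys: np.ndarray, xs: np.ndarray) -> bool:
        h, w = self.occupied.shape
        if ys.min() < 0 or xs.min() < 0 or ys.max() >= h or xs.max() >= w:
            return False
        if not self.roi[ys, xs].all():
            return False
        return not self.occupied[ys, xs].any()

    def _mark(self, ys: np.ndarray, xs: np.ndarray) -> None:
        # occupy the nucleus plus a 1-px moat so neighbours never 8-touch
        h, w = self.occupied.shape
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy = np.clip(ys + dy, 0, h - 1)
                xx = np.clip(xs + dx, 0, w - 1)
                self.occupied[yy, xx] = True

    def place(
        self,
        cy: float,
        cx: float,
        jitter: float,
        mean_area: float,
        sd_area: float,
        ratio_range: tuple[float, float],
        tries: int = 8,
    ) -> bool:
        rng = self.rng
        for attempt in range(tries + 1):
            area = float(
                np.clip(
                    rng.normal(mean_area, sd_area),
                    mean_area - 2 * sd_area,
                    mean_area + 2 * sd_area,
                )
            )
            if attempt < tries:
                jy = rng.uniform(-jitter, jitter)
                jx = rng.uniform(-jitter, jitter)
                ratio = rng.uniform(*ratio_range)
                theta = rng.uniform(0.0, math.pi)
            else:  # last resort: centered circle
                jy = jx = 0.0
                ratio, theta = 1.0, 0.0
            ys, xs = _ellipse_pixels(cy + jy, cx + jx, area, ratio, theta)
            if self._fits(ys, xs):
                self._commit(cy + jy, cx + jx, ys, xs)
                return True
        # shrink a centered circle until it fits
        area = mean_area
        while area >= 9.0:
            ys, xs = _ellipse_pixels(cy, cx, area, 1.0, 0.0)
            if self._fits(ys, xs):
                self._commit(cy, cx, ys, xs)
                return True
            area *= 0.8
        return False

    def _commit(self, cy: float, cx: float, ys: np.ndarray, xs: np.ndarray) -> None:
        self.centers.append((cy, cx))
        self.areas.append(int(ys.size))
        self.pixels.append((ys, xs))
        self._mark(ys, xs)


def generate_epithelium(
    preset: GroupPreset,
    seed: int,
    width: int = 608,
    height: int = 472,
) -> tuple[EpitheliumImage, GroundTruth]:
    """Render one synthetic epithelium image plus its ground truth.

    Identical (preset, seed, width, height) reproduce the raster
    bit-for-bit.  The ROI is a rectangle inset 10 px from the frame with the
    basal lamina along its bottom edge.
    """
    if preset.mean_zone_area <= 0:
        raise ValueError("preset mean_zone_area must be positive")
    margin = 10
    h_roi, w_roi = height - 2 * margin, width - 2 * margin
    if h_roi <= 0 or w_roi <= 0:
        raise ValueError("image too small for the 10-px ROI margin")
    roi_area = h_roi * w_roi
    n_total = int(round(roi_area / preset.mean_zone_area))
    if n_total < 30:
        raise ValueError(
            f"geometry too small: {width}x{height} holds only {n_total} nuclei "
            f"at zone area {preset.mean_zone_area:.0f}; need >= 30"
        )

    rng = np.random.default_rng(seed)
    roi = np.zeros((height, width), dtype=bool)
    roi[margin : height - margin, margin : width - margin] = True
    roi_bottom = height - margin - 1  # last ROI row
    roi_top = margin

    frac = preset.differentiation_fraction
    band_h = int(round(frac * h_roi))
    band_top = roi_bottom - band_h + 1  # first row of the dense band
    upper_h = h_roi - band_h

    s_u = preset.upper_spacing
    n_upper = int(round(upper_h * w_roi / (s_u * s_u))) if upper_h > 0 else 0
    n_upper = min(n_upper, max(0, n_total - 1))
    n_dense = n_total - n_upper

    mean_r = math.sqrt(preset.mean_nucleus_area / math.pi)
    placer = _Placer((height, width), roi, rng)

    # --- dense basal band: lattice sized to the band, small jitter
    if n_dense > 0 and band_h > 0:
        s_d = math.sqrt(band_h * w_roi / n_dense)
        n_rows = max(1, int(round(band_h / s_d)))
        n_cols = int(math.ceil(n_dense / n_rows))
        row_sp = band_h / n_rows
        col_sp = w_roi / n_cols
        jit = max(0.5, 0.12 * min(row_sp, col_sp))
        placed = 0
        for i in range(n_rows):
            cy = roi_bottom - (i + 0.5) * row_sp
            for j in range(n_cols):
                if placed >= n_dense:
                    break
                cx = margin + (j + 0.5) * col_sp
                if placer.place(
                    cy, cx, jit, preset.mean_nucleus_area,
                    preset.sd_nucleus_area, (0.85, 1.0),
                ):
                    placed += 1
        n_dense_placed = placed
    else:
        s_d, n_dense_placed = 0.0, 0

    # --- upper band: sparse lattice kept clear of the closing diameter
    n_upper_placed = 0
    if n_upper > 0 and upper_h > 0:
        # rough closing-size estimate from the lattice pitches, to hold the
        # first upper row out of merging range of the dense band
        mean_edge_est = (n_dense * (s_d or s_u) + n_upper * s_u) / n_total
        k_est = 4.0 * mean_edge_est / max(mean_r, 1.0)
        jit_u = min(0.2 * s_u, 8.0)
        standoff = min(
            2.0 * k_est + 2.0 * mean_r + jit_u + 6.0, max(upper_h - s_u / 2.0, 8.0)
        )
        zone_top = roi_top + margin // 2
        zone_bottom = band_top - standoff
        zh = max(zone_bottom - zone_top, 1.0)
        n_rows = max(1, int(round(zh / s_u)))
        n_cols = int(math.ceil(n_upper / n_rows))
        row_sp = zh / n_rows
        col_sp = w_roi / n_cols
        for i in range(n_rows):
            cy = zone_bottom - (i + 0.5) * row_sp
            for j in range(n_cols):
                if n_upper_placed >= n_upper:
                    break
                cx = margin + (j + 0.5) * col_sp
                if placer.place(
                    cy, cx, jit_u, preset.mean_nucleus_area,
                    preset.sd_nucleus_area, (0.7, 1.0),
                ):
                    n_upper_placed += 1

    # --- render
    grey = np.full((height, width), 250.0)
    grey[roi] = preset.background_grey
    basal_grey = 255.0 - preset.nucleus_darkness
    upper_grey = 255.0 - preset.upper_nucleus_darkness
    for idx, (ys, xs) in enumerate(placer.pixels):
        grey[ys, xs] = basal_grey if idx < n_dense_placed else upper_grey
    grey += rng.normal(0.0, _NOISE_SD, size=grey.shape)
    grey = np.clip(np.rint(grey), 0, 255).astype(np.uint8)

    band_mask = np.zeros((height, width), dtype=bool)
    band_mask[band_top : roi_bottom + 1, margin : width - margin] = True
    band_mask &= roi

    truth = GroundTruth(
        nucleus_centers=np.array(placer.centers, dtype=float).reshape(-1, 2),
        nucleus_areas=np.array(placer.areas, dtype=int),
        roi_area=roi_area,
        true_differentiated_mask=band_mask,
        basal=np.arange(len(placer.centers)) < n_dense_placed,
    )
    return EpitheliumImage(grey, roi), truth


def _disc_offsets(n_pixels: int) -> tuple[np.ndarray, np.ndarray]:
    """Offsets of the ``n_pixels`` grid points closest to the origin."""
    r = int(math.ceil(math.sqrt(n_pixels / math.pi))) + 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    yy, xx = yy.ravel(), xx.ravel()
    order = np.lexsort((xx, yy, yy * yy + xx * xx))
    return yy[order[:n_pixels]], xx[order[:n_pixels]]


def generate_three_disc_scene() -> EpitheliumImage:
    """The three-disc worked-example scene for the closing coefficient.

    Three collinear discs of exactly 199 px area (8 px radius) on a white
    background, the middle disc separated from its neighbours by 32 and
    60 px (center to center, the distances the coefficient divides by a
    quarter radius); the ROI covers the whole frame.  Separations are
    center-to-center because that is what the pipeline's mean Delaunay
    edge measures — and because closing at the worked-example coefficient
    k = 16 then merges exactly the nearer pair, as the example requires:
    a dilation bridging a border gap of 32 would be severed again by the
    matching erosion.
    """
    height, width = 200, 400
    grey = np.full((height, width), 255, dtype=np.uint8)
    dy, dx = _disc_offsets(199)
    cy = height // 2
    for cx in (80, 80 + 32, 80 + 32 + 60):
        grey[cy + dy, cx + dx] = 0
    return EpitheliumImage(grey, np.ones((height, width), dtype=bool))


def write_image_with_truth(
    outdir: str | Path, stem: str, img: EpitheliumImage, truth: GroundTruth
) -> None:
    """Write PNG image + ROI mask + JSON ground-truth sidecar."""
    from .image import save_grey

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_grey(outdir / f"{stem}.png", img.grey)
    save_grey(outdir / f"{stem}.roi.png", img.roi.astype(np.uint8) * 255)
    (outdir / f"{stem}.truth.json").write_text(truth.to_json())
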
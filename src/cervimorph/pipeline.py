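"""End-to-end analysis: segmentation -> tessellation -> differentiation ->
chromaticism -> scoring, for single images and group batches."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chromatics import measure_chromatics
from .differentiation import (
    BASAL_BAND_PX,
    dilation_coefficient,
    measure_differentiation,
    nuclear_radius,
)
from .image import PIXEL_AREA_UM2, EpitheliumImage, load_image
from .reference import GRADES
from .scoring import (
    FeatureVector,
    ScoreCalibration,
    cervical_score,
    classify,
    compute_ratios,
    default_calibration,
    welch_ttest,
)
from .segmentation import DEFAULT_MIN_AREA, measure_basic, segment
from .tessellation import delaunay_edges, geodesic_centers, influence_zones

log = logging.getLogger("cervimorph")

#: Columns of the per-image report, in order.
REPORT_COLUMNS = [
    "image", "group", "count", "A", "N", "V", "D", "Hst", "HstU",
    "nc_ratio", "diff_ratio", "hist_ratio", "mean_edge", "radius", "k",
    "score", "grade", "A_um2", "N_um2",
]


@dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline; absent fields take these defaults."""

    threshold: float | None = None  # None -> Otsu on ROI pixels
    min_area: int = DEFAULT_MIN_AREA
    pixel_area_um2: float = PIXEL_AREA_UM2
    edge_mode: str = "unique"  # "unique" | "per_triangle"
    coefficient_mode: str = "edge"  # "edge" (stated formula) | "gap"
    chromaticism_mode: str = "region"  # "region" | "nuclei"
    basal_band_px: int = BASAL_BAND_PX
    k_override: int | None = None
    flip_vertical: bool = False
    calibration: dict | None = None  # ScoreCalibration.to_dict() payload

    def get_calibration(self) -> ScoreCalibration:
        if self.calibration is None:
            return default_calibration()
        return ScoreCalibration.from_dict(self.calibration)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class PipelineResult:
    features: FeatureVector | None
    ratios: object | None
    score: float | None
    grade: str | None
    count: int
    mean_edge: float | None
    radius: int | None
    k: int | None
    intermediates: dict = field(default_factory=dict)

    def to_row(self, image: str = "", group: str = "") -> dict:
        f = self.features
        r = self.ratios
        return {
            "image": image, "group": group, "count": self.count,
            "A": f.A if f else None, "N": f.N if f else None,
            "V": f.V if f else None, "D": f.D if f else None,
            "Hst": f.Hst if f else None, "HstU": f.HstU if f else None,
            "nc_ratio": r.nc_ratio if r else None,
            "diff_ratio": r.diff_ratio if r else None,
            "hist_ratio": r.hist_ratio if r else None,
            "mean_edge": self.mean_edge, "radius": self.radius, "k": self.k,
            "score": self.score, "grade": self.grade,
            "A_um2": self.intermediates.get("A_um2"),
            "N_um2": self.intermediates.get("N_um2"),
        }


def run_pipeline(
    img: EpitheliumImage, config: PipelineConfig | None = None
) -> PipelineResult:
    """Analyze one epithelium image and return features, ratios, score, grade.

    Deterministic for fixed input and configuration.  With zero surviving
    nuclei the report carries missing features and no grade.
    """
    config = config or PipelineConfig()
    log.info("pipeline v%s config=%s", __version__, dataclasses.asdict(config))
    if config.flip_vertical:
        img = img.flipped()
    img = dataclasses.replace(img, pixel_area_um2=config.pixel_area_um2)

    nuclei = segment(img, config.threshold, config.min_area)
    basic = measure_basic(nuclei, img)
    if nuclei.count == 0:
        return PipelineResult(
            features=None, ratios=None, score=None, grade=None, count=0,
            mean_edge=None, radius=None, k=None,
            intermediates={"A": basic["A"], "A_um2": basic["A_um2"]},
        )

    zones = influence_zones(nuclei, img.roi)
    centers = geodesic_centers(zones)
    tri = delaunay_edges(centers, img.roi)
    mean_edge = (
        tri.mean_edge_length if config.edge_mode == "unique"
        else tri.mean_edge_per_triangle
    )
    radius = nuclear_radius(nuclei.mean_area)
    if config.k_override is not None:
        k = int(config.k_override)
    else:
        edge_for_k = mean_edge
        if config.coefficient_mode == "gap":
            # centre-to-centre edge reduced to a border-to-border gap
            edge_for_k = max(0.0, mean_edge - 2.0 * radius)
        k = dilation_coefficient(edge_for_k, radius)

    diff = measure_differentiation(nuclei, k, img.roi, config.basal_band_px)
    chrom = measure_chromatics(img, nuclei, diff, config.chromaticism_mode)

    features = FeatureVector(
        A=basic["A"], N=basic["N"], V=zones.mean_zone_area,
        D=diff.D, Hst=chrom.Hst, HstU=chrom.HstU,
    )
    ratios = compute_ratios(features)
    cal = config.get_calibration()
    score = cervical_score(ratios, cal)
    grade = classify(score)
    return PipelineResult(
        features=features, ratios=ratios, score=score, grade=grade,
        count=nuclei.count, mean_edge=mean_edge, radius=radius, k=k,
        intermediates={
            "A_um2": basic["A_um2"], "N_um2": basic["N_um2"],
            "nuclei": nuclei, "zones": zones, "centers": centers,
            "triangulation": tri, "differentiation": diff,
            "closed_area": diff.closed_area,
        },
    )


def run_pipeline_file(
    image_path: str | Path,
    roi_path: str | Path | None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """File-based wrapper of :func:`run_pipeline`."""
    config = config or PipelineConfig()
    img = load_image(image_path, roi_path, config.pixel_area_um2)
    return run_pipeline(img, config)


def run_batch(
    manifest: pd.DataFrame | list[dict],
    config: PipelineConfig | None = None,
) -> dict:
    """Analyze a manifest of (image, roi, group) rows.

    Returns per-image report rows, a group mean/SD table and Welch tests
    between successive groups.  Missing files are skipped with a warning;
    row order in the report is canonical (group, then image path), so a
    shuffled manifest yields an identical report.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.DataFrame(manifest)
    rows = []
    for rec in manifest.to_dict("records"):
        image = rec["image"]
        roi = rec.get("roi") or None
        group = rec.get("group", "")
        try:
            res = run_pipeline_file(image, roi, config)
        except FileNotFoundError as exc:
            log.warning("skipping %s: %s", image, exc)
            continue
        rows.append(res.to_row(image=str(image), group=str(group)))
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    order = {g: i for i, g in enumerate(GRADES)}
    report = report.sort_values(
        by=["group", "image"],
        key=lambda s: s.map(order).fillna(99) if s.name == "group" else s,
    ).reset_index(drop=True)
    return {
        "report": report,
        "group_stats": group_statistics(report),
        "welch_tests": successive_welch_tests(report),
    }


_STAT_COLS = ["A", "N", "V", "D", "Hst", "HstU",
              "nc_ratio", "diff_ratio", "hist_ratio", "score"]


def group_statistics(report: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of every measured quantity per diagnostic group."""
    present = [g for g in GRADES if (report["group"] == g).any()]
    out = []
    for g in present:
        sub = report[report["group"] == g]
        for col in _STAT_COLS:
            vals = sub[col].dropna().astype(float)
            out.append({
                "group": g, "parameter": col, "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(out)


def successive_welch_tests(report: pd.DataFrame) -> pd.DataFrame:
    """Welch t-tests between successive groups for each quantity."""
    present = [g for g in GRADES if (report["group"] == g).sum() >= 2]
    out = []
    for g1, g2 in zip(present[:-1], present[1:]):
        a_all = report[report["group"] == g1]
        b_all = report[report["group"] == g2]
        for col in _STAT_COLS:
            a = a_all[col].dropna().astype(float).to_numpy()
            b = b_all[col].dropna().astype(float).to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            out.append({
                "comparison": f"{g1} vs {g2}", "parameter": col,
                "p_value": welch_ttest(a, b),
            })
    return pd.DataFrame(out)
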
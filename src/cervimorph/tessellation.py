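"""Influence zones, geodesic centers and the Delaunay neighbour graph.

The zone of influence of a nucleus is the set of ROI pixels geodesically
(within-ROI) closer to it than to any other nucleus — the discrete Voronoi
partition whose boundary is the SKIZ.  Zone areas proxy cytoplasm area; the
geodesic center of each zone seeds a Delaunay triangulation whose mean edge
length drives the dilation/erosion coefficient.  Edges whose straight
segment leaves the ROI (false neighbours across a concavity) are discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._geodesic import geodesic_center as _region_center
from ._geodesic import geodesic_propagate
from .segmentation import NucleiLabelMap

__all__ = ["InfluenceMap", "Triangulation", "influence_zones",
           "geodesic_centers", "delaunay_edges"]


@dataclass
class InfluenceMap:
    """Voronoi partition of the ROI into per-nucleus zones of influence."""

    zones: np.ndarray  # int raster; zone k >= 1 within ROI, 0 outside
    mean_zone_area: float  # px^2, the V parameter

    @property
    def count(self) -> int:
        m = int(self.zones.max())
        return m

    def zone_areas(self) -> np.ndarray:
        return np.bincount(self.zones.ravel())[1:]


@dataclass
class Triangulation:
    """Delaunay neighbour graph of zone centers, restricted to the ROI."""

    points: np.ndarray  # (n, 2) float, (row, col)
    edges: np.ndarray  # (m, 2) int, unique point-index pairs, i < j
    mean_edge_length: float  # px, over unique retained edges
    mean_edge_per_triangle: float  # px, edges counted once per triangle
    degenerate: bool = False  # True when points were (near-)collinear


def influence_zones(nuclei: NucleiLabelMap, roi: np.ndarray) -> InfluenceMap:
    """Assign every ROI pixel to its geodesically nearest nucleus.

    Equidistant (SKIZ) pixels go to the lower nucleus label, so the zones
    partition the ROI exactly.  The mean zone area equals ROI area / count.
    """
    if nuclei.count == 0:
        raise ValueError("influence zones need at least one nucleus")
    roi = np.asarray(roi, dtype=bool)
    _, labels = geodesic_propagate(roi, nuclei.labels)
    a = float(roi.sum())
    return InfluenceMap(zones=labels, mean_zone_area=a / nuclei.count)


def geodesic_centers(zones: InfluenceMap) -> np.ndarray:
    """One point per zone minimizing the maximum within-zone geodesic distance.

    Ties are broken towards the smallest (row, column).  Returns an (n, 2)
    array of (row, col) pixel coordinates, ordered by zone label.
    """
    out = []
    for k in range(1, zones.count + 1):
        out.append(_region_center(zones.zones == k))
    return np.array(out, dtype=float).reshape(-1, 2)


def _segment_in_roi(p: np.ndarray, q: np.ndarray, roi: np.ndarray) -> bool:
    """True when the straight segment p-q stays inside the ROI."""
    n = int(max(2, math.ceil(np.hypot(*(q - p)) * 2)))
    t = np.linspace(0.0, 1.0, n)
    rows = np.rint(p[0] + t * (q[0] - p[0])).astype(int)
    cols = np.rint(p[1] + t * (q[1] - p[1])).astype(int)
    return bool(roi[rows, cols].all())


def delaunay_edges(points: np.ndarray, roi: np.ndarray) -> Triangulation:
    """Delaunay triangulation of zone centers with ROI-crossing edges removed.

    Two points give the single connecting edge; collinear point sets fall
    back to a chain along the dominant axis and are flagged ``degenerate``.
    The mean edge length is reported both over unique edges (default) and
    with per-triangle multiplicity.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    roi = np.asarray(roi, dtype=bool)
    n = len(points)
    if n == 0:
        raise ValueError("no points to triangulate")
    if n == 1:
        return Triangulation(points, np.empty((0, 2), dtype=int), 0.0, 0.0)

    def lengths(pairs: np.ndarray) -> np.ndarray:
        d = points[pairs[:, 0]] - points[pairs[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    if n == 2:
        pairs = np.array([[0, 1]])
        if _segment_in_roi(points[0], points[1], roi):
            ln = float(lengths(pairs)[0])
            return Triangulation(points, pairs, ln, ln)
        return Triangulation(points, np.empty((0, 2), dtype=int), 0.0, 0.0)

    tri_simplices = None
    try:
        tri = Delaunay(points)
        tri_simplices = tri.simplices
    except QhullError:
        pass
    if tri_simplices is None:
        # collinear: chain consecutive points along the dominant axis
        warnings.warn("collinear zone centers; returning chain edges",
                      stacklevel=2)
        span = points.max(axis=0) - points.min(axis=0)
        order = np.argsort(points[:, int(np.argmax(span))], kind="stable")
        pairs = np.column_stack([order[:-1], order[1:]])
        pairs = np.sort(pairs, axis=1)
        keep = [
            _segment_in_roi(points[i], points[j], roi) for i, j in pairs
        ]
        pairs = pairs[np.array(keep, dtype=bool)]
        ln = lengths(pairs)
        mean = float(ln.mean()) if ln.size else 0.0
        return Triangulation(points, pairs, mean, mean, degenerate=True)

    all_pairs = np.vstack(
        [tri_simplices[:, [0, 1]], tri_simplices[:, [1, 2]], tri_simplices[:, [0, 2]]]
    )
    all_pairs = np.sort(all_pairs, axis=1)
    unique_pairs, inverse = np.unique(all_pairs, axis=0, return_inverse=True)
    in_roi = np.array(
        [_segment_in_roi(points[i], points[j], roi) for i, j in unique_pairs],
        dtype=bool,
    )
    kept = unique_pairs[in_roi]
    if kept.size == 0:
        return Triangulation(points, kept, 0.0, 0.0)
    uniq_len = lengths(kept)
    # per-triangle multiplicity: every simplex edge counts, minus dropped ones
    multi_ok = in_roi[inverse]
    multi_len = lengths(all_pairs[multi_ok])
    return Triangulation(
        points=points,
        edges=kept,
        mean_edge_length=float(uniq_len.mean()),
        mean_edge_per_triangle=float(multi_len.mean()) if multi_len.size else 0.0,
    )
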
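"""Influence zones, geodesic centers and the Delaunay neighbour graph.

The chamfer-geodesic implementation is cross-checked against
scipy.sparse.csgraph shortest paths on the 8-neighbour pixel graph — an
independent route to the same metric.
"""

import numpy as np
import pytest
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from cervimorph import (
    delaunay_edges,
    geodesic_centers,
    influence_zones,
    suppress_border_nuclei,
)
from cervimorph.segmentation import NucleiLabelMap

SQRT2 = np.sqrt(2.0)
EPS = 1e-9


def pixel_graph(mask):
    """Sparse 8-neighbour graph over mask pixels with weights 1 / sqrt(2)."""
    h, w = mask.shape
    idx = -np.ones(mask.shape, dtype=int)
    pix = np.argwhere(mask)
    idx[mask] = np.arange(len(pix))
    rows, cols, data = [], [], []
    for dy, dx in [(-1, -1), (-1, 0), (-1, 1), (0, -1)]:
        wgt = SQRT2 if dy and dx else 1.0
        for (y, x), i in zip(pix, idx[mask]):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                rows.append(i)
                cols.append(idx[ny, nx])
                data.append(wgt)
    n = len(pix)
    g = coo_matrix((data, (rows, cols)), shape=(n, n))
    return pix, (g + g.T).tocsr()


def oracle_assignment(labels, roi):
    """Per-pixel nearest nucleus by exhaustive per-label shortest paths."""
    pix, graph = pixel_graph(roi)
    n_labels = labels.max()
    dists = np.full((n_labels, len(pix)), np.inf)
    lab_at_pix = labels[pix[:, 0], pix[:, 1]]
    for k in range(1, n_labels + 1):
        sources = np.flatnonzero(lab_at_pix == k)
        d = csgraph_dijkstra(graph, indices=sources, min_only=True)
        dists[k - 1] = d
    # argmin with lower-label tie-break
    best = np.argmin(dists, axis=0)
    dmin = dists[best, np.arange(len(pix))]
    ties = np.abs(dists - dmin) <= EPS
    best = ties.argmax(axis=0)  # first (lowest) label among ties
    out = np.zeros(roi.shape, dtype=int)
    out[pix[:, 0], pix[:, 1]] = best + 1
    return out


def make_nuclei(shape, centers, radius=2):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    for k, (cy, cx) in enumerate(centers, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = k
    n = len(centers)
    areas = np.bincount(labels.ravel())[1:]
    return NucleiLabelMap(labels, n, float(areas.mean()))


class TestInfluenceZones:
    def test_single_nucleus_owns_whole_roi(self):
        roi = np.ones((30, 40), dtype=bool)
        nuclei = make_nuclei((30, 40), [(15, 20)])
        zones = influence_zones(nuclei, roi)
        assert (zones.zones[roi] == 1).all()
        assert zones.mean_zone_area == roi.sum()

    def test_mirror_symmetric_pair_splits_evenly(self):
        roi = np.ones((40, 60), dtype=bool)
        nuclei = make_nuclei((40, 60), [(20, 14), (20, 45)])
        zones = influence_zones(nuclei, roi)
        areas = zones.zone_areas()
        assert areas[0] == areas[1]

    def test_partition_conserves_roi(self):
        rng = np.random.default_rng(11)
        roi = np.ones((80, 90), dtype=bool)
        centers = [(int(r), int(c)) for r, c in
                   zip(rng.integers(4, 76, 12), rng.integers(4, 86, 12))]
        nuclei = make_nuclei((80, 90), centers)
        zones = influence_zones(nuclei, roi)
        assert (zones.zones > 0).sum() == roi.sum()
        assert zones.zone_areas().sum() == roi.sum()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_nearest_nucleus_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (60, 70)
        roi = np.ones(shape, dtype=bool)
        if seed == 2:  # non-convex ROI exercises the geodesic metric
            roi[25:35, 0:45] = False
        pts = set()
        while len(pts) < 15:
            cy, cx = int(rng.integers(3, 57)), int(rng.integers(3, 67))
            if roi[cy, cx] and all(abs(cy - a) + abs(cx - b) > 6 for a, b in pts):
                pts.add((cy, cx))
        nuclei = make_nuclei(shape, sorted(pts))
        nuclei.labels[~roi] = 0
        areas = np.bincount(nuclei.labels.ravel())[1:]
        nuclei = NucleiLabelMap(nuclei.labels, len(areas), float(areas.mean()))
        zones = influence_zones(nuclei, roi)
        expected = oracle_assignment(nuclei.labels, roi)
        assert np.array_equal(zones.zones, expected)

    def test_zone_contains_its_nucleus(self, normal_small):
        from cervimorph import segment

        img, _ = normal_small
        nuclei = segment(img)
        zones = influence_zones(nuclei, img.roi)
        inside = nuclei.labels > 0
        assert np.array_equal(zones.zones[inside], nuclei.labels[inside])

    def test_zero_nuclei_rejected(self):
        roi = np.ones((10, 10), dtype=bool)
        empty = NucleiLabelMap(np.zeros((10, 10), np.int32), 0, None)
        with pytest.raises(ValueError):
            influence_zones(empty, roi)


class TestGeodesicCenters:
    def oracle_center(self, mask):
        """Exhaustive eccentricity minimization via csgraph all-pairs."""
        pix, graph = pixel_graph(mask)
        d = csgraph_dijkstra(graph)
        ecc = d.max(axis=1)
        best = ecc.min()
        cands = pix[np.abs(ecc - best) <= EPS]
        order = np.lexsort((cands[:, 1], cands[:, 0]))
        return tuple(cands[order[0]])

    def test_single_pixel_zone(self):
        from cervimorph._geodesic import geodesic_center

        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        assert geodesic_center(mask) == (2, 3)

    def test_rectangle_center(self):
        from cervimorph._geodesic import geodesic_center

        mask = np.zeros((30, 40), dtype=bool)
        mask[5:20, 10:35] = True  # 15 x 25 rectangle
        cy, cx = geodesic_center(mask)
        assert abs(cy - 12) <= 1 and abs(cx - 22) <= 1

    def test_l_shaped_zone_matches_exhaustive_oracle(self):
        from cervimorph._geodesic import geodesic_center

        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:12] = True
        mask[28:35, 5:35] = True
        assert geodesic_center(mask) == self.oracle_center(mask)
        # the Euclidean centroid of the L lies outside the region
        cy, cx = np.argwhere(mask).mean(axis=0)
        assert not mask[int(round(cy)), int(round(cx))]

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_random_blobs_match_exhaustive_oracle(self, seed):
        from cervimorph._geodesic import geodesic_center

        from conftest import random_blob_mask

        mask = random_blob_mask(np.random.default_rng(seed), shape=(36, 36))
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        for k in range(1, n + 1):
            zone = lab == k
            assert geodesic_center(zone) == self.oracle_center(zone)

    def test_centers_lie_inside_their_zones(self, cin3_small):
        from cervimorph import segment

        img, _ = cin3_small
        nuclei = segment(img)
        zones = influence_zones(nuclei, img.roi)
        centers = geodesic_centers(zones)
        for k, (cy, cx) in enumerate(centers, start=1):
            assert zones.zones[int(cy), int(cx)] == k


class TestDelaunay:
    def test_right_triangle_mean_edge(self):
        pts = np.array([[0.0, 0.0], [0.0, 30.0], [40.0, 0.0]])
        roi = np.ones((50, 50), dtype=bool)
        tri = delaunay_edges(pts, roi)
        assert len(tri.edges) == 3
        assert tri.mean_edge_length == pytest.approx(40.0)
        assert tri.mean_edge_per_triangle == pytest.approx(40.0)

    def test_two_points_single_edge(self):
        pts = np.array([[5.0, 5.0], [5.0, 37.0]])
        tri = delaunay_edges(pts, np.ones((20, 50), dtype=bool))
        assert len(tri.edges) == 1
        assert tri.mean_edge_length == pytest.approx(32.0)

    def test_u_shaped_roi_drops_gap_crossing_edges(self):
        roi = np.ones((40, 40), dtype=bool)
        roi[0:26, 17:23] = False  # slot between two arms
        pts = np.array([[10.0, 8.0], [10.0, 32.0], [36.0, 20.0]])
        tri = delaunay_edges(pts, roi)
        crossing = {(0, 1)}
        kept = {tuple(e) for e in tri.edges}
        assert crossing.isdisjoint(kept)
        assert len(kept) == 2

    def test_collinear_points_fall_back_to_chain(self):
        pts = np.array([[10.0, 10.0], [10.0, 42.0], [10.0, 102.0]])
        roi = np.ones((20, 120), dtype=bool)
        with pytest.warns(UserWarning, match="collinear"):
            tri = delaunay_edges(pts, roi)
        assert tri.degenerate
        assert sorted(map(tuple, tri.edges)) == [(0, 1), (1, 2)]
        assert tri.mean_edge_length == pytest.approx((32 + 60) / 2)

    def test_mean_edge_invariant_to_translation_and_rotation(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(10, 50, size=(12, 2))
        roi = np.ones((200, 200), dtype=bool)
        base = delaunay_edges(pts, roi).mean_edge_length
        shifted = delaunay_edges(pts + [30.0, 40.0], roi).mean_edge_length
        rotated = delaunay_edges(
            np.column_stack([pts[:, 1], 100 - pts[:, 0]]), roi
        ).mean_edge_length
        assert shifted == pytest.approx(base, rel=1e-9)
        assert rotated == pytest.approx(base, rel=1e-9)
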
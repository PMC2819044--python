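"""Masked geodesic distance propagation on the pixel grid.

Distances are chamfer path lengths with 8-neighbour moves weighted 1
(axial) and sqrt(2) (diagonal), restricted to a boolean mask.  Ties in
distance are broken towards the lower seed label, which keeps influence
zones deterministic on the equidistant (SKIZ) boundary.

Distinct chamfer sums a + b*sqrt(2) with a, b below ~1e5 are separated by
more than ~1e-5 while float64 accumulation error stays below ~1e-10, so an
epsilon of 1e-9 detects ties exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT2 = np.sqrt(2.0)
_EPS = 1e-9

# 8-neighbourhood: (drow, dcol, step weight)
_MOVES = np.array(
    [
        (-1, -1, _SQRT2), (-1, 0, 1.0), (-1, 1, _SQRT2),
        (0, -1, 1.0), (0, 1, 1.0),
        (1, -1, _SQRT2), (1, 0, 1.0), (1, 1, _SQRT2),
    ],
    dtype=np.float64,
)


@njit(cache=True)
def _dijkstra_labels(mask, seeds, moves):  # pragma: no cover - jitted
    h, w = mask.shape
    n = h * w
    dist = np.full(n, np.inf, dtype=np.float64)
    label = np.zeros(n, dtype=np.int32)

    cap = 4 * n + 16
    heap_key = np.empty(cap, dtype=np.float64)
    heap_pix = np.empty(cap, dtype=np.int64)
    size = 0

    for i in range(h):
        for j in range(w):
            s = seeds[i, j]
            if s > 0 and mask[i, j]:
                p = i * w + j
                dist[p] = 0.0
                label[p] = s
                heap_key[size] = 0.0
                heap_pix[size] = p
                size += 1
    # heapify
    for start in range(size // 2 - 1, -1, -1):
        pos = start
        while True:
            child = 2 * pos + 1
            if child >= size:
                break
            if child + 1 < size and heap_key[child + 1] < heap_key[child]:
                child += 1
            if heap_key[child] < heap_key[pos]:
                heap_key[pos], heap_key[child] = heap_key[child], heap_key[pos]
                heap_pix[pos], heap_pix[child] = heap_pix[child], heap_pix[pos]
                pos = child
            else:
                break

    while size > 0:
        key = heap_key[0]
        p = heap_pix[0]
        size -= 1
        heap_key[0] = heap_key[size]
        heap_pix[0] = heap_pix[size]
        pos = 0
        while True:
            child = 2 * pos + 1
            if child >= size:
                break
            if child + 1 < size and heap_key[child + 1] < heap_key[child]:
                child += 1
            if heap_key[child] < heap_key[pos]:
                heap_key[pos], heap_key[child] = heap_key[child], heap_key[pos]
                heap_pix[pos], heap_pix[child] = heap_pix[child], heap_pix[pos]
                pos = child
            else:
                break
        if key > dist[p] + _EPS:
            continue  # stale entry
        i = p // w
        j = p % w
        dp = dist[p]
        lp = label[p]
        for m in range(8):
            ni = i + int(moves[m, 0])
            nj = j + int(moves[m, 1])
            if ni < 0 or nj < 0 or ni >= h or nj >= w:
                continue
            if not mask[ni, nj]:
                continue
            q = ni * w + nj
            cand = dp + moves[m, 2]
            if cand < dist[q] - _EPS or (
                abs(cand - dist[q]) <= _EPS and lp < label[q]
            ):
                dist[q] = cand
                label[q] = lp
                if size >= cap:
                    # grow
                    new_cap = cap * 2
                    nk = np.empty(new_cap, dtype=np.float64)
                    npix = np.empty(new_cap, dtype=np.int64)
                    nk[:size] = heap_key[:size]
                    npix[:size] = heap_pix[:size]
                    heap_key = nk
                    heap_pix = npix
                    cap = new_cap
                heap_key[size] = cand
                heap_pix[size] = q
                size += 1
                # sift up
                pos = size - 1
                while pos > 0:
                    parent = (pos - 1) // 2
                    if heap_key[pos] < heap_key[parent]:
                        heap_key[pos], heap_key[parent] = (
                            heap_key[parent],
                            heap_key[pos],
                        )
                        heap_pix[pos], heap_pix[parent] = (
                            heap_pix[parent],
                            heap_pix[pos],
                        )
                        pos = parent
                    else:
                        break
    return dist.reshape(h, w), label.reshape(h, w)


def geodesic_propagate(
    mask: np.ndarray, seeds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate seed labels through ``mask`` along chamfer-geodesic paths.

    Parameters
    ----------
    mask:
        Boolean raster; propagation is confined to True pixels.
    seeds:
        Integer raster, 0 = unseeded, k >= 1 = seed label k.

    Returns
    -------
    dist, label:
        Geodesic distance to the nearest seed (inf where unreachable) and
        the label of that seed (0 where unreachable).  Equidistant pixels
        take the lower label.
    """
    mask = np.ascontiguousarray(mask, dtype=np.bool_)
    seeds = np.ascontiguousarray(seeds, dtype=np.int32)
    if mask.shape != seeds.shape:
        raise ValueError("mask and seeds must have identical shapes")
    return _dijkstra_labels(mask, seeds, _MOVES)


def geodesic_distance(mask: np.ndarray, source_rc: tuple[int, int]) -> np.ndarray:
    """Geodesic distance map within ``mask`` from a single source pixel."""
    seeds = np.zeros(mask.shape, dtype=np.int32)
    seeds[source_rc] = 1
    dist, _ = geodesic_propagate(mask, seeds)
    return dist


def geodesic_center(mask: np.ndarray) -> tuple[int, int]:
    """Minimax center of a connected region under the chamfer-geodesic metric.

    Returns the pixel minimizing the maximum within-mask distance to every
    other mask pixel; exact, with ties broken towards the smallest
    (row, column).  Uses iteratively tightened eccentricity lower bounds so
    only a handful of single-source propagations are needed per region.
    """
    pix = np.argwhere(mask)
    if pix.shape[0] == 0:
        raise ValueError("empty region has no geodesic center")
    if pix.shape[0] == 1:
        return int(pix[0, 0]), int(pix[0, 1])

    flat = mask.ravel()
    idx = np.flatnonzero(flat)  # lexicographic (row, col) order
    lower = np.zeros(idx.size, dtype=np.float64)  # eccentricity lower bounds
    true_ecc = np.full(idx.size, np.inf)
    best_ecc = np.inf
    best_pos = -1  # position into idx

    w = mask.shape[1]

    def run(pos: int) -> np.ndarray:
        rc = (int(idx[pos] // w), int(idx[pos] % w))
        d = geodesic_distance(mask, rc).ravel()[idx]
        return d

    while True:
        cand = np.flatnonzero(
            np.isinf(true_ecc) & (lower <= best_ecc + _EPS)
        )
        if cand.size == 0:
            break
        # lexicographically smallest pixel among the lowest bounds
        c = cand[np.argmin(lower[cand])]
        d = run(c)
        ecc = d.max()
        true_ecc[c] = ecc
        np.maximum(lower, d, out=lower)
        lower[c] = ecc
        if ecc < best_ecc - _EPS or (
            abs(ecc - best_ecc) <= _EPS and (best_pos < 0 or c < best_pos)
        ):
            best_ecc = ecc
            best_pos = c
        # farthest witness sharpens the bounds for pixels near the center
        wpos = int(np.argmax(d))
        if np.isinf(true_ecc[wpos]):
            dw = run(wpos)
            true_ecc[wpos] = dw.max()
            np.maximum(lower, dw, out=lower)
            lower[wpos] = true_ecc[wpos]
            if true_ecc[wpos] < best_ecc - _EPS or (
                abs(true_ecc[wpos] - best_ecc) <= _EPS and wpos < best_pos
            ):
                best_ecc = true_ecc[wpos]
                best_pos = wpos

    p = int(idx[best_pos])
    return p // w, p % w
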
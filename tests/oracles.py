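"""Brute-force reference implementations used as independent oracles.

Every function here is written for clarity over speed (explicit set
arithmetic, exhaustive searches, priority queues) and is only ever run on
small grids; the package implementations are checked against these, never
the other way around.
"""

from __future__ import annotations

import heapq

import numpy as np


def neighborhood_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    """Voxel offsets of the 6- (faces) or 26- (full cube) neighborhood."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append((dz, dy, dx))
    return offs


def se_offsets_ball6(radius: int) -> list[tuple[int, int, int]]:
    """All offsets of the radius-r ball in the city-block metric."""
    r = int(radius)
    return [
        (dz, dy, dx)
        for dz in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if abs(dz) + abs(dy) + abs(dx) <= r
    ]


def erode_bf(mask: np.ndarray, se: list[tuple[int, int, int]]) -> np.ndarray:
    """Erosion by explicit set arithmetic; outside the grid counts as background."""
    out = np.zeros_like(mask, dtype=bool)
    for v in np.argwhere(mask):
        keep = True
        for d in se:
            n = v + d
            if not all(0 <= n[a] < mask.shape[a] for a in range(3)) or not mask[tuple(n)]:
                keep = False
                break
        out[tuple(v)] = keep
    return out


def dilate_bf(mask: np.ndarray, se: list[tuple[int, int, int]]) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    for v in np.argwhere(mask):
        for d in se:
            n = v + d
            if all(0 <= n[a] < mask.shape[a] for a in range(3)):
                out[tuple(n)] = True
    return out


def open_bf(mask: np.ndarray, se: list[tuple[int, int, int]]) -> np.ndarray:
    return dilate_bf(erode_bf(mask, se), se)


def com_bf(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Exhaustive center of mass in mm."""
    pts = np.argwhere(mask).astype(float)
    return pts.mean(axis=0) * np.asarray(spacing)


def signed_distance_bf(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """All-pairs nearest-opposite-phase distance, negative inside the mask."""
    spacing = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask) * spacing
    bg = np.argwhere(~mask) * spacing
    out = np.zeros(mask.shape, dtype=float)
    for v in np.ndindex(mask.shape):
        p = np.asarray(v) * spacing
        if mask[v]:
            d = np.sqrt(((bg - p) ** 2).sum(axis=1)).min()
            out[v] = -d
        else:
            d = np.sqrt(((fg - p) ** 2).sum(axis=1)).min()
            out[v] = d
    return out


def watershed_bf(dmap: np.ndarray, seeds: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Priority flood from seeds, ascending distance-map value, 6-connected."""
    out = np.zeros(mask.shape, dtype=np.int32)
    heap: list = []
    cnt = 0
    seeded = np.zeros(mask.shape, dtype=bool)
    for i, s in enumerate(np.asarray(seeds, dtype=int), start=1):
        seeded[tuple(s)] = True
        heapq.heappush(heap, (float(dmap[tuple(s)]), cnt, tuple(s), i))
        cnt += 1
    nb = neighborhood_offsets(6)
    while heap:
        _, _, v, lab = heapq.heappop(heap)
        if out[v]:
            continue
        out[v] = lab
        for d in nb:
            n = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                all(0 <= n[a] < mask.shape[a] for a in range(3))
                and mask[n]
                and not out[n]
                and not seeded[n]
            ):
                heapq.heappush(heap, (float(dmap[n]), cnt, n, lab))
                cnt += 1
    return out


def surface_distances_bf(pred: np.ndarray, ref: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    """Exhaustive nearest-surface search version of the surface metrics."""
    spacing = np.asarray(spacing, dtype=float)

    def surface(mask):
        pts = []
        for v in np.argwhere(mask):
            for d in neighborhood_offsets(6):
                n = v + d
                if not all(0 <= n[a] < mask.shape[a] for a in range(3)) or not mask[tuple(n)]:
                    pts.append(v)
                    break
        return np.asarray(pts)

    ps = surface(pred)
    rs = surface(ref)
    d_pred = np.array(
        [np.sqrt((((rs - v) * spacing) ** 2).sum(axis=1)).min() for v in ps]
    )
    d_ref = np.array(
        [np.sqrt((((ps - v) * spacing) ** 2).sum(axis=1)).min() for v in rs]
    )
    signs = np.array([-1.0 if ref[tuple(v)] else 1.0 for v in ps])
    ds = float((signs * d_pred).mean())
    du = float(d_pred.mean())
    hd = float(max(d_pred.max(), d_ref.max()))
    return ds, du, hd


def flood_fill_from_border(mask: np.ndarray) -> np.ndarray:
    """Background voxels reachable from the volume border (6-connected)."""
    bg = ~mask
    reach = np.zeros(mask.shape, dtype=bool)
    stack = [tuple(v) for v in np.argwhere(bg) if 0 in v or any(v[a] == mask.shape[a] - 1 for a in range(3))]
    for v in stack:
        reach[v] = True
    nb = neighborhood_offsets(6)
    while stack:
        v = stack.pop()
        for d in nb:
            n = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if all(0 <= n[a] < mask.shape[a] for a in range(3)) and bg[n] and not reach[n]:
                reach[n] = True
                stack.append(n)
    return reach
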
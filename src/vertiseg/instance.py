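"""Instance separation and segmentation post-processing.

Given the stitched three-label segmentation and the selected vertebra
centers, individual vertebrae are carved out in five steps:

1. a signed Euclidean distance map is computed on the *body* label only
   (negative inside, positive outside);
2. each center is shifted to the local minimum of the distance map within a
   5x5x5 window (iterated to a fixed point) so seeds sit deep inside bodies;
3. a seeded watershed on the distance map splits the body mask into one
   region per seed;
4. labels are grown back over the boundary shell by constrained dilation
   (never leaving the original body ∪ boundary foreground);
5. foreground components left unlabeled (small or collapsed vertebrae whose
   centers were missed) are recovered one by one, largest first, whenever
   inserting their center does not decrease the clustering score
   (CS(k+1) >= CS(k)), up to the anatomical maximum of 18 vertebrae.

Finally, per-instance islands are removed and internal holes filled, and
instances are relabeled 1..k from bottom to top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .core import LabelMap, ThreeLabelMap
from .center_model import DistanceModel, clustering_score

__all__ = [
    "MAX_VERTEBRAE",
    "InstanceSegmentation",
    "signed_distance_map",
    "refine_centers",
    "split_watershed",
    "recover_boundary",
    "recover_missing",
    "fill_islands_holes",
    "relabel_bottom_to_top",
]

#: maximum number of vertebra instances considered
MAX_VERTEBRAE = 18

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class InstanceSegmentation:
    """Final per-vertebra labeling with provenance flags."""

    labels: LabelMap
    provenance: dict[int, str] = field(default_factory=dict)  # label -> clustered|recovered

    @property
    def k(self) -> int:
        return self.labels.n_instances


def signed_distance_map(body_mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask surface, negative inside."""
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("body mask is empty")
    outside = ndimage.distance_transform_edt(~body_mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(body_mask, sampling=spacing)
    return (outside - inside).astype(np.float64)


def refine_centers(
    centers_vox: np.ndarray, dmap: np.ndarray, window: int = 5, max_iter: int = 10
) -> np.ndarray:
    """Shift each center (voxel coords) to the windowed argmin of the distance map.

    The shift is iterated until a fixed point is reached (or ``max_iter``),
    letting centers that start slightly off a vertebral body slide into it.
    """
    half = window // 2
    out = np.rint(np.asarray(centers_vox, dtype=float)).astype(int)
    out = np.clip(out, 0, np.asarray(dmap.shape) - 1)
    for i, c in enumerate(out):
        cur = c.copy()
        for _ in range(max_iter):
            lo = np.maximum(cur - half, 0)
            hi = np.minimum(cur + half + 1, dmap.shape)
            win = dmap[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            arg = np.unravel_index(np.argmin(win), win.shape)
            nxt = lo + np.asarray(arg)
            if np.array_equal(nxt, cur):
                break
            cur = nxt
        out[i] = cur
    return out


def split_watershed(
    body_mask: np.ndarray, seeds_vox: np.ndarray, dmap: np.ndarray | None = None,
    spacing=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Partition the body mask by seeded watershed on the signed distance map.

    Seeds (voxel coordinates, ordered bottom to top) become labels 1..k.
    Flooding proceeds in ascending distance-map order and is confined to the
    mask; mask components that contain no seed remain unlabeled (label 0) so
    that the recovery step can pick them up later.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    seeds_vox = np.rint(np.asarray(seeds_vox, dtype=float)).astype(int)
    if dmap is None:
        dmap = signed_distance_map(body_mask, spacing)
    markers = np.zeros(body_mask.shape, dtype=np.int32)
    for i, s in enumerate(seeds_vox, start=1):
        if not body_mask[tuple(s)]:
            raise ValueError(f"seed {i} at {tuple(s)} lies outside the body mask")
        markers[tuple(s)] = i
    return watershed(dmap, markers=markers, mask=body_mask, connectivity=1).astype(np.int32)


def recover_boundary(
    labels: np.ndarray, tlm: ThreeLabelMap, max_rounds: int = 5
) -> np.ndarray:
    """Grow instance labels over the boundary shell by constrained dilation.

    Each round claims unlabeled foreground voxels that are face-adjacent to a
    label; a contested voxel goes to the label with more face-adjacent
    claimant voxels (ties to the lower label).  Growth never leaves the body ∪
    boundary foreground and stops at convergence or after ``max_rounds``.
    """
    labels = np.asarray(labels).astype(np.int32).copy()
    allowed = tlm.foreground_mask
    kernel = _CONN6.astype(np.float32)
    present = [int(l) for l in np.unique(labels) if l > 0]
    for _ in range(max_rounds):
        frontier = allowed & (labels == 0)
        if not frontier.any():
            break
        best_count = np.zeros(labels.shape, dtype=np.float32)
        winner = np.zeros(labels.shape, dtype=np.int32)
        for lab in present:  # ascending: ties stay with the lower label
            claims = ndimage.convolve(
                (labels == lab).astype(np.float32), kernel, mode="constant"
            )
            take = frontier & (claims > best_count)
            winner[take] = lab
            best_count = np.maximum(best_count, np.where(frontier, claims, 0))
        grow = winner > 0
        if not grow.any():
            break
        labels[grow] = winner[grow]
    return labels


def fill_islands_holes(instance_mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component, then fill internal cavities.

    Implemented by the inversion trick: after keeping the largest foreground
    component, the mask is inverted, all inverted components except the
    largest (the outer background) are removed, and the result is inverted
    back.
    """
    mask = np.asarray(instance_mask, dtype=bool)
    if not mask.any():
        raise ValueError("instance mask is empty")
    lab, n = ndimage.label(mask, structure=_CONN26)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    inv_lab, n_inv = ndimage.label(~mask, structure=_CONN26)
    if n_inv > 1:
        sizes = np.bincount(inv_lab.ravel())[1:]
        outer = int(np.argmax(sizes)) + 1
        mask = inv_lab != outer
    return mask


def relabel_bottom_to_top(labels: LabelMap) -> LabelMap:
    """Renumber instances 1..k by ascending center-of-mass z (ties: y, then x)."""
    values = labels.values
    present = [int(l) for l in np.unique(values) if l > 0]
    if not present:
        return labels
    coms = ndimage.center_of_mass(values > 0, values, present)
    order = sorted(range(len(present)), key=lambda i: tuple(coms[i]))
    remap = np.zeros(max(present) + 1, dtype=values.dtype)
    for new, i in enumerate(order, start=1):
        remap[present[i]] = new
    return LabelMap(remap[values], labels.spacing, labels.origin)


def recover_missing(
    seg: InstanceSegmentation,
    tlm: ThreeLabelMap,
    model: DistanceModel,
    min_component_voxels: int = 10,
) -> InstanceSegmentation:
    """Recover unlabeled foreground components as additional vertebrae.

    Connected components (26-connectivity) of the three-label foreground not
    covered by the current labeling are visited from largest to smallest.  A
    component is accepted as a new vertebra when inserting its center of mass
    into the z-sorted center list does not decrease the clustering score
    (CS(k+1) >= CS(k)) and the instance cap of 18 is not exceeded.  The final
    map is relabeled bottom to top; recovered instances are flagged in
    ``provenance``.
    """
    lm = seg.labels
    values = lm.values.copy()
    unlabeled = tlm.foreground_mask & (values == 0)
    comp_lab, n_comp = ndimage.label(unlabeled, structure=_CONN26)
    if n_comp == 0:
        return seg
    sizes = np.bincount(comp_lab.ravel())
    order = sorted(
        [c for c in range(1, n_comp + 1) if sizes[c] >= min_component_voxels],
        key=lambda c: -sizes[c],
    )

    spacing = np.asarray(lm.spacing)
    origin = np.asarray(lm.origin)
    present = [int(l) for l in np.unique(values) if l > 0]
    centers = [
        origin + np.asarray(ndimage.center_of_mass(values == l)) * spacing for l in present
    ]
    provenance_flags = [seg.provenance.get(l, "clustered") for l in present]
    k = len(centers)
    next_label = (max(present) if present else 0) + 1

    for c in order:
        if k >= MAX_VERTEBRAE:
            break
        comp_mask = comp_lab == c
        c_mm = origin + np.asarray(ndimage.center_of_mass(comp_mask)) * spacing
        if k >= 3:
            cs_k = clustering_score(np.asarray(centers), model)
            cs_k1 = clustering_score(np.asarray(centers + [c_mm]), model)
            if cs_k1 < cs_k:
                continue
        values[comp_mask] = next_label
        centers.append(c_mm)
        provenance_flags.append("recovered")
        present.append(next_label)
        next_label += 1
        k += 1

    interim = LabelMap(values, lm.spacing, lm.origin)
    final = relabel_bottom_to_top(interim)
    # carry provenance through the relabeling
    provenance: dict[int, str] = {}
    for old_label, flag in zip(present, provenance_flags):
        mask = values == old_label
        if mask.any():
            new_label = int(final.values[mask][0])
            provenance[new_label] = flag
    return InstanceSegmentation(labels=final, provenance=provenance)
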
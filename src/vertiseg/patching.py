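"""Overlapping patch grids and localization ground truth.

The network sees overlapping volume patches (default 32 x 48 x 48 voxels at
50% overlap in all three directions).  For each patch a 1x12 localization
target is built: three offset vectors (mm, patch center to vertebral-body
center) for a *top*, *mid* and *bottom* vertebra, plus three confidence
scores.  The confidence of a vertebra is the fraction of its total volume
lying inside the patch; a neighbor absent from the patch gets confidence 0
and an extrapolated ("plausible") position.

Mid-center selection by number of visible vertebrae:

1. one visible: it is the mid-center;
2. two visible: the *lower* one is the mid-center;
3. three visible: the middle one;
4. more than three: iteratively drop the lowest-confidence instance (ties:
   drop the topmost) until three remain, then take the middle of those three.

Serialization order of the 1x12 vector is fixed as
``(top_offset, mid_offset, bottom_offset, conf_top, conf_mid, conf_bottom)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import LabelMap, ThreeLabelMap
from .preprocess import VOISpec

__all__ = [
    "DEFAULT_PATCH_SIZE",
    "PatchGrid",
    "LocalizationTarget",
    "NotATargetError",
    "build_patch_grid",
    "localization_target",
    "sample_training_batch",
    "stitch_predictions",
]

DEFAULT_PATCH_SIZE = (32, 48, 48)
DEFAULT_OVERLAP = 0.5


class NotATargetError(ValueError):
    """Raised for patches that contain no instance voxels (caller must filter)."""


@dataclass
class LocalizationTarget:
    """Three center offsets (mm) with confidences, ordered (top, mid, bottom)."""

    offsets: np.ndarray  # (3, 3): rows top, mid, bottom; columns (z, y, x) mm
    confidences: np.ndarray  # (3,): top, mid, bottom, each in [0, 1]

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float).reshape(3, 3)
        self.confidences = np.asarray(self.confidences, dtype=float).reshape(3)

    def to_vector(self) -> np.ndarray:
        """The 1x12 vector (top_off, mid_off, bottom_off, conf_t, conf_m, conf_b)."""
        return np.concatenate([self.offsets.ravel(), self.confidences])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "LocalizationTarget":
        vec = np.asarray(vec, dtype=float).reshape(12)
        return cls(offsets=vec[:9].reshape(3, 3), confidences=vec[9:])

    @property
    def conf_top(self) -> float:
        return float(self.confidences[0])

    @property
    def conf_mid(self) -> float:
        return float(self.confidences[1])

    @property
    def conf_bottom(self) -> float:
        return float(self.confidences[2])


@dataclass
class PatchGrid:
    """A regular lattice of overlapping patch origins covering a VOI."""

    patch_size: tuple[int, int, int]
    overlap_fraction: float
    voi_size: tuple[int, int, int]
    origins: np.ndarray  # (N, 3) int voxel lower corners

    def __len__(self) -> int:
        return len(self.origins)

    def patch_slices(self, origin: np.ndarray) -> tuple[slice, slice, slice]:
        return tuple(slice(int(o), int(o) + p) for o, p in zip(origin, self.patch_size))


def build_patch_grid(
    voi: VOISpec | tuple[int, int, int],
    patch_size: tuple[int, int, int] = DEFAULT_PATCH_SIZE,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> PatchGrid:
    """Regular overlapping patch lattice over a VOI.

    The stride is ``patch_size * (1 - overlap_fraction)`` and must be a whole
    number of voxels per axis.  The last patch per axis is clamped so its far
    face coincides with the VOI boundary, guaranteeing full coverage.  A patch
    larger than the VOI along an axis is clamped to the VOI size (with a
    warning), yielding a single position on that axis.
    """
    size = tuple(voi.size) if isinstance(voi, VOISpec) else tuple(int(s) for s in voi)
    eff_patch = []
    for p, L in zip(patch_size, size):
        if p > L:
            warnings.warn(f"patch extent {p} exceeds VOI extent {L}; clamping")
            p = L
        eff_patch.append(int(p))
    axes_positions = []
    for p, L in zip(eff_patch, size):
        s = p * (1.0 - overlap_fraction)
        if abs(s - round(s)) > 1e-9 or round(s) < 1:
            raise ValueError(
                f"overlap {overlap_fraction} gives non-integer or zero stride for patch extent {p}"
            )
        s = int(round(s))
        pos = list(range(0, L - p + 1, s))
        if pos[-1] != L - p:
            pos.append(L - p)  # clamp the last patch to the boundary
        axes_positions.append(pos)
    origins = np.array(
        [(z, y, x) for z in axes_positions[0] for y in axes_positions[1] for x in axes_positions[2]],
        dtype=int,
    )
    return PatchGrid(
        patch_size=tuple(eff_patch),
        overlap_fraction=float(overlap_fraction),
        voi_size=size,
        origins=origins,
    )


def _patch_center_mm(patch_origin, patch_size, lm: LabelMap) -> np.ndarray:
    center_vox = np.asarray(patch_origin, dtype=float) + np.asarray(patch_size, dtype=float) / 2.0
    return lm.voxel_to_mm(center_vox)


def localization_target(
    patch_origin,
    patch_size,
    lm: LabelMap,
    body_centers: dict[int, np.ndarray],
    fallback_gap_mm: float = 30.0,
) -> LocalizationTarget:
    """Ground-truth 1x12 localization vector for one patch.

    ``body_centers`` maps every instance label of ``lm`` to its vertebral-body
    center in mm.  Confidences of present vertebrae are exact volume fractions
    inside the patch; absent neighbors get confidence 0 and a mirrored
    position (``mid + (mid - present_neighbor)``), falling back to a z-shift
    of ``fallback_gap_mm`` when no neighbor is present to mirror.
    """
    patch_origin = np.asarray(patch_origin, dtype=int)
    patch_size = np.asarray(patch_size, dtype=int)
    sub = lm.values[tuple(slice(o, o + p) for o, p in zip(patch_origin, patch_size))]
    total = np.bincount(lm.values.ravel())
    inside = np.bincount(sub.ravel(), minlength=total.size)
    visible = [int(l) for l in np.nonzero(inside)[0] if l > 0]
    if not visible:
        raise NotATargetError("patch contains no instance voxels")
    frac = {l: inside[l] / total[l] for l in visible}

    # mid-center selection; labels are ordered bottom-to-top
    cand = sorted(visible)
    while len(cand) > 3:
        worst = min(frac[l] for l in cand)
        # ties: drop the topmost of the lowest-confidence instances
        drop = max(l for l in cand if frac[l] == worst)
        cand.remove(drop)
    if len(cand) == 1:
        mid = cand[0]
    elif len(cand) == 2:
        mid = cand[0]  # the lower vertebra
    else:
        mid = cand[1]

    all_labels = set(int(l) for l in lm.labels)
    center_mm = _patch_center_mm(patch_origin, patch_size, lm)

    def neighbor(pos_label: int, other_label: int, direction: float):
        """Position and confidence of an anatomical neighbor of mid."""
        if pos_label in all_labels:
            conf = inside[pos_label] / total[pos_label]  # 0 when not visible in patch
            return np.asarray(body_centers[pos_label], dtype=float), float(conf)
        mid_c = np.asarray(body_centers[mid], dtype=float)
        if other_label in all_labels:
            other_c = np.asarray(body_centers[other_label], dtype=float)
            return 2.0 * mid_c - other_c, 0.0  # mirror rule
        return mid_c + np.array([direction * fallback_gap_mm, 0.0, 0.0]), 0.0

    top_pos, top_conf = neighbor(mid + 1, mid - 1, +1.0)
    bot_pos, bot_conf = neighbor(mid - 1, mid + 1, -1.0)
    mid_pos = np.asarray(body_centers[mid], dtype=float)

    offsets = np.stack([top_pos, mid_pos, bot_pos]) - center_mm
    confidences = np.array([top_conf, frac[mid], bot_conf])
    return LocalizationTarget(offsets=offsets, confidences=confidences)


def sample_training_batch(
    grid: PatchGrid,
    lm: LabelMap,
    batch_size: int,
    vertebra_fraction: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Seeded batch of patch origins, at least a fraction intersecting vertebrae.

    At least ``ceil(batch_size * vertebra_fraction)`` origins are drawn from
    patches that contain vertebra voxels; the remainder is drawn uniformly
    over the whole grid.  Returns an ``(batch_size, 3)`` array of origins.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    rng = np.random.default_rng(seed)
    has_vert = np.array(
        [bool((lm.values[grid.patch_slices(o)] > 0).any()) for o in grid.origins]
    )
    vert_idx = np.nonzero(has_vert)[0]
    if vert_idx.size == 0:
        raise ValueError("no patch in the grid intersects a vertebra")
    n_vert = math.ceil(batch_size * vertebra_fraction)
    n_vert = min(n_vert, batch_size)
    chosen_vert = rng.choice(vert_idx, size=n_vert, replace=vert_idx.size < n_vert)
    chosen_rest = rng.choice(len(grid.origins), size=batch_size - n_vert, replace=True)
    idx = np.concatenate([chosen_vert, chosen_rest])
    return grid.origins[idx]


def stitch_predictions(
    patches: list[np.ndarray],
    grid: PatchGrid,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ThreeLabelMap:
    """Combine per-patch class probabilities into one three-label map.

    ``patches[i]`` is the ``(3, pz, py, px)`` class-probability block for
    ``grid.origins[i]``.  Overlapping probabilities are averaged per voxel and
    the per-voxel argmax over {background, body, boundary} is taken (ties go
    to the lower class code).
    """
    if len(patches) != len(grid.origins):
        raise ValueError(
            f"got {len(patches)} blocks for {len(grid.origins)} grid origins"
        )
    acc = np.zeros((3, *grid.voi_size), dtype=np.float64)
    cnt = np.zeros(grid.voi_size, dtype=np.int32)
    expected = (3, *grid.patch_size)
    for block, origin_vox in zip(patches, grid.origins):
        block = np.asarray(block)
        if block.shape != expected:
            raise ValueError(f"block shape {block.shape} != expected {expected}")
        slc = grid.patch_slices(origin_vox)
        acc[(slice(None),) + slc] += block
        cnt[slc] += 1
    probs = acc / cnt  # every voxel covered by >= 1 patch by construction
    values = np.argmax(probs, axis=0).astype(np.int8)
    return ThreeLabelMap(values, spacing, origin)
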
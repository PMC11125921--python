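"""Resampling, intensity normalization and VOI cropping.

Scans are brought onto a common working grid (default 0.977 x 0.977 x 2 mm,
stated (z, y, x) here), clipped to reference-set intensity percentiles and
Z-score normalized with reference-set statistics.  The vertebra volume of
interest (VOI) is anchored either on a user-supplied pelvis mask (its center
of mass defines the bottom center), on an explicit bottom plane, or on the
scan bottom as a fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import LabelMap, Volume, _from_sitk, _to_sitk

__all__ = [
    "WORKING_SPACING",
    "VOISpec",
    "NormStats",
    "compute_norm_stats",
    "resample_to_working_grid",
    "clip_and_normalize",
    "crop_voi",
]

#: default working grid, (z, y, x) mm
WORKING_SPACING = (2.0, 0.977, 0.977)

#: floor on the reference standard deviation
SD_FLOOR = 1e-6

#: default crop extent (z, y, x) voxels for planning-CT style scans
DEFAULT_CROP_SIZE = (128, 256, 256)

#: axial crop extent used for diverse multi-institutional scans
WIDE_AXIAL_CROP = (320, 320)


@dataclass
class VOISpec:
    """A sub-box of the working grid, in voxel coordinates."""

    lower_corner: tuple[int, int, int]
    size: tuple[int, int, int]
    source: Literal["pelvis_mask", "bottom_plane", "scan_bottom"]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(c, c + s) for c, s in zip(self.lower_corner, self.size))


@dataclass
class NormStats:
    """Reference-set intensity statistics ({lo, hi} clip bounds, mean, sd)."""

    lo: float
    hi: float
    mean: float
    sd: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormStats":
        return cls(**json.loads(Path(path).read_text()))


def compute_norm_stats(
    volumes: Sequence[Volume], lo_pct: float = 0.5, hi_pct: float = 99.5
) -> NormStats:
    """Percentile clip bounds and post-clip mean/sd over a reference set.

    Percentiles use linear interpolation between order statistics.  The mean
    and standard deviation are computed on the clipped pooled intensities, so
    that ``clip_and_normalize`` maps the reference set to zero mean and unit
    variance.
    """
    if lo_pct >= hi_pct:
        raise ValueError("lo_pct must be < hi_pct")
    pooled = np.concatenate([np.ravel(v.values) for v in volumes]).astype(np.float64)
    lo, hi = np.percentile(pooled, [lo_pct, hi_pct])
    clipped = np.clip(pooled, lo, hi)
    return NormStats(
        lo=float(lo),
        hi=float(hi),
        mean=float(clipped.mean()),
        sd=float(max(clipped.std(), SD_FLOOR)),
    )


def resample_to_working_grid(
    v: Volume,
    target_spacing: tuple[float, float, float] = WORKING_SPACING,
    is_labels: bool = False,
) -> Volume:
    """Resample onto the target spacing, preserving physical extent.

    Intensities are interpolated linearly, label maps by nearest neighbor (so
    no new label values can appear).  A volume already on the target grid is
    returned value-identical.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    if np.allclose(v.spacing, target_spacing):
        return v
    new_size = tuple(
        int(round(n * s / t)) for n, s, t in zip(v.shape, v.spacing, target_spacing)
    )
    if any(n == 0 for n in new_size):
        raise ValueError(f"resampling to {target_spacing} yields empty output {new_size}")
    img = _to_sitk(v)
    interp = sitk.sitkNearestNeighbor if is_labels else sitk.sitkLinear
    out = sitk.Resample(
        img,
        size=tuple(int(n) for n in new_size[::-1]),
        transform=sitk.Transform(),
        interpolator=interp,
        outputOrigin=img.GetOrigin(),
        outputSpacing=tuple(target_spacing[::-1]),
        outputDirection=img.GetDirection(),
        defaultPixelValue=0.0,
    )
    arr, spacing, origin = _from_sitk(out)
    if is_labels:
        return LabelMap(arr.astype(v.values.dtype), spacing, origin)
    return Volume(arr.astype(np.float32), spacing, origin)


def clip_and_normalize(
    v: Volume,
    lo_pct: float = 0.5,
    hi_pct: float = 99.5,
    ref: NormStats | None = None,
) -> Volume:
    """Clip to reference percentile bounds, then Z-score normalize.

    With ``ref=None`` the reference statistics are computed from the volume
    itself; for test data they should come from the training reference set
    (``compute_norm_stats`` / the ``norm_stats.json`` sidecar).
    """
    if ref is None:
        ref = compute_norm_stats([v], lo_pct=lo_pct, hi_pct=hi_pct)
    if ref.sd < SD_FLOOR:
        raise ValueError(f"reference sd {ref.sd} below floor {SD_FLOOR}")
    clipped = np.clip(v.values.astype(np.float32), ref.lo, ref.hi)
    return v.with_values((clipped - ref.mean) / ref.sd)


def crop_voi(
    v: Volume,
    anchor: LabelMap | Volume | int | None = None,
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
    top_limit: int | None = None,
) -> tuple[Volume, VOISpec]:
    """Crop the vertebra volume of interest.

    ``anchor`` selects the VOI mode:

    * a binary pelvis mask (``LabelMap``/``Volume``): the mask's center of
      mass defines the bottom center of the VOI (axially centered on it);
    * an integer z index (bottom plane): the VOI starts at that plane and is
      centered on the scan's axial center;
    * ``None``: the VOI starts at the scan bottom, axially centered.

    Extents are clipped to the scan bounds (portions outside the scan are
    ignored); ``top_limit`` optionally caps the VOI top plane (exclusive).
    """
    shape = np.asarray(v.shape)
    crop_size = tuple(int(c) for c in crop_size)
    if isinstance(anchor, (LabelMap, Volume)):
        mask = np.asarray(anchor.values) > 0
        if not mask.any():
            raise ValueError("pelvis mask is empty")
        com = ndimage.center_of_mass(mask)
        z_lo = int(round(com[0]))
        yx_center = (com[1], com[2])
        source: str = "pelvis_mask"
    elif anchor is None:
        z_lo = 0
        yx_center = ((shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0)
        source = "scan_bottom"
    else:
        z_lo = int(anchor)
        yx_center = ((shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0)
        source = "bottom_plane"

    z_hi = z_lo + crop_size[0]
    if top_limit is not None:
        z_hi = min(z_hi, int(top_limit))
    lo = [
        z_lo,
        int(round(yx_center[0] - crop_size[1] / 2.0)),
        int(round(yx_center[1] - crop_size[2] / 2.0)),
    ]
    hi = [z_hi, lo[1] + crop_size[1], lo[2] + crop_size[2]]
    lo = [max(l, 0) for l in lo]
    hi = [min(h, int(s)) for h, s in zip(hi, shape)]
    if any(h <= l for l, h in zip(lo, hi)):
        raise ValueError("VOI does not intersect the scan")
    spec = VOISpec(
        lower_corner=tuple(lo),
        size=tuple(h - l for l, h in zip(lo, hi)),
        source=source,  # type: ignore[arg-type]
    )
    sub = v.values[spec.slices()]
    new_origin = tuple(np.asarray(v.origin) + np.asarray(lo) * np.asarray(v.spacing))
    if isinstance(v, LabelMap):
        cropped: Volume = LabelMap(sub.copy(), v.spacing, new_origin)
    else:
        cropped = Volume(sub.copy(), v.spacing, new_origin)
    return cropped, spec
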
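"""Core image containers and file I/O.

All arrays in this package are indexed ``(z, y, x)`` with ``z`` the
cranio-caudal axis; ``spacing`` and ``origin`` follow the same order and are
given in millimeters.  SimpleITK is used for NIfTI / MetaImage round trips;
its ``(x, y, z)`` metadata convention is flipped at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "LabelMap",
    "ThreeLabelMap",
    "BACKGROUND",
    "BODY",
    "BOUNDARY",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]

# three-label codes
BACKGROUND = 0
BODY = 1
BOUNDARY = 2


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray
        Scalar voxel data, indexed ``(z, y, x)``.
    spacing : tuple of float
        Voxel size in mm, ``(z, y, x)``.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "Volume":
        return replace(self, values=values)

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LabelMap(Volume):
    """Integer instance labels on a grid; 0 is background.

    Positive labels identify vertebra instances and are, by convention,
    numbered 1..k from bottom to top (ascending z of their centers).
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("LabelMap values must be an integer array")

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the map."""
        u = np.unique(self.values)
        return u[u > 0]

    @property
    def n_instances(self) -> int:
        return int(self.labels.size)


@dataclass
class ThreeLabelMap(Volume):
    """Per-voxel {background, body, boundary} encoding of vertebra instances.

    ``body`` is the eroded core of each instance and ``boundary`` the eroded-away
    shell; their union is exactly the original foreground.
    """

    erosion_radius: int = 1

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("ThreeLabelMap values must be an integer array")
        bad = np.setdiff1d(np.unique(self.values), [BACKGROUND, BODY, BOUNDARY])
        if bad.size:
            raise ValueError(f"invalid three-label codes present: {bad.tolist()}")

    @property
    def body_mask(self) -> np.ndarray:
        return self.values == BODY

    @property
    def boundary_mask(self) -> np.ndarray:
        return self.values == BOUNDARY

    @property
    def foreground_mask(self) -> np.ndarray:
        return self.values != BACKGROUND


def _to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(vol.values)
    img.SetSpacing(tuple(vol.spacing[::-1]))
    img.SetOrigin(tuple(vol.origin[::-1]))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    return arr, spacing, origin


def read_volume(path: str | Path) -> Volume:
    """Read an intensity volume from NIfTI / MetaImage / any SimpleITK format."""
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return Volume(arr.astype(np.float32), spacing, origin)


def write_volume(vol: Volume, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(vol), str(path))


def read_labels(path: str | Path) -> LabelMap:
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return LabelMap(np.rint(arr).astype(np.int32), spacing, origin)


def write_labels(lm: LabelMap, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(lm), str(path))
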
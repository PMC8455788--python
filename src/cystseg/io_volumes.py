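"""NIFTI I/O and the core grid-aligned volume types.

Arrays are indexed ``(x, y, z)`` with ``z`` the slice axis (coronal
acquisitions: all 2D "in-plane" operations act on fixed-``z`` planes).
Spacing is in millimetres.  Intensity volumes are carried as float32;
instance label maps as non-negative integers with 0 = background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "BinaryMask3D",
    "InstanceMap3D",
    "read_volume",
    "write_volume",
]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _check_grid(data: np.ndarray, spacing) -> tuple[float, float, float]:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class Volume3D:
    """A scalar 3D image on a regular anisotropic grid.

    Parameters
    ----------
    data
        Real-valued array of shape (X, Y, Z); stored as float32.
    spacing
        Voxel size (dx, dy, dz) in mm, each strictly positive.
    affine
        4x4 voxel-to-world matrix; a diagonal affine built from ``spacing``
        when omitted.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = _check_grid(self.data, self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1000 mm^3 = 1 mL)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class BinaryMask3D:
    """A {0,1} mask on the same grid as a companion :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values outside {{0,1}}: {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = _check_grid(self.data, self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class InstanceMap3D:
    """Non-negative integer label map; each positive label is one cyst.

    Labels need not be contiguous (relabelling operations produce 1..K).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("instance map has non-integer values")
            arr = rounded
        if arr.size and arr.min() < 0:
            raise ValueError("instance map has negative labels")
        self.data = arr.astype(np.int32 if arr.size == 0 or arr.max() < 2**31 else np.int64)
        self.spacing = _check_grid(self.data, self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def labels(self) -> np.ndarray:
        """Sorted array of the positive labels present."""
        labs = np.unique(self.data)
        return labs[labs > 0]


_KINDS = {"volume": Volume3D, "mask": BinaryMask3D, "labels": InstanceMap3D}


def read_volume(path, kind: str = "volume"):
    """Read a NIFTI (.nii or .nii.gz) file.

    Parameters
    ----------
    path
        Path to a NIFTI-1 file, optionally gzip-compressed.
    kind
        ``"volume"`` (default), ``"mask"`` or ``"labels"``; value checks for
        the requested type are applied on load (a mask file containing values
        outside {0,1} is rejected).
    """
    path = Path(path)
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {sorted(_KINDS)}, got {kind!r}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return _KINDS[kind](data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(v, path) -> None:
    """Write a volume / mask / instance map as NIFTI.

    A ``.nii.gz`` suffix triggers gzip compression.  Integer maps are stored
    with an integer on-disk type wide enough for the maximum label.
    """
    path = Path(path)
    if isinstance(v, Volume3D):
        out = v.data.astype(np.float32)
    elif isinstance(v, BinaryMask3D):
        out = v.data.astype(np.uint8)
    elif isinstance(v, InstanceMap3D):
        mx = int(v.data.max()) if v.data.size else 0
        if mx < 2**8:
            out = v.data.astype(np.uint8)
        elif mx < 2**16:
            out = v.data.astype(np.uint16)
        else:
            out = v.data.astype(np.int32)
    else:
        raise TypeError(f"cannot write object of type {type(v).__name__}")
    img = nib.Nifti1Image(out, v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
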
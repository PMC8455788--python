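"""Resampling between the acquisition grid and the working grid.

The final pipeline runs on an up-sampled, near-isotropic working grid:
in-plane to 512x512 (or any requested square target) and slices tripled.
Intensities are interpolated bicubically; label maps are interpolated
per-label (one-hot) with trilinear order-1 interpolation and thresholded at
0.5, since interpolating label integers directly would create spurious
intermediate labels.  Decoded instance maps are brought back to the original
grid by nearest-neighbour sampling at block centres, which for integer
factors makes down-sampling an exact inverse of the label up-sampling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io_volumes import BinaryMask3D, InstanceMap3D, Volume3D

__all__ = ["upsample_exam", "downsample_labels"]


def _zoom_factors(shape, inplane_target, z_factor):
    X, Y, Z = shape
    if X != Y:
        raise ValueError(f"in-plane grid must be square, got {X}x{Y}")
    if X > inplane_target:
        raise ValueError(
            f"in-plane size {X} exceeds the working target {inplane_target}"
        )
    return (inplane_target / X, inplane_target / Y, float(z_factor))


def _zoom_binary(mask: np.ndarray, factors) -> np.ndarray:
    """Order-1 zoom of a binary array; ``grid_mode`` keeps the physical
    extent equal to shape x spacing, so block centres land on original
    voxel centres."""
    return ndimage.zoom(
        mask.astype(np.float32),
        factors,
        order=1,
        grid_mode=True,
        mode="grid-constant",
    )


def upsample_exam(mri: Volume3D, labels, inplane_target: int = 512, z_factor: int = 3):
    """Up-sample an exam to the working grid.

    The MR volume is interpolated with bicubic (order-3) interpolation; each
    label of ``labels`` (an :class:`InstanceMap3D` or :class:`BinaryMask3D`)
    is interpolated as a binary mask with order-1 interpolation and
    thresholded at 0.5.  Where two labels both exceed the threshold, the
    larger interpolated value wins; ties go to the smaller label.  Spacing is
    rescaled so the physical extent is preserved.
    """
    if mri.shape != labels.shape:
        raise ValueError(f"grid mismatch: {mri.shape} vs {labels.shape}")
    factors = _zoom_factors(mri.shape, inplane_target, z_factor)
    new_shape = (inplane_target, inplane_target, mri.shape[2] * z_factor)
    new_spacing = tuple(
        s * o / n for s, o, n in zip(mri.spacing, mri.shape, new_shape)
    )

    up_img = ndimage.zoom(
        mri.data.astype(np.float32),
        factors,
        order=3,
        grid_mode=True,
        mode="nearest",
    )
    up_mri = Volume3D(up_img, new_spacing)

    if isinstance(labels, BinaryMask3D):
        up = _zoom_binary(labels.data, factors) >= 0.5
        return up_mri, BinaryMask3D(up.astype(np.uint8), new_spacing)

    if not isinstance(labels, InstanceMap3D):
        raise TypeError(f"labels must be InstanceMap3D or BinaryMask3D, got {type(labels)}")

    best_val = np.zeros(new_shape, dtype=np.float32)
    best_lab = np.zeros(new_shape, dtype=labels.data.dtype)
    for lab in labels.labels():
        val = _zoom_binary(labels.data == lab, factors)
        hit = val >= 0.5
        # larger interpolated value wins; ties -> smaller label (earlier wins
        # only if strictly greater because labels iterate in ascending order)
        win = hit & (val > best_val)
        best_val[win] = val[win]
        best_lab[win] = lab
    return up_mri, InstanceMap3D(best_lab, new_spacing)


def downsample_labels(labels: InstanceMap3D, original_shape) -> InstanceMap3D:
    """Bring a working-grid label map back to the original grid.

    Nearest-neighbour: samples one voxel per (fx, fy, fz) block at the block
    centre, which for labels produced by :func:`upsample_exam` inverts the
    up-sampling exactly.  ``labels.shape`` must be an integer multiple of
    ``original_shape`` per axis.
    """
    original_shape = tuple(int(s) for s in original_shape)
    if len(original_shape) != 3:
        raise ValueError("original_shape must have 3 components")
    factors = []
    for big, small in zip(labels.shape, original_shape):
        if small <= 0 or big % small:
            raise ValueError(
                f"shape {labels.shape} is not an integer multiple of {original_shape}"
            )
        factors.append(big // small)
    fx, fy, fz = factors
    ox, oy, oz = ((f - 1) // 2 for f in factors)
    down = labels.data[ox::fx, oy::fy, oz::fz]
    new_spacing = tuple(s * f for s, f in zip(labels.spacing, factors))
    return InstanceMap3D(np.ascontiguousarray(down), new_spacing)
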
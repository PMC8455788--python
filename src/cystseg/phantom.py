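"""Seeded synthetic cystic-kidney phantoms.

Emulates anisotropic coronal T2-weighted exams of polycystic kidneys: two
ellipsoidal kidneys filled with clustered, touching spherical cysts of mixed
hyper/hypo intensity, an optional bright renal-pelvis-like confounder, and
additive Gaussian noise.  The phantom stands in for clinical exams when
exercising the encode/decode pipeline at desk scale.

Sphere digitization uses physical (mm) coordinates: a voxel belongs to a cyst
iff its *center* lies inside the sphere, so thick slices produce the flattened
few-plane cysts that make the z-axis the hard direction, as in real coronal
MR.  Overlapping placements are truncated, never merged — cysts are distinct
objects that abut, and ground-truth labels partition the cyst foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_volumes import BinaryMask3D, InstanceMap3D, Volume3D

__all__ = ["PhantomSpec", "generate_phantom", "phantom_cyst_table"]

_CROSS3D = ndimage.generate_binary_structure(3, 1)

# Tissue intensity levels on the arbitrary [0, 1] T2-like scale.
_BG, _PARENCHYMA, _HYPER, _HYPO, _PELVIS = 0.05, 0.45, 0.95, 0.12, 0.90


@dataclass
class PhantomSpec:
    """Parameters of one synthetic exam.

    Defaults mirror a typical mid-severity coronal T2 exam at desk scale:
    1.41 mm in-plane / 4.0 mm slices (the median acquisition of the cohort
    the pipeline targets), a few dozen cysts with log-normal radii of median
    4 mm, half of them placed adjacent to an existing cyst so that decoding
    has touching instances to separate, and ~10% hypointense "complicated"
    cysts.
    """

    shape: tuple[int, int, int] = (96, 96, 24)
    spacing: tuple[float, float, float] = (1.41, 1.41, 4.0)
    n_cysts: int = 30
    radius_median_mm: float = 4.0
    radius_sigma: float = 0.35
    cluster_fraction: float = 0.5
    hypointense_fraction: float = 0.1
    noise_sigma: float = 0.03
    pelvis: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.shape) != 3 or any(
            s < m for s, m in zip(self.shape, (16, 16, 4))
        ):
            raise ValueError(f"shape must be >= (16,16,4), got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.n_cysts < 0:
            raise ValueError("n_cysts must be >= 0")
        for name in ("cluster_fraction", "hypointense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.radius_median_mm <= 0 or self.radius_sigma < 0:
            raise ValueError("radius law parameters must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _ellipsoid(coords_mm, center_mm, semi_mm) -> np.ndarray:
    d = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords_mm, center_mm, semi_mm))
    return d <= 1.0


def _sphere(coords_mm, center_mm, r_mm) -> np.ndarray:
    d2 = sum((c - c0) ** 2 for c, c0 in zip(coords_mm, center_mm))
    return d2 <= r_mm**2


def generate_phantom(spec: PhantomSpec):
    """Generate one seeded exam: (MR-like volume, kidney mask, truth labels).

    Cysts are labelled 1..K in placement order; later placements yield to
    earlier ones voxel-wise, so labels never overlap but may touch
    (6-adjacent).  Placements that fail a bounded number of rejection
    attempts are skipped, hence K <= ``spec.n_cysts``.
    """
    if not isinstance(spec, PhantomSpec):
        spec = PhantomSpec(**spec)  # type: ignore[arg-type]
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.shape
    dx, dy, dz = spec.spacing
    fov = (X * dx, Y * dy, Z * dz)
    ax = np.arange(X) * dx
    ay = np.arange(Y) * dy
    az = np.arange(Z) * dz
    coords = np.meshgrid(ax, ay, az, indexing="ij")

    # Two kidneys, long axis in-plane along y, placed left/right of midline.
    kidney = np.zeros(spec.shape, dtype=bool)
    kidney_centers = []
    for cx_frac in (0.28, 0.72):
        center = (cx_frac * fov[0], 0.5 * fov[1], 0.5 * fov[2])
        semi = (0.17 * fov[0], 0.34 * fov[1], 0.40 * fov[2])
        kidney |= _ellipsoid(coords, center, semi)
        kidney_centers.append((center, semi))

    # Pelvis confounder: a small bright ellipsoid at the medial pole of each
    # kidney; cysts are simply painted over it, so it never carries a label.
    pelvis = np.zeros(spec.shape, dtype=bool)
    if spec.pelvis:
        for (center, semi), sign in zip(kidney_centers, (+1, -1)):
            pc = (center[0] + sign * 0.55 * semi[0], center[1], center[2])
            pelvis |= _ellipsoid(coords, pc, (0.30 * semi[0], 0.22 * semi[1], 0.30 * semi[2]))
        pelvis &= kidney

    truth = np.zeros(spec.shape, dtype=np.int32)
    placed: list[tuple[np.ndarray, float]] = []  # (center_mm, radius_mm)
    hypo_flags: list[bool] = []
    next_label = 0
    kidney_idx = np.argwhere(kidney)
    max_attempts = 60
    for _ in range(spec.n_cysts):
        r = spec.radius_median_mm * float(np.exp(rng.normal(0.0, spec.radius_sigma)))
        r = min(max(r, 0.6 * min(dx, dy)), 0.25 * min(fov))
        clustered = bool(placed) and rng.random() < spec.cluster_fraction
        new_vox = None
        for _attempt in range(max_attempts):
            if clustered:
                c0, r0 = placed[rng.integers(len(placed))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                # abut with a slight overlap: distinct cysts press flat
                # against each other rather than interpenetrating deeply
                dist = (r0 + r) * rng.uniform(0.85, 1.0)
                center = c0 + direction * dist
            else:
                iv = kidney_idx[rng.integers(len(kidney_idx))]
                center = iv * np.array(spec.spacing)
            cand = _sphere(coords, center, r)
            if not cand.any() or not cand[kidney].sum() == cand.sum():
                continue  # sticks out of the kidney
            free = cand & (truth == 0)
            # a distinct abutting cyst keeps most of its sphere; deeper cuts
            # would be interpenetration, not a flattened contact face
            if free.sum() < 0.7 * cand.sum():
                continue
            # Keep the largest 6-connected chunk so every label is connected.
            lab, n = ndimage.label(free, structure=_CROSS3D)
            if n > 1:
                sizes = np.bincount(lab.ravel())[1:]
                free = lab == (int(np.argmax(sizes)) + 1)
            new_vox = free
            break
        if new_vox is None:
            continue
        next_label += 1
        truth[new_vox] = next_label
        placed.append((np.asarray(center, dtype=float), r))
        hypo_flags.append(rng.random() < spec.hypointense_fraction)

    # Intensities: background, parenchyma, cysts, pelvis, then noise.
    img = np.full(spec.shape, _BG, dtype=np.float32)
    img[kidney] = _PARENCHYMA
    img[pelvis & (truth == 0)] = _PELVIS
    for lab_id, hypo in enumerate(hypo_flags, start=1):
        img[truth == lab_id] = _HYPO if hypo else _HYPER
    img += rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)

    vol = Volume3D(img, spec.spacing)
    mask = BinaryMask3D(kidney.astype(np.uint8), spec.spacing)
    labels = InstanceMap3D(truth, spec.spacing)
    return vol, mask, labels


def phantom_cyst_table(truth: InstanceMap3D) -> pd.DataFrame:
    """Per-label voxel counts and volumes (mL) of an instance map.

    Returns a DataFrame with columns ``label``, ``voxels``, ``volume_ml``
    (volume = voxel count x voxel volume), one row per positive label.
    """
    labs = truth.labels()
    if labs.size == 0:
        return pd.DataFrame(columns=["label", "voxels", "volume_ml"]).astype(
            {"label": int, "voxels": int, "volume_ml": float}
        )
    counts = np.bincount(truth.data.ravel())
    vox = counts[labs]
    return pd.DataFrame(
        {
            "label": labs.astype(int),
            "voxels": vox.astype(int),
            "volume_ml": vox * truth.voxel_volume_ml,
        }
    )
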
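"""Voxel-wise similarity metrics and cyst biomarkers.

Instance maps are binarized (label > 0) for voxel-wise comparison; the
biomarkers are total cyst volume (TCV, mL), cyst count, and the cystic index
(TCV as a percentage of total kidney volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_volumes import BinaryMask3D, InstanceMap3D

__all__ = ["SimilarityReport", "CystStats", "similarity", "cyst_stats", "total_cyst_volume"]


@dataclass(frozen=True)
class SimilarityReport:
    """Overlap metrics between a predicted and a reference mask.

    dice, jaccard, precision, recall are in [0, 1]; ``arvc`` is the absolute
    relative volume change |V_p - V_r| / V_r (reference denominator).
    """

    dice: float
    jaccard: float
    precision: float
    recall: float
    arvc: float


@dataclass(frozen=True)
class CystStats:
    """Cyst biomarkers of one exam: TCV (mL), count, cystic index (% of
    TKV), and the per-cyst volume table (label -> voxels, mL)."""

    tcv_ml: float
    cyst_count: int
    cystic_index: float
    per_cyst: pd.DataFrame


def total_cyst_volume(labels: InstanceMap3D) -> float:
    """TCV in mL: number of cyst-labelled voxels times the voxel volume."""
    return float((labels.data > 0).sum()) * labels.voxel_volume_ml


def similarity(pred: InstanceMap3D, ref: InstanceMap3D) -> SimilarityReport:
    """Binarized voxel-wise comparison of two instance maps.

    An empty-vs-empty pair scores all overlap metrics 1 and ARVC 0, so that
    cyst-free exams do not produce undefined values.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")
    p = pred.data > 0
    r = ref.data > 0
    np_, nr = int(p.sum()), int(r.sum())
    if np_ == 0 and nr == 0:
        return SimilarityReport(1.0, 1.0, 1.0, 1.0, 0.0)
    inter = int((p & r).sum())
    union = np_ + nr - inter
    vp = np_ * pred.voxel_volume_ml
    vr = nr * ref.voxel_volume_ml
    return SimilarityReport(
        dice=2 * inter / (np_ + nr),
        jaccard=inter / union if union else 1.0,
        precision=inter / np_ if np_ else 1.0,
        recall=inter / nr if nr else 1.0,
        arvc=abs(vp - vr) / vr if vr else np.inf,
    )


def cyst_stats(labels: InstanceMap3D, kidney: BinaryMask3D) -> CystStats:
    """TCV, cyst count and cystic index of one exam.

    Cystic index = 100 x TCV / TKV with TKV computed from the kidney mask
    the same way.  An empty kidney mask with a non-empty label map raises
    (the index is undefined); with both empty all stats are zero.
    """
    if labels.shape != kidney.shape:
        raise ValueError(f"grid mismatch: {labels.shape} vs {kidney.shape}")
    voxvol = labels.voxel_volume_ml
    labs = labels.labels()
    counts = np.bincount(labels.data.ravel()) if labs.size else np.zeros(1, int)
    per = pd.DataFrame(
        {
            "label": labs.astype(int),
            "voxels": counts[labs].astype(int) if labs.size else [],
            "volume_ml": (counts[labs] * voxvol) if labs.size else [],
        }
    )
    tcv = float(per["volume_ml"].sum()) if labs.size else 0.0
    tkv = float((kidney.data > 0).sum()) * kidney.voxel_volume_ml
    if tkv == 0:
        if tcv > 0:
            raise ValueError("cystic index undefined: empty kidney mask with cysts")
        index = 0.0
    else:
        index = 100.0 * tcv / tkv
    return CystStats(
        tcv_ml=tcv, cyst_count=int(labs.size), cystic_index=index, per_cyst=per
    )
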
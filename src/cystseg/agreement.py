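"""Bland-Altman and linear-regression agreement between measurement series.

Used to compare TCV, cystic index and cyst count between two readers or a
reader and the automated pipeline.  Percent differences are taken relative
to the pair mean, d_i = 100 (a_i - b_i) / ((a_i + b_i)/2): bias is their
mean, precision their sample (n-1) standard deviation — the convention that
reproduces the published reader-agreement worked examples exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementReport", "bland_altman", "linreg_r2", "agreement_report"]


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman bias/precision (%) plus OLS regression of b on a."""

    bias: float
    precision: float
    r2: float
    slope: float
    intercept: float


def _series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def bland_altman(a, b) -> tuple[float, float]:
    """Return (bias %, precision %) of two positive paired series.

    bias = mean of the pair-mean-relative percent differences, precision =
    their sample standard deviation (n-1 denominator).  Antisymmetric in its
    arguments: swapping a and b flips the sign of the bias and leaves the
    precision unchanged.
    """
    av = _series(a, "a")
    bv = _series(b, "b")
    if av.size != bv.size:
        raise ValueError(f"length mismatch: {av.size} vs {bv.size}")
    if (av <= 0).any() or (bv <= 0).any():
        raise ValueError("Bland-Altman on relative differences needs positive values")
    d = 100.0 * (av - bv) / ((av + bv) / 2.0)
    return float(d.mean()), float(d.std(ddof=1))


def linreg_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (r2, slope, intercept).

    r2 is the squared Pearson correlation, hence symmetric under swapping
    the series and blind to the sign of the association.
    """
    xv = _series(x, "x")
    yv = _series(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(xv, yv)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def agreement_report(a, b) -> AgreementReport:
    """Full agreement summary of series b against series a."""
    bias, precision = bland_altman(a, b)
    r2, slope, intercept = linreg_r2(a, b)
    return AgreementReport(bias=bias, precision=precision, r2=r2, slope=slope, intercept=intercept)
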
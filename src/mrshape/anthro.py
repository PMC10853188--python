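"""Allometric body-shape indices and rank-based inverse-normal transforms.

Traditional body-shape measures (waist, hip, waist-to-hip ratio) are
strongly correlated with BMI and therefore conflate body shape with
general obesity.  Allometric indices remove that correlation by scaling
the raw measure ``Z`` with powers of weight and height::

    index = Z * weight^p_weight * height^p_height

where ``Z`` is the waist-to-hip ratio (waist-to-hip index, WHI), waist
circumference ("a body shape index", ABSI) or hip circumference (hip
index, HI).  The exponents are calibrated on a reference cohort so that
the resulting index is uncorrelated with weight and height — here by
ordinary least squares of ``log Z`` on ``log weight`` and ``log
height``, whose negated coefficients deliver exact in-sample
orthogonality.

GWAS of such indices are run on the rank-based inverse-normal (Blom)
transform, mapping the value of rank ``r`` (average ranks for ties) to
the standard-normal quantile of ``(r - 3/8) / (n + 1/4)``, so effect
sizes are in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import CalibrationError, DomainError

__all__ = [
    "AnthroRecord",
    "AllometricCoeffs",
    "INDEX_KINDS",
    "allometric_index",
    "calibrate_coeffs",
    "blom_transform",
]

INDEX_KINDS = ("WHI", "ABSI", "HI")


@dataclass
class AnthroRecord:
    """One individual's anthropometry: weight (kg), height (m), waist/hip (cm)."""

    weight: float
    height: float
    waist: float
    hip: float

    def validate(self) -> None:
        for name in ("weight", "height", "waist", "hip"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass
class AllometricCoeffs:
    """Exponents applied to weight and height for one index kind."""

    p_weight: float
    p_height: float
    index_kind: str

    def __post_init__(self) -> None:
        if self.index_kind not in INDEX_KINDS:
            raise ValueError(f"index_kind must be one of {INDEX_KINDS}")
        if not (np.isfinite(self.p_weight) and np.isfinite(self.p_height)):
            raise ValueError("exponents must be finite")


def _base_measure(rec: AnthroRecord, index_kind: str) -> float:
    if index_kind == "WHI":
        return rec.waist / rec.hip
    if index_kind == "ABSI":
        return rec.waist
    return rec.hip  # HI


def allometric_index(rec: AnthroRecord, coeffs: AllometricCoeffs) -> float:
    """``Z * weight^p_weight * height^p_height`` for the configured index kind."""
    rec.validate()
    z = _base_measure(rec, coeffs.index_kind)
    return z * rec.weight**coeffs.p_weight * rec.height**coeffs.p_height


def calibrate_coeffs(
    cohort: Sequence[AnthroRecord], index_kind: str
) -> AllometricCoeffs:
    """Fit index exponents on a reference cohort.

    Ordinary least squares of ``log Z`` on ``log weight`` and ``log
    height`` (with intercept); the negated fitted coefficients make the
    resulting index exactly uncorrelated with both regressors in-sample.
    """
    if len(cohort) < 100:
        raise CalibrationError("calibration requires a cohort of at least 100")
    for rec in cohort:
        rec.validate()
    log_w = np.log([r.weight for r in cohort])
    log_h = np.log([r.height for r in cohort])
    log_z = np.log([_base_measure(r, index_kind) for r in cohort])
    if np.ptp(log_w) == 0 or np.ptp(log_h) == 0:
        raise CalibrationError("degenerate design: constant weight or height")
    design = np.column_stack([np.ones(len(cohort)), log_w, log_h])
    coef, *_ = np.linalg.lstsq(design, log_z, rcond=None)
    return AllometricCoeffs(p_weight=-float(coef[1]), p_height=-float(coef[2]), index_kind=index_kind)


def blom_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offsets) preserving order.

    Value of rank ``r`` (1-based, average ranks for ties) maps to
    ``Phi^-1((r - 3/8) / (n + 1/4))``.  Requires at least two distinct
    values; ties map to equal outputs.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DomainError("blom_transform requires a 1-D sample of size >= 2")
    if np.ptp(arr) == 0:
        raise DomainError("blom_transform undefined for an all-equal sample")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.375) / (arr.size + 0.25))
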
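"""Causal estimators and diagnostics for two-sample MR.

All estimators consume harmonized pairs (exposure effect ``beta_x`` and
outcome effect ``beta_y`` on a shared allele) and report the causal
effect ``theta`` on the scale *SD of outcome per SD of exposure*.

Implemented methods
-------------------
Wald ratio
    Per-SNP estimate ``beta_y / beta_x`` with the first-order delta
    standard error ``se_y / |beta_x|``.
IVW (fixed / multiplicative random effects)
    Inverse-variance-weighted mean of the Wald ratios; algebraically
    identical to weighted least squares of ``beta_y`` on ``beta_x``
    through the origin with weights ``1/se_y^2``.  The random-effects
    variant scales the fixed-effect SE by ``sqrt(Q/(J-1))``, floored at
    1, so fixed and random estimates coincide exactly whenever there is
    no excess heterogeneity.  Cochran's Q, its chi-square p-value and
    the I^2 inconsistency fraction are reported as diagnostics.
Weighted median
    Consistent when instruments carrying at least half of the weight
    are valid; the estimate interpolates the weighted empirical
    distribution of the ratio estimates at probability 0.5 and its SE
    comes from a seeded parametric bootstrap.
MR-Egger
    Weighted regression of ``beta_y`` on ``beta_x`` with a free
    intercept, after orienting every pair so ``beta_x >= 0``.  The
    slope estimates the causal effect under the InSIDE assumption; the
    intercept estimates average directional pleiotropy.  Standard
    errors use a multiplicative residual dispersion floored at 1 and
    inference is on t with J - 2 degrees of freedom.
I^2_GX
    Heterogeneity of the (oriented) exposure effects relative to their
    standard errors; values below 0.9 signal a violation of the NOME
    assumption underlying MR-Egger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedPair

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
    "i2_gx",
    "violates_nome",
    "NOME_I2_GX_THRESHOLD",
]

_Z975 = float(stats.norm.ppf(0.975))

#: I^2_GX below this level indicates a NOME violation.
NOME_I2_GX_THRESHOLD = 0.90


@dataclass
class MREstimate:
    """A causal-effect estimate from one method, with 95% CI and diagnostics."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be > 0")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def _normal_estimate(method: str, theta: float, se: float, n_snps: int, **diagnostics) -> MREstimate:
    z = theta / se
    return MREstimate(
        method=method,
        theta=theta,
        se=se,
        ci_low=theta - _Z975 * se,
        ci_high=theta + _Z975 * se,
        pvalue=float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)),
        n_snps=n_snps,
        diagnostics=dict(diagnostics),
    )


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Per-SNP causal estimate: outcome effect divided by exposure effect."""
    if pair.beta_x == 0:
        raise DomainError(f"{pair.rsid}: Wald ratio undefined for beta_x = 0")
    theta = pair.beta_y / pair.beta_x
    se = pair.se_y / abs(pair.beta_x)
    return _normal_estimate("wald", theta, se, n_snps=1, rsid=pair.rsid)


def _ratio_arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    beta_x = np.array([p.beta_x for p in pairs])
    if np.any(beta_x == 0):
        bad = [p.rsid for p in pairs if p.beta_x == 0]
        raise DomainError(f"Wald ratio undefined for beta_x = 0: {bad}")
    theta = np.array([p.beta_y for p in pairs]) / beta_x
    se = np.array([p.se_y for p in pairs]) / np.abs(beta_x)
    return theta, se


def ivw(
    pairs: Sequence[HarmonizedPair],
    mode: str = "random",
    *,
    strict: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted combination of the per-SNP Wald ratios.

    ``mode="fixed"`` assumes one common effect; ``mode="random"`` is the
    multiplicative random-effects model whose SE inflation
    ``sqrt(Q/(J-1))`` is floored at 1.  With a single pair the estimate
    degrades to the Wald ratio (with a warning, or an error when
    ``strict``).
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    J = len(pairs)
    if J == 0:
        raise InsufficientInstrumentsError("IVW requires at least one pair")
    if J == 1:
        if strict:
            raise InsufficientInstrumentsError("IVW requires >= 2 pairs in strict mode")
        warnings.warn("IVW with a single SNP degrades to the Wald ratio", stacklevel=2)
        single = wald_ratio(pairs[0])
        return _normal_estimate(
            f"ivw_{mode}", single.theta, single.se, n_snps=1,
            Q=0.0, p_heterogeneity=1.0, i2=0.0, dispersion=1.0,
        )
    theta_j, se_j = _ratio_arrays(pairs)
    w = 1.0 / se_j**2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta_j - theta) ** 2))
    p_het = float(stats.chi2.sf(q, J - 1))
    i2 = max(0.0, (q - (J - 1)) / q) if q > 0 else 0.0
    dispersion = max(1.0, np.sqrt(q / (J - 1)))
    se = se_fixed * dispersion if mode == "random" else se_fixed
    return _normal_estimate(
        f"ivw_{mode}", theta, se, n_snps=J,
        Q=q, p_heterogeneity=p_het, i2=i2,
        dispersion=dispersion if mode == "random" else 1.0,
    )


def _weighted_median_point(theta_j: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    With sorted estimates and normalised weights ``w'``, each estimate
    sits at cumulative midpoint rank ``p_j = S_j - w'_j/2``; the median
    interpolates linearly between the estimates bracketing p = 0.5.
    """
    order = np.argsort(theta_j, kind="stable")
    th = theta_j[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w)
    p = s - w / 2.0
    if p[0] >= 0.5:
        return float(th[0])
    if p[-1] <= 0.5:
        return float(th[-1])
    hi = int(np.searchsorted(p, 0.5))
    lo = hi - 1
    frac = (0.5 - p[lo]) / (p[hi] - p[lo])
    return float(th[lo] + frac * (th[hi] - th[lo]))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    ``seed`` is mandatory: the bootstrap resamples ``beta_x`` and
    ``beta_y`` from normals centred on the observed values with their
    standard errors, recomputes the weighted median ``n_boot`` times and
    reports the standard deviation of the replicates.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 pairs")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    theta_j, se_j = _ratio_arrays(pairs)
    w = 1.0 / se_j**2
    theta = _weighted_median_point(theta_j, w)

    rng = np.random.default_rng(seed)
    bx = np.array([p.beta_x for p in pairs])
    by = np.array([p.beta_y for p in pairs])
    sx = np.array([p.se_x for p in pairs])
    sy = np.array([p.se_y for p in pairs])
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        th_b = by_b / bx_b
        w_b = (np.abs(bx_b) / sy) ** 2
        boot[b] = _weighted_median_point(th_b, w_b)
    se = float(np.std(boot, ddof=1))
    return _normal_estimate("weighted_median", theta, se, n_snps=len(pairs), n_boot=n_boot)


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns ``(slope, intercept)`` estimates.

    Pairs are first oriented so every exposure effect is non-negative
    (flipping both betas where needed), then ``beta_y`` is regressed on
    ``beta_x`` with weights ``1/se_y^2`` and a free intercept.
    """
    J = len(pairs)
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 pairs")
    bx = np.array([p.beta_x for p in pairs])
    by = np.array([p.beta_y for p in pairs])
    sy = np.array([p.se_y for p in pairs])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip

    w = 1.0 / sy**2
    x = np.column_stack([np.ones(J), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    rss = float(np.sum(w * resid**2))
    dispersion = max(1.0, rss / (J - 2))
    cov = dispersion * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    tq = float(stats.t.ppf(0.975, J - 2))

    def _estimate(method: str, value: float, stderr: float) -> MREstimate:
        tstat = value / stderr
        return MREstimate(
            method=method,
            theta=float(value),
            se=float(stderr),
            ci_low=float(value - tq * stderr),
            ci_high=float(value + tq * stderr),
            pvalue=float(max(2.0 * stats.t.sf(abs(tstat), J - 2), np.finfo(float).tiny)),
            n_snps=J,
            diagnostics={"dispersion": dispersion, "df": J - 2},
        )

    slope = _estimate("egger_slope", coef[1], se[1])
    intercept = _estimate("egger_intercept", coef[0], se[0])
    return slope, intercept


def i2_gx(pairs: Sequence[HarmonizedPair]) -> float:
    """Heterogeneity of the oriented exposure effects: the NOME diagnostic.

    ``Q_GX = sum((|beta_x| - mean)^2 / se_x^2)`` with the
    inverse-variance-weighted mean of ``|beta_x|``;
    ``I^2_GX = max(0, (Q_GX - (J-1)) / Q_GX)``.
    """
    J = len(pairs)
    if J < 2:
        raise InsufficientInstrumentsError("I^2_GX requires >= 2 pairs")
    bx = np.abs(np.array([p.beta_x for p in pairs]))
    sx = np.array([p.se_x for p in pairs])
    w = 1.0 / sx**2
    mean = np.sum(w * bx) / np.sum(w)
    q = float(np.sum(w * (bx - mean) ** 2))
    if q <= 0:
        return 0.0
    return max(0.0, (q - (J - 1)) / q)


def violates_nome(i2_gx_value: float, threshold: float = NOME_I2_GX_THRESHOLD) -> bool:
    """True when I^2_GX falls below the NOME reliability threshold."""
    return i2_gx_value < threshold
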
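"""MR-PRESSO: residual-sum-of-squares outlier diagnostics for IVW panels.

Three simulation-based tests on a panel of harmonized pairs:

* **Global test** — the observed weighted residual sum of squares
  (RSS), built from leave-one-out IVW slopes, is compared against its
  parametric-bootstrap distribution; a small empirical p indicates
  pleiotropy-driven heterogeneity somewhere in the panel.
* **Outlier (local) test** — each SNP's own weighted squared residual
  is compared against its simulated distribution, Bonferroni-adjusted
  over the panel.
* **Distortion test** — when outliers are found, the causal estimate
  recomputed without them is compared with the original estimate via a
  bootstrap over the non-outlier SNPs; a small p means removing the
  outliers materially shifts the estimate.

The residuals are weighted by ``1/se_y^2`` throughout and the causal
slope is the fixed-effect IVW estimate, so the machinery is consistent
with the estimator it diagnoses.  Empirical p-values use the ``+1``
correction, hence the smallest attainable p is ``1/(n_sim + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedPair
from .mr_core import MREstimate, ivw

__all__ = ["PressoResult", "run_presso"]


@dataclass
class PressoResult:
    """Outcome of the global, outlier and distortion tests."""

    rss_observed: float
    global_p: float
    outlier_pvalues: dict[str, float]
    outlier_pvalues_adjusted: dict[str, float]
    outliers: set[str]
    theta_raw: MREstimate
    theta_corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted-through-origin slopes, vectorised.

    Supports 1-D arrays (one panel) and 2-D arrays (n_sim x J panels).
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def run_presso(
    pairs: list[HarmonizedPair],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
    *,
    n_boot_distortion: int = 1000,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized panel.

    Requires at least four pairs (each leave-one-out slope needs three).
    ``seed`` is mandatory; identical seeds give bit-identical results.
    ``outlier_alpha`` is applied to the Bonferroni-adjusted per-SNP
    p-values.
    """
    J = len(pairs)
    if J < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >= 4 pairs")
    if seed is None:
        raise ValueError("run_presso requires an explicit seed")
    if n_sim < 100:
        warnings.warn(
            f"n_sim = {n_sim} gives unstable empirical p-values", stacklevel=2
        )

    bx = np.array([p.beta_x for p in pairs])
    by = np.array([p.beta_y for p in pairs])
    sx = np.array([p.se_x for p in pairs])
    sy = np.array([p.se_y for p in pairs])
    rsids = [p.rsid for p in pairs]
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    resid = by - theta_loo * bx
    resid_sq_w = w * resid**2
    rss_obs = float(np.sum(resid_sq_w))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    theta_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = by_sim - theta_loo_sim * bx_sim
    resid_sq_w_sim = w * resid_sim**2
    rss_sim = np.sum(resid_sq_w_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(resid_sq_w_sim >= resid_sq_w, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * J)
    outliers = {rsids[j] for j in range(J) if p_adj[j] < outlier_alpha}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theta_raw = ivw(pairs, mode="fixed")

    theta_corrected: MREstimate | None = None
    distortion_p: float | None = None
    keep_idx = [j for j in range(J) if rsids[j] not in outliers]
    if outliers and len(keep_idx) >= 2:
        kept_pairs = [pairs[j] for j in keep_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta_corrected = ivw(kept_pairs, mode="fixed")
        d_obs = theta_corrected.theta - theta_raw.theta
        kb = np.asarray(keep_idx)
        idx_b = rng.choice(kb, size=(n_boot_distortion, len(kb)), replace=True)
        bx_b = bx[idx_b]
        by_b = by[idx_b]
        w_b = w[idx_b]
        theta_b = np.sum(w_b * bx_b * by_b, axis=1) / np.sum(w_b * bx_b**2, axis=1)
        exceed = np.sum(np.abs(theta_b - theta_raw.theta) >= abs(d_obs))
        distortion_p = float((1 + exceed) / (n_boot_distortion + 1))

    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        outlier_pvalues={rsids[j]: float(p_raw[j]) for j in range(J)},
        outlier_pvalues_adjusted={rsids[j]: float(p_adj[j]) for j in range(J)},
        outliers=outliers,
        theta_raw=theta_raw,
        theta_corrected=theta_corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )
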
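"""Pleiotropy and heterogeneity diagnostics for MR instrument panels.

A valid instrument affects the outcome only through the exposure, so under
no pleiotropy the per-SNP Wald ratios differ only by sampling noise.  This
module quantifies departures from that expectation:

* Cochran's Q and I2_MR over the ratio estimates (excess heterogeneity
  flags potential pleiotropy);
* Rucker's Q' (heterogeneity left after the MR-Egger fit) and the
  Q - Q' ~ chi2(1) test of whether the Egger model fits better than IVW;
* I2_GX, heterogeneity of the SNP-exposure effects themselves, which
  gauges regression-dilution bias in MR-Egger (NOME violation);
* MR-PRESSO: a simulation-based global test on the residual sum of
  squares of the zero-intercept fit, a per-SNP outlier test, an
  outlier-corrected IVW estimate and a distortion test;
* funnel- and radial-plot data tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr_core import (
    DEFAULT_SE_ORDER,
    MrEstimate,
    RatioEstimate,
    _beta_space_weights,
    _oriented_arrays,
    egger,
    ivw_fixed,
    wald_ratios,
)
from .summary_io import HarmonizedInstrument, InstrumentSet

__all__ = [
    "HeterogeneityResult",
    "EggerModelSelection",
    "IGXResult",
    "PressoResult",
    "cochran_q",
    "rucker_model_selection",
    "i2_gx",
    "mr_presso",
    "funnel_data",
    "radial_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q heterogeneity of per-SNP ratio estimates."""

    q: float
    df: int
    pval: float
    i2_mr: float

    @property
    def flag_pleiotropy(self) -> bool:
        """Excess heterogeneity: I2_MR > 25% together with Q-test p < 0.05."""
        return self.i2_mr > 25.0 and self.pval < 0.05


@dataclass(frozen=True)
class EggerModelSelection:
    """Rucker framework: does MR-Egger fit better than IVW?"""

    q: float
    q_prime: float
    df_prime: int
    p_q_prime: float
    q_minus_qprime: float
    p_model_test: float

    @property
    def egger_preferred(self) -> bool:
        return self.p_model_test < 0.05


@dataclass(frozen=True)
class IGXResult:
    """Heterogeneity of the SNP-exposure effects (NOME diagnostic)."""

    q_gx: float
    i2_gx: float

    @property
    def low_bias_flag(self) -> bool:
        """I2_GX > 95% indicates low regression-dilution bias in MR-Egger."""
        return self.i2_gx > 95.0


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_obs: float
    global_pval: float
    outlier_pvals: dict
    outliers: tuple
    estimate_raw: MrEstimate
    estimate_corrected: MrEstimate | None
    distortion_pval: float | None
    n_sim: int
    seed: int


def _i2_from_q(q: float, df: int) -> float:
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def cochran_q(ratios: Sequence[RatioEstimate], pooled_beta: float) -> HeterogeneityResult:
    """Q = sum w_j (theta_j - pooled)^2 against chi2 with J - 1 df."""
    if len(ratios) < 2:
        raise ValueError("cochran_q needs at least 2 ratios")
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    q = float(np.sum(w * (theta - pooled_beta) ** 2))
    df = len(ratios) - 1
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, pval=pval, i2_mr=_i2_from_q(q, df))


def rucker_model_selection(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    se_order: str = DEFAULT_SE_ORDER,
) -> EggerModelSelection:
    """Compare IVW (zero-intercept) and Egger fits on weighted residuals.

    Both residual sums use the same beta-space weights; Q' can therefore
    never exceed Q, and Q - Q' is referred to chi2 with 1 df to test
    whether freeing the intercept improves fit significantly.
    """
    insts = list(instruments)
    if len(insts) < 3:
        raise ValueError("rucker_model_selection needs at least 3 instruments")
    ratios = wald_ratios(insts, se_order)
    ivw = ivw_fixed(ratios)
    q = cochran_q(ratios, ivw.beta).q
    eg = egger(insts, se_order)
    q_prime = eg.extras["q_prime"]
    df_prime = len(insts) - 2
    diff = max(0.0, q - q_prime)
    return EggerModelSelection(
        q=q,
        q_prime=q_prime,
        df_prime=df_prime,
        p_q_prime=float(stats.chi2.sf(q_prime, df_prime)),
        q_minus_qprime=diff,
        p_model_test=float(stats.chi2.sf(diff, 1)),
    )


def i2_gx(instruments: InstrumentSet | Sequence[HarmonizedInstrument]) -> IGXResult:
    """I2 heterogeneity of the oriented SNP-exposure effects.

    Computed on beta_x flipped positive (the orientation used by the Egger
    fit) with inverse-variance weights 1/se_x^2.
    """
    insts = list(instruments)
    if len(insts) < 2:
        raise ValueError("i2_gx needs at least 2 instruments")
    bx, sx, _, _ = _oriented_arrays(insts)
    w = sx**-2.0
    bbar = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum(w * (bx - bbar) ** 2))
    return IGXResult(q_gx=q_gx, i2_gx=_i2_from_q(q_gx, len(insts) - 1))


def _loo_ivw_slopes(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW ratio estimates, vectorized over the last axis."""
    sw = np.sum(w, axis=-1, keepdims=True)
    swt = np.sum(w * theta, axis=-1, keepdims=True)
    return (swt - w * theta) / (sw - w)


def _presso_rss(bx, sx, by, sy, se_order):
    """Per-SNP weighted residuals against the leave-one-out IVW fit."""
    theta = by / bx
    w_beta = _beta_space_weights(bx, sx, by, sy, se_order)
    w_ratio = w_beta * bx**2
    loo = _loo_ivw_slopes(theta, w_ratio)
    rss_j = w_beta * (by - loo * bx) ** 2
    return rss_j, loo


def mr_presso(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    se_order: str = DEFAULT_SE_ORDER,
) -> PressoResult:
    """MR-PRESSO pleiotropy residual sum and outlier test.

    The observed statistic is the weighted residual sum of squares of each
    SNP against the leave-one-out IVW slope.  Its null distribution is
    simulated by redrawing summary statistics from their sampling
    distributions under no pleiotropy: beta_x* ~ N(beta_x, se_x) and
    beta_y* ~ N(theta_loo * beta_x, se_y).  Empirical p-values use the
    add-one rule so they are never exactly zero.  Per-SNP outlier p-values
    are Bonferroni-multiplied by the panel size; when outliers are found
    the IVW estimate is recomputed without them and a distortion test
    compares the observed relative shift in the estimate with the shift
    from removing random subsets of the same size.
    """
    insts = list(instruments)
    J = len(insts)
    if J < 4:
        raise ValueError("mr_presso needs at least 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    rsids = [i.rsid for i in insts]
    bx, sx, by, sy = _oriented_arrays(insts)

    rss_j, loo = _presso_rss(bx, sx, by, sy, se_order)
    rss_obs = float(np.sum(rss_j))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, J))
    by_star = rng.normal(loo * bx, sy, size=(n_sim, J))
    rss_star_j, _ = _presso_rss(bx_star, sx, by_star, sy, se_order)
    rss_star = np.sum(rss_star_j, axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    tail = np.sum(rss_star_j >= rss_j[None, :], axis=0)
    p_raw = (1 + tail) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * J)
    outlier_pvals = dict(zip(rsids, p_adj.tolist()))
    outlier_mask = p_adj < outlier_alpha
    outliers = tuple(r for r, m in zip(rsids, outlier_mask) if m)
    if len(outliers) == J:
        raise ValueError("all SNPs flagged as outliers: fewer than 50% valid instruments assumption violated")

    ratios = wald_ratios(insts, se_order)
    estimate_raw = ivw_fixed(ratios, method_tag="presso_raw")

    estimate_corrected = None
    distortion_pval = None
    if outliers:
        kept = [r for r, m in zip(ratios, outlier_mask) if not m]
        estimate_corrected = ivw_fixed(kept, method_tag="presso_outlier_corrected")
        k = len(outliers)
        d_obs = (estimate_raw.beta - estimate_corrected.beta) / estimate_corrected.beta
        theta = np.array([r.theta for r in ratios])
        w = np.array([r.weight for r in ratios])
        swt, sw = np.sum(w * theta), np.sum(w)
        d_star = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(J, size=k, replace=False)
            beta_s = (swt - np.sum(w[drop] * theta[drop])) / (sw - np.sum(w[drop]))
            d_star[s] = (estimate_raw.beta - beta_s) / beta_s
        distortion_pval = float((1 + np.sum(np.abs(d_star) >= abs(d_obs))) / (n_sim + 1))

    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        estimate_raw=estimate_raw,
        estimate_corrected=estimate_corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def funnel_data(ratios: Sequence[RatioEstimate], pooled: MrEstimate) -> pd.DataFrame:
    """Funnel-plot table: per-SNP ratio against its precision.

    Asymmetry around the pooled line suggests directional pleiotropy.
    """
    if not ratios:
        raise ValueError("funnel_data needs at least one ratio")
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in ratios],
            "theta": [r.theta for r in ratios],
            "precision": [1.0 / r.se_theta for r in ratios],
        }
    )
    df.attrs["pooled_beta"] = pooled.beta
    df["pooled_beta"] = pooled.beta
    return df


def radial_data(ratios: Sequence[RatioEstimate]) -> pd.DataFrame:
    """Radial-plot table: (sqrt(w_j), theta_j * sqrt(w_j)).

    The through-origin slope of these points equals the IVW estimate.
    """
    if not ratios:
        raise ValueError("radial_data needs at least one ratio")
    sqrtw = np.array([math.sqrt(r.weight) for r in ratios])
    theta = np.array([r.theta for r in ratios])
    slope = float(np.sum(sqrtw * theta * sqrtw) / np.sum(sqrtw**2))
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in ratios],
            "sqrt_weight": sqrtw,
            "theta_sqrt_weight": theta * sqrtw,
        }
    )
    df["slope"] = slope
    return df
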
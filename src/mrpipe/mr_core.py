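"""Core Mendelian randomization estimators.

Given a panel of harmonized instruments with per-SNP exposure effects
``beta_x`` (SD units) and outcome effects ``beta_y`` (log odds ratio), the
per-SNP causal estimate is the Wald ratio ``theta_j = beta_y / beta_x`` with
a delta-method standard error.  With first-order weights the SE is
``se_y / |beta_x|``; the second-order expansion adds the exposure
uncertainty, ``sqrt(se_y^2 / beta_x^2 + beta_y^2 * se_x^2 / beta_x^4)``,
and is the default throughout.

Pooled estimators:

* ``ivw_fixed`` — fixed-effect inverse-variance weighted mean of the Wald
  ratios; consistent when every instrument is valid.
* ``egger`` — weighted linear regression of beta_y on beta_x with a free
  intercept; the slope is a causal estimate robust to directional
  pleiotropy under the InSIDE assumption, and the intercept estimates the
  average direct (pleiotropic) effect.
* ``weighted_median`` — median of the precision-weighted ratio
  distribution; consistent when valid instruments carry more than half the
  weight.  CIs come from a parametric bootstrap.
* ``weighted_mode`` — mode of a weighted kernel density of the ratios;
  consistent when the largest cluster of concordant ratios is valid
  (ZEMPA assumption).

All pooled results are returned as :class:`MrEstimate` rows carrying both
log-OR and OR scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_io import HarmonizedInstrument, InstrumentSet

__all__ = [
    "RatioEstimate",
    "MrEstimate",
    "InstrumentStrength",
    "f_statistic",
    "instrument_strength",
    "wald_ratio",
    "wald_ratios",
    "ivw_fixed",
    "egger",
    "weighted_median",
    "weighted_mode",
    "weighted_median_point",
    "weighted_mode_point",
    "mode_bandwidth",
    "DEFAULT_SE_ORDER",
    "DEFAULT_N_BOOT",
    "MODE_GRID_POINTS",
]

DEFAULT_SE_ORDER = "second"
DEFAULT_N_BOOT = 1000
MODE_GRID_POINTS = 512

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with delta-method SE and IVW weight."""

    rsid: str
    theta: float
    se_theta: float
    beta_x: float = math.nan  # oriented exposure effect, kept for regression-based methods
    se_x: float = math.nan
    beta_y: float = math.nan
    se_y: float = math.nan

    @property
    def weight(self) -> float:
        return self.se_theta**-2


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal estimate on the log-OR-per-SD scale.

    ``or_``, ``or_ci_low`` and ``or_ci_high`` are the exponentiated
    (odds-ratio) versions of ``beta`` and its confidence bounds.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def to_row(self) -> dict:
        row = {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or": self.or_,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "pval": self.pval,
        }
        row.update(self.extras)
        return row


@dataclass(frozen=True)
class InstrumentStrength:
    """Instrument-strength summary for one SNP."""

    rsid: str
    r2: float
    n: int
    f_stat: float

    @property
    def weak(self) -> bool:
        """True when F <= 10, the conventional weak-instrument flag."""
        return self.f_stat <= 10


def f_statistic(r2: float, n: float) -> float:
    """F = r2 * (n - 2) / (1 - r2), the single-instrument strength statistic.

    ``r2`` is the fraction of exposure variance explained by the SNP and
    ``n`` the exposure-GWAS sample size.  F > 10 is the conventional
    threshold for low risk of weak-instrument bias.
    """
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1 - r2)


def instrument_strength(rsid: str, r2: float, n: int) -> InstrumentStrength:
    return InstrumentStrength(rsid=rsid, r2=r2, n=n, f_stat=f_statistic(r2, n))


def wald_ratio(inst: HarmonizedInstrument, se_order: str = DEFAULT_SE_ORDER) -> RatioEstimate:
    """Per-SNP causal estimate beta_y / beta_x with a delta-method SE."""
    if inst.beta_x == 0:
        raise ZeroDivisionError(f"{inst.rsid}: beta_x is zero, Wald ratio undefined")
    theta = inst.beta_y / inst.beta_x
    se = _ratio_se(inst.beta_x, inst.se_x, inst.beta_y, inst.se_y, se_order)
    return RatioEstimate(
        rsid=inst.rsid,
        theta=theta,
        se_theta=se,
        beta_x=inst.beta_x,
        se_x=inst.se_x,
        beta_y=inst.beta_y,
        se_y=inst.se_y,
    )


def _ratio_se(bx, sx, by, sy, se_order: str):
    if se_order == "first":
        return abs(sy / bx)
    if se_order == "second":
        return math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    raise ValueError(f"unknown se_order {se_order!r}")


def wald_ratios(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    se_order: str = DEFAULT_SE_ORDER,
) -> list[RatioEstimate]:
    return [wald_ratio(i, se_order) for i in instruments]


def _theta_w(ratios: Sequence[RatioEstimate]):
    theta = np.array([r.theta for r in ratios], dtype=float)
    w = np.array([r.weight for r in ratios], dtype=float)
    return theta, w


def _normal_estimate(method, beta, se, n_snps, extras=None) -> MrEstimate:
    z = beta / se
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z975 * se),
        ci_high=float(beta + _Z975 * se),
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snps=n_snps,
        extras=extras or {},
    )


def ivw_fixed(ratios: Sequence[RatioEstimate], method_tag: str = "ivw_fixed") -> MrEstimate:
    """Fixed-effect inverse-variance weighted pooling of Wald ratios.

    beta = sum(w_j theta_j) / sum(w_j), se = sum(w_j)^{-1/2}; the 95% CI and
    p-value use the normal reference.
    """
    if len(ratios) < 1:
        raise ValueError("ivw_fixed needs at least one ratio")
    theta, w = _theta_w(ratios)
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return _normal_estimate(method_tag, beta, se, len(ratios))


def _oriented_arrays(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
):
    """Flip each SNP so beta_x > 0 (both betas change sign together)."""
    bx = np.array([i.beta_x for i in instruments], dtype=float)
    sx = np.array([i.se_x for i in instruments], dtype=float)
    by = np.array([i.beta_y for i in instruments], dtype=float)
    sy = np.array([i.se_y for i in instruments], dtype=float)
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, sx, by * s, sy


def _beta_space_weights(bx, sx, by, sy, se_order: str):
    """Weights for regressions of beta_y on beta_x.

    These are the Wald-ratio weights divided by beta_x^2, i.e. 1/se_y^2 for
    first-order and 1/(se_y^2 + theta^2 se_x^2) for second-order, so that
    the zero-intercept weighted fit reproduces the IVW ratio estimate.
    """
    if se_order == "first":
        return sy**-2.0
    if se_order == "second":
        theta = by / bx
        return 1.0 / (sy**2 + theta**2 * sx**2)
    raise ValueError(f"unknown se_order {se_order!r}")


def egger(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    se_order: str = DEFAULT_SE_ORDER,
) -> MrEstimate:
    """MR-Egger: weighted regression of beta_y on beta_x with free intercept.

    SNPs are oriented so beta_x > 0.  Inference uses a t reference with
    J - 2 degrees of freedom and SEs inflated by max(1, sqrt(Q'/(J-2)))
    (multiplicative random-effects convention), where Q' is the weighted
    residual sum of squares of the fit (Rucker's Q').  The intercept and
    its test, an estimate of average directional pleiotropy, are returned
    in ``extras``.
    """
    J = len(list(instruments))
    if J < 3:
        raise ValueError("egger needs at least 3 instruments")
    bx, sx, by, sy = _oriented_arrays(instruments)
    w = _beta_space_weights(bx, sx, by, sy, se_order)
    sw = np.sum(w)
    xbar = np.sum(w * bx) / sw
    ybar = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - xbar) ** 2)
    if sxx <= 0:
        raise ValueError("zero spread in beta_x: Egger design is singular")
    slope = float(np.sum(w * (bx - xbar) * (by - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = by - intercept - slope * bx
    q_prime = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(q_prime / (J - 2)))
    se_slope = scale / math.sqrt(sxx)
    se_intercept = scale * math.sqrt(1.0 / sw + xbar**2 / sxx)
    df = J - 2
    tq = stats.t.ppf(0.975, df)
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_intercept = float(2 * stats.t.sf(abs(intercept / se_intercept), df))
    return MrEstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=p_slope,
        n_snps=J,
        extras={
            "intercept": intercept,
            "intercept_se": se_intercept,
            "intercept_pval": p_intercept,
            "q_prime": q_prime,
            "se_order": se_order,
            "ci_reference": f"t({df})",
        },
    )


def _weighted_median_core(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of theta with weights w.

    The j-th sorted ratio sits at standardized cumulative weight
    p_j = (S_j - w_j / 2) / S_J; the estimate interpolates theta linearly
    at p = 0.5 (clamped to the extreme order statistics outside the range).
    """
    order = np.argsort(theta)
    th = theta[order]
    ww = w[order]
    cum = np.cumsum(ww)
    p = (cum - 0.5 * ww) / cum[-1]
    return float(np.interp(0.5, p, th))


def weighted_median_point(ratios: Sequence[RatioEstimate]) -> float:
    theta, w = _theta_w(ratios)
    return _weighted_median_core(theta, w)


def _bootstrap_se(
    theta: np.ndarray,
    se_theta: np.ndarray,
    w: np.ndarray,
    estimator,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """Parametric bootstrap: redraw theta_j ~ N(theta_j, se_j), re-estimate."""
    draws = rng.normal(theta, se_theta, size=(n_boot, theta.size))
    reps = np.array([estimator(row, w) for row in draws])
    return float(np.std(reps, ddof=1))


def weighted_median(
    ratios: Sequence[RatioEstimate],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
) -> MrEstimate:
    """Precision-weighted median of the Wald ratios.

    The SE is the standard deviation of the estimator over ``n_boot``
    parametric-bootstrap replicates; CI = estimate +/- z_{0.975} SE and the
    p-value uses the normal reference.
    """
    if len(ratios) < 3:
        raise ValueError("weighted_median needs at least 3 ratios")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    theta, w = _theta_w(ratios)
    se_theta = np.array([r.se_theta for r in ratios])
    est = _weighted_median_core(theta, w)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(theta, se_theta, w, _weighted_median_core, n_boot, rng)
    out = _normal_estimate("weighted_median", est, se, len(ratios), {"n_boot": n_boot})
    return out


def mode_bandwidth(theta: np.ndarray, phi: float = 1.0) -> float:
    """Modified Silverman bandwidth on the ratio sample.

    h = phi * 0.9 * min(sd, 1.4826 * MAD) * J^(-1/5); a zero spread yields
    h = 0, which callers treat as a degenerate point mass.
    """
    J = theta.size
    sd = float(np.std(theta, ddof=1)) if J > 1 else 0.0
    mad = float(np.median(np.abs(theta - np.median(theta))))
    s = min(sd, 1.4826 * mad) if mad > 0 else sd
    return phi * 0.9 * s * J ** (-1 / 5)


def _weighted_mode_core(theta: np.ndarray, w: np.ndarray, phi: float = 1.0) -> float:
    h = mode_bandwidth(theta, phi)
    if h <= 0 or np.ptp(theta) == 0:
        return float(np.median(theta))
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, MODE_GRID_POINTS)
    wn = w / np.sum(w)
    dens = np.sum(wn[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2), axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode_point(ratios: Sequence[RatioEstimate], phi: float = 1.0) -> float:
    theta, w = _theta_w(ratios)
    return _weighted_mode_core(theta, w, phi)


def weighted_mode(
    ratios: Sequence[RatioEstimate],
    phi: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
) -> MrEstimate:
    """Weighted mode-based estimate: argmax of a weighted normal-kernel
    density of the Wald ratios, evaluated on a dense grid.

    ``phi`` multiplies the default bandwidth.  SE, CI and p follow the same
    parametric-bootstrap scheme as :func:`weighted_median`.
    """
    if len(ratios) < 3:
        raise ValueError("weighted_mode needs at least 3 ratios")
    if phi <= 0:
        raise ValueError("phi must be positive")
    theta, w = _theta_w(ratios)
    se_theta = np.array([r.se_theta for r in ratios])
    est = _weighted_mode_core(theta, w, phi)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(
        theta, se_theta, w, lambda t, ww: _weighted_mode_core(t, ww, phi), n_boot, rng
    )
    return _normal_estimate(
        "weighted_mode", est, se, len(ratios), {"phi": phi, "n_boot": n_boot}
    )
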
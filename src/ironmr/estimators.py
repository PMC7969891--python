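"""MR point estimators and heterogeneity statistics.

Per-SNP causal effects are Wald ratios beta_y / beta_x with first-order
delta-method standard errors se_y / |beta_x| (the exposure uncertainty is
negligible for strong instruments; a second-order SE including se_x is
available via ``second_order``). The pooled estimators are:

* IVW — inverse-variance-weighted mean of the Wald ratios, weights
  w_j = bx_j^2 / se_yj^2 (equivalently WLS of by on bx through the
  origin). Fixed-effect SE is (sum w)^-1/2; the multiplicative
  random-effects variant scales it by max(1, sqrt(Q/(J-1))).
* MR-Egger — WLS of by on bx with an intercept after orienting every
  bx >= 0; the intercept estimates average directional pleiotropy.
* Weighted median — weighted 50th percentile of the Wald ratios,
  consistent when at least half the weight comes from valid instruments;
  SE by parametric bootstrap.

Results are reported as odds ratios for the outcome per SD increase in
the exposure, with normal-approximation 95% CIs and p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

Z95 = 1.96  # normal multiplier for the reported 95% CI


class EstimationError(ValueError):
    """Estimator preconditions violated (too few or degenerate instruments)."""


@dataclass(frozen=True)
class MRResult:
    """One estimator's pooled causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    n_snp: int
    or_value: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pvalue: float | None = None  # normal two-sided unless the method says otherwise
    exposure: str = ""
    mode: str = ""
    q_stat: float | None = None
    q_df: int | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        orv, lo, hi, p = to_odds_ratio(self.beta, self.se)
        object.__setattr__(self, "or_value", orv)
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)
        if self.pvalue is None:
            object.__setattr__(self, "pvalue", p)

    def relabel(self, exposure: str, mode: str) -> "MRResult":
        from dataclasses import replace
        return replace(self, exposure=exposure, mode=mode)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, 95% CI low, CI high, two-sided normal p) from log-OR and SE."""
    if not (se > 0):
        raise EstimationError(f"se must be positive, got {se}")
    orv = math.exp(beta)
    lo = math.exp(beta - Z95 * se)
    hi = math.exp(beta + Z95 * se)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return orv, lo, hi, p


def _arrays(insts: Sequence[HarmonizedInstrument]):
    bx = np.array([i.bx for i in insts], float)
    by = np.array([i.by for i in insts], float)
    sx = np.array([i.se_x for i in insts], float)
    sy = np.array([i.se_y for i in insts], float)
    return bx, by, sx, sy


def wald_ratio(inst: HarmonizedInstrument, *, second_order: bool = False) -> MRResult:
    """Single-SNP causal estimate by/bx with delta-method SE."""
    if inst.bx == 0:
        raise EstimationError(f"{inst.rsid}: exposure effect is zero; Wald ratio undefined")
    beta = inst.by / inst.bx
    se = inst.se_y / abs(inst.bx)
    if second_order:
        se = math.sqrt(inst.se_y**2 / inst.bx**2
                       + inst.by**2 * inst.se_x**2 / inst.bx**4)
    return MRResult(method="wald", beta=beta, se=se, n_snp=1)


def _ivw_weights(bx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect among instruments")
    return bx**2 / sy**2


def cochran_q(insts: Sequence[HarmonizedInstrument], beta_hat: float) -> tuple[float, int]:
    """Cochran's Q = sum w_j (ratio_j - beta_hat)^2 with J-1 df."""
    if len(insts) < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    bx, by, _, sy = _arrays(insts)
    w = _ivw_weights(bx, sy)
    ratios = by / bx
    q = float(np.sum(w * (ratios - beta_hat) ** 2))
    return q, len(insts) - 1


def ivw(insts: Sequence[HarmonizedInstrument],
        effects_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted pooled estimate of the Wald ratios."""
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    if len(insts) == 0:
        raise EstimationError("ivw needs at least 1 instrument")
    if len(insts) == 1:
        return wald_ratio(insts[0])
    bx, by, _, sy = _arrays(insts)
    w = _ivw_weights(bx, sy)
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q, q_df = cochran_q(insts, beta)
    if effects_model == "multiplicative_random":
        se *= max(1.0, math.sqrt(q / q_df))
    method = "ivw_fe" if effects_model == "fixed" else "ivw_mre"
    return MRResult(method=method, beta=beta, se=se, n_snp=len(insts),
                    q_stat=q, q_df=q_df)


def mr_egger(insts: Sequence[HarmonizedInstrument],
             pvalue_dist: str = "t") -> MRResult:
    """MR-Egger: WLS with intercept on instruments oriented to bx >= 0.

    Intercept = average directional pleiotropy; slope = causal effect.
    Both SEs are scaled by max(1, sigma_hat) where sigma_hat^2 is the
    weighted residual mean square on J-2 df. Slope and intercept
    p-values use the t distribution with J-2 df, the regression-based
    convention of the standard MR software; ``pvalue_dist="normal"``
    switches to the normal reference. CIs stay on the reported
    1.96-multiplier normal scale either way.
    """
    if len(insts) < 3:
        raise EstimationError("mr_egger needs at least 3 instruments")
    if pvalue_dist not in ("t", "normal"):
        raise ValueError(f"unknown pvalue_dist {pvalue_dist!r}")
    bx, by, _, sy = _arrays(insts)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x, y = bx * flip, by * flip
    w = 1.0 / sy**2
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        raise EstimationError("all oriented exposure effects identical; Egger slope undefined")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    df = len(insts) - 2
    sigma2 = float(np.sum(w * resid**2) / df) if df > 0 else 0.0
    scale = max(1.0, math.sqrt(sigma2))
    se_slope = scale / math.sqrt(sxx)
    se_int = scale * math.sqrt(1.0 / sw + xbar**2 / sxx)
    if pvalue_dist == "t":
        slope_p = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
        int_p = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    else:
        slope_p = 2.0 * stats.norm.sf(abs(slope) / se_slope)
        int_p = 2.0 * stats.norm.sf(abs(intercept) / se_int)
    q = float(np.sum(w * resid**2))
    return MRResult(method="egger", beta=slope, se=se_slope, n_snp=len(insts),
                    pvalue=float(slope_p), q_stat=q, q_df=df,
                    egger_intercept=intercept, egger_intercept_se=se_int,
                    egger_intercept_p=float(int_p))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    b = ratios[order]
    p = weights[order] / np.sum(weights)
    s = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5, s, b))


def weighted_median(insts: Sequence[HarmonizedInstrument], n_boot: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap SE (seeded)."""
    if len(insts) < 3:
        raise EstimationError("weighted_median needs at least 3 instruments")
    bx, by, sx, sy = _arrays(insts)
    w = _ivw_weights(bx, sy)
    beta = _weighted_median(by / bx, w)
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(insts)))
    by_star = rng.normal(by, sy, size=(n_boot, len(insts)))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        xs = bx_star[i]
        xs = np.where(xs == 0, np.finfo(float).tiny, xs)
        boots[i] = _weighted_median(by_star[i] / xs, xs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return MRResult(method="weighted_median", beta=beta, se=se, n_snp=len(insts))
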
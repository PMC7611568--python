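"""Summary-level causal estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure effects ``b_X`` (SE ``s_X``)
and outcome effects ``b_Y`` (SE ``s_Y``), the per-variant Wald ratio
``theta_j = b_Yj / b_Xj`` estimates the causal effect if variant j is a
valid instrument.  The estimators here combine the ratios under different
validity assumptions:

* **IVW** — precision-weighted mean of the ratios; unbiased when every
  instrument is valid.  The fixed-effects SE assumes homogeneity; the
  multiplicative random-effects SE inflates it by the overdispersion
  factor ``sqrt(Q/(J-1))`` (floored at 1) when the ratios are heterogeneous.
* **Weighted median** — consistent as long as instruments carrying at
  least half the weight are valid; SE by parametric bootstrap.
* **MR-Egger** — weighted regression of ``b_Y`` on ``b_X`` with a free
  intercept; the intercept estimates average directional pleiotropy and
  the slope remains a consistent causal estimate under the InSIDE
  assumption (pleiotropy uncorrelated with instrument strength).

All estimates are on the log-odds scale (per 1 SD of a continuous
exposure, per 1 log-odds unit of a binary exposure); heterogeneity is
summarized by Cochran's Q and I².
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .datatypes import (
    EstimationError,
    HarmonizedInstrument,
    MRResult,
    RatioEstimate,
    Z_95,
)

__all__ = [
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "mr_egger",
    "cochran_q",
    "leave_one_out_ivw",
]


def wald_ratio(
    instr: HarmonizedInstrument, se_order: str = "first"
) -> RatioEstimate:
    """Per-variant causal estimate b_Y/b_X with a delta-method SE.

    ``se_order="first"`` gives ``s_Y/|b_X|`` (exposure effect treated as
    known — the default, and the choice under which IVW coincides with the
    zero-intercept weighted regression of b_Y on b_X).  ``"second"`` adds
    the exposure-side uncertainty term
    ``sqrt(s_Y²/b_X² + b_Y²·s_X²/b_X⁴)``.
    """
    bx, by = instr.beta_exposure, instr.beta_outcome
    if bx == 0:
        raise EstimationError(f"{instr.variant_id}: beta_exposure is zero")
    theta = by / bx
    if se_order == "first":
        sigma = instr.se_outcome / abs(bx)
    elif se_order == "second":
        sigma = math.sqrt(
            instr.se_outcome**2 / bx**2 + by**2 * instr.se_exposure**2 / bx**4
        )
    else:
        raise ValueError(f"se_order must be 'first' or 'second', got {se_order!r}")
    return RatioEstimate(variant_id=instr.variant_id, theta=theta, sigma=sigma)


def wald_ratios(
    instruments: list[HarmonizedInstrument], se_order: str = "first"
) -> list[RatioEstimate]:
    """Wald ratio for every instrument."""
    return [wald_ratio(i, se_order) for i in instruments]


# ---------------------------------------------------------------------------
# array kernels — shared by the result-building wrappers and the simulation
# studies, where millions of replicate fits make per-call overhead matter
# ---------------------------------------------------------------------------


def _ivw_arrays(theta: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Return (estimate, fixed-effects se, Cochran's Q)."""
    sw = w.sum()
    est = float((w * theta).sum() / sw)
    q = float((w * (theta - est) ** 2).sum())
    return est, float(sw**-0.5), q


def _weighted_median_arrays(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by interpolation at cumulative-midpoint positions.

    With normalized weights w' sorted by theta, position
    ``p_j = S_j - w'_j/2`` (S_j the cumulative sum); the estimate is theta
    interpolated at p = 0.5, clamped to the extreme order statistic when
    0.5 falls outside [p_1, p_J].
    """
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    wn = w[order] / w.sum()
    p = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, p, th))


def _egger_arrays(
    bx: np.ndarray, by: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Weighted least squares of by on bx with intercept, weights w.

    Returns (slope, intercept, se_slope, se_intercept, scale) where the SEs
    carry the multiplicative overdispersion ``max(1, RSS/(J-2))`` and scale
    is that factor.
    """
    j = bx.size
    sw = w.sum()
    mx = (w * bx).sum() / sw
    my = (w * by).sum() / sw
    sxx = (w * (bx - mx) ** 2).sum()
    if sxx <= 0:
        raise EstimationError("no variation in exposure effects: Egger undefined")
    slope = float((w * (bx - mx) * (by - my)).sum() / sxx)
    intercept = float(my - slope * mx)
    resid = by - intercept - slope * bx
    scale = max(1.0, float((w * resid**2).sum() / (j - 2))) if j > 2 else 1.0
    se_slope = math.sqrt(scale / sxx)
    se_intercept = math.sqrt(scale * (1.0 / sw + mx**2 / sxx))
    return slope, intercept, se_slope, se_intercept, scale


def _ratio_arrays(ratios: list[RatioEstimate]) -> tuple[np.ndarray, np.ndarray]:
    # lexicographic tie-break on variant_id keeps every downstream sort
    # deterministic regardless of input order
    ordered = sorted(ratios, key=lambda r: r.variant_id)
    theta = np.array([r.theta for r in ordered])
    w = np.array([r.weight for r in ordered])
    return theta, w


def _heterogeneity(q: float, j: int) -> tuple[float, float]:
    """I² (percent, truncated at 0) and the chi-square p for Q with J-1 df."""
    i2 = max(0.0, (q - (j - 1)) / q) * 100.0 if q > 0 else 0.0
    p = float(stats.chi2.sf(q, j - 1))
    return i2, p


def ivw(
    ratios: list[RatioEstimate], model: str = "multiplicative_random"
) -> MRResult:
    """Inverse-variance weighted estimate of the causal effect.

    ``model="fixed"`` uses se ``(sum w)^(-1/2)``; ``"multiplicative_random"``
    multiplies it by ``max(1, sqrt(Q/(J-1)))`` so heterogeneous ratios widen
    the interval but never narrow it.  With a single instrument both models
    coincide and heterogeneity is undefined (reported as NaN).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if not ratios:
        raise EstimationError("IVW requires at least one instrument")
    theta, w = _ratio_arrays(ratios)
    j = theta.size
    est, se_fixed, q = _ivw_arrays(theta, w)
    if j >= 2:
        i2, q_p = _heterogeneity(q, j)
        overdispersion = max(1.0, math.sqrt(q / (j - 1)))
    else:
        q, i2, q_p = math.nan, math.nan, math.nan
        overdispersion = 1.0
    se = se_fixed if model == "fixed" else se_fixed * overdispersion
    return MRResult(
        method="ivw_fe" if model == "fixed" else "ivw_mre",
        estimate=est,
        se=se,
        n_snps=j,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        p_value=float(2 * stats.norm.sf(abs(est) / se)),
        q_stat=q,
        i_squared=i2,
        q_p_value=q_p,
    )


def weighted_median(
    ratios: list[RatioEstimate],
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when valid instruments carry more than half the total
    inverse-variance weight.  The SE is the standard deviation of the
    estimate over ``n_boot`` replicates drawing ``theta*_j ~
    Normal(theta_j, sigma_j)`` with the weights held fixed.
    """
    if len(ratios) < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    theta, w = _ratio_arrays(ratios)
    sigma = w**-0.5
    est = _weighted_median_arrays(theta, w)

    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.normal(theta, sigma, size=(n_boot, theta.size))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _weighted_median_arrays(draws[b], w)
    se = float(boot.std(ddof=1))

    j = theta.size
    _, _, q = _ivw_arrays(theta, w)
    i2, q_p = _heterogeneity(q, j)
    return MRResult(
        method="weighted_median",
        estimate=est,
        se=se,
        n_snps=j,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        p_value=float(2 * stats.norm.sf(abs(est) / se)),
        q_stat=q,
        i_squared=i2,
        q_p_value=q_p,
    )


def mr_egger(
    instruments: list[HarmonizedInstrument],
) -> tuple[MRResult, MRResult]:
    """MR-Egger regression: returns (slope result, intercept result).

    Weighted least squares of outcome on exposure effects with weights
    ``1/s_Y²``.  The intercept estimates the average directional pleiotropy
    per instrument; a non-zero intercept is evidence the IVW estimate is
    biased.  SEs carry a multiplicative overdispersion factor floored at 1
    and p-values use the t distribution with J-2 degrees of freedom,
    appropriate for the small instrument counts typical of binary exposures.
    """
    j = len(instruments)
    if j < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    ordered = sorted(instruments, key=lambda i: i.variant_id)
    bx = np.array([i.beta_exposure for i in ordered])
    by = np.array([i.beta_outcome for i in ordered])
    w = np.array([i.se_outcome for i in ordered]) ** -2.0
    slope, intercept, se_s, se_i, _ = _egger_arrays(bx, by, w)

    df = j - 2
    tq = float(stats.t.ppf(0.975, df))
    resid = by - intercept - slope * bx
    q = float((w * resid**2).sum())
    i2, q_p = _heterogeneity(q, j - 1) if j > 3 else (math.nan, math.nan)

    def result(method: str, est: float, se: float) -> MRResult:
        return MRResult(
            method=method,
            estimate=est,
            se=se,
            n_snps=j,
            ci_low=est - tq * se,
            ci_high=est + tq * se,
            p_value=float(2 * stats.t.sf(abs(est) / se, df)),
            q_stat=q,
            i_squared=i2,
            q_p_value=q_p,
        )

    return result("egger_slope", slope, se_s), result(
        "egger_intercept", intercept, se_i
    )


def cochran_q(
    ratios: list[RatioEstimate],
) -> tuple[float, int, float, float]:
    """Heterogeneity across Wald ratios: (Q, df, p, I² percent).

    Large Q relative to J-1 signals that the per-variant ratios disagree
    beyond sampling noise — a symptom of horizontal pleiotropy or invalid
    instruments.
    """
    if len(ratios) < 2:
        raise EstimationError("heterogeneity undefined for fewer than 2 ratios")
    theta, w = _ratio_arrays(ratios)
    _, _, q = _ivw_arrays(theta, w)
    i2, p = _heterogeneity(q, theta.size)
    return q, theta.size - 1, p, i2


def leave_one_out_ivw(ratios: list[RatioEstimate]) -> dict[str, float]:
    """Fixed-effects IVW estimate with each instrument removed in turn."""
    if len(ratios) < 2:
        raise EstimationError("leave-one-out requires at least 2 instruments")
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    sw, swt = w.sum(), (w * theta).sum()
    return {
        r.variant_id: float((swt - w[i] * theta[i]) / (sw - w[i]))
        for i, r in enumerate(ratios)
    }
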
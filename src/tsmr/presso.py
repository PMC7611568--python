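"""MR-PRESSO: pleiotropy residual sum and outlier test by parametric simulation.

The observed residual sum of squares compares each instrument's outcome
effect with the prediction of the leave-one-out IVW fit,

    RSS = sum_j (b_Yj - theta_hat_{-j} * b_Xj)^2 / s_Yj^2 .

K simulated datasets are drawn under the no-pleiotropy model
(``b*_Xj ~ N(b_Xj, s_Xj)``, ``b*_Yj ~ N(theta_hat_{-j} * b_Xj, s_Yj)``) and
the RSS recomputed on each, giving an empirical global p-value.  Per-variant
residuals tested the same way flag outliers (Bonferroni-adjusted), the
causal estimate is re-fit without them, and a distortion test asks whether
removing the flagged set moved the estimate more than removing as many
instruments at random would.

Empirical p-values use the add-one rule ``(1 + b)/(K + 1)`` so they are
never zero; everything is deterministic given (inputs, K, seed).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datatypes import (
    EstimationError,
    HarmonizedInstrument,
    MRResult,
    OutlierFlag,
    PressoReport,
)
from .estimators import ivw, wald_ratios

__all__ = ["presso_global", "presso_outliers"]


def _arrays(
    instruments: list[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ordered = sorted(instruments, key=lambda i: i.variant_id)
    bx = np.array([i.beta_exposure for i in ordered])
    sx = np.array([i.se_exposure for i in ordered])
    by = np.array([i.beta_outcome for i in ordered])
    sy = np.array([i.se_outcome for i in ordered])
    return bx, sx, by, sy


def _loo_theta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each j, vectorized over instruments.

    Supports stacked inputs of shape (..., J); the IVW here is the
    zero-intercept weighted regression of b_Y on b_X with weights 1/s_Y²,
    identical to inverse-variance weighting of first-order Wald ratios.
    """
    w = sy**-2.0
    num = (w * bx * by).sum(axis=-1, keepdims=True) - w * bx * by
    den = (w * bx * bx).sum(axis=-1, keepdims=True) - w * bx * bx
    return num / den


def _observed_and_simulated_residuals(
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    k_sims: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Squared standardized residuals: observed (J,) and simulated (K, J)."""
    theta_loo = _loo_theta(bx, by, sy)
    obs = ((by - theta_loo * bx) / sy) ** 2

    j = bx.size
    bx_sim = rng.normal(bx, sx, size=(k_sims, j))
    by_sim = rng.normal(theta_loo * bx, sy, size=(k_sims, j))
    theta_loo_sim = _loo_theta(bx_sim, by_sim, sy)
    sim = ((by_sim - theta_loo_sim * bx_sim) / sy) ** 2
    return obs, sim


def presso_global(
    instruments: list[HarmonizedInstrument],
    k_sims: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Global heterogeneity test; returns (observed RSS, empirical p).

    A small p means the instruments' outcome effects deviate from a single
    causal slope more than sampling noise allows — horizontal pleiotropy
    somewhere in the set.  The smallest attainable p is ``1/(K+1)``.
    """
    if len(instruments) < 4:
        raise EstimationError("MR-PRESSO requires at least 4 instruments")
    if k_sims < 100:
        raise ValueError("k_sims must be at least 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(instruments)
    obs, sim = _observed_and_simulated_residuals(bx, sx, by, sy, k_sims, rng)
    rss_obs = float(obs.sum())
    global_p = float((1 + (sim.sum(axis=1) >= rss_obs).sum()) / (k_sims + 1))
    return rss_obs, global_p


def presso_outliers(
    instruments: list[HarmonizedInstrument],
    k_sims: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    ivw_model: str = "fixed",
) -> PressoReport:
    """Outlier test with causal-estimate correction and distortion test.

    Instrument j is flagged when its empirical residual p-value survives a
    Bonferroni adjustment over J instruments (``p_j * J < alpha``).  The
    corrected estimate is the IVW fit on the unflagged set; correction is
    always by removal.  The distortion p compares the raw-minus-corrected
    shift against the shift produced by deleting equally many instruments
    drawn at random from the unflagged set.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if len(instruments) < 4:
        raise EstimationError("MR-PRESSO requires at least 4 instruments")
    if k_sims < 100:
        raise ValueError("k_sims must be at least 100")
    rng = np.random.default_rng(seed)

    ordered = sorted(instruments, key=lambda i: i.variant_id)
    bx, sx, by, sy = _arrays(ordered)
    obs, sim = _observed_and_simulated_residuals(bx, sx, by, sy, k_sims, rng)
    rss_obs = float(obs.sum())
    global_p = float((1 + (sim.sum(axis=1) >= rss_obs).sum()) / (k_sims + 1))

    # Per-variant p-values deliberately omit the add-one correction: an
    # observed residual exceeding every simulated one must be able to reach
    # p = 0, otherwise no outlier could ever pass a Bonferroni adjustment
    # over J ~ 50 instruments at K = 1000.  The global test keeps add-one.
    j = len(ordered)
    p_per_snp = (sim >= obs).sum(axis=0) / k_sims
    flags = tuple(
        OutlierFlag(
            variant_id=ins.variant_id,
            p_value=float(p),
            p_bonferroni=float(min(1.0, p * j)),
            is_outlier=bool(p * j < alpha),
        )
        for ins, p in zip(ordered, p_per_snp)
    )
    outlier_mask = np.array([f.is_outlier for f in flags])
    raw = replace(ivw(wald_ratios(ordered), model=ivw_model), method="mr_presso_raw")

    if outlier_mask.all():
        raise EstimationError("every instrument flagged as an outlier")

    if not outlier_mask.any():
        corrected = replace(raw, method="mr_presso_corrected")
        return PressoReport(
            rss_obs=rss_obs,
            global_p=global_p,
            outliers=flags,
            raw_result=raw,
            corrected_result=corrected,
            distortion_p=None,
            k_sims=k_sims,
        )

    keep = [ins for ins, out in zip(ordered, outlier_mask) if not out]
    corrected = replace(
        ivw(wald_ratios(keep), model=ivw_model), method="mr_presso_corrected"
    )

    # Distortion: how unusual is the raw-vs-corrected shift compared with
    # removing the same number of randomly chosen unflagged instruments?
    n_out = int(outlier_mask.sum())
    keep_idx = np.flatnonzero(~outlier_mask)
    w = sy**-2.0
    num_all = float((w * bx * by)[keep_idx].sum())
    den_all = float((w * bx * bx)[keep_idx].sum())
    obs_shift = abs(raw.estimate - corrected.estimate)
    count = 0
    n_draws = k_sims
    for _ in range(n_draws):
        drop = rng.choice(keep_idx, size=n_out, replace=False)
        num = num_all - float((w * bx * by)[drop].sum())
        den = den_all - float((w * bx * bx)[drop].sum())
        count += abs(raw.estimate - num / den) >= obs_shift
    distortion_p = float((1 + count) / (n_draws + 1))

    return PressoReport(
        rss_obs=rss_obs,
        global_p=global_p,
        outliers=flags,
        raw_result=raw,
        corrected_result=corrected,
        distortion_p=distortion_p,
        k_sims=k_sims,
    )
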
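"""Fixed-effects meta-analysis of odds ratios across outcome sources.

When the same exposure-outcome pair is analysed in two cohorts (e.g. a
disease consortium and a population biobank), pooling the two log odds
ratios by inverse-variance weighting sharpens the estimate.  Published
results usually arrive as ``OR (CI_low, CI_high)``; the standard error is
recovered from the CI width on the log scale,

    se = (ln CI_high - ln CI_low) / (2 * 1.959964).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd
from scipy import stats

from .datatypes import DataError, MRResult, StudySummary, Z_95

logger = logging.getLogger(__name__)

__all__ = ["ci_to_se", "fixed_effects_meta", "read_study_table", "from_mr_result"]


def ci_to_se(
    odds_ratio: float,
    ci_low: float,
    ci_high: float,
    label: str = "",
) -> StudySummary:
    """Back-transform a published OR with 95% CI to log-OR and SE.

    A CI printed at low precision is slightly asymmetric around the OR on
    the log scale; the SE always uses the full CI width, and marked
    asymmetry (beyond what rounding explains) only triggers a warning.
    """
    if not 0 < ci_low < ci_high:
        raise DataError(f"{label or odds_ratio}: need 0 < ci_low < ci_high")
    if not ci_low <= odds_ratio <= ci_high:
        raise DataError(f"{label or odds_ratio}: odds ratio outside its CI")
    log_or = math.log(odds_ratio)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z_95)
    if se <= 0:
        raise DataError(f"{label or odds_ratio}: degenerate CI (zero width)")
    asym = abs((math.log(ci_high) - log_or) - (log_or - math.log(ci_low)))
    if asym > 0.2 * se:
        logger.warning(
            "%s: CI asymmetric on the log scale (likely rounded inputs)",
            label or odds_ratio,
        )
    return StudySummary(
        label=label,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        log_or=log_or,
        se_log_or=se,
    )


def from_mr_result(result: MRResult, label: str) -> StudySummary:
    """Wrap a causal estimate as a study for pooling, carrying its exact SE."""
    return StudySummary(
        label=label,
        odds_ratio=result.odds_ratio,
        ci_low=math.exp(result.estimate - Z_95 * result.se),
        ci_high=math.exp(result.estimate + Z_95 * result.se),
        log_or=result.estimate,
        se_log_or=result.se,
    )


def fixed_effects_meta(studies: list[StudySummary]) -> MRResult:
    """Pool log odds ratios with inverse-variance weights.

    The pooled SE is ``(sum 1/se_i²)^(-1/2)``, always smaller than any
    single study's.  Cochran's Q across studies is reported; a fixed-effects
    model assumes the studies estimate one common effect.
    """
    if len(studies) < 2:
        raise DataError("fixed-effects meta-analysis requires >= 2 studies")
    w = [s.se_log_or**-2 for s in studies]
    sw = sum(w)
    est = sum(wi * s.log_or for wi, s in zip(w, studies)) / sw
    se = sw**-0.5
    q = sum(wi * (s.log_or - est) ** 2 for wi, s in zip(w, studies))
    df = len(studies) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return MRResult(
        method="meta_fixed",
        estimate=est,
        se=se,
        n_snps=len(studies),
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        p_value=float(2 * stats.norm.sf(abs(est) / se)),
        q_stat=q,
        i_squared=i2,
        q_p_value=float(stats.chi2.sf(q, df)),
    )


def read_study_table(path: str | Path) -> list[StudySummary]:
    """Read a table of published estimates: label, or, ci_low, ci_high."""
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    for col in ("label", "or", "ci_low", "ci_high"):
        if col not in df.columns:
            raise DataError(f"{path}: required column {col!r} not found")
    return [
        ci_to_se(
            float(row["or"]),
            float(row["ci_low"]),
            float(row["ci_high"]),
            label=str(row["label"]),
        )
        for row in df.to_dict("records")
    ]
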
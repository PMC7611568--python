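"""Core record types shared across the package.

Effect sizes live on the scale of the source GWAS: per-allele SD units for
continuous traits (e.g. a hormone level), per-allele log-odds for binary
traits (disease liability or a cancer outcome).  Causal estimates are kept
on the log-odds scale internally and exponentiated to odds ratios only for
reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: two-sided 97.5% standard-normal quantile used for every 95% interval
Z_95 = 1.959964


class TsmrError(Exception):
    """Base class for all package errors."""


class FormatError(TsmrError):
    """A summary-statistics file does not match the expected layout."""


class DataError(TsmrError):
    """Record-level inconsistency (alleles, allele maps, orderings)."""


class ConfigError(TsmrError):
    """Invalid analysis or simulation configuration."""


class EstimationError(TsmrError):
    """An estimator cannot run on the provided instruments."""


@dataclass(frozen=True)
class SummaryAssociation:
    """One variant's association with one trait in one GWAS."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p_value: float
    eaf: float | None = None
    n: float | None = None
    trait_id: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise DataError(
                f"{self.variant_id}: invalid effect allele {self.effect_allele!r}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise DataError(
                f"{self.variant_id}: invalid other allele {self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise DataError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise DataError(f"{self.variant_id}: eaf outside [0,1]: {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure/outcome effect pair oriented to the exposure-increasing allele.

    After harmonization ``beta_exposure > 0`` always holds: the effect allele
    is, by construction, the allele that raises the exposure.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    def __post_init__(self) -> None:
        if not self.beta_exposure > 0:
            raise DataError(
                f"{self.variant_id}: harmonized beta_exposure must be > 0"
            )
        if not (self.se_exposure > 0 and self.se_outcome > 0):
            raise DataError(f"{self.variant_id}: standard errors must be > 0")


@dataclass(frozen=True)
class ProxyRecord:
    """A high-LD stand-in for an instrument missing from the outcome GWAS.

    ``allele_map`` pairs each allele of the missing variant with the
    corresponding allele of the proxy, e.g. ``{"A": "C", "G": "T"}``.
    """

    missing_variant: str
    proxy_variant: str
    r_squared: float
    allele_map: dict[str, str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise DataError(
                f"proxy {self.proxy_variant}: r_squared outside [0,1]"
            )
        if len(self.allele_map) != 2:
            raise DataError(
                f"proxy {self.proxy_variant}: allele_map must pair two alleles"
            )


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio: outcome effect divided by exposure effect."""

    variant_id: str
    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DataError(f"{self.variant_id}: ratio sigma must be > 0")

    @property
    def weight(self) -> float:
        """Inverse-variance weight 1/sigma**2."""
        return self.sigma**-2


@dataclass(frozen=True)
class MRResult:
    """One method's causal estimate on the log scale with 95% CI."""

    method: str
    estimate: float
    se: float
    n_snps: int
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    p_value: float = field(default=math.nan)
    q_stat: float = field(default=math.nan)
    i_squared: float = field(default=math.nan)
    q_p_value: float = field(default=math.nan)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass(frozen=True)
class OutlierFlag:
    """Per-variant outcome of the MR-PRESSO outlier test."""

    variant_id: str
    p_value: float
    p_bonferroni: float
    is_outlier: bool


@dataclass(frozen=True)
class PressoReport:
    """Global, outlier and distortion test results from MR-PRESSO."""

    rss_obs: float
    global_p: float
    outliers: tuple[OutlierFlag, ...]
    raw_result: MRResult
    corrected_result: MRResult
    distortion_p: float | None
    k_sims: int

    @property
    def n_outliers(self) -> int:
        return sum(f.is_outlier for f in self.outliers)


@dataclass(frozen=True)
class StudySummary:
    """A published odds ratio with its 95% CI, back-transformed to log scale."""

    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low < self.ci_high):
            raise DataError(f"{self.label}: CI bounds must satisfy 0 < low < high")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise DataError(f"{self.label}: odds ratio outside its CI")
        if not self.se_log_or > 0:
            raise DataError(f"{self.label}: se of log OR must be > 0")
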
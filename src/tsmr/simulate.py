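"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the summary-data layout of a large two-sample MR
study: a continuous exposure (hormone level in SD units) instrumented by
~60 genome-wide-significant variants from a GWAS of ~72,000 individuals,
or a binary exposure (disease liability on the log-odds scale) with 7-8
instruments, paired with a binary outcome GWAS whose case counts range
from a few hundred (a rare cancer in a biobank) to >100,000 (a dedicated
consortium).

Per variant j the model is

    gamma_j  ~ true exposure effect        (|Normal(0, gamma_sd)| + floor)
    alpha_j  =  horizontal pleiotropy      (0 for valid instruments)
    Gamma_j  =  theta * gamma_j + alpha_j + outlier shift
    b_Xj ~ Normal(gamma_j, s_Xj),   b_Yj ~ Normal(Gamma_j, s_Yj)

so every estimator can be checked against the known causal effect theta.
Pleiotropy modes: ``none``, ``balanced`` (zero-mean alpha), ``directional``
(non-zero mean, independent of gamma — InSIDE holds), ``inside_violated``
(alpha correlated with gamma).  All randomness flows from a single seed
through independent child streams, so replicate r of a study is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConfigError, SummaryAssociation
from . import io as tsmr_io

__all__ = ["SimulationConfig", "TruthRecord", "simulate_two_sample",
           "scramble_for_harmonization", "child_rng"]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violated")

#: non-palindromic allele pairs used round-robin for simulated variants
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator for a (seed, key...) path via SeedSequence."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-sample dataset.

    Defaults mirror a strong continuous-exposure instrument set: with
    ``gamma_sd=0.03`` and ``gamma_floor=0.01`` the mean true effect is
    ~0.034 SD per allele, and exposure SEs of ~0.0025-0.0045 (a GWAS of
    ~72,000) give a mean per-variant F-statistic near 100 (|gamma|/s_X
    ~ 10).  Outcome SEs of 0.01-0.02 correspond to a case-control GWAS
    with on the order of 100,000 cases.
    """

    n_snps: int = 60
    theta: float = 0.0
    gamma_sd: float = 0.03
    gamma_floor: float = 0.01
    se_exposure_range: tuple[float, float] = (0.0025, 0.0045)
    se_outcome_range: tuple[float, float] = (0.01, 0.02)
    pleiotropy_mode: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    invalid_fraction: float = 0.0
    outlier_indices: tuple[int, ...] = ()
    outlier_shift: float = 0.0  # in units of the variant's outcome SE
    palindromic_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}"
            )
        for name in ("se_exposure_range", "se_outcome_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ConfigError(f"{name} must satisfy 0 < low <= high")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ConfigError("invalid_fraction must lie in [0,1]")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ConfigError("palindromic_fraction must lie in [0,1]")
        if any(i < 0 or i >= self.n_snps for i in self.outlier_indices):
            raise ConfigError("outlier_indices out of range")

    @staticmethod
    def binary_exposure(**overrides) -> "SimulationConfig":
        """Preset for a binary exposure: few instruments, log-odds effects."""
        defaults = dict(
            n_snps=8,
            gamma_sd=0.15,
            gamma_floor=0.05,
            se_exposure_range=(0.015, 0.03),
        )
        defaults.update(overrides)
        return SimulationConfig(**defaults)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated dataset."""

    theta: float
    table: pd.DataFrame = field(repr=False)  # per-variant gamma/alpha/flags


def simulate_two_sample(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SummaryAssociation], list[SummaryAssociation], TruthRecord]:
    """Draw one synthetic (exposure table, outcome table, truth) triple.

    Exposure p-values are exact Wald p-values, so simulated instruments are
    genome-wide significant by construction whenever |gamma|/s_X is large.
    """
    config.validate()
    if rng is None:
        rng = child_rng(config.seed, 0)
    j = config.n_snps

    gamma = np.abs(rng.normal(0.0, config.gamma_sd, j)) + config.gamma_floor
    se_x = rng.uniform(*config.se_exposure_range, j)
    se_y = rng.uniform(*config.se_outcome_range, j)

    n_invalid = int(round(config.invalid_fraction * j))
    invalid = np.zeros(j, dtype=bool)
    if n_invalid:
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True

    alpha = np.zeros(j)
    mode = config.pleiotropy_mode
    if mode != "none" and invalid.any():
        if mode == "balanced":
            alpha[invalid] = rng.normal(0.0, config.alpha_sd, n_invalid)
        elif mode == "directional":
            alpha[invalid] = rng.normal(
                config.alpha_mean, config.alpha_sd, n_invalid
            )
        elif mode == "inside_violated":
            # pleiotropy proportional to instrument strength plus noise
            alpha[invalid] = (
                config.alpha_mean * gamma[invalid] / gamma.mean()
                + rng.normal(0.0, config.alpha_sd, n_invalid)
            )

    outlier = np.zeros(j, dtype=bool)
    outlier[list(config.outlier_indices)] = True
    big_gamma = config.theta * gamma + alpha
    big_gamma[outlier] += config.outlier_shift * se_y[outlier]

    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(big_gamma, se_y)
    eaf = rng.uniform(0.05, 0.95, j)

    n_palin = int(round(config.palindromic_fraction * j))
    is_palin = np.zeros(j, dtype=bool)
    if n_palin:
        is_palin[rng.choice(j, size=n_palin, replace=False)] = True

    from scipy import stats

    p_x = 2 * stats.norm.sf(np.abs(beta_x) / se_x)
    p_y = 2 * stats.norm.sf(np.abs(beta_y) / se_y)

    width = len(str(j))
    exposure, outcome = [], []
    for i in range(j):
        if is_palin[i]:
            ea, oa = _PALINDROMIC_PAIRS[i % len(_PALINDROMIC_PAIRS)]
        else:
            ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        vid = f"rs{i + 1:0{width}d}"
        exposure.append(
            SummaryAssociation(
                variant_id=vid, effect_allele=ea, other_allele=oa,
                beta=float(beta_x[i]), se=float(se_x[i]),
                p_value=float(max(p_x[i], 1e-320)), eaf=float(eaf[i]),
                trait_id="exposure",
            )
        )
        outcome.append(
            SummaryAssociation(
                variant_id=vid, effect_allele=ea, other_allele=oa,
                beta=float(beta_y[i]), se=float(se_y[i]),
                p_value=float(max(p_y[i], 1e-320)), eaf=float(eaf[i]),
                trait_id="outcome",
            )
        )

    truth = TruthRecord(
        theta=config.theta,
        table=pd.DataFrame(
            {
                "variant_id": [a.variant_id for a in exposure],
                "gamma": gamma,
                "alpha": alpha,
                "big_gamma": big_gamma,
                "is_invalid": invalid,
                "is_outlier": outlier,
                "is_palindromic": is_palin,
            }
        ),
    )
    return exposure, outcome, truth


@dataclass(frozen=True)
class ScrambleAction:
    """The allele re-encoding applied to one outcome record."""

    variant_id: str
    swapped: bool  # effect/other alleles exchanged (beta and eaf recoded)
    flipped: bool  # both alleles replaced by strand complements


def scramble_for_harmonization(
    outcome: list[SummaryAssociation],
    seed: int,
) -> tuple[list[SummaryAssociation], list[ScrambleAction]]:
    """Randomly swap and/or strand-flip outcome allele encodings.

    The statistical content is untouched: a swap negates the beta and
    mirrors the frequency, a flip rewrites the alleles as their
    complements.  The returned actions let a test check that harmonization
    restores the original encoding exactly.
    """
    from .datatypes import COMPLEMENT

    rng = child_rng(seed, 99)
    scrambled: list[SummaryAssociation] = []
    actions: list[ScrambleAction] = []
    for rec in outcome:
        swap, flip = bool(rng.integers(2)), bool(rng.integers(2))
        ea, oa, beta, eaf = rec.effect_allele, rec.other_allele, rec.beta, rec.eaf
        if swap:
            ea, oa = oa, ea
            beta = -beta
            eaf = None if eaf is None else 1.0 - eaf
        if flip:
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        scrambled.append(
            SummaryAssociation(
                variant_id=rec.variant_id, effect_allele=ea, other_allele=oa,
                beta=beta, se=rec.se, p_value=rec.p_value, eaf=eaf,
                n=rec.n, trait_id=rec.trait_id,
            )
        )
        actions.append(ScrambleAction(rec.variant_id, swap, flip))
    return scrambled, actions


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Simulate once and write exposure.tsv, outcome.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = simulate_two_sample(config)
    e_path, o_path, t_path = (
        out / "exposure.tsv", out / "outcome.tsv", out / "truth.tsv"
    )
    tsmr_io.write_summary_table(exposure, e_path)
    tsmr_io.write_summary_table(outcome, o_path)
    tbl = truth.table.copy()
    tbl.insert(1, "theta", truth.theta)
    tbl.to_csv(t_path, sep="\t", index=False, float_format="%.17g")
    return e_path, o_path, t_path
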
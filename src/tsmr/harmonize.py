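"""Instrument selection, proxy substitution and allele harmonization.

Two-sample Mendelian randomization pairs a per-variant exposure effect from
one GWAS with the same variant's outcome effect from another.  Before the
ratio estimators can run, the two effect estimates must refer to the same
allele on the same strand, and by convention the pair is oriented so the
effect allele is the one that *raises* the exposure (``beta_exposure > 0``).

Every dropped, proxied or reoriented variant is recorded with a
machine-parsable reason code so a run is fully auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .datatypes import (
    COMPLEMENT,
    DataError,
    HarmonizedInstrument,
    ProxyRecord,
    SummaryAssociation,
)

logger = logging.getLogger(__name__)

#: palindromic variants with effect-allele frequency in this open interval
#: cannot be strand-resolved from frequency and are dropped by default
DEFAULT_PALINDROMIC_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class HarmonizationEvent:
    """Audit-trail entry for one variant during harmonization or proxying."""

    variant_id: str
    code: str  # e.g. DROP_PALINDROMIC_AMBIGUOUS, PROXY_SUBSTITUTED, FLIP_STRAND
    detail: str = ""


def select_instruments(
    assocs: list[SummaryAssociation],
    p_threshold: float = 5e-8,
    exclusion_list: dict[str, str] | set[str] | None = None,
) -> list[SummaryAssociation]:
    """Keep genome-wide-significant variants not on the exclusion list.

    Retains records with ``p_value < p_threshold`` whose variant ID is not
    excluded; input order is preserved.  An empty result is legal (a warning
    is logged) — downstream estimators decide whether they can proceed.
    """
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must lie in (0,1), got {p_threshold}")
    excluded = set(exclusion_list or ())
    kept = [
        a
        for a in assocs
        if a.p_value < p_threshold and a.variant_id not in excluded
    ]
    n_excluded = sum(1 for a in assocs if a.variant_id in excluded)
    if n_excluded:
        logger.info("excluded %d variant(s) from the exclusion list", n_excluded)
    if not kept:
        logger.warning("no instruments pass p < %g", p_threshold)
    return kept


def substitute_proxies(
    instruments: list[SummaryAssociation],
    outcome_variants: set[str],
    proxies: list[ProxyRecord],
    r2_min: float = 0.9,
) -> tuple[list[SummaryAssociation], list[HarmonizationEvent]]:
    """Replace instruments absent from the outcome GWAS by LD proxies.

    For each instrument missing from ``outcome_variants`` the highest-R²
    proxy with ``r_squared >= r2_min`` is substituted, remapping the
    instrument's alleles through the proxy's allele pairing; instruments
    with no qualifying proxy are dropped.  Returns the surviving instrument
    list and the substitution log.
    """
    if not 0 < r2_min <= 1:
        raise ValueError(f"r2_min must lie in (0,1], got {r2_min}")
    by_missing: dict[str, list[ProxyRecord]] = {}
    for p in proxies:
        by_missing.setdefault(p.missing_variant, []).append(p)

    out: list[SummaryAssociation] = []
    log: list[HarmonizationEvent] = []
    for instr in instruments:
        if instr.variant_id in outcome_variants:
            out.append(instr)
            continue
        candidates = [
            p
            for p in by_missing.get(instr.variant_id, [])
            if p.r_squared >= r2_min
        ]
        if not candidates:
            log.append(
                HarmonizationEvent(instr.variant_id, "DROP_NO_PROXY")
            )
            continue
        best = max(candidates, key=lambda p: p.r_squared)
        if set(best.allele_map) != {instr.effect_allele, instr.other_allele}:
            raise DataError(
                f"proxy {best.proxy_variant}: allele_map keys do not match "
                f"alleles of {instr.variant_id}"
            )
        out.append(
            SummaryAssociation(
                variant_id=best.proxy_variant,
                effect_allele=best.allele_map[instr.effect_allele],
                other_allele=best.allele_map[instr.other_allele],
                beta=instr.beta,
                se=instr.se,
                p_value=instr.p_value,
                eaf=instr.eaf,
                n=instr.n,
                trait_id=instr.trait_id,
            )
        )
        log.append(
            HarmonizationEvent(
                instr.variant_id,
                "PROXY_SUBSTITUTED",
                f"proxy={best.proxy_variant} r2={best.r_squared}",
            )
        )
    return out, log


def _alleles_match(a: SummaryAssociation, b: SummaryAssociation) -> str | None:
    """Classify how the outcome record's alleles relate to the exposure's.

    Returns one of ``same`` (effect alleles agree), ``swapped`` (outcome
    effect allele is the exposure other allele), ``flip_same`` /
    ``flip_swapped`` (ditto after complementing the outcome alleles), or
    None when the allele pairs are irreconcilable.
    """
    ea, oa = a.effect_allele, a.other_allele
    if (b.effect_allele, b.other_allele) == (ea, oa):
        return "same"
    if (b.effect_allele, b.other_allele) == (oa, ea):
        return "swapped"
    flipped = (COMPLEMENT[b.effect_allele], COMPLEMENT[b.other_allele])
    if flipped == (ea, oa):
        return "flip_same"
    if flipped == (oa, ea):
        return "flip_swapped"
    return None


def harmonize(
    exposure: list[SummaryAssociation],
    outcome: list[SummaryAssociation],
    palindromic_eaf_window: tuple[float, float] = DEFAULT_PALINDROMIC_WINDOW,
) -> tuple[list[HarmonizedInstrument], list[HarmonizationEvent]]:
    """Pair exposure and outcome records onto the exposure-increasing allele.

    For each variant shared between the two collections:

    * if the outcome effect allele equals the exposure effect allele the
      outcome beta is copied; if it equals the exposure *other* allele the
      outcome beta is negated;
    * if the alleles agree only after a strand flip (A<->T, C<->G) the
      outcome alleles are complemented first and the same rule applied;
    * palindromic variants (A/T or C/G) cannot be strand-resolved from
      alleles alone: they are dropped when the exposure effect-allele
      frequency falls inside ``palindromic_eaf_window`` or is missing,
      otherwise the frequencies on the two sides disambiguate the strand
      (agreeing sides of 0.5 mean same strand);
    * finally any pair with a negative exposure beta has both betas negated
      so every harmonized instrument satisfies ``beta_exposure > 0``.

    Variants with irreconcilable alleles are dropped and logged, never
    silently kept.  The function is idempotent: running it on its own
    output changes nothing.
    """
    lo, hi = palindromic_eaf_window
    out_by_id = {r.variant_id: r for r in outcome}
    harmonized: list[HarmonizedInstrument] = []
    log: list[HarmonizationEvent] = []

    for exp in exposure:
        outc = out_by_id.get(exp.variant_id)
        if outc is None:
            log.append(HarmonizationEvent(exp.variant_id, "DROP_NOT_IN_OUTCOME"))
            continue

        if exp.is_palindromic:
            # Alleles carry no strand information; use allele frequency.
            if (
                exp.eaf is None
                or outc.eaf is None
                or lo < exp.eaf < hi
                or lo < outc.eaf < hi
            ):
                log.append(
                    HarmonizationEvent(
                        exp.variant_id,
                        "DROP_PALINDROMIC_AMBIGUOUS",
                        f"eaf={exp.eaf}",
                    )
                )
                continue
            if {outc.effect_allele, outc.other_allele} != {
                exp.effect_allele,
                exp.other_allele,
            }:
                log.append(
                    HarmonizationEvent(exp.variant_id, "DROP_ALLELE_MISMATCH")
                )
                continue
            # For a palindromic variant the written letter carries no strand
            # information (the same physical allele reads A on one strand and
            # T on the other); only the frequency identifies the allele.
            # Matching sides of 0.5 mean the two effect alleles coincide.
            same_freq_side = (exp.eaf < 0.5) == (outc.eaf < 0.5)
            sign = 1.0 if same_freq_side else -1.0
            if outc.effect_allele != exp.effect_allele or not same_freq_side:
                log.append(
                    HarmonizationEvent(
                        exp.variant_id,
                        "PALINDROMIC_FREQ_RESOLVED",
                        f"sign={sign:+.0f}",
                    )
                )
            beta_outcome = sign * outc.beta
        else:
            relation = _alleles_match(exp, outc)
            if relation is None:
                log.append(
                    HarmonizationEvent(exp.variant_id, "DROP_ALLELE_MISMATCH")
                )
                continue
            if relation.startswith("flip"):
                log.append(HarmonizationEvent(exp.variant_id, "FLIP_STRAND"))
            beta_outcome = (
                outc.beta if relation in ("same", "flip_same") else -outc.beta
            )
            if relation in ("swapped", "flip_swapped"):
                log.append(HarmonizationEvent(exp.variant_id, "SWAP_ALLELES"))

        beta_exposure = exp.beta
        if beta_exposure == 0:
            log.append(HarmonizationEvent(exp.variant_id, "DROP_NULL_EXPOSURE"))
            continue
        if beta_exposure < 0:
            beta_exposure, beta_outcome = -beta_exposure, -beta_outcome
            log.append(HarmonizationEvent(exp.variant_id, "ORIENT_TO_INCREASING"))

        harmonized.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                beta_exposure=beta_exposure,
                se_exposure=exp.se,
                beta_outcome=beta_outcome,
                se_outcome=outc.se,
            )
        )
    return harmonized, log
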
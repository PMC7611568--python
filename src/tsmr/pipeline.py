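"""Orchestration of a full multi-trait MR study from a plan file.

A plan names exposure and outcome summary-statistic files, the methods to
run, thresholds, and which (exposure, outcome-source) groups to pool by
fixed-effects meta-analysis.  ``run_plan`` executes
select -> proxy -> harmonize -> estimate for every exposure-outcome pair
and returns one tidy results table — a row per (exposure, outcome, method)
— plus per-pair diagnostics.  A pair that fails entirely yields a row whose
``notes`` column records the reason; the run always continues.

Sensitivity methods (weighted median, MR-Egger, MR-PRESSO) run whenever
the instrument count permits; the ``sensitivity_triggered`` note records
whether the conventional protocol (run them only when the primary IVW
p < 0.05) would have invoked them, without changing what is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tsmr_io
from .datatypes import ConfigError, EstimationError, MRResult, TsmrError
from .estimators import ivw, mr_egger, wald_ratios, weighted_median
from .harmonize import (
    DEFAULT_PALINDROMIC_WINDOW,
    HarmonizationEvent,
    harmonize,
    select_instruments,
    substitute_proxies,
)
from .meta import fixed_effects_meta, from_mr_result
from .presso import presso_outliers

logger = logging.getLogger(__name__)

VALID_METHODS = ("ivw_fe", "ivw_mre", "weighted_median", "egger", "presso")

RESULT_COLUMNS = [
    "exposure", "outcome", "method", "n_snps", "beta", "se", "or",
    "ci_low", "ci_high", "p", "q", "i_squared", "q_p", "notes",
]


@dataclass(frozen=True)
class ExposureSpec:
    trait_id: str
    path: str
    scale: str = "per_sd"  # or per_logodds


@dataclass(frozen=True)
class OutcomeSpec:
    outcome_id: str
    path: str
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass(frozen=True)
class AnalysisPlan:
    """Declarative description of a study: inputs, methods, thresholds."""

    exposures: tuple[ExposureSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    methods: tuple[str, ...] = VALID_METHODS
    meta_groups: tuple[tuple[str, tuple[str, ...]], ...] = ()
    p_instrument: float = 5e-8
    proxy_r2_min: float = 0.9
    palindromic_window: tuple[float, float] = DEFAULT_PALINDROMIC_WINDOW
    presso_k: int = 1000
    presso_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    exclusion_path: str | None = None
    proxy_path: str | None = None

    def validate(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigError("plan needs at least one exposure and one outcome")
        if not self.methods:
            raise ConfigError("plan methods list is empty")
        unknown = set(self.methods) - set(VALID_METHODS)
        if unknown:
            raise ConfigError(f"unknown methods in plan: {sorted(unknown)}")
        paths = [e.path for e in self.exposures] + [o.path for o in self.outcomes]
        if len(set(paths)) != len(paths):
            raise ConfigError("every exposure/outcome path must be distinct")
        declared = {o.outcome_id for o in self.outcomes}
        for exposure_id, sources in self.meta_groups:
            if exposure_id not in {e.trait_id for e in self.exposures}:
                raise ConfigError(f"meta group references unknown exposure {exposure_id}")
            missing = set(sources) - declared
            if missing:
                raise ConfigError(
                    f"meta group references undeclared outcomes: {sorted(missing)}"
                )


def load_plan(path: str | Path) -> AnalysisPlan:
    """Read a plan from a YAML file and validate it."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        plan = AnalysisPlan(
            exposures=tuple(
                ExposureSpec(
                    trait_id=e["trait_id"],
                    path=e["path"],
                    scale=e.get("scale", "per_sd"),
                )
                for e in raw["exposures"]
            ),
            outcomes=tuple(
                OutcomeSpec(
                    outcome_id=o["outcome_id"],
                    path=o["path"],
                    n_cases=o.get("n_cases"),
                    n_controls=o.get("n_controls"),
                )
                for o in raw["outcomes"]
            ),
            methods=tuple(raw.get("methods", VALID_METHODS)),
            meta_groups=tuple(
                (g["exposure"], tuple(g["outcomes"]))
                for g in raw.get("meta_groups", [])
            ),
            p_instrument=float(raw.get("p_instrument", 5e-8)),
            proxy_r2_min=float(raw.get("proxy_r2_min", 0.9)),
            palindromic_window=tuple(
                raw.get("palindromic_window", DEFAULT_PALINDROMIC_WINDOW)
            ),
            presso_k=int(raw.get("presso_k", 1000)),
            presso_alpha=float(raw.get("presso_alpha", 0.05)),
            n_boot=int(raw.get("n_boot", 1000)),
            seed=int(raw.get("seed", 0)),
            exclusion_path=raw.get("exclusion_list"),
            proxy_path=raw.get("proxy_table"),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed plan ({exc})") from exc
    plan.validate()
    return plan


def _result_row(
    exposure: str, outcome: str, result: MRResult, notes: str = ""
) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": result.method,
        "n_snps": result.n_snps,
        "beta": result.estimate,
        "se": result.se,
        "or": result.odds_ratio,
        "ci_low": result.or_ci[0],
        "ci_high": result.or_ci[1],
        "p": result.p_value,
        "q": result.q_stat,
        "i_squared": result.i_squared,
        "q_p": result.q_p_value,
        "notes": notes,
    }


def _failure_row(exposure: str, outcome: str, method: str, reason: str) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": method,
        "n_snps": 0,
        **{k: math.nan for k in ("beta", "se", "or", "ci_low", "ci_high",
                                 "p", "q", "i_squared", "q_p")},
        "notes": reason,
    }


@dataclass
class PairDiagnostics:
    """Audit trail for one exposure-outcome pair."""

    exposure: str
    outcome: str
    n_selected: int = 0
    n_harmonized: int = 0
    events: list[HarmonizationEvent] = dc_field(default_factory=list)
    outlier_flags: list = dc_field(default_factory=list)


def run_plan(
    plan: AnalysisPlan,
) -> tuple[pd.DataFrame, list[PairDiagnostics]]:
    """Execute the whole plan; returns (tidy results table, diagnostics).

    Deterministic given the plan (bootstrap and simulation seeds derive
    from ``plan.seed`` and the pair's position).  Degenerate pairs (too few
    instruments after harmonization) produce rows with an explanatory note
    for the methods that cannot run, never a crash or a partial table.
    """
    plan.validate()
    exclusion = (
        tsmr_io.read_exclusion_list(plan.exclusion_path)
        if plan.exclusion_path
        else {}
    )
    proxies = (
        tsmr_io.read_proxy_table(plan.proxy_path) if plan.proxy_path else []
    )

    rows: list[dict] = []
    diagnostics: list[PairDiagnostics] = []
    study_cache: dict[tuple[str, str], MRResult] = {}

    for pair_index, (exp_spec, out_spec) in enumerate(
        (e, o) for e in plan.exposures for o in plan.outcomes
    ):
        diag = PairDiagnostics(exp_spec.trait_id, out_spec.outcome_id)
        diagnostics.append(diag)
        pair_seed = plan.seed * 100003 + pair_index
        try:
            exposure = tsmr_io.read_summary_table(exp_spec.path, exp_spec.trait_id)
            outcome = tsmr_io.read_summary_table(out_spec.path, out_spec.outcome_id)
        except TsmrError as exc:
            for method in plan.methods:
                rows.append(
                    _failure_row(
                        exp_spec.trait_id, out_spec.outcome_id, method,
                        f"read_failed: {exc}",
                    )
                )
            continue

        selected = select_instruments(exposure, plan.p_instrument, exclusion)
        diag.n_selected = len(selected)
        if proxies:
            selected, proxy_log = substitute_proxies(
                selected,
                {r.variant_id for r in outcome},
                proxies,
                plan.proxy_r2_min,
            )
            diag.events.extend(proxy_log)

        instruments, harm_log = harmonize(
            selected, outcome, plan.palindromic_window
        )
        diag.events.extend(harm_log)
        diag.n_harmonized = len(instruments)
        for event in harm_log:
            logger.info(
                "%s/%s %s %s %s", exp_spec.trait_id, out_spec.outcome_id,
                event.variant_id, event.code, event.detail,
            )

        j = len(instruments)
        exposure_id, outcome_id = exp_spec.trait_id, out_spec.outcome_id
        if j == 0:
            for method in plan.methods:
                rows.append(
                    _failure_row(exposure_id, outcome_id, method,
                                 "no_instruments_after_harmonization")
                )
            continue

        ratios = wald_ratios(instruments)
        primary_p = math.nan
        scale_note = f"scale={exp_spec.scale}"

        # primary IVW rows first so the sensitivity trigger can be recorded
        if "ivw_mre" in plan.methods or "ivw_fe" in plan.methods:
            mre = ivw(ratios, model="multiplicative_random")
            primary_p = mre.p_value
        trigger = (
            "sensitivity_triggered=yes"
            if not math.isnan(primary_p) and primary_p < 0.05
            else "sensitivity_triggered=no"
        )

        for method in plan.methods:
            try:
                if method == "ivw_fe":
                    rows.append(_result_row(
                        exposure_id, outcome_id,
                        ivw(ratios, model="fixed"), scale_note,
                    ))
                elif method == "ivw_mre":
                    rows.append(_result_row(
                        exposure_id, outcome_id, mre,
                        f"{scale_note};primary",
                    ))
                elif method == "weighted_median":
                    rows.append(_result_row(
                        exposure_id, outcome_id,
                        weighted_median(
                            ratios, n_boot=plan.n_boot, seed=pair_seed
                        ),
                        f"{scale_note};{trigger}",
                    ))
                elif method == "egger":
                    slope, intercept = mr_egger(instruments)
                    rows.append(_result_row(
                        exposure_id, outcome_id, slope,
                        f"{scale_note};{trigger}",
                    ))
                    rows.append(_result_row(
                        exposure_id, outcome_id, intercept,
                        f"{scale_note};{trigger}",
                    ))
                elif method == "presso":
                    report = presso_outliers(
                        instruments,
                        k_sims=plan.presso_k,
                        alpha=plan.presso_alpha,
                        seed=pair_seed,
                    )
                    diag.outlier_flags = list(report.outliers)
                    presso_note = (
                        f"{scale_note};{trigger};global_p={report.global_p:.4g}"
                        f";n_outliers={report.n_outliers}"
                    )
                    rows.append(_result_row(
                        exposure_id, outcome_id, report.raw_result, presso_note,
                    ))
                    rows.append(_result_row(
                        exposure_id, outcome_id, report.corrected_result,
                        presso_note + (
                            f";distortion_p={report.distortion_p:.4g}"
                            if report.distortion_p is not None else ""
                        ),
                    ))
            except (EstimationError, ValueError) as exc:
                rows.append(_failure_row(exposure_id, outcome_id, method, str(exc)))

        if not math.isnan(primary_p):
            study_cache[(exposure_id, outcome_id)] = mre

    # meta-analysis stage: pool the primary IVW rows across outcome sources
    for exposure_id, sources in plan.meta_groups:
        studies = [
            from_mr_result(study_cache[(exposure_id, s)], label=s)
            for s in sources
            if (exposure_id, s) in study_cache
        ]
        if len(studies) < 2:
            rows.append(_failure_row(
                exposure_id, "+".join(sources), "meta_fixed",
                "fewer_than_two_poolable_sources",
            ))
            continue
        pooled = fixed_effects_meta(studies)
        rows.append(_result_row(
            exposure_id, "+".join(sources), pooled,
            f"pooled_sources={len(studies)}",
        ))

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return table, diagnostics


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy results table, full precision, tab-delimited."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
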
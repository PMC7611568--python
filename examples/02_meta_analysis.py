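"""Pool per-source odds ratios by fixed-effects meta-analysis.

Starts from the kind of numbers a results table prints — an odds ratio
with its 95% confidence interval per data source — back-transforms each
to the log scale, and pools.  The rows below are the breast-cancer
estimates per standard deviation of thyroid-stimulating hormone from a
consortium GWAS and a population biobank.
"""

from tsmr import ci_to_se, fixed_effects_meta

studies = [
    ci_to_se(0.95, 0.90, 1.00, label="consortium"),
    ci_to_se(0.93, 0.86, 1.00, label="biobank"),
]
for s in studies:
    print(f"{s.label:>10}: OR {s.odds_ratio:.2f} "
          f"(log OR {s.log_or:+.4f}, se {s.se_log_or:.4f})")

pooled = fixed_effects_meta(studies)
lo, hi = pooled.or_ci
print(f"\npooled OR {pooled.odds_ratio:.4f} (95% CI {lo:.4f} to {hi:.4f}), "
      f"p = {pooled.p_value:.4f}")
print(f"heterogeneity: Q = {pooled.q_stat:.3f}, I^2 = {pooled.i_squared:.1f}%")
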
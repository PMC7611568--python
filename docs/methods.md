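# Methods note

This note records the statistical model behind `tsmr`, the default value
of every tunable parameter and why it has that value, what the synthetic
generator does and does not emulate, and the numerical conventions that
matter for reproducing results to the last digit. Empirical statements
about estimator behaviour refer to quantities computed by the test suite
or by `scripts/acceptance.py`; nothing here is asserted from memory.

## 1. Model

For variant *j*, two independent GWAS provide the variant–exposure
association β̂_Xj ~ N(β_Xj, σ²_Xj) and the variant–outcome association
β̂_Yj ~ N(Γ_j, σ²_Yj). Under the instrumental-variable assumptions
(relevance, exchangeability, exclusion restriction),

  Γ_j = θ β_Xj,

with θ the causal effect of one exposure unit on the outcome — a
log-odds difference when the outcome GWAS is case-control. Horizontal
pleiotropy adds a direct effect α_j: Γ_j = θ β_Xj + α_j. Instrument *j*
is *invalid* when α_j ≠ 0.

### Wald ratio

θ̂_j = β̂_Yj / β̂_Xj. The default first-order delta-method standard
error is σ_Yj / |β̂_Xj|; the second-order option adds the term
β̂²_Yj σ²_Xj / β̂⁴_Xj, which matters only for weak instruments and is
off by default because the instruments this design admits are strong.

### IVW

With weights w_j = σ_j^{-2} on the ratios, the fixed-effects estimate is
θ̂ = Σw_jθ̂_j / Σw_j with se (Σw_j)^{-1/2}; identical to zero-intercept
weighted least squares of β̂_Y on β̂_X with weights σ_Y^{-2} (the test
suite asserts this equivalence against statsmodels WLS). Heterogeneity:
Cochran's Q = Σw_j(θ̂_j − θ̂)², I² = max(0, (Q − (J−1))/Q)·100. The
multiplicative-random-effects (MRE) standard error inflates the fixed se
by max(1, √(Q/(J−1))) — floored at 1 so random effects can never be
*anti*-conservative, the standard convention.

### Weighted median

Ratios are sorted by θ̂ (ties broken lexicographically by variant id for
determinism); with normalized weights w'_j, positions p_j = S_j − w'_j/2
(S_j the cumulative weight) define a piecewise-linear quantile function
evaluated at 0.5 by `np.interp`; outside the range of p the nearest
order statistic is returned. The standard error is a parametric
bootstrap (resample β̂_X, β̂_Y from their normal sampling
distributions, recompute the median), default 1000 draws — enough for a
bootstrap se to stabilize to ~2% relative error; the estimate itself is
deterministic. The estimator is consistent while valid instruments hold
> 50% of the total weight.

### MR-Egger

Weighted least squares of β̂_Y on β̂_X *with* intercept, weights
σ_Y^{-2}, after orienting all β̂_X > 0 (done once, at harmonization).
The intercept estimates the mean directional-pleiotropy effect; the
slope is consistent for θ when instrument strength is independent of
pleiotropy (the InSIDE assumption). Residual overdispersion is absorbed
by the scale max(1, RSS/(J−2)) and inference uses a t reference with
J − 2 degrees of freedom, both per the original method.

### MR-PRESSO

Residual sum of squares where each variant's prediction uses the
leave-one-out IVW slope θ̂_{−j}. The null distribution comes from K
parametric simulations: β*_X ~ N(β̂_X, σ_X), β*_Y ~ N(θ̂_{−j} β̂_X,
σ_Y). The global p-value uses the add-one convention (1+b)/(K+1), so its
floor is 1/(K+1). The **per-variant** p-value deliberately drops the
add-one correction (p_j = b_j/K): with J ≈ 50 instruments at K = 1000, a
floor of 1/1001 would make the Bonferroni-adjusted threshold
p_j · J < α unreachable and no outlier could ever be flagged. Variants
with p_j · J < α (default α = 0.05) are removed; the corrected estimate
is IVW on the remainder. The distortion test compares the raw-minus-
corrected shift against shifts from deleting equally many variants drawn
at random from the unflagged set. K defaults to 1000: the smallest round
K giving the global test a floor below 10⁻³.

### Fixed-effects meta-analysis

Published per-source rows `OR (CI_low, CI_high)` are back-transformed by
log; se = (ln CI_high − ln CI_low) / (2 × 1.959964). Pooling is inverse-
variance on the log-OR scale; Q and I² across sources are reported. A
warning is emitted when a CI is asymmetric on the log scale by more than
0.2 se — the signature of rounded published inputs, which propagates
roughly ±0.01 into a two-source pooled OR.

## 2. Harmonization rules

Matching outcome records to exposure instruments by variant id, in
order: exact allele match → keep; alleles exchanged → swap (negate β,
mirror eaf); alleles are strand complements (A↔T, C↔G) → flip letters;
complement-of-swap → both. Anything else is a mismatch and drops.

Palindromic variants (A/T or C/G pairs) are the special case: the
written letters carry no strand information at all, so only the effect
allele frequency can align the two files. The records agree when both
effect-allele frequencies fall on the same side of 0.5, otherwise the
outcome β is negated. When either frequency lies inside (0.42, 0.58) —
or is missing — the side of 0.5 is not trustworthy and the variant is
dropped. The 0.42/0.58 window is the conventional ambiguity band in
published MR pipelines; it is configurable per plan.

Finally every instrument is oriented so β_X > 0 (required for Egger,
harmless elsewhere), and instruments with β_X = 0 are dropped as
uninformative.

Selection defaults: instrument p-value < 5×10⁻⁸ (genome-wide
significance; binary exposures often need a relaxed threshold, which the
plan exposes), optional exclusion list (e.g. known pleiotropic loci),
optional LD-proxy substitution accepting the best proxy with r² ≥ 0.9 —
high enough that the proxy's effect is essentially the index variant's.

## 3. The synthetic generator

`SimulationConfig` defaults describe a strong continuous-exposure
instrument set:

- `n_snps = 60` — the order of instruments a well-powered hormone GWAS
  yields after LD pruning.
- `gamma_sd = 0.03`, `gamma_floor = 0.01`: true effects
  γ_j = |N(0, 0.03)| + 0.01 SD per allele, mean ≈ 0.034.
- `se_exposure_range = (0.0025, 0.0045)` (uniform): with the γ above,
  mean instrument strength |γ|/σ_X ≈ 10 (per-variant F ≈ 100),
  matching an exposure GWAS of roughly 70k samples.
- `se_outcome_range = (0.01, 0.02)`: the log-OR precision of a
  case-control GWAS with on the order of 10⁵ cases.
- Pleiotropy modes: `none`; `balanced` (α ~ N(0, α_sd), InSIDE holds);
  `directional` (α ~ N(α_mean, α_sd) for an `invalid_fraction` of
  variants); `inside_violated` (α correlated with γ). Outliers: chosen
  indices get Γ shifted by `outlier_shift` × that variant's σ_Y.
- `palindromic_fraction` controls how many variants get A/T or C/G
  allele pairs; observed eafs are drawn so a share of them falls in the
  ambiguity window.
- The `binary_exposure` preset (8 instruments, γ on the log-odds scale
  with sd 0.15 and floor 0.05, σ_X in 0.015–0.03) mirrors a disease
  exposure such as hypo- or hyperthyroidism: few instruments, larger
  effects, noisier first-stage estimates.

Observed β̂ are drawn normal around truth; p-values are exact
two-sided normal. Randomness flows through
`numpy.random.SeedSequence(seed, spawn_key=keys)`, so replicate r of
study s is an independent, individually reproducible stream.

What the generator does **not** emulate: LD between instruments
(draws are independent), sample overlap between the two GWAS (the
two-sample assumption is exact here), winner's curse in instrument
selection, allele-frequency-dependent power, and non-normal effect-size
distributions.

## 4. Numerical conventions

- 95% intervals use z = 1.959964 everywhere a normal reference applies;
  Egger uses t with J − 2 df.
- Ratio-space computations sort by variant id before any accumulation,
  making results independent of input file order (asserted by a
  property-based test).
- TSV output is written with fixed float formats (`%.17g` for data
  files, `%.10g` for result tables), making byte-identical reruns a
  meaningful test.
- All stochastic components (bootstrap, MR-PRESSO, simulator) accept
  either a seed or a `numpy` Generator and are deterministic given one.

## 5. Weak-instrument attenuation — a known, quantified bias

Regression-dilution bias attenuates slope-style estimators when β̂_X is
noisy. For IVW the expected multiplicative attenuation is roughly
E[σ²_X]/E[γ²] ≈ 0.9% under the default generator — at θ = 0.1 a bias of
order −0.001, which sits inside the two-Monte-Carlo-SE band of a
1000-replicate recovery study. MR-Egger is hit harder: its dilution is
governed by the *spread* of instrument strengths (the I²_GX statistic,
≈ 0.96 here), giving ≈ 4–6% slope attenuation, about −0.006 at θ = 0.1.
That exceeds the 2·MC-SE bound (≈ 0.0065 at 1000 replicates but
centred on the attenuated mean), so the Egger θ = 0.1 recovery check
fails at the committed seed and is left failing: the bias is a real
property of the estimator at this instrument strength, not a defect to
tune away. The measured biases are emitted by `scripts/acceptance.py`
(`egger_slope_bias_theta_0p1`, `ivw_bias_theta_0p1`) for any seed.

## 6. Limitations

- Proxy substitution trusts the supplied r² and allele map; no LD
  reference panel is bundled.
- The weighted-median bootstrap is parametric, not resampling-based;
  with very few instruments its se is optimistic.
- MR-PRESSO's corrected estimate conditions on the outlier search; its
  nominal se does not account for the selection step (the distortion
  test is the designed guard).
- Fixed-effects meta-analysis only; with two sources a random-effects
  variant is barely identified and is deliberately not offered.
- The generator's independence assumptions (section 3) mean coverage
  and bias results transfer to real data only to the extent those
  assumptions hold there.
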
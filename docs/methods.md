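# Methods

## Model and procedure

contrastkit tests directional hypotheses about the pattern of condition
means in a K-condition experiment. A hypothesis is encoded as contrast
weights λ with Σλᵢ = 0, usually derived from a predicted mean pattern by
subtracting its grand mean (`weights_from_pattern`; an optional positive
scale factor yields round numbers and never changes the inference — t, p,
and all correlation-style effect sizes are invariant under λ → cλ, c > 0).

**Between subjects.** With group means x̄ᵢ, variances σ̂ᵢ², sizes nᵢ:

- L = Σ λᵢ x̄ᵢ; σ̂_L = sqrt(σ̂²_within Σ λᵢ²/nᵢ); t = L/σ̂_L on N − K df.
- SS_contrast = L² / Σ(λᵢ²/nᵢ) on 1 df, F = SS_contrast/σ̂²_within = t².
- Assumptions: independent observations, normal errors, homoscedastic
  groups (a common within-group variance pools across conditions).

**Within subjects.** Each subject's measurements collapse to
Lᵢ = Σⱼ λⱼ xᵢⱼ and the test is a one-sample t of the Lᵢ on N − 1 df with
σ̂²_L the n−1 sample variance. Because Σλⱼ = 0, any subject-level constant
cancels from Lᵢ, so between-subject heterogeneity is absorbed without being
modelled; no sphericity assumption is needed beyond normality of the Lᵢ.

**Competing contrasts.** Rival hypotheses are compared by testing
λ_diff = λ*_favored − λ*_rival, where λ* = λ/s_λ and s_λ = sqrt(Σλᵢ²/K).
Standardization uses the population (divide-by-K) form throughout, never
K−1; without it the hypothesis with larger absolute weights would dominate
the difference. The test is directional: positive t favors the favored
pattern; swapping the hypotheses negates L and t exactly. Proportional
rivals leave a zero difference vector (detected at ‖λ_diff‖ < 1e−10·K) and
raise an error rather than a vacuous test.

## Error term for independent samples

Two pooled-variance estimators are offered. `df_weighted` (default) is the
classical ANOVA mean squared error Σ(nᵢ−1)σ̂ᵢ²/(N−K); `unweighted` is the
plain mean of the group variances Σσ̂ᵢ²/K. They coincide exactly for
balanced designs (all worked examples here are balanced); for unbalanced
data the df-weighted form is the standard generalization, while the
unweighted form reproduces the hand-calculation convention some texts use.

## Effect sizes

- `r_alerting`: Pearson correlation between the K weights and the K group
  means; the group-level fit of the prediction, and an upper bound on
  |r_effectsize|.
- `r_effectsize` = sign(L)·sqrt(SS_contrast/SS_total). Needs SS_total, so
  it is only reported when individual-level data are supplied (it is `None`
  from summaries).
- `r_contrast` = sign(t)·sqrt(t²/(t²+df)); for K = 2 this reduces to the
  point-biserial correlation. It is the quantity fed to the between-design
  power solver.
- `g_contrast` (within only) = L̄/s_L, the standardized mean of the
  per-subject contrast scores — scale-invariant in the weights and an
  estimate of Cohen's d for the paired power solver. There is no universal
  convention for this quantity; this definition is chosen precisely because
  it plugs into the noncentral-t power machinery unchanged.

Effect sizes carry the sign of the association (correlation convention).

## Power solvers

- Between: power of the test of ρ = 0 via the bias-corrected Fisher-z
  approximation — z_r = atanh(r) + r/(2(n−1)), critical r from the central
  t quantile at df = n−2, power = Φ((z_r − atanh(r_c))√(n−3)); two-tailed
  tests use α/2 and add the opposite rejection region. The solved n is
  rounded up to a multiple of K so conditions stay balanced; the ceiling
  also absorbs the ±1–2 disagreement this approximation can have with exact
  methods. Reference plan: r = .45, power .80, α = .05 one-tailed, K = 4 →
  raw n = 29 → 32 total, 8 per condition.
- Within: exact noncentral-t power, df = n−1, noncentrality d√n.
  Reference plan: d = 0.8, power .95, one-tailed → n = 19.
- Both searches are integer-only (bracket doubling then bisection, cap
  10⁷), so the returned n satisfies power(n) ≥ target > power(n−1).
- Guidance: if only r_effectsize is available, using it as r_contrast is
  conservative (they coincide when r_alerting = 1).

## Synthetic data generator

`generate(SyntheticSpec)` draws homoscedastic normal data — the implicit
model of the t/F machinery above. Between designs are independent
N(μᵢ, σ²) groups. Within designs use compound symmetry: a subject intercept
with variance ρσ² plus residuals with variance (1−ρ)σ², so every condition
has variance σ² and every pair of a subject's measurements correlates at ρ.
Generation is bit-reproducible under the spec's required seed.

What it does *not* emulate: heteroscedastic groups, skewed or heavy-tailed
errors, unequal pairwise correlations (sphericity violations), missing
data, or bounded DVs such as proportions near 0/1. Passing tests therefore
certify the arithmetic and the calibration of the tests *under the model's
own assumptions*, not robustness to their violation.

`moment_matched_sample` affinely rescales a normal draw so its sample mean
and n−1 variance hit published summary statistics to machine precision,
letting raw-data code paths be exercised against summary-level fixtures.

## Numerical choices

- Zero-sum validation: |Σλᵢ| ≤ 1e−8 · max(1, max|λᵢ|). Violations are
  rejected, not auto-centered — silent centering would mask typos in
  hand-entered weights. (`weights_from_pattern` centers by construction.)
- Weights bind to condition labels, and every analysis re-aligns them to
  the data's labels, erroring on mismatch; condition order follows first
  appearance in the input, so re-sorted files cannot permute a hypothesis.
- Degenerate inputs raise typed errors rather than returning inf/nan:
  zero pooled variance, constant per-subject contrast scores, constant
  predicted patterns, identical rivals, n < 2 per group.
- Incomplete subjects in repeated measures are a hard error by default;
  `drop_incomplete=True` removes them with a warning (listwise deletion
  changes df and should never be silent).
- Display rounding (CLI text reports): 2 decimals for weights and t,
  3 for L and variances; JSON output is full precision.

## Problem sizes used in validation

The bundled worked examples are desk-scale (K = 3 groups of 40 summary
statistics; a 4×3 within-subjects table) and run in milliseconds. The
Monte-Carlo checks use 5,000 replicate null experiments for the type-I
error calibration (99.7% binomial band around α = .05) and 50,000
replicates for each power-formula oracle (agreement within ±0.01), sizes at
which binomial noise is well below the tolerances being asserted.

## Known limitations

- No Welch-type heteroscedastic contrast test and no robust/trimmed
  variants; with strongly unequal variances the pooled error term is
  anticonservative for contrasts weighting the noisier groups.
- No mixed between×within designs and no sphericity corrections (the
  L-score reduction sidesteps sphericity for a single contrast but does not
  generalize to families of contrasts tested jointly).
- The correlation-power routine is an approximation; its raw n can differ
  by 1–2 from exact-distribution methods before the per-condition ceiling.
- Power for competing contrasts under a specified rival truth is not
  solved analytically; use the synthetic generator to simulate it.
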
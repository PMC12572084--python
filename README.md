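# contrastkit

Planned-contrast and competing-contrast analysis for multi-condition
experiments, with contrast effect sizes and matching power/sample-size
solvers. Built for experimental researchers (psychology, cognitive science,
behavioral biology) who have a *directional, a priori* hypothesis about the
pattern of condition means and want one focused test instead of an omnibus
ANOVA followed by post-hoc comparisons.

## The method

A contrast encodes a predicted mean pattern as weights
λ = (λ₁, …, λ_K) with Σλᵢ = 0. For independent groups the contrast estimate
is the weighted sum of the observed condition means,

    L = Σ λᵢ x̄ᵢ,    t = L / σ̂_L,    σ̂_L = sqrt(σ̂²_within · Σ λᵢ²/nᵢ),

referred to a central t distribution with N − K degrees of freedom
(one-tailed: a positive t supports the stated pattern). The companion F
table carries SS_contrast = L² / Σ(λᵢ²/nᵢ) on one degree of freedom, so
F = t². For repeated measures, each subject's J measurements collapse to a
single score Lᵢ = Σⱼ λⱼ xᵢⱼ — the zero-sum weights cancel each subject's
overall level — and t = L̄ / sqrt(σ̂²_L / N) on N − 1 degrees of freedom.

**Competing contrasts.** Two rival predicted patterns can be tested against
each other directly: standardize each weight vector to unit root-mean-square
(λ* = λ / s_λ, s_λ = sqrt(Σλᵢ²/K)), subtract, and test the difference
λ_diff = λ*_favored − λ*_rival as a contrast of its own. A significantly
positive t means the favored pattern covaries more strongly with the
observed means than the rival does.

**Effect sizes.** r_alerting (correlation of weights with group means),
r_effectsize (= sign(L)·sqrt(SS_contrast/SS_total), needs raw data),
r_contrast (= sign(t)·sqrt(t²/(t²+df))) for between designs; r_contrast and
g_contrast (= L̄/s_L, a Cohen's-d estimate) for within designs.

**Power.** Between designs are planned via r_contrast as a correlation-test
effect size (bias-corrected Fisher-z approximation, result rounded up to a
multiple of K for balance); within designs via g_contrast as d in an exact
noncentral-t paired test.

## Worked example

```python
import contrastkit as ck

summaries = ck.load_fixture("maraver_summaries")   # 3 conditions, n=40 each
hyp1 = ck.ContrastWeights.from_mapping(
    {"imagine": 1.0, "memorize": -0.5, "pay attention": -0.5}
)
res = ck.between_contrast_test(summaries, hyp1, mse_method="unweighted")
print(round(res.l_estimate, 3), round(res.t, 2), res.df)
```

prints `0.189 7.41 117`: the imagine condition exceeds the average of the
two control conditions by 0.189 (proportion correct), and the directional
test is highly significant. Comparing this hypothesis against the rival
"strictly decreasing" pattern (1, 0, −1):

```python
hyp2 = ck.ContrastWeights.from_mapping(
    {"imagine": 1.0, "memorize": 0.0, "pay attention": -1.0}
)
cmp = ck.compare_hypotheses_between(summaries, hyp1, hyp2, mse_method="unweighted")
print(round(cmp.l_estimate, 3), round(cmp.t, 2))
```

prints `0.066 3.56`: the favored pattern fits significantly better. The
same analyses are available from the shell:

```sh
contrastkit between --fixture maraver_summaries \
    --weights "imagine=1,memorize=-0.5,pay attention=-0.5"
contrastkit lambda-diff --favored "1,-0.5,-0.5" --rival "1,0,-1"
contrastkit within --fixture akan_toy \
    --weights "testing=1,restudying=-0.5,control=-0.5"
contrastkit power between --r .45 --power .80 --k 4   # -> 32 total, 8 per condition
contrastkit power within --d .8 --power .95           # -> n = 19
```

The `examples/` directory holds short narrative scripts, one per
capability (between, competing, within, power, simulation).

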
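"""Simulate a repeated-measures experiment and recover the planted effect.

The generator draws homoscedastic normal data with compound symmetry: every
condition has variance sd^2 and every pair of a subject's measurements
correlates at rho.  Condition means are set proportional to the
(standardized) contrast weights, so the contrast is exactly the direction of
the planted effect.
"""

import contrastkit as ck

labels = ("testing", "restudying", "control")
w = ck.validate_weights(labels, (1, -0.5, -0.5)).standardized()
delta = 0.5  # planted standardized pattern strength

spec = ck.SyntheticSpec(
    labels=labels,
    condition_means=tuple(delta * v for v in w.lam),
    within_group_sd=1.0,
    n_per_group=40,
    design="within",
    icc_rho=0.5,
    seed=2026,
)
data = ck.generate(spec)
print(f"simulated {spec.n_per_group} subjects x {len(labels)} conditions "
      f"(rho = {spec.icc_rho}, seed = {spec.seed})")

m = ck.WithinMatrix.from_long(data)
res = ck.within_contrast_test(m, w)
print(f"L_bar = {res.l_bar:.3f}, t({res.df}) = {res.t:.2f}, "
      f"one-tailed p = {res.p_one_tailed:.2g}")
print(f"g_contrast = {res.g_contrast:.2f}")
print()
print(
    "With a planted pattern of strength 0.5 the directional test should\n"
    "usually reject; rerun with delta = 0 to watch the rejection rate fall\n"
    "to the nominal 5% level."
)
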
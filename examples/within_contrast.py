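"""Within-subjects contrast analysis on a four-participant toy dataset.

Each participant contributes one value per condition (testing, restudying,
control; DV = correctly selected contexts).  The contrast collapses every
row to a single score L_i = sum(lambda_j * x_ij); because the weights sum to
zero, each subject's overall level cancels, and the test is a one-sample t
test of the L_i against zero on N-1 degrees of freedom.
"""

import contrastkit as ck

toy = ck.load_fixture("akan_toy")
w = ck.ContrastWeights.from_mapping(
    {"testing": 1.0, "restudying": -0.5, "control": -0.5}
)

res = ck.within_contrast_test(toy, w)
for sid, L in zip(toy.subject_ids, res.l_scores):
    print(f"participant {sid}: L = {L:5.1f}")
print(f"\nL_bar      = {res.l_bar:.2f}")
print(f"sigma^2_L  = {res.sigma2_l:.2f}")
print(f"t({res.df})  = {res.t:.2f}, one-tailed p = {res.p_one_tailed:.3f}")
print(f"g_contrast = {res.g_contrast:.2f}  (Cohen's-d-style effect size)")
print(f"critical t({res.df}) at alpha=.05, one-tailed: "
      f"{ck.critical_t(res.df, 0.05, 'one'):.2f}")
print()
print(
    "With only four participants |t| stays below the critical value, so\n"
    "the null is retained — the toy data alone cannot establish the\n"
    "predicted advantage of the testing condition."
)
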
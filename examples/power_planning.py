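"""Sample-size planning for contrast analyses.

Between-subjects designs are planned through r_contrast, treated as the
effect size of a correlation test (bias-corrected Fisher-z power).  Within-
subjects designs are planned through g_contrast as a Cohen's d in a paired
t test (exact noncentral-t power).
"""

import contrastkit as ck

between = ck.required_n_between(
    ck.PowerSpec(effect=0.45, design="between", alpha=0.05,
                 target_power=0.80, tails="one", k=4)
)
print(
    f"between: r_contrast = .45, power .80, one-tailed, K = 4 conditions\n"
    f"  raw n = {between.n_raw}, balanced total = {between.n_total} "
    f"({between.n_per_condition} per condition), "
    f"achieved power = {between.achieved_power:.3f}"
)

within = ck.required_n_within(
    ck.PowerSpec(effect=0.8, design="within", alpha=0.05,
                 target_power=0.95, tails="one")
)
print(
    f"within:  d = 0.8, power .95, one-tailed\n"
    f"  n = {within.n_total} subjects, "
    f"achieved power = {within.achieved_power:.3f}"
)
print()
print(
    "The between plan rounds the raw solution up to a multiple of K so the\n"
    "design stays balanced.  If only r_effectsize is known, using it in\n"
    "place of r_contrast yields a conservative (larger) plan."
)
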
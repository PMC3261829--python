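"""Exhaustive permutation test of trial eligibility.

Every with-replacement composition of the observed panel (C(2n-1, n)
multisets) is pooled and classified; the p-value for the null hypothesis
"do not recruit" is the exact fraction of compositions outside the
equipoise region.  A case is eligible at the 5% level when p < 0.05.
"""

import equipoise as eq

panels = eq.heel_fracture_panels()

for rule, name in [(eq.heel_trial_rule(), "80:20 (e=8/14)"),
                   (eq.mean_threshold(), "mean threshold")]:
    print(f"--- {name} ---")
    for cid in panels.case_ids:
        fits = eq.fit_case(panels.for_case(cid), panels.scale)
        res = eq.permutation_test(fits, rule, level=0.05, case_id=cid)
        print(f"{cid}: belief={res.counts['belief']:>3} "
              f"disbelief={res.counts['disbelief']:>3} of {res.total:>3}  "
              f"p={res.p_value_fraction} = {res.p_value:.3f}  "
              f"eligible={res.eligible}")

# Case 1 (experts disagree widely) stays recruitable under both rules;
# case 4 (unanimous disbelief in surgery) is never recruitable (p = 1).
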
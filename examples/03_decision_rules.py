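"""Classify pooled opinions against the 80:20 and mean-threshold rules.

The 80:20 rule disturbs equipoise once more than 80% of the pooled
probability mass lies on one side of the equipoise point (8/14 here,
because surgery is an active intervention).  The mean-threshold rule keeps
equipoise while the pooled mean effectiveness stays in [0.4, 0.7].
"""

import equipoise as eq

panels = eq.heel_fracture_panels()
rule_8020 = eq.heel_trial_rule()           # 80:20 at e = 8/14
rule_mean = eq.mean_threshold()            # equipoise iff 0.4 <= mu <= 0.7

for cid in panels.case_ids:
    pooled = eq.pool_beta(eq.fit_case(panels.for_case(cid), panels.scale))
    r1 = eq.classify(pooled.alpha_bar, pooled.beta_bar, rule_8020)
    r2 = eq.classify(pooled.alpha_bar, pooled.beta_bar, rule_mean)
    print(f"{cid}: mean={pooled.mean:.3f}  80:20 -> {r1}  mean-threshold -> {r2}")

# The rules draw boundaries in the ternary opinion space; the upper
# mean-threshold boundary runs from (b,d,u) = (0.7, 0.3, 0) on the base to
# (4/7, 0, 3/7) on the right edge:
boundary = eq.trace_boundary_mean(0.7)
print("mu=0.7 boundary endpoints:",
      tuple(round(v, 4) for v in boundary.start),
      tuple(round(v, 4) for v in boundary.end))
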
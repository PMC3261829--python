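"""Render the ternary opinion space with rule boundaries and opinion clouds.

Each case's resampled opinions form a cloud whose spread reflects expert
disagreement; the large marker is the pooled panel opinion.  Writes
opinion_space.svg next to this script.
"""

from pathlib import Path

import equipoise as eq

panels = eq.heel_fracture_panels()
points = []
for cid in panels.case_ids:
    fits = eq.fit_case(panels.for_case(cid), panels.scale)
    points += [(op, cid) for _, op in eq.resample_opinions(fits)]

pooled1 = eq.pool_beta(eq.fit_case(panels.for_case("case1"), panels.scale))
out = Path(__file__).with_name("opinion_space.svg")
eq.plot_opinion_space(
    points,
    rules=[eq.heel_trial_rule(), eq.mean_threshold()],
    highlight=eq.opinion_from_beta(pooled1.alpha_bar, pooled1.beta_bar),
    out=out,
)
print(f"wrote {out}")
print("disbelief is the left vertex, belief the right, uncertainty the apex;")
print("clouds crossing a dashed boundary contain non-equipoise compositions.")
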
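"""Fit per-expert Beta distributions and pool a panel multiplicatively.

Each expert's percentage assessment over the seven-category effectiveness
scale is fitted by constrained weighted maximum likelihood (both shapes
>= 1); the panel is pooled by averaging shapes, which is the exact form of
the normalised geometric-mean density.
"""

import equipoise as eq

panels = eq.heel_fracture_panels()

for cid in panels.case_ids:
    fits = eq.fit_case(panels.for_case(cid), panels.scale)
    pooled = eq.pool_beta(fits)
    op = eq.opinion_from_beta(pooled.alpha_bar, pooled.beta_bar)
    print(f"{cid}: pooled Beta({pooled.alpha_bar:.2f}, {pooled.beta_bar:.2f})  "
          f"opinion b={op.belief:.3f} d={op.disbelief:.3f} u={op.uncertainty:.3f}")

# alpha_bar >> beta_bar means the panel collectively believes the surgery
# helps (case 2); beta_bar >> alpha_bar means collective disbelief (case 4);
# shapes near (1, 1) mean the panel is mostly uncertain (case 3).
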
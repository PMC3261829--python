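"""Distribution-free opinions from weighted moments.

The moment route needs no Beta assumption: uncertainty is the variance of
the assessment relative to the maximum possible at its mean,
u = sigma^2 / (mu (1 - mu)), and belief/disbelief split the remainder in
proportion to the mean.
"""

import equipoise as eq

panels = eq.heel_fracture_panels()

# A single symmetric, mid-spread expert: mu = 0.5, sigma = 0.226.
expert = panels.for_case("case3")[3]
m = eq.weighted_moments(expert, panels.scale)
op = eq.opinion_from_moments(m)
print(f"single expert: mu={m.mu:.3f} sigma={m.sigma:.3f} -> "
      f"u={op.uncertainty:.3f}, b=d={op.belief:.3f}")

# Pool a whole panel: per-category geometric mean of the raw weights
# (zeros propagate — the pooled panel supports only categories every
# expert gave some weight to).
weights, pooled_op = eq.pool_nonparametric(panels.for_case("case2"), panels.scale)
print("case2 pooled weights:", [round(float(w), 3) for w in weights])
print(f"case2 pooled opinion: b={pooled_op.belief:.3f} "
      f"d={pooled_op.disbelief:.3f} u={pooled_op.uncertainty:.3f}")
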
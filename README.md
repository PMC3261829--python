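# equipoise

Quantifying clinical (collective) equipoise from panels of expert
assessments, to decide whether a patient is eligible for recruitment to a
randomised controlled trial.

Recruiting to surgical trials is hard: individual clinicians often hold
strong preferences, but the ethical precondition for randomisation is
*collective* equipoise — genuine uncertainty in the wider expert community
about which of two treatments is better. This package implements a
statistical pipeline for that judgement. A panel of experts each assign
percentage weights over an ordered effectiveness scale (seven categories
from "much worse" to "much better" in the motivating heel-fracture trial,
which compared operative against conservative treatment); the pipeline
turns those assessments into a single pooled *opinion* and an exact
eligibility test.

## The model

Category `k` of a K-point scale maps to the midpoint `(2k−1)/(2K)` of the
unit interval. Each expert's weights are modelled as a Beta(α, β) density
with α, β ≥ 1 (unimodal or uniform), fitted by maximising the weighted
log-likelihood Σₖ (wₖ/100) · log f(mₖ; α, β). The panel is pooled
multiplicatively — the normalised geometric mean of the member densities,
representing the intersection of the experts' beliefs — which for Beta
members is again Beta with the arithmetic-mean shapes (ᾱ, β̄). Pooled
shapes map to a subjective-logic opinion triplet

    b = (ᾱ−1)/(ᾱ+β̄−1),   d = (β̄−1)/(ᾱ+β̄−1),   u = 1/(ᾱ+β̄−1),

belief, disbelief and uncertainty, with b + d + u = 1. A distribution-free
alternative uses weighted moments directly: u = σ²/(μ(1−μ)),
b = μ(1−u), d = (1−μ)(1−u).

Opinions live on the 2-simplex, drawn as a ternary plot (disbelief left,
belief right, uncertainty at the apex). Decision rules partition this
opinion space: the **80:20 rule** ends equipoise once more than 80% of the
pooled mass lies on one side of the equipoise point e (e = 8/14 when one
arm is an active intervention such as surgery); the **mean-threshold
rule** keeps equipoise while the pooled mean μ = ᾱ/(ᾱ+β̄) stays in
[0.4, 0.7]. Eligibility is tested exactly: all C(2n−1, n) with-replacement
compositions (multisets) of the n-expert panel are pooled and classified,
and the p-value for the null "do not recruit" is the fraction of
compositions falling outside the equipoise region.

## Worked example

```python
import equipoise as eq

panels = eq.heel_fracture_panels()           # four bundled example cases
for cid in panels.case_ids:
    fits = eq.fit_case(panels.for_case(cid), panels.scale)
    pooled = eq.pool_beta(fits)
    op = eq.opinion_from_beta(pooled.alpha_bar, pooled.beta_bar)
    res = eq.permutation_test(fits, eq.heel_trial_rule(), level=0.05)
    print(f"{cid}: Beta({pooled.alpha_bar:.2f}, {pooled.beta_bar:.2f}) "
          f"b={op.belief:.3f} d={op.disbelief:.3f} u={op.uncertainty:.3f} "
          f"p={res.p_value_fraction} eligible={res.eligible}")
```

prints

```
case1: Beta(7.10, 5.67) b=0.518 d=0.397 u=0.085 p=12/462 eligible=True
case2: Beta(9.57, 4.71) b=0.645 d=0.279 u=0.075 p=42/126 eligible=False
case3: Beta(1.87, 1.97) b=0.307 d=0.341 u=0.351 p=0/35 eligible=True
case4: Beta(5.14, 19.00) b=0.179 d=0.778 u=0.043 p=126/126 eligible=False
```

Case 1's experts disagree widely, but only 12 of the 462 possible panel
compositions leave the equipoise region, so the case is recruitable
(p ≈ 0.026 < 0.05). Case 2's panel collectively believes surgery helps
(b = 0.645): a third of compositions sit in the belief region and
recruitment would be unethical under the 80:20 rule. Case 3 is dominated
by uncertainty (u = 0.351) and is clearly recruitable; case 4's panel is
unanimous that surgery makes things worse (d = 0.778), so every
composition lands in the disbelief region and the case should be treated
conservatively rather than randomised.

The `examples/` directory has one short script per capability (fitting and
pooling, the nonparametric route, decision rules, eligibility testing,
ternary plotting, synthetic-panel parameter recovery). The same pipeline
is available from the shell:

```sh
equipoise run --input panel.csv --rule eighty_twenty \
    --equipoise-point 8/14 --level 0.05 --out results/
```

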
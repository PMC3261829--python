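# Methods

## Data model

An assessment is one expert's allocation of 100 percentage points across an
ordered K-category effectiveness scale for one case. Category k is placed
at the midpoint (2k−1)/(2K) of K equal-width bins on [0, 1], preserving the
even verbal spacing and centring the scale at 1/2. Weights are stored as
percentages, as elicited, and normalised to probabilities only at the model
boundary. The sum-to-100 check uses a 1e−6 absolute tolerance: inputs are
human-entered integers, and strictness catches entry errors. Panels may
differ in size between cases. Partially completed assessments (sum < 100)
are rejected rather than renormalised, since silently rescaling would
change the expert's stated distribution. A single-category assessment is
valid data but is flagged with a warning: it has zero variance, so the
parametric fit refuses it (see below).

The equipoise point e is part of the scale/rule configuration, not of the
data. It defaults to the scale centre 1/2; for trials where one arm is an
active intervention the point can sit off-centre (the bundled heel-fracture
configuration uses 8/14, the boundary between "no difference" and "a bit
better"), because "no difference" then argues against intervening.
Fractions are accepted as strings ("8/14") to avoid decimal drift.

## Parametric model

Each expert's distribution is modelled as Beta(α, β) with α, β ≥ 1 so the
density is unimodal (or uniform at the corner α = β = 1); U-shaped
densities are excluded as implausible for effectiveness judgements and
because the opinion mapping below is undefined for them. The fit maximises
the weighted log-likelihood Σₖ (wₖ/100)·log f(mₖ; α, β) at the category
midpoints mₖ — exactly the MLE for a pseudo-sample of 100 observations
placed at the midpoints with the percentages as multiplicities. This
weighting is deterministic and order-invariant. The optimiser is
box-constrained L-BFGS-B on (α, β) ∈ [1, 1000]², started from
method-of-moments values clipped into the box, with a Nelder–Mead fallback
on log-shifted parameters; the box ceiling of 1000 is a numerical guard,
and a fit pinned there is flagged (`at_bound`) as near-degenerate. An
exactly degenerate (point-mass) assessment raises an error by default
rather than being capped: its MLE diverges and its opinion would claim
u = 0, which breaks pooling semantics.

Multiplicative pooling — the normalised geometric mean of member densities,
representing the intersection of the panel's beliefs — is computed through
its exact parametric identity: the pooled density is Beta(ᾱ, β̄) with ᾱ, β̄
the arithmetic means of the member shapes. No numerical density
multiplication is involved.

Pooled shapes map to the opinion triplet b = (ᾱ−1)/(ᾱ+β̄−1),
d = (β̄−1)/(ᾱ+β̄−1), u = 1/(ᾱ+β̄−1). The triplet sums to one by
construction; (1, 1) maps to total ignorance {0, 0, 1}, and belief rises
(uncertainty falls) monotonically in ᾱ at fixed β̄.

## Nonparametric model

The moment route assumes nothing beyond support on [0, 1]: with weighted
mean μ and SD σ, u = σ²/(μ(1−μ)), b = μ(1−u), d = (1−μ)(1−u). The
*population* SD is used (divisor = total weight), because the weights are a
complete elicited distribution, not a sample. The parametric mapping is the
special case obtained from the moments of Beta(α−1, β−1) — a rescaling
identity asserted numerically in the tests. Pooling acts on the raw weight
vectors: category-wise n-th root of the product, renormalised. Zeros
propagate deliberately (intersection-of-beliefs semantics); a panel whose
supports share no category raises an error, with an optional epsilon floor
(off by default) for exploratory use. The 80:20 rule is defined through the
Beta CDF and is therefore restricted to the parametric path; the
mean-threshold rule works under both models.

## Decision rules

The 80:20 split is read as cumulative probability: with P = BetaCDF(e; ᾱ, β̄),
P < 0.2 is belief, P > 0.8 is disbelief, otherwise equipoise. This
cumulative reading is the one that yields a one-dimensional boundary in
opinion space. The mean-threshold rule classes μ > hi as belief, μ < lo as
disbelief, the closed interval as equipoise. Opinions landing exactly on a
boundary (within 1e−12) count as equipoise — conservative with respect to
the "do not recruit" null; the tie rule is our choice and is documented
rather than inherited.

Boundary geometry: mean-threshold boundaries are closed-form lines
b = μ₀ − (1−μ₀)u, d = (1−μ₀) − μ₀u, from u = 0 to the first component
hitting zero (for μ₀ = 0.7: from (0.7, 0.3, 0) to (4/7, 0, 3/7)). The
80:20 boundaries are traced by root-finding, over a log-spaced α grid, the
β with CDF(e; α, β) equal to 0.2 or 0.8 (Brent's method, tolerance 1e−10,
bracket [1, 1000] — grid points with no bracketed root are skipped with a
warning). With e off-centre the two curves are visibly asymmetric.

## Eligibility testing

Pooling is a symmetric function of panel members, so with-replacement
resampling enumerates *multisets*: a panel of n experts has C(2n−1, n)
distinct compositions (462 at n = 6), each pooled by averaging the selected
members' shapes. The p-value for the null hypothesis that the case should
not be recruited is the exact fraction of compositions classified outside
equipoise — belief and disbelief exceedances counted together in one
proportion, with no continuity correction; the result is reported both as
an exact fraction and a decimal. Exhaustive enumeration is the default up
to n = 8 and refused above n = 12; beyond that a seeded bootstrap (default
M = 1000) approximates the same distribution. Note the two sampling frames
differ in weighting — exhaustive counts each multiset once, while the
bootstrap weights multisets by their number of orderings — so bootstrap
convergence checks compare against ordering-weighted exhaustive
proportions. A percentile bootstrap interval for the opinion components is
provided as a descriptive companion; the region-count test is the
inferential tool.

## Opinion space

The triplet maps to triangle coordinates x = b + u/2, y = u·√3/2, with
disbelief at the left vertex, belief at the right and uncertainty at the
apex. The orientation is fixed explicitly because ternary plotting
conventions differ between libraries; the mapping is affine and invertible,
and rendering is done directly in matplotlib (SVG or PNG, vector default).

## Synthetic panels

The generator emulates the elicitation instrument: each expert starts from
the exact bin masses of a generating Beta(α, β) over K equal bins,
perturbs them with a Dirichlet draw whose concentration parameter controls
inter-expert agreement, and rounds to integer percentages summing exactly
to 100 by largest-remainder rounding. Defaults (6 experts, 7 categories,
Beta(5, 2) truth, concentration 200) mirror a realistic panel with moderate
agreement; bin-mass discretisation was chosen over sampling-then-histogram
because its noise-free limit is deterministic, which makes recovery tests
clean. What the generator does *not* emulate: anchoring, overconfidence or
other behavioural biases, correlated experts, and the tendency of real
assessors to use round numbers — so passing recovery tests show the
pipeline inverts its own generative model, not that real panels are
unbiased.

Recovery accuracy is limited by midpoint discretisation: fitting the
midpoint-weighted likelihood to exact Beta(5, 2) bin masses gives a
parameter error of ≈0.29 at K = 7 falling to ≈0.04 at K = 41, and the
error is not monotone from K = 5 (it is slightly *smaller* there than at
K = 7 for this truth). Tests therefore assert the decreasing trend from
K = 7 upward. Relatedly, the MLE of a discretised uniform assessment is
not exactly (1, 1): the midpoints of seven bins are slightly
under-dispersed relative to Beta(1, 1), so the fit sits near (1.27, 1.25)
and the opinion is uncertainty-dominated (u ≈ 0.76) rather than exactly
{0, 0, 1}.

## Problem sizes in the test suite

The suite runs entirely at desk scale: the bundled four-case table (20
assessments), exhaustive enumerations up to 462 compositions, a 10⁴-draw
bootstrap convergence check, 2×10⁵-draw Monte-Carlo CDF checks, and
synthetic recovery batches of 12–30 seeded panels — about half a minute in
total on one CPU.

## Known limitations

Two-arm comparisons only. Pooling degenerate or totally opposed experts is
deliberately refused rather than patched: a pooled opinion that represents
no individual expert's view is not a meaningful consensus. Additive
pooling, elicitation tooling, and use of the pooled opinion as a Bayesian
prior in subsequent trial analysis are out of scope.
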
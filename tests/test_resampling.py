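import itertools
import math

import numpy as np
import pytest

import equipoise as eq
from equipoise.resampling import EXHAUSTIVE_LIMIT


class TestEnumerateMultisets:
    def test_hand_enumeration_n2(self):
        assert list(eq.enumerate_multisets(2)) == [(1, 1), (1, 2), (2, 2)]

    @pytest.mark.parametrize("n,expected", [(4, 35), (5, 126), (6, 462)])
    def test_panel_combination_counts(self, n, expected):
        assert eq.n_multisets(n) == expected
        assert sum(1 for _ in eq.enumerate_multisets(n)) == expected

    def test_matches_collapsed_ordered_tuples(self):
        # Oracle: enumerate all ordered with-replacement tuples and collapse
        # to sorted form; the distinct multisets must coincide.
        n = 5
        ordered = {tuple(sorted(t)) for t in itertools.product(range(1, n + 1), repeat=n)}
        assert set(eq.enumerate_multisets(n)) == ordered

    @pytest.mark.parametrize("n", range(1, 13))
    def test_closed_form_count(self, n):
        assert eq.n_multisets(n) == math.comb(2 * n - 1, n)

    def test_large_panel_refused(self):
        with pytest.raises(ValueError, match="bootstrap"):
            list(eq.enumerate_multisets(EXHAUSTIVE_LIMIT + 1))


class TestResampleOpinions:
    def test_single_expert_multiset_reproduces_that_expert(self, heel_fits):
        fits = heel_fits["case1"]
        resampled = eq.resample_opinions(fits)
        # Multiset (3,3,3,3,3,3) is at the canonical position of that
        # combination in lexicographic order.
        index_sets = list(eq.enumerate_multisets(len(fits)))
        pos = index_sets.index((3,) * 6)
        pooled, op = resampled[pos]
        assert pooled.alpha_bar == pytest.approx(fits[2].alpha)
        assert pooled.beta_bar == pytest.approx(fits[2].beta)
        assert np.round(list(op), 3) == pytest.approx([0.712, 0.211, 0.077])

    def test_bootstrap_is_seed_reproducible(self, heel_fits):
        fits = heel_fits["case2"]
        r1 = eq.resample_opinions(fits, method="bootstrap", M=500, seed=42)
        r2 = eq.resample_opinions(fits, method="bootstrap", M=500, seed=42)
        assert all(
            p1.alpha_bar == p2.alpha_bar and o1.as_tuple() == o2.as_tuple()
            for (p1, o1), (p2, o2) in zip(r1, r2)
        )

    def test_bootstrap_requires_seed(self, heel_fits):
        with pytest.raises(ValueError, match="seed"):
            eq.resample_opinions(heel_fits["case1"], method="bootstrap", M=10)

    def test_bootstrap_converges_to_exhaustive_proportions(self, heel_fits):
        # Law of large numbers: bootstrap region proportions approach the
        # exact multiset-weighted proportions (ordered tuples, so weight
        # each multiset by its number of orderings) within 3 SE at M = 1e4.
        fits = heel_fits["case1"]
        rule = eq.heel_trial_rule()
        n = len(fits)
        weighted_outside = 0
        total = 0
        for multiset in eq.enumerate_multisets(n):
            counts = {k: multiset.count(k) for k in set(multiset)}
            orderings = math.factorial(n)
            for c in counts.values():
                orderings //= math.factorial(c)
            pooled = eq.pool_beta([fits[i - 1] for i in multiset])
            region = eq.classify(pooled.alpha_bar, pooled.beta_bar, rule)
            if region is not eq.Region.EQUIPOISE:
                weighted_outside += orderings
            total += orderings
        p_exact = weighted_outside / total
        M = 10_000
        boot = eq.resample_opinions(fits, method="bootstrap", M=M, seed=3)
        p_boot = np.mean([
            eq.classify(p.alpha_bar, p.beta_bar, rule) is not eq.Region.EQUIPOISE
            for p, _ in boot
        ])
        se = np.sqrt(p_exact * (1 - p_exact) / M)
        assert abs(p_boot - p_exact) < 3 * se


class TestPermutationTest:
    def test_case1_eighty_twenty(self, heel_fits):
        res = eq.permutation_test(heel_fits["case1"], eq.heel_trial_rule(),
                                  case_id="case1")
        assert res.total == 462
        assert res.counts["belief"] == 12
        assert res.counts["disbelief"] == 0
        assert res.p_value == pytest.approx(12 / 462)
        assert res.p_value_fraction == "12/462"
        assert res.eligible

    def test_case2_eighty_twenty_not_eligible(self, heel_fits):
        res = eq.permutation_test(heel_fits["case2"], eq.heel_trial_rule())
        assert res.counts["belief"] == 42
        assert res.p_value == pytest.approx(42 / 126)
        assert not res.eligible

    def test_identical_experts_in_equipoise_give_p_zero(self):
        fit = eq.BetaFit(2.0, 2.0, loglik=0.0)
        res = eq.permutation_test([fit] * 4, eq.eighty_twenty())
        assert res.p_value == 0.0
        assert res.eligible

    def test_p_value_invariant_to_expert_relabelling(self, heel_fits):
        fits = heel_fits["case2"]
        rule = eq.heel_trial_rule()
        p_fwd = eq.permutation_test(fits, rule).p_value
        p_rev = eq.permutation_test(fits[::-1], rule).p_value
        assert p_fwd == p_rev

    def test_counts_sum_to_total(self, heel_fits):
        for fits in heel_fits.values():
            res = eq.permutation_test(fits, eq.mean_threshold())
            assert sum(res.counts.values()) == res.total
            assert res.total == eq.n_multisets(len(fits))

    def test_json_payload_shape(self, heel_fits):
        res = eq.permutation_test(heel_fits["case4"], eq.heel_trial_rule(),
                                  case_id="case4")
        payload = res.to_dict()
        assert payload["counts"]["disbelief"] == 126
        assert payload["p_value_fraction"] == "126/126"
        assert payload["rule"]["equipoise_point"] == pytest.approx(8 / 14)
        assert set(payload) >= {"case_id", "rule", "counts", "total",
                                "p_value", "eligible", "level", "method"}


class TestBootstrapInterval:
    def test_interval_brackets_pooled_opinion(self, heel_fits):
        fits = heel_fits["case1"]
        pooled = eq.pool_beta(fits)
        op = eq.opinion_from_beta(pooled.alpha_bar, pooled.beta_bar)
        ci = eq.bootstrap_opinion_interval(fits, M=2000, seed=11)
        for key, value in zip(("b", "d", "u"), op):
            lo, hi = ci[key]
            assert lo <= value <= hi
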
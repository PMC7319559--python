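"""Core statistics: ORA, running-sum enrichment, correction, chi-square."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trailkit.enrich import (
    _running_sum as _profile,
    adjust,
    chi_square_2x2,
    hypergeom_tail,
    ora,
    running_sum_es,
    running_sum_pvalue,
)

from conftest import ora_bruteforce


def _universe(n):
    return [f"g{i}" for i in range(n)]


class TestOra:
    def test_matches_enumeration_oracle_example(self):
        # N=10, K=4, n=5, k=3: 66 of the 252 draws have >= 3 category members
        genes = _universe(10)
        rec = ora(genes[:3] + genes[4:6], genes[:4], genes, direction="over")
        assert rec.n_overlap == 3
        assert rec.p_raw == pytest.approx(66 / 252)
        assert rec.p_raw == pytest.approx(ora_bruteforce(10, 4, 5, 3))

    @pytest.mark.parametrize("direction", ["over", "under"])
    def test_matches_enumeration_oracle_small_universes(self, direction):
        for N in (4, 7, 9):
            for K in range(1, N):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        expected = ora_bruteforce(N, K, n, k, direction)
                        assert hypergeom_tail(N, K, n, k, direction) == pytest.approx(expected), (
                            N, K, n, k, direction,
                        )

    def test_test_set_equals_universe_gives_p_one(self):
        genes = _universe(6)
        rec = ora(genes, genes[:2], genes, direction="over")
        assert rec.n_overlap == rec.n_category
        assert rec.p_raw == pytest.approx(1.0)

    def test_zero_overlap_over_is_one(self):
        genes = _universe(8)
        rec = ora(genes[4:6], genes[:3], genes, direction="over")
        assert rec.n_overlap == 0
        assert rec.p_raw == pytest.approx(1.0)

    def test_p_over_nonincreasing_in_overlap(self):
        N, K, n = 30, 8, 10
        ps = [hypergeom_tail(N, K, n, k, "over") for k in range(0, min(K, n) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_two_sided_is_doubled_smaller_tail_capped(self):
        p2 = hypergeom_tail(20, 5, 8, 4, "two_sided")
        expected = min(1.0, 2 * min(hypergeom_tail(20, 5, 8, 4, "over"),
                                    hypergeom_tail(20, 5, 8, 4, "under")))
        assert p2 == pytest.approx(expected)

    def test_hits_sorted_and_subset(self):
        genes = _universe(10)
        rec = ora({"g3", "g1", "g7"}, {"g1", "g3", "g9"}, genes)
        assert rec.hits == ["g1", "g3"]

    def test_errors(self):
        genes = _universe(5)
        with pytest.raises(ValueError, match="empty"):
            ora(set(), genes[:2], genes)
        with pytest.raises(ValueError, match="subset"):
            ora({"nope"}, genes[:2], genes)


class TestRunningSum:
    def test_all_hits_at_top_gives_one(self):
        assert running_sum_es(["a", "b", "c", "d"], {"a", "b"}) == pytest.approx(1.0)

    def test_all_hits_at_bottom_gives_minus_one(self):
        assert running_sum_es(["a", "b", "c", "d"], {"c", "d"}) == pytest.approx(-1.0)

    def test_hand_walked_example(self):
        # N=6, K=2, hits at ranks 1 and 4: running sum 1/2, 1/4, 0, 1/2, 1/4, 0
        es = running_sum_es(list("abcdef"), {"a", "d"})
        assert es == pytest.approx(0.5)

    def test_antisymmetric_under_reversal(self):
        # reversal negates the running-sum profile, so ES flips sign; when
        # the positive and negative extrema tie exactly in magnitude the
        # sign depends on the (position-based) tie-break, but the magnitude
        # is always preserved
        rng = np.random.default_rng(7)
        for _ in range(30):
            genes = [f"g{i}" for i in range(12)]
            cat = set(rng.choice(genes, size=4, replace=False))
            es = running_sum_es(genes, cat)
            es_rev = running_sum_es(genes[::-1], cat)
            assert abs(es_rev) == pytest.approx(abs(es))
            rs, _ = _profile(genes, cat)
            if not np.isclose(rs.max(), -rs.min()):
                assert es_rev == pytest.approx(-es)

    def test_degenerate_category_errors(self):
        with pytest.raises(ValueError):
            running_sum_es(["a", "b"], {"x"})
        with pytest.raises(ValueError):
            running_sum_es(["a", "b"], {"a", "b"})
        with pytest.raises(ValueError, match="duplicates"):
            running_sum_es(["a", "a", "b"], {"a"})

    def test_permutation_pvalue_bounds_and_determinism(self):
        genes = [f"g{i}" for i in range(100)]
        cat = set(genes[:8])  # all hits at the very top
        r1 = running_sum_pvalue(genes, cat, n_permutations=1000, seed=5)
        r2 = running_sum_pvalue(genes, cat, n_permutations=1000, seed=5)
        assert r1.p_raw == r2.p_raw  # determinism contract
        assert r1.p_raw >= 1 / 1001  # add-one estimator bound
        assert r1.p_raw <= 0.05  # an extreme score is rarely matched by chance
        assert r1.es == pytest.approx(1.0)
        assert set(r1.leading_edge) <= cat

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError):
            running_sum_pvalue(["a", "b", "c"], {"a"}, n_permutations=10, seed=0)


class TestAdjust:
    def test_bh_step_up_hand_example(self):
        # min over j>=i of p(j) * m / j = 0.04 for every position
        assert adjust([0.01, 0.02, 0.03, 0.04], "bh") == pytest.approx([0.04] * 4)

    @pytest.mark.parametrize("method", ["bonferroni", "holm", "bh", "by"])
    def test_single_p_unchanged(self, method):
        assert adjust([0.5], method) == pytest.approx([0.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False), min_size=1, max_size=20))
    def test_ordering_invariants(self, ps):
        raw = np.array(ps)
        bonf = np.array(adjust(ps, "bonferroni"))
        holm = np.array(adjust(ps, "holm"))
        bh = np.array(adjust(ps, "bh"))
        by = np.array(adjust(ps, "by"))
        assert np.all(bonf >= holm - 1e-12)
        assert np.all(holm >= raw - 1e-12)
        assert np.all(bh >= raw - 1e-12)
        assert np.all(by >= bh - 1e-12)
        for adj in (bonf, holm, bh, by):
            assert np.all(adj <= 1.0 + 1e-12)
            # monotone: adjusted order respects the raw order
            order = np.argsort(raw, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-12)

    @pytest.mark.parametrize("method,sm_method", [
        ("bonferroni", "bonferroni"), ("holm", "holm"), ("bh", "fdr_bh"), ("by", "fdr_by"),
    ])
    def test_agrees_with_statsmodels(self, method, sm_method):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(20):
            ps = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 15)))
            ours = adjust(ps, method)
            _, ref, _, _ = multipletests(ps, method=sm_method)
            np.testing.assert_allclose(ours, np.minimum(ref, 1.0), rtol=1e-12)

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [float("nan")], [-0.1]):
            with pytest.raises(ValueError):
                adjust(bad, "bh")
        with pytest.raises(ValueError):
            adjust([0.5], "nope")


class TestChiSquare:
    def test_closed_form_example(self):
        chi2, p, orat = chi_square_2x2(10, 20, 30, 40)
        assert chi2 == pytest.approx(4_000_000 / 5_040_000)
        assert orat == pytest.approx((10 * 40) / (20 * 30))
        assert 0 < p < 1

    def test_independence(self):
        chi2, p, orat = chi_square_2x2(5, 5, 5, 5)
        assert chi2 == 0
        assert p == pytest.approx(1.0)
        assert orat == pytest.approx(1.0)

    def test_perfect_association_uses_haldane_correction(self):
        k = 7
        chi2, p, orat = chi_square_2x2(k, 0, 0, k)
        assert chi2 == pytest.approx(2 * k)  # N(ad)^2 / (k*k*k*k) = 2k
        assert orat == pytest.approx((7.5 * 7.5) / (0.5 * 0.5))

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 50, size=4)
            s1 = chi_square_2x2(int(a), int(b), int(c), int(d))[0]
            s2 = chi_square_2x2(int(d), int(c), int(b), int(a))[0]
            assert s1 == pytest.approx(s2)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(0, 0, 3, 4)
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(0, 3, 0, 4)
        with pytest.raises(ValueError):
            chi_square_2x2(-1, 2, 3, 4)

    def test_matches_scipy_without_correction(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(11)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(1, 100, size=4))
            chi2, p, _ = chi_square_2x2(a, b, c, d)
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)
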
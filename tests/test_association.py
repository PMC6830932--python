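"""Single-SNP association tests, odds ratios, permutation correction."""

import numpy as np
import pytest
from scipy import stats

from panelassoc import (
    CASE,
    CONTROL,
    MISSING,
    Contingency2x2,
    chi2_2x2,
    collapse,
    f_test,
    genotypic_test,
    logistic_dominant,
    max_test,
    model_test,
    odds_ratio_woolf,
    permutation_maxT,
)
from panelassoc.simulate import simulate_count_row

from conftest import make_matrix, make_row


class TestCollapse:
    def test_recessive_minor_homozygotes_vs_rest(self):
        row = make_row((56, 219, 159), (31, 59, 48))
        t = collapse(row, "recessive")
        assert t.cells == (56, 378, 31, 107)

    def test_dominant_carriers_vs_noncarriers(self):
        row = make_row((7, 101, 327), (1, 17, 120))
        t = collapse(row, "dominant")
        assert t.cells == (108, 327, 18, 120)

    @pytest.mark.parametrize("model", ["dominant", "recessive"])
    def test_empty_minor_classes_give_zero_exposed(self, model):
        row = make_row((0, 0, 50), (0, 0, 30))
        t = collapse(row, model)
        assert t.a == 0 and t.c == 0


class TestChi2:
    def test_published_recessive_p(self):
        _, p = chi2_2x2(Contingency2x2(56, 378, 31, 107))
        assert p == pytest.approx(0.0065, abs=1e-4)

    def test_published_dominant_p(self):
        _, p = chi2_2x2(Contingency2x2(108, 327, 18, 120))
        assert p == pytest.approx(0.0036, abs=1e-4)

    def test_equal_proportions_are_null(self):
        x, p = chi2_2x2(Contingency2x2(10, 90, 5, 45))
        assert x == 0.0 and p == 1.0

    def test_zero_margin_degenerate(self):
        x, p = chi2_2x2(Contingency2x2(0, 100, 0, 50))
        assert (x, p) == (0.0, 1.0)

    def test_yates_variant_differs_and_does_not_match_published(self):
        x_plain, p_plain = chi2_2x2(Contingency2x2(56, 378, 31, 107))
        x_yates, p_yates = chi2_2x2(Contingency2x2(56, 378, 31, 107),
                                    continuity=True)
        assert x_yates < x_plain
        assert abs(p_yates - 0.0065) > 5e-4  # continuity-corrected p does not match

    def test_matches_scipy_uncorrected(self):
        t = Contingency2x2(41, 202, 12, 113)
        x, p = chi2_2x2(t)
        x_sp, p_sp, _, _ = stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False)
        assert x == pytest.approx(x_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-12)


class TestWoolf:
    def test_published_or_examples(self):
        orr, _ = odds_ratio_woolf(Contingency2x2(56, 378, 31, 107))
        assert round(orr, 2) == 0.51
        orr, ci = odds_ratio_woolf(Contingency2x2(30, 400, 1, 134))
        # computed 10.05 sits half a printed ulp from the published 10.0
        assert orr == pytest.approx(10.0, abs=0.06)
        assert round(ci[0], 1) == 1.4 and round(ci[1], 1) == 74.4

    def test_derived_ci_for_inconsistently_printed_row(self):
        # the published CI for this row contradicts its own OR; the Woolf
        # formula that reproduces every other row gives (0.31, 0.83)
        _, ci = odds_ratio_woolf(Contingency2x2(56, 378, 31, 107))
        assert ci == pytest.approx((0.31, 0.83), abs=5e-3)

    def test_zero_cell_undefined_unless_haldane(self):
        t = Contingency2x2(0, 10, 5, 5)
        assert odds_ratio_woolf(t) == (None, None)
        orr, ci = odds_ratio_woolf(t, haldane=True)
        assert orr is not None and ci[0] < orr < ci[1]


class TestGenotypicAndF:
    def test_identical_distributions_null(self):
        row = make_row((10, 20, 10), (10, 20, 10))
        x, df, p = genotypic_test(row)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)
        f, df1, df2, pf = f_test(row)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert pf == pytest.approx(1.0)

    def test_textbook_2x3_computation(self):
        row = make_row((56, 219, 159), (31, 59, 48))
        x, df, p = genotypic_test(row)
        x_sp, p_sp, df_sp, _ = stats.chi2_contingency(
            [[56, 219, 159], [31, 59, 48]], correction=False)
        assert (x, df, p) == pytest.approx((x_sp, df_sp, p_sp), rel=1e-12)

    def test_empty_column_drops_df(self):
        row = make_row((0, 30, 70), (0, 20, 80))
        _, df, _ = genotypic_test(row)
        assert df == 1

    def test_f_matches_expansion_oracle(self):
        row = make_row((56, 219, 159), (31, 59, 48))
        f, df1, df2, p = f_test(row)
        # oracle: expand to per-sample 0/1 phenotype and genotype group
        pheno, group = [], []
        for gi, (n_ca, n_co) in enumerate(zip(row.case_counts, row.control_counts)):
            pheno += [1] * n_ca + [0] * n_co
            group += [gi] * (n_ca + n_co)
        pheno, group = np.array(pheno), np.array(group)
        f_sp, p_sp = stats.f_oneway(*[pheno[group == k] for k in range(3)])
        assert f == pytest.approx(f_sp, rel=1e-10)
        assert p == pytest.approx(p_sp, rel=1e-10)
        assert (df1, df2) == (2, len(pheno) - 3)

    def test_two_group_degenerate_df(self):
        row = make_row((0, 30, 70), (0, 25, 75))
        f, df1, df2, p = f_test(row)
        assert df1 == 1


class TestMaxTest:
    def test_stat_is_max_of_models(self):
        row = make_row((30, 100, 70), (10, 50, 40))
        x_dom, _ = chi2_2x2(collapse(row, "dominant"))
        x_rec, _ = chi2_2x2(collapse(row, "recessive"))
        stat, p = max_test(row, n_perm=2000, seed=0)
        assert stat == max(x_dom, x_rec)

    def test_p_bounded_by_single_model_and_bonferroni(self):
        row = make_row((40, 120, 275), (25, 50, 63))
        _, p_dom = chi2_2x2(collapse(row, "dominant"))
        _, p_rec = chi2_2x2(collapse(row, "recessive"))
        stat, p = max_test(row, n_perm=20000, seed=1)
        lo = min(p_dom, p_rec)
        assert lo / 2 <= p <= min(1.0, 2.5 * lo)

    def test_null_rows_give_uniformish_p(self):
        rng = np.random.default_rng(2)
        ps = []
        for i in range(60):
            row = simulate_count_row(0.3, "dominant", 1.0, 200, 200, seed=100 + i)
            _, p = max_test(row, n_perm=1000, seed=i)
            ps.append(p)
        ps = np.array(ps)
        assert 0.2 < ps.mean() < 0.8
        assert (ps < 0.05).mean() < 0.2

    def test_fixed_seed_reproducible(self):
        row = make_row((30, 100, 70), (10, 50, 40))
        assert max_test(row, n_perm=2000, seed=7) == max_test(row, n_perm=2000, seed=7)

    def test_requires_minimum_permutations(self):
        with pytest.raises(ValueError):
            max_test(make_row((1, 1, 1), (1, 1, 1)), n_perm=10, seed=0)


class TestLogistic:
    def test_exp_beta_equals_cross_product_or(self):
        row = make_row((7, 101, 327), (1, 17, 120))
        beta, se, p, orr = logistic_dominant(row)
        woolf_or, _ = odds_ratio_woolf(collapse(row, "dominant"))
        assert abs(orr - woolf_or) < 1e-8
        assert round(orr, 2) == 2.20

    def test_balanced_null_beta_zero(self):
        row = make_row((10, 40, 50), (10, 40, 50))
        beta, _, _, _ = logistic_dominant(row)
        assert beta == pytest.approx(0.0, abs=1e-8)

    def test_wald_p_tracks_chi2_p_on_large_tables(self):
        row = make_row((200, 300, 500), (120, 260, 620))
        _, _, p_wald, _ = logistic_dominant(row)
        _, p_chi = chi2_2x2(collapse(row, "dominant"))
        assert p_wald == pytest.approx(p_chi, rel=0.1)

    def test_separation_flagged(self):
        row = make_row((0, 0, 100), (5, 20, 75))
        with pytest.raises(ValueError):
            logistic_dominant(row)


class TestPermutationMaxT:
    def _panel(self, n_case=80, n_ctrl=80, m=12, seed=3):
        rng = np.random.default_rng(seed)
        codes = rng.binomial(2, 0.3, (n_case + n_ctrl, m)).astype(np.int8)
        return make_matrix(codes, phenotypes=[CASE] * n_case + [CONTROL] * n_ctrl)

    def test_single_variant_corrected_equals_pointwise(self):
        g = self._panel(m=1)
        (res,) = permutation_maxT(g, model="dominant", n_perm=3000, seed=4)
        assert res.corrected_p == res.pointwise_p

    def test_corrected_dominates_pointwise(self):
        g = self._panel()
        for res in permutation_maxT(g, model="dominant", n_perm=2000, seed=5):
            assert res.corrected_p >= res.pointwise_p

    def test_seed_reproducible_and_sample_order_invariant(self):
        g = self._panel()
        r1 = permutation_maxT(g, model="recessive", n_perm=2000, seed=6)
        r2 = permutation_maxT(g, model="recessive", n_perm=2000, seed=6)
        assert [x.corrected_p for x in r1] == [x.corrected_p for x in r2]
        # shuffling sample rows leaves the permutation null unchanged in law;
        # observed statistics (and hence sorted p-values) are identical
        rng = np.random.default_rng(7)
        perm = rng.permutation(g.n_samples)
        g_shuf = g.subset_samples(perm)
        r3 = permutation_maxT(g_shuf, model="recessive", n_perm=2000, seed=6)
        p1 = np.array(sorted(x.pointwise_p for x in r1))
        p3 = np.array(sorted(x.pointwise_p for x in r3))
        assert np.abs(p1 - p3).max() < 0.05
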
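import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from lateralize.association import (
    ContingencyTable,
    cohen_kappa,
    collapse_dominance,
    contingency,
    edinburgh_lq,
    fisher_exact,
    mps3,
    mps7,
    occurrence_regression,
    spearman,
)
from lateralize.association import _enumerate_tables, _log_table_prob


def table(counts, rows=None, cols=None):
    counts = np.array(counts)
    return ContingencyTable(
        counts,
        rows or tuple(range(counts.shape[0])),
        cols or tuple(range(counts.shape[1])),
    )


class TestEdinburgh:
    @pytest.mark.parametrize(
        "r, l, expected", [(9, 0, 100.0), (0, 9, -100.0), (6, 3, 100 / 3)]
    )
    def test_quotient(self, r, l, expected):
        assert edinburgh_lq(r, l) == pytest.approx(expected)

    def test_no_tallies_undefined(self):
        with pytest.raises(ValueError):
            edinburgh_lq(0, 0)


class TestMpsCategories:
    @pytest.mark.parametrize(
        "score, expected",
        [(-55.0, "Strong L"), (100.0, "Strong R"), (0.0, "Moderate"),
         (-100.0, "Strong L"), (-54.9, "Moderate"), (99.9, "Moderate")],
    )
    def test_mps3(self, score, expected):
        assert mps3(score) == expected

    @pytest.mark.parametrize(
        "score, expected",
        [(-100.0, 1), (100.0, 7), (-75.0, 2), (-99.0, 2), (-25.0, 3),
         (0.0, 4), (25.0, 4), (50.0, 5), (75.0, 5), (87.0, 6), (99.0, 6)],
    )
    def test_mps7_boundaries_resolve_downward(self, score, expected):
        assert mps7(score) == expected

    @pytest.mark.parametrize("func", [mps3, mps7])
    def test_out_of_range_rejected(self, func):
        with pytest.raises(ValueError):
            func(150.0)

    @given(score=st.floats(-100, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mps7_is_monotone_in_score(self, score):
        assert mps7(score) <= mps7(min(score + 10, 100.0))


class TestContingency:
    def test_published_type_by_handedness_counts(self, published_type_cohort):
        ct = contingency(published_type_cohort, "handedness", "lat_type")
        df = ct.to_dataframe()
        assert df.loc["RH", "Typical"] == 130
        assert df.loc["LH", "Strongly-atypical"] == 10
        assert ct.total == 297

    def test_single_subject(self):
        df = pd.DataFrame({"a": ["x"], "b": ["y"]})
        ct = contingency(df, "a", "b")
        assert ct.counts.tolist() == [[1]]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            contingency(pd.DataFrame({"a": [], "b": []}), "a", "b")

    def test_collapse_dominance_reproduces_2x2(self, published_type_cohort):
        ct = collapse_dominance(published_type_cohort)
        assert ct.counts.tolist() == [[130, 14], [120, 33]]

    def test_collapse_excluding_strongly_atypical(self, published_type_cohort):
        ct = collapse_dominance(published_type_cohort, include_strongly_atypical=False)
        assert ct.counts.tolist() == [[130, 14], [120, 23]]


class TestKappa:
    def test_perfect_agreement(self):
        k = cohen_kappa(table([[30, 0], [0, 70]]))
        assert k.kappa == pytest.approx(1.0)

    def test_exact_independence_is_zero(self):
        # rows proportional to the column margins
        k = cohen_kappa(table([[40, 10], [80, 20]]))
        assert k.kappa == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        c = np.array([[20, 5, 2], [3, 30, 4], [1, 6, 29]])
        k0 = cohen_kappa(table(c)).kappa
        perm = [2, 0, 1]
        k1 = cohen_kappa(table(c[np.ix_(perm, perm)])).kappa
        assert k1 == pytest.approx(k0)

    def test_zero_category_removal_leaves_kappa_unchanged(self):
        c = np.array([[20, 5], [3, 30]])
        padded = np.zeros((3, 3), dtype=int)
        padded[:2, :2] = c
        k_trim = cohen_kappa(table(c)).kappa
        k_pad = cohen_kappa(ContingencyTable(padded, ("a", "b", "z"),
                                             ("a", "b", "z")).drop_empty()).kappa
        assert k_pad == pytest.approx(k_trim)

    def test_matches_independent_implementation(self):
        """Cross-check kappa and its null SE against statsmodels."""
        from statsmodels.stats.inter_rater import cohens_kappa

        c = np.array([[130, 14], [120, 33]])
        mine = cohen_kappa(table(c))
        ref = cohens_kappa(c, return_results=True)
        assert mine.kappa == pytest.approx(ref.kappa, abs=1e-12)
        assert mine.se == pytest.approx(ref.std_kappa0, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue_two_sided, abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(table([[1, 2, 3], [4, 5, 6]]))

    def test_independent_traits_give_null_kappa_at_scale(self):
        """Hand and language dominance assigned independently: kappa -> 0."""
        gen = np.random.default_rng(0)
        n = 10**5
        df = pd.DataFrame(
            {
                "handedness": np.where(gen.random(n) < 0.5, "RH", "LH"),
                "lat_type": gen.choice(
                    ["Typical", "Ambilateral", "Strongly-atypical"],
                    size=n, p=[0.84, 0.12, 0.04],
                ),
            }
        )
        k = cohen_kappa(collapse_dominance(df))
        assert abs(k.kappa) < 0.01


class TestFisher:
    def test_2x2_matches_direct_hypergeometric_sum(self):
        """Textbook oracle: sum hypergeometric pmf over the support."""
        c = np.array([[1, 9], [11, 3]])
        n, r1, c1 = c.sum(), c[0].sum(), c[:, 0].sum()
        pmf = lambda k: (
            comb(c1, k, exact=True) * comb(n - c1, r1 - k, exact=True)
        ) / comb(n, r1, exact=True)
        p_obs = pmf(c[0, 0])
        expected = sum(
            pmf(k)
            for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if pmf(k) <= p_obs * (1 + 1e-12)
        )
        res = fisher_exact(table(c))
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact(table([[5, 7, 3], [5, 7, 3]])).p == pytest.approx(1.0)

    def test_2x3_agrees_with_r_reference(self):
        """Value cross-checked against R's fisher.test (0.0008488)."""
        res = fisher_exact(table([[130, 14, 0], [120, 23, 10]]))
        assert res.method == "enumeration"
        assert res.p == pytest.approx(0.0008488283, rel=1e-6)

    def test_3x3_agrees_with_r_reference(self):
        """Value cross-checked against R's fisher.test (0.0010273)."""
        res = fisher_exact(table([[87, 11, 0], [90, 9, 1], [73, 17, 9]]))
        assert res.p == pytest.approx(0.001027313, rel=1e-6)

    def test_enumeration_probabilities_sum_to_one(self):
        c = np.array([[4, 3, 1], [2, 5, 3]])
        row_m, col_m = c.sum(axis=1), c.sum(axis=0)
        n = int(c.sum())
        total = sum(
            np.exp(_log_table_prob(np.asarray(t), row_m, col_m, n))
            for t in _enumerate_tables(row_m, col_m, 10**6)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_matches_enumeration(self):
        c = table([[8, 2, 4], [3, 9, 5], [6, 1, 7]])
        exact = fisher_exact(c)
        mc = fisher_exact(c, max_tables=1, n_mc=20000, seed=1)
        assert mc.method == "monte-carlo"
        assert mc.p == pytest.approx(exact.p, abs=4 * max(mc.mc_se, 1e-4))

    def test_zero_margin_category_ignored(self):
        with_zero = fisher_exact(table([[8, 2, 0], [3, 9, 0]]))
        without = fisher_exact(table([[8, 2], [3, 9]]))
        assert with_zero.p == pytest.approx(without.p, rel=1e-12)


class TestSpearman:
    def test_monotone_sequences(self, rng):
        x = rng.normal(size=30)
        up = spearman(x, np.argsort(np.argsort(x)).astype(float))
        assert up.estimate["rho"] == pytest.approx(1.0)
        down = spearman(x, -x)
        assert down.estimate["rho"] == pytest.approx(-1.0)

    def test_matches_rank_and_correlate_oracle(self, rng):
        x = rng.normal(size=200)
        y = 0.3 * x + rng.normal(size=200)
        res = spearman(x, y)
        rx = stats.rankdata(x)  # midrank ties
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.estimate["rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_flagged(self):
        res = spearman(np.ones(10), np.arange(10.0))
        assert not res.estimate["defined"]


class TestOccurrenceRegression:
    @staticmethod
    def cohort_with_occurrence(occ_by_cat, n=40):
        rows = []
        for cat, occ in occ_by_cat.items():
            n_atyp = int(round(occ * n / 100))
            for i in range(n):
                rows.append(
                    {
                        "mps7": cat,
                        "lat_type": "Ambilateral" if i < n_atyp else "Typical",
                    }
                )
        return pd.DataFrame(rows)

    def test_flat_occurrence_gives_zero_slope(self):
        df = self.cohort_with_occurrence({c: 10.0 for c in range(1, 8)})
        res = occurrence_regression(df)
        assert res.estimate["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exactly_linear_occurrence_recovered(self):
        mids = {1: -100.0, 2: -87.0, 3: -50.0, 4: 0.0, 5: 50.0, 6: 87.0, 7: 100.0}
        # occurrence = 20 - 0.1 * mid, realizable exactly with n=1000 per cell
        df = self.cohort_with_occurrence(
            {c: 20 - 0.1 * mids[c] for c in mids}, n=1000
        )
        res = occurrence_regression(df)
        assert res.estimate["slope"] == pytest.approx(-0.1, abs=1e-12)
        assert res.estimate["intercept"] == pytest.approx(20.0, abs=1e-9)

    def test_single_category_rejected(self):
        df = self.cohort_with_occurrence({4: 10.0})
        with pytest.raises(ValueError):
            occurrence_regression(df)

    def test_synthetic_cohorts_give_negative_slope_majority(self):
        """Left-hand-preferring strongly-atypicals drag the slope negative."""
        from lateralize.classify import assign_types
        from lateralize.synthetic import CohortConfig, generate_cohort

        neg = 0
        n_rep = 20
        for seed in range(n_rep):
            cohort = generate_cohort(CohortConfig(seed=seed))
            cohort["lat_type"] = assign_types(cohort["hfli"]).lat_type.values
            cohort["mps7"] = cohort["mps"].map(mps7)
            res = occurrence_regression(cohort)
            neg += res.estimate["slope"] < 0
        assert neg > n_rep / 2
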
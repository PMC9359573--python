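"""Resistance statistics: allele frequencies, concordance, Fisher exact,
proportional-odds regression, and bottle-bioassay metrics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from culexkdr import stats, tables
from culexkdr.stats import (
    BioassayResult,
    allele_frequency,
    ancova_slopes,
    classify_cdc_resistance,
    concordance,
    fisher_exact_mc,
    fisher_exact_rxc,
    fit_proportional_odds,
    fit_proportional_odds_counts,
    knockdown_regression,
    resistance_ratio,
)


class TestAlleleFrequency:
    def test_survey_species_rows(self):
        assert allele_frequency(208, 226, 310).f == pytest.approx(846 / 1488)
        assert allele_frequency(208, 226, 310).rounded() == 0.57
        assert allele_frequency(401, 57, 49).rounded() == 0.15

    def test_all_wildtype_is_zero(self):
        assert allele_frequency(126, 0, 0).f == 0.0

    def test_all_mutant_is_one(self):
        assert allele_frequency(0, 0, 44).f == 1.0

    def test_equals_mean_allele_dosage_over_two(self):
        n_ll, n_lf, n_ff = 13, 29, 7
        dosage = (0 * n_ll + 1 * n_lf + 2 * n_ff) / (n_ll + n_lf + n_ff)
        assert allele_frequency(n_ll, n_lf, n_ff).f == pytest.approx(dosage / 2)

    def test_se_is_binomial_on_allele_draws(self):
        est = allele_frequency(10, 20, 10)
        assert est.se == pytest.approx(math.sqrt(est.f * (1 - est.f) / 80))

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            allele_frequency(0, 0, 0)


class TestConcordance:
    def test_identical_sets_100_percent(self):
        calls = {f"s{i}": "LL" for i in range(10)}
        assert concordance(calls, dict(calls)).percent == 100.0

    def test_single_discordant_in_190(self):
        a = {f"s{i}": "LL" for i in range(190)}
        b = dict(a)
        b["s0"] = "FF"
        res = concordance(a, b)
        assert res.n_concordant == 189
        assert res.percent > 99.0

    def test_exclusions_dropped_before_comparison(self):
        """75 pairs with 3 excluded and 3 discordant: 69/72 = 95.8%."""
        a = {f"s{i}": "LF" for i in range(75)}
        b = dict(a)
        for i in range(3):
            a[f"s{i}"] = "EXCLUDED"
        for i in range(3, 6):
            b[f"s{i}"] = "LL"
        res = concordance(a, b)
        assert (res.n_valid, res.n_concordant) == (72, 69)
        assert round(res.percent) == 96

    def test_confusion_matrix_counts(self):
        a = {"s1": "LL", "s2": "LL", "s3": "FF"}
        b = {"s1": "LL", "s2": "LF", "s3": "FF"}
        res = concordance(a, b)
        assert res.confusion.loc["LL", "LF"] == 1
        assert res.confusion.to_numpy().sum() == 3

    def test_no_shared_ids_rejected(self):
        with pytest.raises(ValueError):
            concordance({"a": "LL"}, {"b": "LL"})


class TestFisherExact:
    def test_2x2_matches_scipy_hypergeometric_closed_form(self):
        table = [[1, 9], [11, 3]]
        expected = sps.fisher_exact(table).pvalue
        assert fisher_exact_rxc(table) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_2x2_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 12, size=(2, 2))
        table[0, 0] += 1
        expected = sps.fisher_exact(table).pvalue
        assert fisher_exact_rxc(table) == pytest.approx(expected, rel=1e-9)

    def test_proportional_rows_give_p_one(self):
        assert fisher_exact_rxc([[2, 4, 6], [1, 2, 3]]) == pytest.approx(1.0)

    def test_bioassay_association_tables(self):
        """Genotype x knockdown for the resistant lab strain. Permethrin
        reproduces the published p = 0.138; the deltamethrin table is
        significant (the oracle value from the same enumeration definition
        is 0.0221)."""
        perm = [list(tables.BIOASSAY_GENOTYPES["permethrin"]["not_knocked"]),
                list(tables.BIOASSAY_GENOTYPES["permethrin"]["knocked"])]
        delt = [list(tables.BIOASSAY_GENOTYPES["deltamethrin"]["not_knocked"]),
                list(tables.BIOASSAY_GENOTYPES["deltamethrin"]["knocked"])]
        # frozen R fisher.test values
        assert fisher_exact_rxc(perm) == pytest.approx(0.1382943, abs=1e-6)
        assert fisher_exact_rxc(delt) == pytest.approx(0.0220736, abs=1e-6)
        assert fisher_exact_rxc(delt) < 0.05

    def test_zero_margin_rows_dropped(self):
        p_with = fisher_exact_rxc([[0, 5, 3], [0, 2, 7], [0, 0, 0]])
        p_without = fisher_exact_rxc([[5, 3], [2, 7]])
        assert p_with == pytest.approx(p_without, rel=1e-12)

    def test_budget_exceeded_raises(self):
        big = (np.ones((4, 4), dtype=int) * 40).tolist()
        with pytest.raises(stats.EnumerationBudgetExceeded):
            fisher_exact_rxc(big, budget=100)

    def test_monte_carlo_close_to_exact(self):
        table = [[3, 9], [10, 2]]
        exact = fisher_exact_rxc(table)
        mc = fisher_exact_mc(table, n_resamples=20000, seed=5)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_point_probabilities_sum_to_one(self, recwarn):
        # the engine warns if enumerated probabilities do not sum to 1
        fisher_exact_rxc([[4, 1, 3], [2, 5, 1], [3, 2, 2]])
        assert not [w for w in recwarn.list if "probability" in str(w.message)]


class TestProportionalOdds:
    def test_identical_groups_give_null_effect(self):
        fit = fit_proportional_odds_counts(
            {"a": (30, 20, 10), "b": (30, 20, 10)}, reference="a"
        )
        assert fit.coef["b"] == pytest.approx(0.0, abs=1e-6)
        assert fit.odds_ratios["b"] == pytest.approx(1.0, abs=1e-6)

    def test_binary_outcome_matches_2x2_closed_form(self):
        """With J=2 the model is plain logistic regression: the MLE odds
        ratio for a 2x2 table [[a,b],[c,d]] is (a*d)/(b*c)."""
        a, b, c, d = 20, 11, 7, 17
        fit = fit_proportional_odds(
            X=[[0.0], [1.0]], counts=[[a, b], [c, d]], coef_names=["g"]
        )
        assert fit.odds_ratios["g"] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_species_counts_reproduce_published_or(self):
        fit = fit_proportional_odds_counts(
            dict(
                (k, tables.SPECIES_COUNTS[k]) for k in ("Cx. tarsalis", "Cx. pipiens")
            ),
            reference="Cx. tarsalis",
        )
        assert fit.converged
        assert fit.odds_ratios["Cx. pipiens"] == pytest.approx(8.99, abs=0.05)
        assert fit.p_values["Cx. pipiens"] < 0.001

    def test_matches_statsmodels_ordered_model(self):
        """Independent MLE cross-check on expanded per-specimen data."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rows = {"ref": (40, 25, 12), "alt": (18, 22, 30)}
        fit = fit_proportional_odds_counts(rows, reference="ref")

        y, x = [], []
        for lvl, (nll, nlf, nff) in rows.items():
            for cat, n in zip((0, 1, 2), (nll, nlf, nff)):
                y += [cat] * n
                x += [0.0 if lvl == "ref" else 1.0] * n
        sm_fit = OrderedModel(np.array(y), np.array(x)[:, None], distr="logit").fit(
            method="bfgs", disp=False
        )
        assert fit.coef["alt"] == pytest.approx(sm_fit.params[0], abs=1e-3)
        assert fit.se["alt"] == pytest.approx(sm_fit.bse[0], abs=1e-3)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)

    def test_cutpoints_ascending_and_cov_symmetric(self):
        fit = fit_proportional_odds_counts(
            {"a": (50, 30, 20), "b": (20, 30, 50)}, reference="a"
        )
        assert np.all(np.diff(fit.cutpoints) > 0)
        assert np.allclose(fit.cov, fit.cov.T)
        assert fit.ci_low["b"] < fit.odds_ratios["b"] < fit.ci_high["b"]

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            fit_proportional_odds_counts({"a": (1, 2, 3)}, reference="z")


class TestKnockdownRegression:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 10.0, 20.0, 30.0])
        line = knockdown_regression(x, 2 * x + 1)
        assert line.slope == pytest.approx(2.0, abs=1e-12)
        assert line.intercept == pytest.approx(1.0, abs=1e-12)
        assert line.r_squared == pytest.approx(1.0)
        assert line.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_hand_computed_three_points(self):
        """(0,0),(1,1),(2,4): normal equations give slope 2, intercept -1/3."""
        line = knockdown_regression([0, 1, 2], [0, 1, 4])
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(-1 / 3)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            knockdown_regression([15, 15], [10, 20])


class TestAncova:
    def test_identical_groups_f_zero(self):
        x = np.arange(10.0)
        y = 2 * x + np.array([0.1, -0.2, 0.3, 0, 0.2, -0.1, 0, 0.1, -0.3, 0.2])
        f, df, p = ancova_slopes(x, y, x, y)
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_parallel_noiseless_lines_f_zero(self):
        x = np.arange(8.0)
        f, _, _ = ancova_slopes(x, 2 * x + 1, x, 2 * x + 9)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_matches_nested_model_lstsq_oracle(self):
        """Full (4-parameter) vs reduced (common slope) residual comparison
        computed independently with least squares."""
        rng = np.random.default_rng(8)
        x1, x2 = np.arange(15.0), np.arange(15.0)
        y1 = 1.8 * x1 - 2 + rng.normal(0, 3, 15)
        y2 = 0.2 * x2 - 5 + rng.normal(0, 3, 15)
        f, (df1, df2), p = ancova_slopes(x1, y1, x2, y2)

        n = 30
        g = np.r_[np.zeros(15), np.ones(15)]
        x = np.r_[x1, x2]
        y = np.r_[y1, y2]
        X_full = np.c_[np.ones(n), g, x, g * x]
        X_red = np.c_[np.ones(n), g, x]
        sse = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        f_oracle = (sse(X_red) - sse(X_full)) / (sse(X_full) / (n - 4))
        assert f == pytest.approx(f_oracle, rel=1e-9)
        assert df2 == n - 4
        assert p == pytest.approx(float(sps.f.sf(f_oracle, 1, n - 4)), rel=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            ancova_slopes([1, 1], [0, 1], [1, 2], [0, 1])


class TestResistanceMetrics:
    def test_equal_proportions_ratio_one(self):
        assert resistance_ratio(0.4, 0.4) == 1.0

    def test_three_fold(self):
        assert resistance_ratio(0.90, 0.30) == pytest.approx(3.0)

    def test_full_reference_knockdown_scale(self):
        """Reference at 100% knockdown vs test near 1.8% gives the ~55-fold
        magnitude the resistant strain showed."""
        assert resistance_ratio(1.0, 1 / 54.5) == pytest.approx(54.5)

    def test_zero_denominator_warns_and_returns_inf(self):
        with pytest.warns(UserWarning):
            assert resistance_ratio(0.9, 0.0) == math.inf

    def test_bioassay_record_accessors(self):
        rec = BioassayResult(
            strain="KNWR", insecticide="permethrin", n_total=66,
            counts={15: 10, 30: 30, 45: 60, 60: 66, 120: 66},
        )
        assert rec.proportion(45) == pytest.approx(60 / 66)
        assert resistance_ratio(rec, rec) == 1.0

    def test_nonmonotone_counts_rejected(self):
        with pytest.raises(ValueError):
            BioassayResult("a", "b", 20, counts={15: 5, 30: 3})

    @pytest.mark.parametrize(
        "p,expected",
        [(0.15, "resistant_suspected"), (1.0, "susceptible"), (0.90, "susceptible")],
    )
    def test_cdc_classification_rule(self, p, expected):
        assert classify_cdc_resistance(p) == expected

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            classify_cdc_resistance(1.2)
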
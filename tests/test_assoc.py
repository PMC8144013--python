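"""Allelic chi-squared, odds ratios, logistic adjustment, Breslow-Day."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cdgps import genio, simdata
from cdgps.assoc import (AssocConfig, ContingencyTable2x2, allele_table,
                         allelic_chi2, breslow_day, logistic_assoc,
                         mantel_haenszel_or, odds_ratio_ci, run_association,
                         sex_stratified_tables)


class TestAlleleTable:
    def test_direct_count(self):
        t = allele_table([2, 1, 0, 0, 0], [1, 1, 1, 0, 0])
        assert (t.a, t.b, t.c, t.d) == (3, 3, 0, 4)

    def test_missing_doses_excluded(self):
        t = allele_table([2, np.nan, 0, 0], [1, 1, 0, 0])
        assert (t.a, t.b) == (2, 0)

    def test_x_males_contribute_one_allele(self):
        doses = [2.0, 2.0, 1.0, 0.0]
        labels = [1, 1, 0, 0]
        sex = ["M", "F", "F", "F"]
        t = allele_table(doses, labels, sex=sex, chrom="X")
        # case male dose 2 -> 1 allele; case female dose 2 -> 2 alleles
        assert (t.a, t.b) == (3, 0)
        assert (t.c, t.d) == (1, 3)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            allele_table([np.nan, 1], [1, 1])


class TestChi2:
    def test_null_table(self):
        chi2, p = allelic_chi2(ContingencyTable2x2(10, 10, 10, 10))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_expanded_value(self):
        # expected cell counts all 5 -> sum (O-E)^2/E = 4 * 0.2
        chi2, p = allelic_chi2(ContingencyTable2x2(6, 4, 4, 6))
        assert chi2 == pytest.approx(0.8)
        assert p == pytest.approx(0.3711, abs=5e-4)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            allelic_chi2(ContingencyTable2x2(0, 5, 0, 5))

    def test_equals_squared_two_proportion_z(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 100, 4)
            chi2, _ = allelic_chi2(ContingencyTable2x2(a, b, c, d))
            p1, p2 = a / (a + b), c / (c + d)
            pbar = (a + c) / (a + b + c + d)
            z = (p1 - p2) / np.sqrt(pbar * (1 - pbar)
                                    * (1 / (a + b) + 1 / (c + d)))
            assert chi2 == pytest.approx(z ** 2, rel=1e-10)


class TestOddsRatio:
    def test_null_is_symmetric_on_log_scale(self):
        or_, lo, hi, corr = odds_ratio_ci(ContingencyTable2x2(10, 10, 10, 10))
        assert or_ == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0, rel=1e-10)
        assert not corr

    def test_zero_cell_haldane_correction(self):
        or_, lo, hi, corr = odds_ratio_ci(ContingencyTable2x2(5, 0, 3, 7))
        assert corr
        assert np.isfinite(or_) and lo < or_ < hi

    def test_allele_flip_inverts(self):
        t = ContingencyTable2x2(12, 20, 30, 15)
        flipped = ContingencyTable2x2(20, 12, 15, 30)
        or1, lo1, hi1, _ = odds_ratio_ci(t)
        or2, lo2, hi2, _ = odds_ratio_ci(flipped)
        assert or2 == pytest.approx(1 / or1, rel=1e-12)
        assert lo2 == pytest.approx(1 / hi1, rel=1e-12)
        assert hi2 == pytest.approx(1 / lo1, rel=1e-12)
        c1 = allelic_chi2(t)
        c2 = allelic_chi2(flipped)
        assert c1[0] == pytest.approx(c2[0], rel=1e-12)


class TestLogistic:
    def test_null_data_or_near_one(self):
        rng = np.random.default_rng(5)
        doses = rng.binomial(2, 0.3, 2000).astype(float)
        labels = rng.binomial(1, 0.25, 2000).astype(float)
        sex = np.where(rng.random(2000) < 0.5, "F", "M")
        fit = logistic_assoc(doses, labels, sex=sex)
        assert fit["or_adjusted"] == pytest.approx(1.0, abs=0.15)

    def test_covariate_free_fit_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        doses = rng.binomial(2, 0.4, 500).astype(float)
        labels = (rng.random(500) < 1 / (1 + np.exp(-(-1 + 0.4 * doses)))
                  ).astype(float)
        fit = logistic_assoc(doses, labels)
        ref = sm.Logit(labels, sm.add_constant(doses)).fit(disp=0)
        assert fit["or_adjusted"] == pytest.approx(np.exp(ref.params[1]),
                                                   rel=1e-6)

    def test_perfect_separation_flagged(self):
        doses = np.array([0, 0, 0, 2, 2, 2], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = logistic_assoc(doses, labels)
        assert "separation" in fit["flags"] or "non_convergence" in fit["flags"]

    def test_interaction_p_reported(self):
        rng = np.random.default_rng(7)
        doses = rng.binomial(2, 0.3, 800).astype(float)
        labels = rng.binomial(1, 0.3, 800).astype(float)
        sex = np.where(rng.random(800) < 0.5, "F", "M")
        fit = logistic_assoc(doses, labels, sex=sex, interaction=True)
        assert 0 <= fit["p_interaction"] <= 1


class TestBreslowDay:
    def test_identical_strata_homogeneous(self):
        p, or_mh = breslow_day([ContingencyTable2x2(6, 4, 4, 6)] * 2)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_opposing_strata_heterogeneous(self):
        p, _ = breslow_day([ContingencyTable2x2(20, 5, 5, 20),
                            ContingencyTable2x2(5, 20, 20, 5)])
        assert p < 1e-6

    def test_matches_statsmodels_on_random_tables(self):
        """Independent-oracle agreement on 20+ random stratified tables."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            strata = [ContingencyTable2x2(*rng.integers(3, 150, 4))
                      for _ in range(int(rng.integers(2, 4)))]
            p_mine, or_mine = breslow_day(strata)
            st = sm.stats.StratifiedTable([t.as_array() for t in strata])
            assert p_mine == pytest.approx(
                st.test_equal_odds(adjust=False).pvalue, abs=1e-8)
            assert or_mine == pytest.approx(st.oddsratio_pooled, rel=1e-10)

    def test_calibration_under_common_or(self):
        """Null BD P roughly uniform when the OR is shared across sexes."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            tables = []
            for n1, n0 in ((150, 300), (100, 220)):
                p_ctrl = 0.3
                p_case = 0.3 * 1.5 / (1 - 0.3 + 0.3 * 1.5)
                a = rng.binomial(n1, p_case)
                c = rng.binomial(n0, p_ctrl)
                tables.append(ContingencyTable2x2(a, n1 - a, c, n0 - c))
            try:
                pvals.append(breslow_day(tables)[0])
            except ValueError:
                continue
        pvals = np.asarray(pvals)
        # uniformity: mean ~0.5, 5% tail ~5%
        assert abs(pvals.mean() - 0.5) < 0.06
        assert abs((pvals < 0.05).mean() - 0.05) < 0.04

    def test_single_stratum_errors(self):
        with pytest.raises(ValueError):
            breslow_day([ContingencyTable2x2(6, 4, 4, 6)])


class TestRunAssociation:
    def test_causal_snp_ranks_first(self):
        cfg = simdata.SimConfig(
            n_cases=600, n_controls=1800,
            variants=[simdata.SimVariant("causal", "1", 1_000_000, 0.3,
                                         beta_disease=float(np.log(2.0)))]
            + [simdata.SimVariant(f"null{j}", "2", 1_000_000 * (j + 1), 0.3)
               for j in range(9)],
            intercept=-2.5, beta_sex=0.0, seed=21)
        g, pheno, _ = simdata.simulate_cohort(cfg)
        cohort = genio.Cohort(g, pheno)
        results = run_association(cohort, "status")
        best = max(results, key=lambda r: r.chi2)
        assert best.variant_id == "causal"
        assert best.or_ == pytest.approx(2.0, rel=0.25)

    def test_min_events_rule(self, paper_shape_cohort):
        cohort = paper_shape_cohort
        cohort.phenotypes.table["rare_flag"] = np.nan
        cases = cohort.phenotypes.is_case()
        vals = np.full(len(cases), np.nan)
        vals[cases] = 0.0
        vals[np.flatnonzero(cases)[:3]] = 1.0
        cohort.phenotypes.table["rare_flag"] = vals
        with pytest.raises(ValueError, match="fewer than"):
            run_association(cohort, "rare_flag")
        cohort.phenotypes.table.drop(columns=["rare_flag"], inplace=True)

    def test_x_variant_uses_stratified_tests(self, paper_shape_cohort):
        results = run_association(paper_shape_cohort, "status")
        by_id = {r.variant_id: r for r in results}
        rx = by_id["rs5979785"]
        assert np.isfinite(rx.or_mh)
        assert np.isfinite(rx.p_bd)
        # sex-stratified tables exist for both sexes
        g = paper_shape_cohort.genotypes
        j = g.variant_index()["rs5979785"]
        labels = paper_shape_cohort.phenotypes.is_case().astype(float)
        strata = sex_stratified_tables(g.dose[:, j], labels, g.sex,
                                       chrom="X")
        assert len(strata) == 2

    def test_sex_confounding_controlled(self):
        """A sex-only effect inflates the crude test, not the adjusted one."""
        rng = np.random.default_rng(33)
        n = 3000
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        # dose correlated with sex, disease driven by sex only
        p_dose = np.where(sex == "F", 0.45, 0.25)
        doses = rng.binomial(2, p_dose).astype(float)
        p_case = np.where(sex == "F", 0.45, 0.15)
        labels = (rng.random(n) < p_case).astype(float)
        crude = logistic_assoc(doses, labels)
        adjusted = logistic_assoc(doses, labels, sex=sex)
        assert abs(np.log(adjusted["or_adjusted"])) < \
            abs(np.log(crude["or_adjusted"]))
        assert abs(np.log(adjusted["or_adjusted"])) < 0.12
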
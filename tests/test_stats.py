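from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

import pelvimetry3d as p
from pelvimetry3d import calibration
from pelvimetry3d.measures import DISTANCE_MEASURES, MEASURE_REGISTRY
from pelvimetry3d.stats import (
    CohortComparison,
    GroupSummary,
    cohort_table,
    t_power,
    two_sample_t,
)
from pelvimetry3d.synthetic import PhantomParams, _calibrate_generator, sample_landmark_cohort


class TestTwoSampleT:
    def test_identical_groups_give_null_result(self):
        res = two_sample_t(GroupSummary("x", 10, 5.0, 1.0, 10, 5.0, 1.0))
        assert res.t == 0.0 and res.p_value == 1.0

    def test_pooled_formula_on_exact_rationals(self):
        """Textbook pooled formula evaluated symbolically on small integers."""
        n1, m1, s1 = 4, 10, 2
        n2, m2, s2 = 6, 7, 3
        sp2 = Fraction((n1 - 1) * s1**2 + (n2 - 1) * s2**2, n1 + n2 - 2)
        t_exact = (m1 - m2) / float(sp2 * Fraction(1, n1) + sp2 * Fraction(1, n2)) ** 0.5
        res = two_sample_t(GroupSummary("x", n1, m1, s1, n2, m2, s2))
        assert res.t == pytest.approx(t_exact, rel=1e-12)
        assert res.df == n1 + n2 - 2

    def test_matches_scipy_reference(self):
        res = two_sample_t(GroupSummary("x", 100, 126.2, 8.6, 100, 119.4, 9.9))
        t_ref, p_ref = sps.ttest_ind_from_stats(126.2, 8.6, 100, 119.4, 9.9, 100)
        assert res.t == pytest.approx(float(t_ref), rel=1e-12)
        assert res.p_value == pytest.approx(float(p_ref), rel=1e-12)

    def test_obstetric_conjugate_from_printed_summaries(self):
        """Rounded published summaries give t ≈ 5.19, p ≈ 5e-7 — the same
        order of magnitude as the published 4.4e-7 from unrounded data."""
        res = two_sample_t(GroupSummary("obstetric", 100, 126.2, 8.6, 100, 119.4, 9.9))
        assert res.t == pytest.approx(5.19, abs=0.01)
        assert 1e-7 < res.p_value < 1e-6

    def test_pelvic_depth_below_headline_bound(self):
        res = two_sample_t(GroupSummary("depth", 100, 102.8, 9.8, 100, 111.5, 8.8))
        assert res.p_value < 1e-4

    def test_zero_variance_edge_cases(self):
        with pytest.raises(ValueError, match="infinite"):
            two_sample_t(GroupSummary("x", 5, 1.0, 0.0, 5, 2.0, 0.0))
        res = two_sample_t(GroupSummary("x", 5, 1.0, 0.0, 5, 1.0, 0.0))
        assert res.p_value == 1.0

    def test_welch_differs_under_variance_heterogeneity(self):
        pooled = two_sample_t(GroupSummary("x", 10, 5.0, 1.0, 40, 4.0, 5.0))
        welch = two_sample_t(GroupSummary("x", 10, 5.0, 1.0, 40, 4.0, 5.0), welch=True)
        assert welch.df < pooled.df
        assert welch.t != pooled.t


class TestPower:
    def test_reference_design_quadruple_to_1e6(self):
        """d=0.4, n=100/100, α=0.05, two-tailed."""
        res = t_power(0.4, 100, 100, 0.05)
        assert res.noncentrality == pytest.approx(2.8284271, abs=1e-6)
        assert res.critical_t == pytest.approx(1.9720175, abs=1e-6)
        assert res.df == 198
        assert res.power == pytest.approx(0.8036475, abs=1e-6)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestIndPower

        for d, n in [(0.4, 100), (0.2, 50), (0.8, 20)]:
            ours = t_power(d, n, n, 0.05).power
            ref = TTestIndPower().power(effect_size=d, nobs1=n, ratio=1.0, alpha=0.05,
                                        alternative="two-sided")
            assert ours == pytest.approx(float(ref), abs=1e-8)

    def test_null_limit_power_approaches_alpha(self):
        assert t_power(1e-9, 100, 100, 0.05).power == pytest.approx(0.05, abs=1e-6)

    def test_power_monotone_in_sample_size(self):
        assert t_power(0.4, 200, 200).power > t_power(0.4, 100, 100).power

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_power(0.0, 100, 100)
        with pytest.raises(ValueError):
            t_power(0.4, 1, 100)
        with pytest.raises(ValueError):
            t_power(0.4, 100, 100, alpha=1.5)


@pytest.fixture(scope="module")
def synthetic_cohorts():
    records, labels = [], []
    for sex, seed in (("female", 17), ("male", 18)):
        cohort = sample_landmark_cohort(PhantomParams(sex_label=sex, seed=seed), 100)
        for lset, label in cohort:
            records.append(p.compute_pelvimetry(lset, validate=False))
            labels.append(label)
    return records, labels


class TestCohortTable:
    def test_exactly_21_rows_in_registry_order(self, synthetic_cohorts):
        records, labels = synthetic_cohorts
        table = cohort_table(records, labels)
        assert len(table) == 21
        assert list(table["measure"]) == list(MEASURE_REGISTRY)

    def test_distance_means_recover_calibration_targets(self, synthetic_cohorts):
        """Full-pipeline parameter recovery: cohort means within 3 SE."""
        records, labels = synthetic_cohorts
        table = cohort_table(records, labels).set_index("measure")
        for sex, targets in (("female", calibration.FEMALE_TARGETS),
                             ("male", calibration.MALE_TARGETS)):
            for m in DISTANCE_MEASURES:
                row = table.loc[m]
                se = row[f"sd_{sex}"] / np.sqrt(row[f"n_{sex}"])
                assert abs(row[f"mean_{sex}"] - targets[m][0]) < 3 * se, (sex, m)

    def test_sex_dimorphism_recovered(self, synthetic_cohorts):
        """Synthetic cohorts reproduce the calibrated direction of
        dimorphism: wider female inlet/outlet, deeper male pelvis."""
        records, labels = synthetic_cohorts
        table = cohort_table(records, labels).set_index("measure")
        assert table.loc["bis_ischiatic_diameter", "mean_female"] > table.loc["bis_ischiatic_diameter", "mean_male"]
        assert table.loc["pelvic_depth", "mean_female"] < table.loc["pelvic_depth", "mean_male"]
        assert table.loc["bis_ischiatic_diameter", "p_value"] < 0.05

    def test_duplicated_records_in_both_groups_give_p_one(self, synthetic_cohorts):
        records, _ = synthetic_cohorts
        some = records[:10]
        table = cohort_table(some + some, ["female"] * 10 + ["male"] * 10)
        assert (table["p_value"] == 1.0).all()

    def test_small_group_rejected(self, synthetic_cohorts):
        records, _ = synthetic_cohorts
        with pytest.raises(ValueError, match="at least 2"):
            cohort_table(records[:3], ["female", "female", "male"])

    def test_model_results_surface(self, synthetic_cohorts):
        records, labels = synthetic_cohorts
        results = CohortComparison(records, labels).fit()
        assert 0 <= results.n_significant <= 21
        text = results.summary()
        assert "obstetric_conjugate" in text and "female" in text
        assert {"p_bonferroni", "p_fdr_bh"} <= set(results.table.columns)


def test_type_one_error_calibrated_under_null():
    """With both groups drawn from the same template, the fraction of
    (replicate, measure) pairs with p < 0.05 stays inside the binomial 99%
    band around 0.05 (200 replicates, fixed seed)."""
    params = PhantomParams(sex_label="female", seed=0)
    gen = _calibrate_generator(params, p.MeasureConfig())
    n_rep, n_per_group = 200, 12
    hits = total = 0
    for rep in range(n_rep):
        draw = sample_landmark_cohort(
            PhantomParams(sex_label="female", seed=10_000 + rep),
            2 * n_per_group, generator=gen,
        )
        recs = [p.compute_pelvimetry(l, validate=False) for l, _ in draw]
        df = p.records_to_frame(recs)
        a, b = df.iloc[:n_per_group], df.iloc[n_per_group:]
        for m in MEASURE_REGISTRY:
            res = two_sample_t(GroupSummary(
                m, n_per_group, a[m].mean(), a[m].std(ddof=1),
                n_per_group, b[m].mean(), b[m].std(ddof=1)))
            hits += res.p_value < 0.05
            total += 1
    frac = hits / total
    half_width = 2.576 * np.sqrt(0.05 * 0.95 / total)
    assert abs(frac - 0.05) < half_width, frac
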
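"""Shapley axioms, Welch tests, chi-square with continuity correction."""

import numpy as np
import pytest
from scipy import stats

from neurofuse.interpret import (ContingencyTable2x2, chisq_yates,
                                 demographics_table, shapley_values,
                                 welch_from_summary, welch_ttest)
from neurofuse.io_data import SubjectRecord


class TestShapleyExact:
    """Axioms under exhaustive enumeration on <=4-region toy games."""

    def test_efficiency_on_linear_model(self, rng):
        x = rng.normal(size=4)
        base = np.zeros(4)
        w = np.array([1.0, -2.0, 0.5, 3.0])
        f = lambda v: float(v @ w)
        phi = shapley_values(f, x, base, groups=4, n_permutations=None)
        assert abs(phi.sum() - (f(x) - f(base))) < 1e-6
        np.testing.assert_allclose(phi, w * x, atol=1e-10)

    def test_efficiency_on_nonlinear_model(self, rng):
        x = rng.normal(size=3)
        base = rng.normal(size=3) * 0.1
        f = lambda v: float(np.tanh(v[0] * v[1]) + v[2] ** 2)
        phi = shapley_values(f, x, base, groups=3, n_permutations=None)
        assert abs(phi.sum() - (f(x) - f(base))) < 1e-6

    def test_symmetry_of_interchangeable_regions(self):
        x = np.array([1.0, 1.0, 0.3])
        base = np.zeros(3)
        f = lambda v: float(v[0] + v[1] + 5.0 * v[0] * v[1] + v[2])
        phi = shapley_values(f, x, base, groups=3, n_permutations=None)
        assert abs(phi[0] - phi[1]) < 1e-10

    def test_dummy_region_gets_zero(self, rng):
        x = rng.normal(size=3)
        base = rng.normal(size=3)
        f = lambda v: float(v[0] ** 2 - v[1])
        phi = shapley_values(f, x, base, groups=3, n_permutations=None)
        assert abs(phi[2]) < 1e-12

    def test_grouped_features(self, rng):
        x = rng.normal(size=4)
        base = np.zeros(4)
        f = lambda v: float(v.sum())
        groups = [np.array([0, 1]), np.array([2]), np.array([3])]
        phi = shapley_values(f, x, base, groups=groups, n_permutations=None)
        assert abs(phi[0] - (x[0] + x[1])) < 1e-10


class TestShapleyMonteCarlo:
    def test_estimate_within_two_se_of_exact(self, rng):
        x = rng.normal(size=3)
        base = np.zeros(3)
        f = lambda v: float(np.sin(v[0]) + v[1] * v[2] + 0.5 * v[2])
        exact = shapley_values(f, x, base, groups=3, n_permutations=None)
        reps = [shapley_values(f, x, base, groups=3, n_permutations=64,
                               seed=s) for s in range(30)]
        reps = np.stack(reps)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert (np.abs(reps.mean(axis=0) - exact) <= 2 * se + 1e-9).all()

    def test_constant_model_attributes_zero(self, rng):
        f = lambda v: 0.42
        phi = shapley_values(f, rng.normal(size=4), np.zeros(4), groups=4,
                             n_permutations=32, seed=0)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ValueError):
            shapley_values(lambda v: 0.0, np.zeros(2), np.zeros(2),
                           groups=2, n_permutations=0)


@pytest.fixture(scope="module")
def model_and_cohort(tiny_cohort):
    from neurofuse.model import ModelConfig, MultimodalNet
    cohort, _ = tiny_cohort
    model = MultimodalNet(ModelConfig.compact(d_in=8, n_sites=3), seed=0)
    return model, cohort


class TestRegionShapley:
    def test_constant_head_attributes_zero_everywhere(self,
                                                      model_and_cohort):
        """A model whose disease head ignores its inputs yields exactly
        zero attribution for every region."""
        from neurofuse.interpret import region_shapley
        model, cohort = model_and_cohort
        model.disease_head.linear.weight.data[:] = 0.0
        table = region_shapley(model, cohort, "ts", n_permutations=2,
                               seed=0, subject_idx=np.r_[0:2, 4:6])
        np.testing.assert_allclose(table.attribution.to_numpy(), 0.0,
                                   atol=1e-12)
        assert len(table) == 8
        assert (table.modality == "ts").all()

    def test_gmv_attribution_table_shape_and_sorting(self,
                                                     model_and_cohort):
        from neurofuse.interpret import region_shapley
        model, cohort = model_and_cohort
        model.disease_head.linear.weight.data[:] = 0.01
        table = region_shapley(model, cohort, "gmv", n_permutations=1,
                               seed=1, subject_idx=np.r_[0:2, 4:6])
        assert len(table) == 8
        mags = table.attribution.abs().to_numpy()
        assert (np.diff(mags) <= 1e-15).all()  # sorted by |attribution|
        assert ((table.p_value > 0) & (table.p_value <= 1)).all()

    def test_invalid_permutations_rejected(self, model_and_cohort):
        from neurofuse.interpret import region_shapley
        model, cohort = model_and_cohort
        with pytest.raises(ValueError):
            region_shapley(model, cohort, "ts", n_permutations=0)


class TestWelch:
    def test_identical_samples_t_zero_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        t, _, p = welch_ttest(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_on_random_draw(self, rng):
        a = rng.normal(0, 1, size=20)
        b = rng.normal(0.4, 2, size=20)
        t, df, p = welch_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(t - ref.statistic) < 1e-10
        assert abs(p - ref.pvalue) < 1e-10

    def test_matches_direct_formula(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        t, df, _ = welch_ttest(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_direct = (a.mean() - b.mean()) / np.sqrt(va / 20 + vb / 20)
        assert abs(t - t_direct) < 1e-10

    def test_one_sd_shift_detected_in_large_samples(self, rng):
        a = rng.normal(1.0, 1.0, size=400)
        b = rng.normal(0.0, 1.0, size=400)
        _, _, p = welch_ttest(a, b)
        assert p < 0.001

    def test_summary_agrees_with_sample_statistic(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(0.5, 1.5, size=30)
        t_samples, _, _ = welch_ttest(a, b)
        t_summary = welch_from_summary(a.mean(), a.std(ddof=1), 25,
                                       b.mean(), b.std(ddof=1), 30)
        assert abs(t_samples - t_summary) < 1e-10

    def test_equal_summaries_give_zero(self):
        assert welch_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5) == 0.0


class TestChiSquare:
    def test_proportional_table_is_zero_after_clamping(self):
        chi2, p = chisq_yates(ContingencyTable2x2(10, 20, 30, 60))
        assert chi2 == 0.0 and p == 1.0

    def test_transpose_invariance(self):
        t1 = ContingencyTable2x2(12, 34, 56, 78)
        t2 = ContingencyTable2x2(12, 56, 34, 78)
        assert chisq_yates(t1)[0] == pytest.approx(chisq_yates(t2)[0])

    def test_matches_scipy_contingency(self):
        table = ContingencyTable2x2(20, 30, 25, 15)
        chi2, p = chisq_yates(table)
        ref = stats.chi2_contingency(table.as_array(), correction=True)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_uncorrected_variant_direct_formula(self):
        table = ContingencyTable2x2(463, 813, 462, 642)
        chi2, _ = chisq_yates(table, correction=False)
        obs = table.as_array()
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        direct = ((obs - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(direct, abs=1e-10)
        assert chi2 == pytest.approx(7.708, abs=0.001)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_yates(ContingencyTable2x2(0, 0, 5, 5))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestDemographicsTable:
    def test_reports_all_three_characteristics(self, rng):
        records = []
        for i in range(40):
            records.append(SubjectRecord(
                subject_id=f"s{i}", site_id=0, label=i % 2,
                age=float(rng.normal(35, 10)),
                education=float(rng.normal(12, 3)),
                sex="male" if rng.uniform() < 0.4 else "female"))
        table = demographics_table(records)
        assert set(table.characteristic) == {"age", "education", "sex"}
        assert ((table.p_value > 0) & (table.p_value <= 1)).all()
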
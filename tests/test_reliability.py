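import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import speechlex as sl
from speechlex import PreconditionError, ValidationError
from speechlex.reliability import _derangements, fisher_mean, fisher_z
from speechlex.simulate import SyntheticCohortSpec, generate_feature_matrix


def _small_matrix(values_by_task, feature="f", group="intact"):
    """Matrix with one feature, explicit per-task participant columns."""
    rows = []
    for task, vals in values_by_task.items():
        for i, v in enumerate(vals):
            rows.append((f"p{i}", task, feature, float(v), group))
    return sl.FeatureMatrix(
        pd.DataFrame(rows, columns=list(sl.FeatureMatrix.COLUMNS))
    )


class TestZScore:
    def test_closed_form_column(self):
        m = _small_matrix({t: (2, 4, 6) for t in sl.TASKS})
        z = sl.zscore(m)
        vals = z.df.query("task_id == 'PDT1'").sort_values("participant_id")["value"]
        assert vals.to_list() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self):
        m = _small_matrix({t: (-1.0, 0.0, 1.0) for t in sl.TASKS})
        z = sl.zscore(m)
        assert np.allclose(z.df["value"], m.df["value"], atol=1e-12)

    def test_every_stratum_standardized(self):
        m = generate_feature_matrix(SyntheticCohortSpec(n_mci=6, n_intact=9, seed=11))
        z = sl.zscore(m, stratify_by_group=True)
        for (feat, task, grp), sub in z.df.groupby(
                ["feature_name", "task_id", "group"]):
            assert abs(sub["value"].mean()) < 1e-10
            assert sub["value"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_stratum_names_the_stratum(self):
        m = _small_matrix({t: (3, 3, 3) for t in sl.TASKS})
        with pytest.raises(PreconditionError, match="f"):
            sl.zscore(m)

    def test_pearson_invariant_to_zscoring(self):
        m = generate_feature_matrix(SyntheticCohortSpec(n_mci=5, n_intact=12, seed=3))
        raw = sl.pairwise_correlations(m, "picture", "full")
        z = sl.zscore(m, stratify_by_group=False)
        standardized = sl.pairwise_correlations(z, "picture", "full")
        assert np.allclose(raw, standardized, atol=1e-10)


class TestFisherMachinery:
    def test_round_trip_identity(self):
        rs = np.linspace(-0.999, 0.999, 51)
        assert np.allclose(np.tanh(fisher_z(rs)), rs, atol=1e-12)

    def test_averaging_identical_correlations_is_identity(self):
        for r in (-0.7, 0.0, 0.31, 0.95):
            assert fisher_mean([r, r, r]) == pytest.approx(r, abs=1e-12)

    def test_two_pair_average_closed_form(self):
        expect = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
        assert fisher_mean([0.2, 0.6]) == pytest.approx(expect, abs=1e-12)
        assert fisher_mean([0.2, 0.6]) == pytest.approx(0.4203, abs=1e-3)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(-0.999, 0.999))
    def test_round_trip_property(self, r):
        assert float(np.tanh(fisher_z(r))) == pytest.approx(r, abs=1e-12)


class TestWithinFeatureReliability:
    def test_identical_values_give_perfect_reliability(self):
        vals = (1.0, 2.0, 5.0, 7.0)
        m = _small_matrix({t: vals for t in sl.TASKS})
        ests = sl.within_feature_reliability(m, "picture", "full")
        assert len(ests) == 1
        assert ests[0].r_mean == pytest.approx(1.0)
        assert ests[0].n_pairs == 3

    def test_expository_uses_the_single_task_pair(self):
        m = generate_feature_matrix(SyntheticCohortSpec(n_mci=5, n_intact=10, seed=9))
        ests = sl.within_feature_reliability(
            sl.zscore(m, stratify_by_group=False), "expository", "full")
        assert all(e.n_pairs == 1 for e in ests)
        r = sl.pairwise_correlations(m, "expository", "full")
        for k, e in enumerate(ests):
            assert e.r_mean == pytest.approx(r[0, k], abs=1e-10)

    def test_monte_carlo_recovery_of_generative_rho(self):
        spec = SyntheticCohortSpec(n_mci=250, n_intact=250, rho=0.6, seed=21)
        z = sl.zscore(generate_feature_matrix(spec), stratify_by_group=False)
        grand = sl.grand_mean_correlation(z, "picture", "full")
        assert grand == pytest.approx(0.6, abs=0.05)

    def test_consistency_small_bias_at_large_n(self):
        for rho, seed in ((0.3, 1), (0.6, 2), (0.9, 3)):
            spec = SyntheticCohortSpec(n_mci=500, n_intact=500, rho=rho, seed=seed)
            z = sl.zscore(generate_feature_matrix(spec), stratify_by_group=False)
            grand = sl.grand_mean_correlation(z, "picture", "full")
            assert abs(grand - rho) < 0.02


class TestResamplingNull:
    def test_derangements_have_no_fixed_points(self):
        rng = np.random.default_rng(0)
        perms = _derangements(rng, 7, 200)
        assert perms.shape == (200, 7)
        assert (perms != np.arange(7)).all()
        assert np.array_equal(np.sort(perms, axis=1),
                              np.tile(np.arange(7), (200, 1)))

    def test_seed_gives_bit_identical_null(self):
        m = generate_feature_matrix(SyntheticCohortSpec(n_mci=5, n_intact=12, seed=4))
        z = sl.zscore(m, stratify_by_group=False)
        a = sl.resample_null(z, "picture", "full", reps=300, seed=99)
        b = sl.resample_null(z, "picture", "full", reps=300, seed=99)
        assert np.array_equal(a.values, b.values)

    def test_seed_is_required(self):
        m = generate_feature_matrix(SyntheticCohortSpec(n_mci=5, n_intact=12, seed=4))
        with pytest.raises(ValidationError, match="seed"):
            sl.resample_null(m, "picture", "full", reps=100)

    def test_null_mean_near_zero_on_uncorrelated_cohort(self):
        spec = SyntheticCohortSpec(n_mci=10, n_intact=29, rho=0.0, seed=6)
        z = sl.zscore(generate_feature_matrix(spec), stratify_by_group=False)
        null = sl.resample_null(z, "picture", "full", reps=10_000, seed=17)
        assert abs(null.mean) < 0.02

    def test_reliable_cohort_rejects_null(self):
        spec = SyntheticCohortSpec(n_mci=20, n_intact=80, rho=0.6, seed=8)
        z = sl.zscore(generate_feature_matrix(spec), stratify_by_group=False)
        null = sl.resample_null(z, "picture", "full", reps=2000, seed=5)
        observed = sl.grand_mean_correlation(z, "picture", "full")
        assert null.p_value(observed) < 0.001

    def test_p_value_is_add_one_smoothed_and_one_sided(self):
        null = sl.NullDistribution("picture", "full", np.linspace(-0.5, 0.5, 99))
        assert null.p_value(1.0) == pytest.approx(1 / 100)
        assert null.p_value(-1.0) == pytest.approx(1.0)


class TestCompareGroups:
    def test_identical_lists_t_zero_p_one(self):
        rs = [0.1 * k for k in range(1, 17)]
        cmp = sl.compare_groups(rs, rs)
        assert cmp.t == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)

    def test_df_is_thirty_for_16_features_per_group(self):
        rng = np.random.default_rng(0)
        cmp = sl.compare_groups(rng.uniform(0, 0.9, 16), rng.uniform(0, 0.9, 16))
        assert cmp.df == 30

    def test_shifted_lists_significant(self):
        rng = np.random.default_rng(12)
        za = rng.normal(0.8, 0.1, 16)
        zb = za - 0.5
        cmp = sl.compare_groups(np.tanh(za), np.tanh(zb))
        assert cmp.p < 0.001
        assert cmp.ci_low > 0

    def test_matches_scipy_t_oracle(self):
        rng = np.random.default_rng(3)
        a, b = np.tanh(rng.normal(0.5, 0.2, 16)), np.tanh(rng.normal(0.4, 0.2, 16))
        cmp = sl.compare_groups(a, b)
        from scipy import stats
        t, p = stats.ttest_ind(np.arctanh(a), np.arctanh(b), equal_var=True)
        assert cmp.t == pytest.approx(float(t), abs=1e-12)
        assert cmp.p == pytest.approx(float(p), abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            sl.compare_groups([0.1] * 15, [0.1] * 16)


class TestIntraindividualVariability:
    def test_constant_scores_give_zero_itv(self):
        m = _small_matrix({t: (0.31, -0.5, 1.7) for t in sl.TASKS})
        res = sl.intraindividual_variability(m, "intact")
        assert res[0].itv == pytest.approx(0.0, abs=1e-12)

    def test_alternating_scores_sample_sd(self):
        vals = {"ET1": (1, 0), "ET2": (-1, 0), "PDT1": (1, 0),
                "PDT2": (-1, 0), "PDT3": (1, 0)}
        res = sl.intraindividual_variability(_small_matrix(vals), "intact")
        # participant p0 has z = (1,-1,1,-1,1): sample SD = sqrt(1.2)
        # participant p1 is constant; group mean = sqrt(1.2)/2
        assert res[0].itv == pytest.approx(np.sqrt(1.2) / 2, abs=1e-12)
        assert np.sqrt(1.2) == pytest.approx(1.0954, abs=1e-4)

    def test_group_mean_of_participant_sds(self):
        # participant SDs 0.5 and 1.5 -> itv 1.0
        base = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
        sd = np.std(base, ddof=1)
        vals = {t: (0.5 * v / sd, 1.5 * v / sd) for t, v in zip(sl.TASKS, base)}
        res = sl.intraindividual_variability(_small_matrix(vals), "intact")
        assert res[0].itv == pytest.approx(1.0, abs=1e-12)

    def test_variance_pooled_mode_matches_printed_form(self):
        m = generate_feature_matrix(SyntheticCohortSpec(n_mci=4, n_intact=8, seed=2))
        res = sl.intraindividual_variability(m, "full", mode="variance_pooled")
        arr, pids = m.to_array()
        expect = (arr.std(axis=0, ddof=1) ** 2).sum(axis=0) / len(pids)
        for r, e in zip(res, expect):
            assert r.itv == pytest.approx(float(e), abs=1e-12)

    def test_itv_increases_with_task_noise(self):
        itvs = []
        for sigma in (0.2, 0.5, 1.0):
            rho = 1.0 / (1.0 + sigma**2)  # trait variance 1
            spec = SyntheticCohortSpec(n_mci=50, n_intact=150, rho=rho, seed=31)
            z = sl.zscore(generate_feature_matrix(spec), stratify_by_group=False)
            res = sl.intraindividual_variability(z, "full")
            itvs.append(np.mean([r.itv for r in res]))
        assert itvs[0] < itvs[1] < itvs[2]

    def test_higher_rho_means_lower_itv_and_higher_reliability(self):
        out = []
        for rho in (0.3, 0.8):
            spec = SyntheticCohortSpec(n_mci=40, n_intact=160, rho=rho, seed=13)
            z = sl.zscore(generate_feature_matrix(spec), stratify_by_group=False)
            itv = np.mean([r.itv for r in sl.intraindividual_variability(z, "full")])
            rel = sl.grand_mean_correlation(z, "picture", "full")
            out.append((itv, rel))
        assert out[1][0] < out[0][0]  # itv falls
        assert out[1][1] > out[0][1]  # reliability rises
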
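"""AUC, covariate removal, t/chi-square tests, FDR, and group pipelines."""

import numpy as np
import pandas as pd
import pytest

from funconn import (
    SparsityGrid,
    SubjectTable,
    behavior_correlation,
    bh_fdr,
    chi_square_2x2,
    edgewise_group_test,
    metric_auc,
    residualize,
    welch_ttest,
)
from funconn.stats import demographic_table, pooled_ttest

from conftest import cohort_tables
from funconn.synthetic import CohortConfig, make_cohort


def subject_frame(n_a=10, n_b=10, seed=0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    return SubjectTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["IAD"] * n_a + ["HC"] * n_b,
        "age": rng.integers(13, 20, n),
        "sex": rng.choice(["M", "F"], n),
        "education": rng.integers(8, 14, n),
    }))


class TestAuc:
    def test_constant_curve_is_rectangle(self):
        grid = SparsityGrid(0.10, 0.34, 0.01)
        assert metric_auc(np.ones(25), grid) == pytest.approx(0.24)

    def test_linear_curve_is_trapezoid(self):
        grid = SparsityGrid(0.1, 0.3, 0.1)
        assert metric_auc(np.array([0.0, 1.0, 2.0]), grid) == pytest.approx(0.2)

    def test_zero_curve(self):
        grid = SparsityGrid(0.1, 0.3, 0.1)
        assert metric_auc(np.zeros(3), grid) == 0.0

    def test_single_point_grid_rejected(self):
        grid = SparsityGrid(0.2, 0.21, 0.05)
        with pytest.raises(ValueError):
            metric_auc(np.array([1.0]), grid)


class TestResidualize:
    def test_mean_preserved_and_signal_retained(self):
        st = subject_frame(seed=1)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(20) + 3.0
        adj = residualize(y, st)
        assert adj.mean() == pytest.approx(y.mean())
        assert np.corrcoef(adj, y)[0, 1] > 0.7  # independent of covariates

    def test_pure_age_effect_removed(self):
        st = subject_frame(seed=3)
        y = 2.0 * st.data["age"].to_numpy(float) + 1.0
        adj = residualize(y, st)
        np.testing.assert_allclose(adj, y.mean(), atol=1e-8)

    def test_residual_orthogonal_to_design(self):
        st = subject_frame(seed=4)
        y = np.random.default_rng(5).standard_normal(20)
        adj = residualize(y, st)
        x, _ = st.design_matrix()
        np.testing.assert_allclose(x.T @ (adj - adj.mean()), 0, atol=1e-8)


class TestWelch:
    def test_education_summary_stats(self):
        _, _, p = welch_ttest((17, 10.8, 2.6), (16, 11.6, 2.8))
        assert p == pytest.approx(0.4029, abs=0.005)

    def test_bis11_summary_stats(self):
        _, _, p = welch_ttest((17, 69.2, 12.7), (16, 66.8, 7.8))
        assert p == pytest.approx(0.5154, abs=0.005)

    def test_identical_groups(self):
        t, _, p = welch_ttest((10, 5.0, 1.0), (12, 5.0, 1.0))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_permutation_test(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 17)
        b = rng.normal(0.6, 1.0, 16)
        t_obs, _, p_welch = welch_ttest(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            t_perm, _, _ = welch_ttest(pooled[:17], pooled[17:])
            count += abs(t_perm) >= abs(t_obs)
        assert p_welch == pytest.approx(count / n_perm, abs=0.02)

    def test_pooled_variant_available(self):
        t, df, p = pooled_ttest((17, 10.8, 2.6), (16, 11.6, 2.8))
        assert df == 31


class TestChiSquare:
    def test_gender_counts(self):
        chi2, p = chi_square_2x2([[15, 2], [14, 2]])
        assert p == pytest.approx(0.9484, abs=1e-4)

    def test_balanced_table(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_perfect_separation(self):
        chi2, p = chi_square_2x2([[5, 0], [0, 5]])
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(0.00157, abs=1e-4)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[5, 0], [5, 0]])


def brute_force_bh(pvals, q):
    """Independent step-up enumeration: largest k with p_(k) <= k q / m."""
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBhFdr:
    def test_all_at_uniform_thresholds_rejected(self):
        _, rej = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert rej.all()

    def test_all_ones_rejected_nothing(self):
        _, rej = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not rej.any()

    def test_step_up_walk(self):
        qv, rej = bh_fdr([0.001, 0.8, 0.9], q=0.05)
        assert list(rej) == [True, False, False]
        assert np.all(np.diff(qv[np.argsort([0.001, 0.8, 0.9])]) >= 0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random(5) ** rng.uniform(0.5, 3)
            _, rej = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(rej, brute_force_bh(p, 0.05))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        p = rng.random(30)
        qv, _ = bh_fdr(p)
        assert np.all(qv >= p - 1e-12)


class TestGroupPipelines:
    def test_copied_groups_give_zero_t(self):
        cfg = CohortConfig(
            n_group_a=4, n_group_b=4, n_regions=6, n_timepoints=60,
            module_sizes=(3, 3), seed=20,
        )
        cohort = make_cohort(cfg)
        conns, st = cohort_tables(cohort)
        # make group B an exact copy of group A (connectivity and covariates)
        ids = st.data["subject_id"].tolist()
        for a_id, b_id in zip(ids[:4], ids[4:]):
            conns[b_id] = conns[a_id]
            for col in ["age", "sex", "education"]:
                st.data.loc[st.data.subject_id == b_id, col] = \
                    st.data.loc[st.data.subject_id == a_id, col].to_numpy()
        res = edgewise_group_test(conns, st)
        np.testing.assert_allclose(res["t"].fillna(0.0), 0, atol=1e-10)
        assert not res["significant"].any()

    def test_score_copy_of_metric_correlates_perfectly(self):
        st = subject_frame(n_a=12, n_b=10, seed=9)
        rng = np.random.default_rng(10)
        aucs = pd.DataFrame({
            "degree:R0": rng.standard_normal(22),
            "nodal_efficiency:R0": rng.standard_normal(22),
            "betweenness:R0": rng.standard_normal(22),
        })
        st.data["YIAS"] = aucs["nodal_efficiency:R0"]
        for s in ["BIS-11", "TMDS", "SDQ-P", "SDQ-C", "FAD"]:
            st.data[s] = rng.standard_normal(22)
        res = behavior_correlation(aucs, st, regions=["R0"], adjust_covariates=False)
        hit = res[(res.metric == "nodal_efficiency") & (res.score == "YIAS")]
        assert hit["r"].iloc[0] == pytest.approx(1.0)
        assert hit["p"].iloc[0] < 1e-10
        assert hit["significant"].iloc[0]

    def test_demographic_table_shape(self, small_null_cohort):
        _, st = cohort_tables(small_null_cohort)
        demo = demographic_table(st)
        assert set(demo["variable"]) >= {"sex", "age", "education", "YIAS"}
        assert ((demo["p"].dropna() >= 0) & (demo["p"].dropna() <= 1)).all()
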
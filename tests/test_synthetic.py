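"""Synthetic cohort generator: covariance structure, determinism, recovery."""

import json

import numpy as np
import pytest

from funconn.synthetic import (
    CohortConfig,
    build_group_covariance,
    default_config,
    make_cohort,
    simulate_timeseries,
    write_cohort,
)


def two_module_config(**kw):
    defaults = dict(
        n_group_a=2, n_group_b=2, n_regions=4, n_timepoints=50,
        module_sizes=(2, 2), r_within=0.6, r_between=0.1, seed=0,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestGroupCovariance:
    def test_block_structure_exact(self):
        cfg = two_module_config()
        cov = build_group_covariance(cfg, "IAD")
        assert cov[0, 1] == pytest.approx(0.6) and cov[2, 3] == pytest.approx(0.6)
        assert cov[0, 2] == pytest.approx(0.1) and cov[1, 3] == pytest.approx(0.1)
        np.testing.assert_allclose(np.diag(cov), 1.0)
        # already positive-definite: the repair is the identity here
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_planted_edge_is_additive(self):
        cfg = two_module_config(planted_edges=((0, 3, 0.3),))
        cov_b = build_group_covariance(cfg, "HC")
        assert cov_b[0, 3] == pytest.approx(0.4)
        cov_a = build_group_covariance(cfg, "IAD")
        assert cov_a[0, 3] == pytest.approx(0.1)

    def test_zero_correlations_give_identity(self):
        cfg = two_module_config(r_within=0.0, r_between=0.0)
        np.testing.assert_array_equal(build_group_covariance(cfg, "IAD"), np.eye(4))

    def test_repair_restores_positive_definiteness(self):
        # r_between high enough to break PD with many equal-correlation blocks
        cfg = CohortConfig(
            n_regions=6, module_sizes=(3, 3), r_within=0.1, r_between=-0.3,
            n_group_a=2, n_group_b=2, n_timepoints=50, seed=0,
        )
        cov = build_group_covariance(cfg, "IAD")
        assert np.linalg.eigvalsh(cov).min() > 0
        np.testing.assert_allclose(np.diag(cov), 1.0)

    def test_invalid_planted_edges_rejected(self):
        with pytest.raises(ValueError):
            two_module_config(planted_edges=((0, 9, 0.2),))
        with pytest.raises(ValueError):
            two_module_config(planted_edges=((0, 1, 0.2), (1, 0, 0.1)))

    def test_module_sizes_must_sum(self):
        with pytest.raises(ValueError):
            two_module_config(module_sizes=(2, 3))


class TestSimulateTimeseries:
    def test_identity_covariance_recovered(self):
        ts = simulate_timeseries(np.eye(4), 4000, seed=1)
        r = np.corrcoef(ts.values, rowvar=False)
        off = r[np.triu_indices(4, 1)]
        assert np.abs(off).max() < 0.05  # 3/sqrt(T) Monte-Carlo band

    def test_target_correlation_recovered(self):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.6
        ts = simulate_timeseries(cov, 4000, seed=2)
        r = np.corrcoef(ts.values, rowvar=False)
        assert r[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_timeseries(np.eye(3), 100, seed=7)
        b = simulate_timeseries(np.eye(3), 100, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 1.1], [1.1, 1.0]])
        with pytest.raises(ValueError):
            simulate_timeseries(bad, 10, seed=0)


class TestMakeCohort:
    def test_default_config_shapes(self):
        cohort = make_cohort(default_config(seed=5))
        assert len(cohort.subjects) == 33
        groups = [s.group for s in cohort.subjects]
        assert groups.count("IAD") == 17 and groups.count("HC") == 16
        for s in cohort.subjects:
            assert s.timeseries.values.shape == (210, 90)
            assert s.motion.values.shape == (210, 6)
            assert set(s.scores) == {"YIAS", "BIS-11", "TMDS", "SDQ-P", "SDQ-C", "FAD"}

    def test_planted_contrast_approaches_delta(self):
        delta = 0.4
        cfg = CohortConfig(
            n_group_a=8, n_group_b=8, n_regions=6, n_timepoints=3000,
            module_sizes=(3, 3), planted_edges=((0, 4, delta),), seed=9,
        )
        cohort = make_cohort(cfg)
        r_a = [np.corrcoef(s.timeseries.values, rowvar=False)[0, 4]
               for s in cohort.subjects if s.group == "IAD"]
        r_b = [np.corrcoef(s.timeseries.values, rowvar=False)[0, 4]
               for s in cohort.subjects if s.group == "HC"]
        assert np.mean(r_b) - np.mean(r_a) == pytest.approx(delta, abs=0.1)

    def test_adding_subjects_preserves_existing_draws(self):
        small = make_cohort(two_module_config(seed=4))
        large = make_cohort(two_module_config(seed=4, n_group_b=3))
        for s_small, s_large in zip(small.subjects[:2], large.subjects[:2]):
            np.testing.assert_array_equal(
                s_small.timeseries.values, s_large.timeseries.values
            )

    def test_ground_truth_carries_planted_edges(self):
        cfg = two_module_config(planted_edges=((0, 2, 0.3),))
        gt = make_cohort(cfg).ground_truth
        assert gt["planted_edges"] == [[0, 2, 0.3]]
        assert "group_covariance" in gt


class TestWriteCohort:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = two_module_config(seed=8)
        d1 = write_cohort(make_cohort(cfg), tmp_path / "a")
        d2 = write_cohort(make_cohort(cfg), tmp_path / "b")
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_expected_files_written(self, tmp_path):
        out = write_cohort(make_cohort(two_module_config()), tmp_path / "c")
        names = {p.name for p in out.iterdir()}
        assert "subjects.tsv" in names and "ground_truth.json" in names
        assert "subject_sub-000_ts.tsv" in names
        assert "subject_sub-000_motion.tsv" in names
        gt = json.loads((out / "ground_truth.json").read_text())
        assert set(gt["group_covariance"]) == {"IAD", "HC"}
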
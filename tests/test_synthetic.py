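"""Tests of the VAR(1) cohort generator: stationarity guards, determinism,
parameter recovery against OLS oracles, and null-distribution fidelity."""

import numpy as np
import pytest
from scipy import stats

from twinconn import (
    ClinicalScoreSpec,
    CohortSpec,
    NonStationaryError,
    extract_regional_series,
    fit_bivariate_gc,
    render_voxel_volumes,
    simulate_clinical_table,
    simulate_cohort,
    simulate_subject,
)
from twinconn.connectivity import GCConfig
from twinconn.clinical import GroupSummary, anova_from_raw, anova_from_summary

from conftest import cohort_ec_table, planted_cohort_spec


class TestSimulateSubject:
    def test_white_noise_has_no_lag_structure(self):
        s = simulate_subject(np.zeros((4, 4)), np.eye(4), 10000, seed=0)
        x = s.data
        t = x.shape[1]
        lag_cov = x[:, 1:] @ x[:, :-1].T / (t - 1)
        assert np.all(np.abs(lag_cov) < 4 / np.sqrt(t))

    def test_planted_coupling_recovered_by_ols(self):
        # directed edge 1 -> 2 (0-based (0, 1)) with weight 0.4; OLS of
        # region 2 on both lagged regions should recover it within 3 SE
        a = np.zeros((4, 4))
        a[0, 1] = 0.4
        s = simulate_subject(a, np.eye(4), 10000, seed=7)
        x = s.data
        design = np.column_stack([np.ones(x.shape[1] - 1), x[1, :-1], x[0, :-1]])
        beta, *_ = np.linalg.lstsq(design, x[1, 1:], rcond=None)
        se = 1.0 / np.sqrt(x.shape[1])
        assert abs(beta[-1] - 0.4) < 3 * se

    def test_same_seed_bit_identical(self):
        a = 0.3 * np.eye(3)
        s1 = simulate_subject(a, np.eye(3), 100, seed=42)
        s2 = simulate_subject(a, np.eye(3), 100, seed=42)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_nonstationary_coupling_rejected(self):
        with pytest.raises(NonStationaryError, match="spectral radius"):
            simulate_subject(1.1 * np.eye(3), np.eye(3), 50, seed=0)

    def test_non_positive_definite_cov_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive definite"):
            simulate_subject(np.zeros((2, 2)), bad, 50, seed=0)


class TestSimulateCohort:
    def test_subject_count_and_labels(self):
        spec = CohortSpec(n_regions=6, n_volumes=40,
                          groups=(("HC", 3), ("COTWIN", 2), ("SZ", 4)), seed=1)
        subjects = simulate_cohort(spec)
        assert len(subjects) == 9
        assert [s.group for s in subjects] == ["HC"] * 3 + ["COTWIN"] * 2 + ["SZ"] * 4
        assert len({s.subject_id for s in subjects}) == 9

    def test_reproducible_from_seed(self):
        spec = CohortSpec(n_regions=5, n_volumes=30, groups=(("a", 2), ("b", 2)), seed=3)
        c1 = simulate_cohort(spec)
        c2 = simulate_cohort(CohortSpec(n_regions=5, n_volumes=30,
                                        groups=(("a", 2), ("b", 2)), seed=3))
        for s1, s2 in zip(c1, c2):
            np.testing.assert_array_equal(s1.data, s2.data)

    def test_planted_group_difference_detectable(self):
        # +0.5 planted on one directed edge for SZ only: the two-sample t
        # on per-subject EC estimates of that edge should be large
        tvals = []
        for seed in range(3):
            edges = {(0, 1): 0.5}
            spec = CohortSpec(n_regions=8, n_volumes=180,
                              groups=(("HC", 20), ("SZ", 20)),
                              group_coupling_deltas={"SZ": edges}, seed=seed)
            subjects = simulate_cohort(spec)
            est = {
                g: [fit_bivariate_gc(s.data[0], s.data[1]) for s in subjects if s.group == g]
                for g in ("HC", "SZ")
            }
            tvals.append(abs(stats.ttest_ind(est["SZ"], est["HC"]).statistic))
        assert np.mean(tvals) > 3

    def test_zero_subject_sd_variance_shrinks_with_t(self):
        # with no between-subject jitter, across-subject spread of the
        # planted-edge estimate is innovation noise only: shrinks with T
        def spread(n_volumes):
            spec = CohortSpec(n_regions=4, n_volumes=n_volumes,
                              groups=(("SZ", 8),),
                              group_coupling_deltas={"SZ": {(0, 1): 0.4}},
                              subject_sd=0.0, seed=9)
            ests = [fit_bivariate_gc(s.data[0], s.data[1]) for s in simulate_cohort(spec)]
            return np.var(ests)

        assert spread(2000) < spread(170) / 3

    def test_stationarity_guard_on_planted_edges(self):
        with pytest.raises(NonStationaryError):
            CohortSpec(n_regions=3, n_volumes=50, groups=(("a", 2),),
                       base_coupling=0.9 * np.eye(3),
                       group_coupling_deltas={"a": {(0, 0): 0.2}}, seed=0)

    def test_parameter_recovery_matches_large_t_oracle(self):
        # oracle: the same bivariate regression computed on one very long
        # series from the same model (the bivariate estimate, not the
        # planted weight, is the target)
        for w in (0.2, 0.4):
            a = np.zeros((4, 4))
            a[0, 1] = w
            long = simulate_subject(a, np.eye(4), 120_000, seed=100)
            x, y = long.data[0], long.data[1]
            zx = (x - x.mean()) / x.std(ddof=1)
            zy = (y - y.mean()) / y.std(ddof=1)
            design = np.column_stack([np.ones(zx.size - 1), zy[:-1], zx[:-1]])
            oracle = np.linalg.lstsq(design, zy[1:], rcond=None)[0][-1]

            spec = CohortSpec(n_regions=4, n_volumes=180, groups=(("g", 50),),
                              group_coupling_deltas={"g": {(0, 1): w}},
                              subject_sd=0.0, seed=200 + int(10 * w))
            ests = [fit_bivariate_gc(s.data[0], s.data[1]) for s in simulate_cohort(spec)]
            assert abs(np.mean(ests) - oracle) < 0.05

    def test_null_two_sample_t_follows_t_distribution(self):
        # no planted differences: edge t statistics across two groups of 10
        # should be approximately t(18) over ~5000 directed edges
        from twinconn import two_sample_maxt_perm

        spec = CohortSpec(n_regions=71, n_volumes=180,
                          groups=(("a", 10), ("b", 10)), seed=5)
        table = cohort_ec_table(spec)
        res = two_sample_maxt_perm(table, "a", "b", n_perm=1, seed=0)
        assert res.true_t.size == 71 * 70
        assert stats.kstest(res.true_t, "t", args=(18,)).pvalue > 0.01


class TestRenderVoxelVolumes:
    def _series(self, data):
        from twinconn import RegionTimeSeries

        return RegionTimeSeries("s", "g", np.asarray(data, dtype=float))

    def test_noise_free_round_trip(self):
        rng = np.random.default_rng(0)
        series = self._series(rng.standard_normal((3, 12)))
        atlas = np.array([[[1, 1], [2, 3]], [[0, 2], [3, 3]]])
        vol = render_voxel_volumes(series, atlas, noise_sd=0.0)
        out = extract_regional_series(vol, atlas)
        np.testing.assert_allclose(out.data, series.data, atol=1e-12)

    def test_label_zero_voxels_stay_zero(self):
        series = self._series(np.ones((1, 5)) * 5.0)
        atlas = np.array([[[0, 1]]])
        vol = render_voxel_volumes(series, atlas, noise_sd=0.0)
        assert np.all(vol[0, 0, 0] == 0)
        assert np.all(vol[0, 0, 1] == 5.0)

    def test_label_beyond_regions_rejected(self):
        series = self._series(np.ones((2, 4)))
        atlas = np.array([[[1, 3]]])
        with pytest.raises(ValueError, match="label 3"):
            render_voxel_volumes(series, atlas, noise_sd=0.0)

    def test_noisy_region_mean_near_truth(self):
        # 1000 voxels at noise_sd=1: extracted mean within 0.1 of the truth
        # ~95% of the time (SE = 1/sqrt(1000) ~ 0.032; 0.1 is ~3 SE)
        series = self._series(np.zeros((1, 50)))
        atlas = np.ones((10, 10, 10), dtype=int)
        vol = render_voxel_volumes(series, atlas, noise_sd=1.0, seed=4)
        out = extract_regional_series(vol, atlas)
        assert np.mean(np.abs(out.data[0]) < 0.1) > 0.9


class TestClinicalTable:
    def test_zero_sd_gives_group_mean(self):
        spec = ClinicalScoreSpec(scores={"age": {"a": (30.0, 0.0), "b": (40.0, 0.0)}}, seed=0)
        df = simulate_clinical_table(spec, {"a": 3, "b": 2})
        assert set(df.loc[df.group == "a", "age"]) == {30.0}
        assert set(df.loc[df.group == "b", "age"]) == {40.0}

    def test_same_seed_identical(self):
        spec = ClinicalScoreSpec(scores={"x": {"a": (0.0, 1.0)}}, seed=5)
        df1 = simulate_clinical_table(spec, {"a": 4})
        df2 = simulate_clinical_table(spec, {"a": 4})
        assert df1.equals(df2)

    def test_missing_group_score_is_nan(self):
        spec = ClinicalScoreSpec(scores={"panss": {"SZ": (67.1, 6.8)}}, seed=0)
        df = simulate_clinical_table(spec, {"HC": 2, "SZ": 2})
        assert df.loc[df.group == "HC", "panss"].isna().all()
        assert df.loc[df.group == "SZ", "panss"].notna().all()

    def test_replicate_anova_matches_population_f_for_strong_effect(self):
        # Monte-Carlo oracle on the global-functioning row (strong group
        # separation): mean replicate F approaches the F implied by the
        # population means/SDs.  (Near the null this equivalence fails —
        # E[F] ~ 1 — so a strong-effect row is the valid probe.)
        pop = [(98.5, 8.6), (86.0, 7.5), (78.0, 7.6)]
        implied = anova_from_summary([GroupSummary(m, s, 20) for m, s in pop])
        rng = np.random.default_rng(11)
        fs = [
            anova_from_raw(
                np.concatenate([rng.normal(m, s, 20) for m, s in pop]),
                np.repeat(["a", "b", "c"], 20),
            )
            for _ in range(400)
        ]
        assert abs(np.mean(fs) / implied - 1) < 0.10
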
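"""Tests of signal cleaning: volume discarding, motion exclusion, atlas
extraction, nuisance regression, band-pass filtering and detrending."""

import numpy as np
import pytest

from twinconn import (
    RegionTimeSeries,
    bandpass,
    detrend_linear,
    discard_initial_volumes,
    exclude_by_motion,
    expand_motion_24,
    extract_regional_series,
    regress_nuisance,
    render_voxel_volumes,
)
from twinconn.prep import clean_series, PrepConfig


def make_series(data, tr=2.0):
    return RegionTimeSeries("s1", "HC", np.asarray(data, dtype=float), tr_seconds=tr)


class TestDiscard:
    def test_default_discard_180_to_170(self, rng):
        s = make_series(rng.standard_normal((3, 180)))
        out = discard_initial_volumes(s, 10)
        assert out.n_timepoints == 170
        np.testing.assert_array_equal(out.data, s.data[:, 10:])
        assert out.subject_id == s.subject_id and out.region_ids == s.region_ids

    def test_zero_discard_is_identity(self, small_series):
        out = discard_initial_volumes(small_series, 0)
        np.testing.assert_array_equal(out.data, small_series.data)

    def test_too_short_rejected(self, rng):
        s = make_series(rng.standard_normal((2, 5)))
        with pytest.raises(ValueError, match="discard"):
            discard_initial_volumes(s, 10)

    def test_works_on_4d_volumes(self, rng):
        vol = rng.standard_normal((2, 2, 2, 30))
        assert discard_initial_volumes(vol, 10).shape == (2, 2, 2, 20)


class TestMotionExclusion:
    def test_excess_displacement_excluded(self):
        trace = np.zeros((100, 6))
        trace[50, 1] = 2.1
        decision = exclude_by_motion(trace)
        assert not decision.keep and "displacement" in decision.reason

    def test_excess_rotation_excluded(self):
        trace = np.zeros((100, 6))
        trace[3, 5] = -2.5
        decision = exclude_by_motion(trace)
        assert not decision.keep and "rotation" in decision.reason

    def test_boundary_exactly_two_is_kept(self):
        # thresholds are strict: a trace touching exactly 2.0 passes
        trace = np.full((10, 6), 2.0)
        assert exclude_by_motion(trace).keep

    def test_zero_motion_kept(self):
        assert exclude_by_motion(np.zeros((10, 6))).keep

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            exclude_by_motion(np.empty((0, 6)))

    def test_24_parameter_expansion(self):
        trace = np.arange(18, dtype=float).reshape(3, 6)
        out = expand_motion_24(trace)
        assert out.shape == (3, 24)
        np.testing.assert_array_equal(out[:, :6], trace)
        np.testing.assert_array_equal(out[0, 6:12], np.zeros(6))  # lag pad
        np.testing.assert_array_equal(out[1:, 6:12], trace[:-1])
        np.testing.assert_array_equal(out[:, 12:], out[:, :12] ** 2)


class TestExtraction:
    def test_constant_regions_average_exactly(self):
        atlas = np.array([[[1, 1], [2, 2]]])
        vol = np.zeros((1, 2, 2, 4))
        vol[0, 0] = 3.0
        vol[0, 1] = 7.0
        out = extract_regional_series(vol, atlas)
        np.testing.assert_array_equal(out.data, [[3.0] * 4, [7.0] * 4])
        assert out.region_ids == (1, 2)

    def test_empty_expected_region_named_in_error(self):
        atlas = np.array([[[1, 1]]])
        vol = np.zeros((1, 1, 2, 3))
        with pytest.raises(ValueError, match="region 2"):
            extract_regional_series(vol, atlas, expected_labels=[1, 2])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            extract_regional_series(np.zeros((2, 2, 2, 5)), np.ones((3, 3, 3), dtype=int))

    def test_round_trip_with_renderer(self, rng):
        series = make_series(rng.standard_normal((4, 20)))
        atlas = rng.integers(0, 5, size=(6, 6, 6))
        while len(np.unique(atlas[atlas > 0])) < 4:  # ensure all labels present
            atlas = rng.integers(0, 5, size=(6, 6, 6))
        vol = render_voxel_volumes(series, atlas, noise_sd=0.0)
        out = extract_regional_series(vol, atlas)
        np.testing.assert_allclose(out.data, series.data, atol=1e-12)


class TestNuisanceRegression:
    def test_residuals_orthogonal_to_covariates(self, rng):
        s = make_series(rng.standard_normal((4, 170)))
        nuis = rng.standard_normal((170, 5))
        out = regress_nuisance(s, nuis)
        for row in out.data:
            norms = np.abs(nuis.T @ row) / np.linalg.norm(row)
            assert np.all(norms < 1e-8)
            assert abs(row.sum()) < 1e-8  # intercept removed

    def test_series_equal_to_covariate_is_annihilated(self, rng):
        cov = rng.standard_normal(170)
        s = make_series(cov[None, :])
        out = regress_nuisance(s, cov[:, None])
        assert np.max(np.abs(out.data)) < 1e-8

    def test_intercept_only_mean_centers(self, rng):
        s = make_series(rng.standard_normal((3, 100)) + 5.0)
        out = regress_nuisance(s, np.empty((100, 0)))
        np.testing.assert_allclose(out.data, s.data - s.data.mean(axis=1, keepdims=True),
                                   atol=1e-10)

    def test_planted_motion_contamination_removed(self, rng):
        motion = rng.standard_normal(170)
        signal = rng.standard_normal(170)
        s = make_series((0.7 * motion + signal)[None, :])
        out = regress_nuisance(s, motion[:, None])
        r = np.corrcoef(out.data[0], signal)[0, 1]
        assert r > 0.99

    def test_rank_deficient_design_names_columns(self, rng):
        cov = rng.standard_normal(50)
        nuis = np.column_stack([cov, 2 * cov])
        s = make_series(rng.standard_normal((2, 50)))
        with pytest.raises(ValueError, match=r"collinear columns: \[1\]"):
            regress_nuisance(s, nuis)

    def test_regression_is_idempotent(self, rng):
        s = make_series(rng.standard_normal((3, 120)))
        nuis = rng.standard_normal((120, 4))
        once = regress_nuisance(s, nuis)
        twice = regress_nuisance(once, nuis)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)


class TestBandpass:
    def _sinusoid(self, freq, t=512, tr=2.0):
        time = np.arange(t) * tr
        return make_series(np.sin(2 * np.pi * freq * time)[None, :], tr)

    def test_in_band_amplitude_preserved(self):
        out = bandpass(self._sinusoid(0.05)).data[0]
        amp = np.max(np.abs(out[100:-100]))
        assert abs(amp - 1.0) < 0.05

    def test_low_frequency_attenuated(self):
        out = bandpass(self._sinusoid(0.005)).data[0]
        assert np.max(np.abs(out)) < 0.1  # >= 10x reduction

    def test_octave_above_high_edge_attenuated_20db(self):
        # steady-state response; the first/last samples carry boundary
        # transients of the forward-backward pass and are excluded
        out = bandpass(self._sinusoid(0.2)).data[0]
        assert np.max(np.abs(out[50:-50])) < 0.1

    def test_zero_series_stays_zero(self):
        out = bandpass(make_series(np.zeros((2, 64))))
        assert np.all(out.data == 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(self._sinusoid(0.05), band=(0.01, 0.3))


class TestDetrend:
    def test_exact_ramp_removed(self):
        t = np.arange(100, dtype=float)
        s = make_series(np.vstack([2.0 + 0.3 * t, -1.0 + 5.0 * t]))
        out = detrend_linear(s)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_constant_becomes_zero(self):
        out = detrend_linear(make_series(np.full((2, 50), 7.0)))
        assert np.max(np.abs(out.data)) < 1e-8

    def test_matches_direct_ols_fit(self, rng):
        data = rng.standard_normal((3, 80))
        s = make_series(data)
        out = detrend_linear(s)
        t = np.arange(80, dtype=float)
        design = np.column_stack([np.ones(80), t])
        for raw, removed in zip(data, out.data):
            beta, *_ = np.linalg.lstsq(design, raw, rcond=None)
            np.testing.assert_allclose(removed, raw - design @ beta, atol=1e-10)
        # residual uncorrelated with time index
        for row in out.data:
            assert abs(np.corrcoef(row, t)[0, 1]) < 1e-8


def test_clean_series_preserves_metadata_and_shape(rng):
    s = make_series(rng.standard_normal((6, 170)))
    out = clean_series(s, nuisance=rng.standard_normal((170, 3)), config=PrepConfig())
    assert out.subject_id == s.subject_id
    assert out.group == s.group
    assert out.region_ids == s.region_ids
    assert out.data.shape == s.data.shape
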
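"""Masks, temporal preprocessing and the matrix-free centrality computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmap import (
    BoldRun,
    dct_highpass_basis,
    ecm_pair,
    fast_ecm,
    highpass_filter,
    intersection_mask,
    normalize_timeseries,
    regress_motion,
    single_subject_mask,
    variance_mask,
)
from conftest import dense_ecm_oracle, random_normalized, random_run


class TestMasks:
    def test_all_positive_run_gives_full_mask(self, rng):
        run = random_run(rng)
        assert single_subject_mask(run).all()

    def test_single_zero_timepoint_excludes_voxel(self, rng):
        run = random_run(rng)
        run.data[2, 3, 1, 17] = 0.0
        mask = single_subject_mask(run)
        assert not mask[2, 3, 1]
        assert mask.sum() == mask.size - 1

    def test_partial_coverage_slices_excluded(self, rng):
        run = random_run(rng)
        run.data[:, :, -2:, :] = 0.0
        mask = single_subject_mask(run)
        # oracle: direct per-voxel temporal-minimum scan
        direct = np.array(
            [[[run.data[x, y, z].min() > 0 for z in range(run.data.shape[2])]
              for y in range(run.data.shape[1])]
             for x in range(run.data.shape[0])]
        )
        assert np.array_equal(mask, direct)
        assert not mask[:, :, -2:].any()

    def test_empty_mask_is_an_error(self):
        run = BoldRun(data=np.zeros((3, 3, 3, 5)), tr_s=2.0)
        with pytest.raises(ValueError, match="empty"):
            single_subject_mask(run)

    def test_intersection_identity_and_disjoint(self, rng):
        m = rng.random((5, 5, 4)) > 0.3
        m[0, 0, 0] = True
        assert np.array_equal(intersection_mask([m, m.copy()]), m)
        a = np.zeros((4, 4, 2), bool)
        b = np.zeros((4, 4, 2), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        with pytest.raises(ValueError, match="empty"):
            intersection_mask([a, b])

    def test_intersection_equals_elementwise_and(self, rng):
        masks = [rng.random((6, 5, 4)) > 0.2 for _ in range(4)]
        expected = masks[0] & masks[1] & masks[2] & masks[3]
        if not expected.any():
            pytest.skip("degenerate draw")
        got = intersection_mask(masks)
        for idx in np.ndindex(*expected.shape):
            assert got[idx] == all(m[idx] for m in masks)


class TestHighpass:
    def test_constant_plus_drift_removed(self):
        # constant + linear drift at the study settings: the drift basis
        # must absorb nearly all of it, and the residual must equal the
        # explicit projection onto [intercept, drift basis]
        t = np.arange(325)
        series = 5.0 + 0.01 * t
        data = np.tile(series, (2, 2, 1, 1))
        run = BoldRun(data=data, tr_s=1.82)
        out = highpass_filter(run, 182.0)
        basis = dct_highpass_basis(325, 1.82, 182.0)
        x = np.column_stack([np.ones(325), basis])
        beta, *_ = np.linalg.lstsq(x, series, rcond=None)
        explicit_resid = series - x @ beta
        np.testing.assert_allclose(out.data[0, 0, 0], explicit_resid, atol=1e-9)
        centered = series - series.mean()
        assert np.linalg.norm(out.data[0, 0, 0]) < 0.05 * np.linalg.norm(centered)

    def test_fast_oscillation_preserved(self):
        t = np.arange(325) * 1.82
        series = np.sin(2 * np.pi * t / 20.0)  # 20 s period, well above cutoff
        run = BoldRun(data=series.reshape(1, 1, 1, -1), tr_s=1.82)
        out = highpass_filter(run, 182.0)
        ratio = np.linalg.norm(out.data) / np.linalg.norm(series - series.mean())
        assert ratio > 0.99

    def test_default_cutoff_basis_order(self):
        # 182 s = 100 TR at TR 1.82 with 325 volumes: K = floor(2*325*1.82/182)
        basis = dct_highpass_basis(325, 1.82, 182.0)
        assert basis.shape == (325, 6)
        # every retained regressor has period above the cutoff
        for k in range(1, basis.shape[1] + 1):
            assert 2 * 325 * 1.82 / k >= 182.0

    def test_output_is_mean_zero(self, rng):
        run = random_run(rng, t=80)
        out = highpass_filter(run, 100.0)
        assert np.abs(out.data.mean(axis=3)).max() < 1e-9

    def test_unrepresentable_cutoff_warns_and_is_identity(self, rng):
        run = random_run(rng, t=10, tr_s=2.0)
        with pytest.warns(UserWarning, match="no drift regressor"):
            out = highpass_filter(run, 1000.0)
        centered = run.data - run.data.mean(axis=3, keepdims=True)
        np.testing.assert_allclose(out.data, centered, atol=1e-12)

    def test_cutoff_below_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="twice the TR"):
            highpass_filter(random_run(rng), 3.0)


class TestMotionRegression:
    def test_zero_motion_is_identity(self, rng):
        run = random_run(rng)
        out = regress_motion(run, np.zeros((run.n_timepoints, 6)))
        np.testing.assert_allclose(out.data, run.data, atol=1e-10)

    def test_series_in_regressor_span_fully_removed(self, rng):
        t = 50
        params = rng.normal(size=(t, 6))
        series = 3.0 + params @ rng.normal(size=6)
        data = np.tile(series, (2, 2, 1, 1))
        out = regress_motion(BoldRun(data=data, tr_s=2.0), params)
        resid = out.data[0, 0, 0] - out.data[0, 0, 0].mean()
        assert resid.var() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        # residuals (after removing the preserved voxel mean) must equal the
        # full-design OLS residuals from an explicit lstsq solve
        run = random_run(rng, shape=(3, 3, 2), t=30)
        params = rng.normal(size=(30, 6))
        out = regress_motion(run, params)
        y = run.data.reshape(-1, 30).T
        x = np.column_stack([np.ones(30), params])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        full_resid = y - x @ beta
        got = out.data.reshape(-1, 30).T
        got_centered = got - got.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(got_centered, full_resid, atol=1e-8)

    def test_residuals_orthogonal_to_regressors_and_mean_kept(self, rng):
        run = random_run(rng)
        params = rng.normal(size=(run.n_timepoints, 6))
        out = regress_motion(run, params)
        np.testing.assert_allclose(
            out.data.mean(axis=3), run.data.mean(axis=3), atol=1e-8
        )
        centered = params - params.mean(axis=0)
        dots = out.data.reshape(-1, run.n_timepoints) @ centered
        assert np.abs(dots).max() < 1e-6

    def test_collinear_regressors_warned_and_dropped(self, rng):
        run = random_run(rng, t=30)
        col = rng.normal(size=30)
        params = np.column_stack([col, col, col, col, col, col])
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_motion(run, params)
        assert out.data.shape == run.data.shape


class TestNormalization:
    def test_hand_example_1_2_3(self):
        run = BoldRun(data=np.array([1.0, 2.0, 3.0]).reshape(1, 1, 1, 3), tr_s=2.0)
        run2 = BoldRun(data=np.tile([1.0, 2.0, 3.0], (2, 1, 1, 1)), tr_s=2.0)
        m = normalize_timeseries(run2, np.ones((2, 1, 1), bool))
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)
        np.testing.assert_allclose(m.rows[0], expected, atol=1e-12)

    def test_rows_centered_unit_norm_and_correlation_dot(self, rng):
        m = random_normalized(rng, 12, 30)
        assert np.abs(m.rows.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(np.linalg.norm(m.rows, axis=1), 1.0, atol=1e-10)
        r = np.corrcoef(m.rows[3], m.rows[7])[0, 1]
        assert abs(m.rows[3] @ m.rows[7] - r) < 1e-10

    def test_identical_rows_hit_scale_maximum_two(self):
        series = np.array([1.0, 4.0, 2.0, 6.0])
        data = np.tile(series, (2, 1, 1, 1))
        m = normalize_timeseries(BoldRun(data=data, tr_s=2.0), np.ones((2, 1, 1), bool))
        assert abs(m.connectivity_entry(0, 1) - 2.0) < 1e-12

    def test_anticorrelated_rows_hit_scale_minimum_zero(self):
        series = np.array([1.0, 4.0, 2.0, 6.0])
        data = np.stack([series, -series]).reshape(2, 1, 1, 4)
        m = normalize_timeseries(BoldRun(data=data, tr_s=2.0), np.ones((2, 1, 1), bool))
        assert abs(m.connectivity_entry(0, 1)) < 1e-12

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40).filter(
        lambda s: np.std(s) > 1e-6))
    def test_normalization_invariants_hold_for_arbitrary_series(self, series):
        data = np.tile(np.asarray(series), (2, 1, 1, 1))
        m = normalize_timeseries(BoldRun(data=data, tr_s=2.0),
                                 np.ones((2, 1, 1), bool))
        assert abs(m.rows[0].mean()) < 1e-10
        assert abs(np.linalg.norm(m.rows[0]) - 1.0) < 1e-10
        assert abs(m.connectivity_entry(0, 1) - 2.0) < 1e-9

    def test_zero_variance_voxel_is_named_error(self):
        data = np.ones((2, 1, 1, 5))
        data[1, 0, 0] = [1, 2, 3, 4, 5]
        with pytest.raises(ValueError, match=r"\(0, 0, 0\)"):
            normalize_timeseries(BoldRun(data=data, tr_s=2.0), np.ones((2, 1, 1), bool))

    def test_variance_mask_removes_flat_voxels(self):
        data = np.ones((2, 1, 1, 5))
        data[1, 0, 0] = [1, 2, 3, 4, 5]
        run = BoldRun(data=data, tr_s=2.0)
        out = variance_mask(run, np.ones((2, 1, 1), bool))
        assert not out[0, 0, 0] and out[1, 0, 0]


class TestFastEcm:
    def test_identical_rows_give_uniform_eigenvector(self):
        series = np.sin(np.arange(20))
        data = np.tile(series, (5, 1, 1, 1)) + 10.0
        m = normalize_timeseries(BoldRun(data=data, tr_s=2.0), np.ones((5, 1, 1), bool))
        cm = fast_ecm(m)
        np.testing.assert_allclose(cm.values, 1.0 / np.sqrt(5), atol=1e-8)

    @pytest.mark.parametrize("n,t", [(20, 15), (200, 120), (57, 99)])
    def test_matches_dense_eigendecomposition(self, rng, n, t):
        m = random_normalized(rng, n, t)
        cm = fast_ecm(m)
        assert np.max(np.abs(cm.values - dense_ecm_oracle(m.rows))) < 1e-6

    def test_probed_connectivity_entries_in_0_2(self, rng):
        m = random_normalized(rng, 30, 25)
        for _ in range(200):
            i, j = rng.integers(0, 30, size=2)
            e = m.connectivity_entry(int(i), int(j))
            assert 0.0 <= e <= 2.0 + 1e-12

    def test_output_invariants(self, rng):
        m = random_normalized(rng, 40, 30)
        cm = fast_ecm(m)
        assert cm.converged
        assert np.all(cm.values > 0)
        assert abs(np.linalg.norm(cm.values) - 1.0) < 1e-8

    def test_scale_invariance_of_raw_series(self, rng):
        data = rng.normal(size=(4, 4, 2, 30)) + 50.0
        mask = np.ones((4, 4, 2), bool)
        a = fast_ecm(normalize_timeseries(BoldRun(data=data, tr_s=2.0), mask))
        b = fast_ecm(normalize_timeseries(BoldRun(data=data * 7.3, tr_s=2.0), mask))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_iteration_count_modest_on_random_data(self, rng):
        m = random_normalized(rng, 500, 325)
        cm = fast_ecm(m, tol=1e-9)
        assert cm.converged and cm.iterations_used <= 100

    def test_degenerate_single_voxel_rejected(self, rng):
        m = random_normalized(rng, 2, 10)
        m.rows = m.rows[:1]
        with pytest.raises(ValueError, match="at least 2"):
            fast_ecm(m)


class TestEcmPair:
    def test_zero_motion_gives_identical_maps(self, rng):
        run = random_run(rng, shape=(5, 5, 3), t=60)
        mask = np.ones((5, 5, 3), bool)
        plain, mreg = ecm_pair(run, np.zeros((60, 6)), mask, cutoff_s=60.0)
        np.testing.assert_allclose(plain.values, mreg.values, atol=1e-7)

    def test_shared_motion_artefact_suppressed_by_regression(self, rng):
        # a strong nuisance signal shared by all voxels inflates uniform
        # similarity; regression should reduce it
        t = 80
        params = np.zeros((t, 6))
        params[:, 0] = np.cumsum(rng.normal(size=t))
        artefact = params[:, 0] - params[:, 0].mean()
        data = rng.normal(size=(4, 4, 3, t)) + 100.0
        data += 3.0 * (artefact / artefact.std())
        run = BoldRun(data=data, tr_s=2.0)
        mask = np.ones((4, 4, 3), bool)
        plain, mreg = ecm_pair(run, params, mask, cutoff_s=60.0)
        uniform = np.full(plain.values.shape, 1.0 / np.sqrt(plain.values.size))
        sim_plain = plain.values @ uniform
        sim_mreg = mreg.values @ uniform
        assert sim_plain > sim_mreg

    def test_deterministic_rerun(self, rng):
        run = random_run(rng, shape=(4, 4, 2), t=50)
        params = rng.normal(size=(50, 6)) * 0.01
        mask = np.ones((4, 4, 2), bool)
        a = ecm_pair(run, params, mask, cutoff_s=60.0)
        b = ecm_pair(run, params, mask, cutoff_s=60.0)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
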
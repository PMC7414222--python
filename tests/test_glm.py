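"""HRF, design construction, OLS/FIR fitting, PSC scaling, ROI extraction, QC."""

import numpy as np
import pytest

from eventbold.glm import (
    DesignMatrix,
    RoiTimeSeries,
    adjusted_beta,
    build_design,
    canonical_hrf,
    contrast_variance,
    extract_roi_timeseries,
    fit_fir,
    fit_glm,
    qc_filter,
    scale_psc,
)
from eventbold.synth import SubjectRecord, simulate_roi_bold

TR = 2.47


def make_ts(values, tr_s=TR):
    return RoiTimeSeries("sub", "roi", np.asarray(values, float), tr_s)


def make_subject(i, mean_fd=0.1, max_fd=0.3, tsnr=100.0):
    return SubjectRecord(
        subject_id=f"s{i:02d}", age=50.0, sex="F", mean_fd=mean_fd, max_fd=max_fd,
        tsnr=tsnr, logmem_imm=14.0, logmem_del=13.0, fluency=11.0,
        visuospatial=14.0, word_memory=21.0,
    )


class TestHrf:
    def test_shape_and_normalization(self):
        k = canonical_hrf(TR)
        assert k[0] == 0.0
        assert k.max() == 1.0
        assert k.sum() * TR > 0

    def test_peak_between_4_and_8_seconds(self):
        # evaluate the gamma-difference on a fine grid
        k = canonical_hrf(0.01)
        t_peak = 0.01 * np.argmax(k)
        assert 4.0 <= t_peak <= 8.0

    def test_undershoot_present(self):
        k = canonical_hrf(0.1)
        assert k[int(16 / 0.1)] < 0

    def test_duration_shorter_than_tr(self):
        with pytest.raises(ValueError):
            canonical_hrf(2.0, duration_s=1.0)


class TestBuildDesign:
    def test_no_events_zero_columns(self):
        d = build_design([], [], np.zeros(50), None, 50, TR)
        assert np.all(d.column("boundary") == 0)
        assert np.all(d.column("within_event") == 0)

    def test_impulse_at_zero_is_kernel(self):
        d = build_design([0.0], [], np.zeros(50), None, 50, TR)
        k = canonical_hrf(TR)
        np.testing.assert_allclose(d.column("boundary")[: k.size], k)

    def test_two_events_equal_convolution_oracle(self):
        # explicit convolution of a two-impulse train with the kernel
        d = build_design([0.0, 3 * TR + 0.1], [], np.zeros(60), None, 60, TR)
        imp = np.zeros(60)
        imp[0] = imp[3] = 1.0
        k = canonical_hrf(TR)
        np.testing.assert_allclose(d.column("boundary"), np.convolve(imp, k)[:60])

    def test_event_outside_scan_listed(self):
        with pytest.raises(ValueError, match="999"):
            build_design([999.0], [], np.zeros(50), None, 50, TR)

    def test_motion_derivatives_are_first_differences(self, rng):
        motion = rng.normal(size=(50, 6))
        d = build_design([], [], np.zeros(50), motion, 50, TR)
        for i in range(1, 7):
            deriv = d.column(f"motion_{i}_deriv")
            assert deriv[0] == 0.0
            np.testing.assert_allclose(deriv[1:], np.diff(motion[:, i - 1]))

    def test_drift_mean_centered_and_zero_before_first_event(self):
        d = build_design([100.0], [200.0], np.zeros(120), None, 120, TR)
        assert d.column("drift").mean() == pytest.approx(0.0)
        first_bin = int(100.0 // TR)
        assert np.all(d.column("boundary")[:first_bin] == 0)


class TestFitGlm:
    def test_exact_recovery_noise_free(self, small_design, rng):
        design, _, _ = small_design
        truth = rng.normal(size=len(design.names))
        ts = make_ts(design.X @ truth)
        betas = fit_glm(ts, design)
        assert betas.boundary_beta == pytest.approx(truth[0], abs=1e-10)
        assert betas.within_beta == pytest.approx(truth[1], abs=1e-10)
        assert betas.adjusted_beta == pytest.approx(truth[0] - truth[1], abs=1e-10)

    def test_matches_normal_equation_oracle(self, small_design, rng):
        design, _, _ = small_design
        y = rng.normal(size=design.n_tr)
        betas = fit_glm(make_ts(y), design)
        oracle = np.linalg.solve(design.X.T @ design.X, design.X.T @ y)
        assert betas.boundary_beta == pytest.approx(oracle[0], rel=1e-8)
        assert betas.within_beta == pytest.approx(oracle[1], rel=1e-8)
        for name, value in betas.nuisance_betas.items():
            assert value == pytest.approx(oracle[design.names.index(name)], rel=1e-8)

    def test_linearity(self, small_design, rng):
        design, _, _ = small_design
        y = rng.normal(size=design.n_tr)
        b1 = fit_glm(make_ts(y), design)
        b3 = fit_glm(make_ts(3.0 * y), design)
        assert b3.boundary_beta == pytest.approx(3.0 * b1.boundary_beta)
        assert b3.adjusted_beta == pytest.approx(3.0 * b1.adjusted_beta)

    def test_swapping_event_sets_swaps_betas(self, rng):
        b, w = [30.0, 150.0], [90.0, 210.0]
        edge = rng.random(120)
        d1 = build_design(b, w, edge, None, 120, TR)
        d2 = build_design(w, b, edge, None, 120, TR)
        y = rng.normal(size=120)
        f1, f2 = fit_glm(make_ts(y), d1), fit_glm(make_ts(y), d2)
        assert f1.boundary_beta == pytest.approx(f2.within_beta)
        assert f1.within_beta == pytest.approx(f2.boundary_beta)
        assert f1.adjusted_beta == pytest.approx(-f2.adjusted_beta)

    def test_rank_deficiency_names_columns(self, small_design):
        design, _, _ = small_design
        X = design.X.copy()
        X[:, 2] = X[:, -1] * 2.0  # edge column duplicates the intercept
        broken = DesignMatrix(X=X, names=design.names, tr_s=design.tr_s, n_tr=design.n_tr)
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(make_ts(np.ones(design.n_tr)), broken)

    def test_null_boundary_beta_centered(self, small_design):
        """Pure AR(1) noise with zero true betas: boundary beta centered on 0
        across 200 simulations."""
        design, _, _ = small_design
        zeros = np.zeros(len(design.names))
        vals = np.array(
            [
                fit_glm(simulate_roi_bold(design, zeros, 0.5, 0.4, seed=s), design).boundary_beta
                for s in range(200)
            ]
        )
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(200)

    def test_adjusted_beta_arithmetic(self, small_design, rng):
        design, _, _ = small_design
        betas = fit_glm(make_ts(rng.normal(size=design.n_tr)), design)
        assert adjusted_beta(betas) == betas.boundary_beta - betas.within_beta


class TestContrastVariance:
    def test_matches_monte_carlo(self, small_design):
        design, _, _ = small_design
        closed = contrast_variance(design, {"boundary": 1.0, "within_event": -1.0}, 0.1, 0.3)
        zeros = np.zeros(len(design.names))
        adj = np.array(
            [
                fit_glm(simulate_roi_bold(design, zeros, 0.1, 0.3, seed=1000 + s), design).adjusted_beta
                for s in range(1000)
            ]
        )
        assert np.var(adj, ddof=1) == pytest.approx(closed, rel=0.15)


class TestFir:
    def test_recovers_kernel_noise_free(self):
        n_tr = 120
        k = canonical_hrf(TR)
        ev_bins = np.array([20, 50, 80])
        imp = np.zeros(n_tr)
        imp[ev_bins] = 1.0
        y = np.convolve(imp, k)[:n_tr]
        fir = fit_fir(make_ts(y), ev_bins * TR + 0.1, lags=range(0, k.size))
        np.testing.assert_allclose(fir.amplitudes, k, atol=1e-8)

    def test_zero_signal_zero_amplitudes(self):
        fir = fit_fir(make_ts(np.zeros(120)), [50.0, 150.0], lags=range(-2, 9))
        np.testing.assert_allclose(fir.amplitudes, 0.0, atol=1e-12)

    def test_equals_event_locked_average_oracle(self, rng):
        """With disjoint lag windows, each FIR beta is the event-locked mean
        minus the baseline mean of uncovered timepoints."""
        n_tr = 120
        y = rng.normal(size=n_tr)
        ev_bins = np.array([20, 40, 60])
        lags = range(-2, 9)
        fir = fit_fir(make_ts(y), ev_bins * TR + 0.1, lags=lags)
        covered = np.zeros(n_tr, bool)
        for lag in lags:
            covered[ev_bins + lag] = True
        baseline = y[~covered].mean()
        for lag, amp in zip(fir.lags, fir.amplitudes):
            assert amp == pytest.approx(y[ev_bins + lag].mean() - baseline, abs=1e-10)

    def test_lag_outside_scan(self):
        with pytest.raises(ValueError, match="outside the scan"):
            fit_fir(make_ts(np.zeros(50)), [1.0], lags=range(-2, 9))

    def test_collinear_nuisance_error(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_fir(make_ts(np.zeros(120)), [100.0], lags=range(0, 3),
                    nuisance=np.ones((120, 1)))

    def test_noncontiguous_lags_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            fit_fir(make_ts(np.zeros(120)), [100.0], lags=[0, 2, 4])


class TestScalePsc:
    def test_constant_series_zeros(self):
        np.testing.assert_allclose(scale_psc(np.full(10, 55.0)), 0.0)

    def test_unit_example(self):
        raw = np.array([100.0, 101.0, 99.0])
        out = scale_psc(raw)
        assert out[1] == pytest.approx(1.0)

    def test_output_mean_zero(self, rng):
        out = scale_psc(rng.random(64) + 5.0)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_mean_error(self):
        with pytest.raises(ValueError, match="positive"):
            scale_psc(np.array([-1.0, -2.0]))


class TestExtractRoi:
    def test_single_voxel_mask(self, rng):
        vol = rng.random((3, 3, 2, 20)) + 1.0
        mask = np.zeros((3, 3, 2), bool)
        mask[1, 2, 0] = True
        ts = extract_roi_timeseries(vol, mask, TR)
        np.testing.assert_allclose(ts.values, scale_psc(vol[1, 2, 0]))

    def test_uniform_volume_zero_series(self):
        vol = np.full((2, 2, 2, 10), 7.0)
        ts = extract_roi_timeseries(vol, np.ones((2, 2, 2)), TR)
        np.testing.assert_allclose(ts.values, 0.0)

    def test_two_voxel_mean(self, rng):
        vol = rng.random((2, 1, 1, 15)) + 1.0
        mask = np.ones((2, 1, 1), bool)
        ts = extract_roi_timeseries(vol, mask, TR)
        np.testing.assert_allclose(ts.values, scale_psc(vol[:, 0, 0].mean(axis=0)))

    def test_empty_mask_and_shape_mismatch(self):
        vol = np.ones((2, 2, 2, 5))
        with pytest.raises(ValueError, match="empty"):
            extract_roi_timeseries(vol, np.zeros((2, 2, 2)), TR)
        with pytest.raises(ValueError, match="shape"):
            extract_roi_timeseries(vol, np.ones((3, 2, 2)), TR)


class TestQcFilter:
    def test_clean_cohort_kept(self):
        cohort = [make_subject(i) for i in range(10)]
        kept, excluded = qc_filter(cohort)
        assert len(kept) == 10 and excluded == []

    def test_mean_fd_violators_with_reasons(self):
        cohort = [make_subject(i) for i in range(8)]
        cohort += [make_subject(8, mean_fd=0.7, max_fd=1.0), make_subject(9, mean_fd=0.9, max_fd=1.2)]
        kept, excluded = qc_filter(cohort)
        assert len(kept) == 8
        assert sorted(e.subject_id for e in excluded) == ["s08", "s09"]
        assert all(e.reasons == ("mean_fd",) for e in excluded)

    def test_boundary_value_kept(self):
        # "exceeded" is a strict inequality
        cohort = [make_subject(i) for i in range(5)] + [make_subject(5, mean_fd=0.5, max_fd=0.8)]
        kept, _ = qc_filter(cohort)
        assert any(s.subject_id == "s05" for s in kept)

    def test_tsnr_criterion_uses_full_cohort(self):
        cohort = [make_subject(i, tsnr=100.0 + (i % 3)) for i in range(19)]
        cohort.append(make_subject(19, tsnr=40.0))
        kept, excluded = qc_filter(cohort)
        assert [e.subject_id for e in excluded] == ["s19"]
        assert excluded[0].reasons == ("tsnr",)

    def test_empty_cohort(self):
        with pytest.raises(ValueError, match="empty"):
            qc_filter([])
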
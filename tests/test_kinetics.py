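"""Concentration conversion, arrival detection, AUC90, ROIs, curves."""

import numpy as np
import pytest

import dcequant as dq
from dcequant.errors import InputError
from dcequant.kinetics import auc90_voxel


class TestConcentrationConversion:
    def test_noiseless_round_trip_recovers_truth(self, noiseless):
        conc, truth = noiseless["conc"], noiseless["truth"]
        err = np.abs(conc.data - truth)[conc.valid_mask]
        assert np.max(err) < 1e-6  # mM

    def test_zero_concentration_maps_to_zero(self, phantom, acq):
        dead = tuple(dq.TissueClass(c.name, c.t1_ms, c.m0) for c in dq.DEFAULT_CLASSES)
        ph = dq.build_phantom(classes=dead)
        dyn, _ = dq.simulate_dynamic(ph, acq, None, 0.0, seed=0)
        vfa = dq.simulate_vfa(ph, acq, 0.0, seed=0)
        t1_map, m0_map = dq.map_t1_volume(vfa, acq)
        conc = dq.signal_to_concentration(dyn, t1_map, m0_map, acq)
        assert conc.arrival_fell_back
        assert np.nanmax(np.abs(conc.data)) < 1e-9

    def test_pre_arrival_mean_near_zero_under_noise(self, noisy_snr50, acq):
        conc = noisy_snr50["conc"]
        base = conc.data[..., acq.baseline_frames][conc.valid_mask]
        # Rician floor biases individual voxels; the tissue-wide mean stays small
        assert abs(np.mean(base)) < 0.05  # mM

    def test_plateau_error_small_at_snr50(self, phantom, noisy_snr50):
        conc, truth = noisy_snr50["conc"], noisy_snr50["truth"]
        vox = phantom.rim_mask & conc.valid_mask
        plateau = slice(-10, None)
        rel = np.abs(conc.data[vox][:, plateau] - truth[vox][:, plateau]) / truth[vox][:, plateau]
        assert np.median(rel) < 0.05


class TestArrivalDetection:
    def test_noiseless_arrival_at_first_enhanced_frame(self, noiseless, acq):
        conc = noiseless["conc"]
        truth = noiseless["truth"]
        first_nonzero = int(np.argmax(truth.max(axis=(0, 1, 2)) > 0))
        assert not conc.arrival_fell_back
        assert conc.arrival_index == first_nonzero == acq.injection_frame

    def test_flat_series_falls_back_with_warning(self, acq):
        conc = np.zeros((4, 4, 2, acq.n_frames))
        with pytest.warns(UserWarning):
            res = dq.detect_arrival(conc, acq.baseline_frames, fallback_index=acq.injection_frame)
        assert res.fell_back and res.index == acq.injection_frame

    def test_noisy_arrival_within_one_frame(self, noisy_snr50, acq):
        assert abs(noisy_snr50["conc"].arrival_index - acq.injection_frame) <= 1

    def test_too_few_baseline_frames_rejected(self):
        with pytest.raises(InputError):
            dq.detect_arrival(np.zeros((2, 2, 2, 10)), np.array([0]))


class TestAuc90:
    def test_constant_concentration_closed_form(self, acq):
        times = acq.frame_times_s
        curve = np.where(np.arange(len(times)) >= 14, 0.8, 0.0)
        curve[14:] = 0.8
        assert auc90_voxel(curve, times, 14) == pytest.approx(1.5 * 0.8, rel=1e-12)

    def test_zero_curve_gives_zero(self, acq):
        assert auc90_voxel(np.zeros(acq.n_frames), acq.frame_times_s, 10) == 0.0

    def test_linear_ramp_closed_form(self):
        # C(t) = 0.01 (t - t_arr) mM: integral over 90 s is 40.5 mM*s = 0.675 mM*min
        times = np.arange(0, 200.0, 9.1)
        arrival = 5
        curve = np.clip(0.01 * (times - times[arrival]), 0, None)
        assert auc90_voxel(curve, times, arrival) == pytest.approx(0.675, rel=1e-12)

    def test_trapezoid_matches_fine_quadrature_for_tofts_curve(self, acq):
        cp = lambda t: dq.aif(t, 120.0, dq.AIFParams())
        times = acq.frame_times_s
        coarse = dq.tofts_concentration(0.25, 0.35, 0.03, cp, times, refine=50)
        a_coarse = auc90_voxel(coarse, times, 14)
        t_fine = np.linspace(0, times[-1], (len(times) - 1) * 50 + 1)
        fine = dq.tofts_concentration(0.25, 0.35, 0.03, cp, t_fine, refine=10)
        m = (t_fine >= times[14]) & (t_fine <= times[14] + 90.0)
        a_fine = np.trapezoid(fine[m], t_fine[m]) / 60.0
        assert a_coarse == pytest.approx(a_fine, rel=0.005)

    def test_window_beyond_run_raises_named_error(self, acq):
        with pytest.raises(InputError, match="short"):
            auc90_voxel(np.zeros(acq.n_frames), acq.frame_times_s, acq.n_frames - 2)

    def test_scaling_concentration_scales_auc_linearly(self, noiseless):
        conc = noiseless["conc"]
        base = dq.auc90_map(conc)
        scaled = dq.auc90_map(
            dq.ConcentrationSeries(3.0 * conc.data, conc.times_s, conc.arrival_index, conc.valid_mask)
        )
        m = base.valid_mask
        assert np.allclose(scaled.values[m], 3.0 * base.values[m], rtol=1e-12)

    def test_rim_mean_exceeds_five_times_core_mean(self, phantom, noiseless):
        auc = dq.auc90_map(noiseless["conc"])
        rim = np.nanmean(auc.values[auc.valid_mask & phantom.rim_mask])
        core = np.nanmean(auc.values[auc.valid_mask & phantom.core_mask])
        assert rim > 5 * core


class TestHistogram:
    def test_counts_conserve_valid_voxels(self, phantom, noiseless):
        auc = dq.auc90_map(noiseless["conc"])
        hist = dq.auc90_histogram(auc, phantom.tumor_mask, np.linspace(0, 2, 11))
        assert hist.total == int((auc.valid_mask & phantom.tumor_mask).sum())

    def test_single_wide_bin_counts_whole_mask(self, phantom, noiseless):
        auc = dq.auc90_map(noiseless["conc"])
        hist = dq.auc90_histogram(auc, phantom.tumor_mask, np.array([-1e6, 1e6]))
        assert hist.counts[0] == int((auc.valid_mask & phantom.tumor_mask).sum())

    def test_values_below_first_edge_land_in_out_of_range_tally(self, phantom, noiseless):
        auc = dq.auc90_map(noiseless["conc"])
        hist = dq.auc90_histogram(auc, phantom.tumor_mask, np.array([1e5, 1e6]))
        assert hist.counts.sum() == 0
        assert hist.n_below == int((auc.valid_mask & phantom.tumor_mask).sum())

    def test_bigger_core_shifts_mass_to_lowest_bin(self, acq):
        def lowest_fraction(core_radius):
            ph = dq.build_phantom((32, 32, 8), core_radius, 2)
            vfa = dq.simulate_vfa(ph, acq, 0.0, seed=1)
            dyn, _ = dq.simulate_dynamic(ph, acq, None, 0.0, seed=2)
            t1_map, m0_map = dq.map_t1_volume(vfa, acq)
            conc = dq.signal_to_concentration(dyn, t1_map, m0_map, acq, arrival_mask=ph.tumor_mask)
            hist = dq.auc90_histogram(dq.auc90_map(conc), ph.tumor_mask, np.linspace(0, 2, 11))
            return hist.counts[0] / hist.counts.sum()

        assert lowest_fraction(8) > lowest_fraction(4)

    def test_empty_mask_warns(self, noiseless):
        auc = dq.auc90_map(noiseless["conc"])
        with pytest.warns(UserWarning):
            hist = dq.auc90_histogram(auc, np.zeros(auc.values.shape, bool))
        assert hist.total == 0

    def test_decreasing_edges_rejected(self, noiseless):
        with pytest.raises(InputError):
            dq.auc90_histogram(dq.auc90_map(noiseless["conc"]), bin_edges=np.array([1.0, 0.5]))


class TestRois:
    def test_rim_core_partition_solid_sphere(self):
        g = np.ogrid[:24, :24, :24]
        sphere = (g[0] - 12) ** 2 + (g[1] - 12) ** 2 + (g[2] - 12) ** 2 <= 9**2
        rois = dq.define_rim_core_rois(sphere, 2)
        assert not (rois.rim_mask & rois.core_mask).any()
        assert np.array_equal(rois.rim_mask | rois.core_mask, sphere)

    def test_rim_width_exceeding_radius_rejected(self):
        g = np.ogrid[:16, :16, :16]
        sphere = (g[0] - 8) ** 2 + (g[1] - 8) ** 2 + (g[2] - 8) ** 2 <= 4**2
        with pytest.raises(InputError, match="smaller rim"):
            dq.define_rim_core_rois(sphere, 6)

    def test_derived_rim_matches_phantom_rim(self, phantom):
        rois = dq.define_rim_core_rois(phantom.tumor_mask, phantom.rim_width_vox)
        inter = (rois.rim_mask & phantom.rim_mask).sum()
        dice = 2 * inter / (rois.rim_mask.sum() + phantom.rim_mask.sum())
        assert dice >= 0.9


class TestRelativeEnhancement:
    def test_constant_signal_gives_zero_percent(self, acq):
        data = np.full((4, 4, 2, acq.n_frames), 50.0)
        series = dq.DynamicSeries(data, acq.frame_times_s, acq)
        curve = dq.relative_enhancement(series, np.ones((4, 4, 2), bool))
        assert np.allclose(curve.si_rel_percent, 0.0)

    def test_doubling_signal_gives_hundred_percent(self, acq):
        data = np.full((4, 4, 2, acq.n_frames), 50.0)
        data[..., 30] = 100.0
        series = dq.DynamicSeries(data, acq.frame_times_s, acq)
        curve = dq.relative_enhancement(series, np.ones((4, 4, 2), bool))
        assert curve.si_rel_percent[30] == pytest.approx(100.0)
        assert np.mean(curve.si_rel_percent[acq.baseline_frames]) == pytest.approx(0.0, abs=1e-12)

    def test_air_roi_rejected(self, acq):
        data = np.zeros((4, 4, 2, acq.n_frames))
        series = dq.DynamicSeries(data, acq.frame_times_s, acq)
        with pytest.raises(InputError):
            dq.relative_enhancement(series, np.ones((4, 4, 2), bool))

    def test_rim_plateau_exceeds_core_everywhere_post_arrival(self, phantom, noiseless, acq):
        dyn = noiseless["dyn"]
        rois = dq.define_rim_core_rois(phantom.tumor_mask, phantom.rim_width_vox)
        rim = dq.relative_enhancement(dyn, rois.rim_mask, acq.baseline_frames, "rim")
        core = dq.relative_enhancement(dyn, rois.core_mask, acq.baseline_frames, "core")
        post = acq.frame_times_s > acq.injection_time_s
        assert np.all(rim.si_rel_percent[post] > core.si_rel_percent[post])


class TestRimCoreOrderingUnderNoise:
    @pytest.mark.parametrize("snr,seed", [(50, 11), (30, 12), (20, 13)])
    def test_rim_auc_exceeds_core_auc(self, phantom, acq, snr, seed):
        sigma = dq.noise_sigma_for_snr(phantom.classes[3], acq, snr)
        vfa = dq.simulate_vfa(phantom, acq, sigma, seed=seed)
        dyn, _ = dq.simulate_dynamic(phantom, acq, None, sigma, seed=seed + 100)
        t1_map, m0_map = dq.map_t1_volume(vfa, acq)
        conc = dq.signal_to_concentration(dyn, t1_map, m0_map, acq, arrival_mask=phantom.tumor_mask)
        auc = dq.auc90_map(conc)
        rim = np.nanmean(auc.values[auc.valid_mask & phantom.rim_mask])
        core = np.nanmean(auc.values[auc.valid_mask & phantom.core_mask])
        assert rim > core
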
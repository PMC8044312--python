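import numpy as np
import pytest

from twac import (
    BeatModelParams,
    EcgRecord,
    IndicatorConfig,
    SearchWindowParams,
    area_indicator,
    classify_rr_case,
    delineate_record,
    detect_r_peaks,
    fit_search_boundaries,
    locate_t_offset,
    locate_t_onset,
    search_window,
    synthesize_record,
    tune_window_params,
)
from twac.errors import InsufficientDataError, RangeError, WindowError

FS = 1000.0
PARAMS = SearchWindowParams()


def brute_force_locate(signal, window, cfg, fs, mode):
    """Independent oracle: evaluate the indicator at every candidate."""
    best_t, best_mag = None, -1.0
    for t in range(window[0], window[1]):
        mag = abs(area_indicator(signal, t, cfg, fs, mode))
        if mag > best_mag:
            best_t, best_mag = t, mag
    return None if best_mag == 0.0 else best_t


class TestRrCases:
    @pytest.mark.parametrize(
        "rr,target,case",
        [
            (0.5, "onset", 1), (0.67, "onset", 2), (1.22, "onset", 2), (1.23, "onset", 3),
            (0.70, "offset", 1), (0.71, "offset", 2), (1.1, "offset", 3),
        ],
    )
    def test_boundaries_assigned_to_upper_case(self, rr, target, case):
        assert classify_rr_case(rr, target, PARAMS) == case

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            classify_rr_case(0.0, "onset", PARAMS)


class TestSearchWindow:
    def test_onset_case1_literal_evaluation(self):
        assert search_window(1000, 0.5, FS, "onset", PARAMS) == (1220, 1260)

    def test_offset_case3_literal_evaluation(self):
        assert search_window(2000, 1.2, FS, "offset", PARAMS) == (2180, 2600)

    def test_windows_are_non_degenerate_when_valid(self):
        rng = np.random.default_rng(0)
        for rr in rng.uniform(0.35, 1.9, size=200):
            for target in ("onset", "offset"):
                try:
                    t1, t2 = search_window(5000, float(rr), FS, target, PARAMS)
                except WindowError:
                    continue  # the published onset case-3 coefficients degenerate
                assert t2 - t1 >= 1

    def test_onset_case3_is_degenerate_with_published_coefficients(self):
        with pytest.raises(WindowError):
            search_window(5000, 1.3, FS, "onset", PARAMS)

    def test_bounds_monotone_in_rr_within_case(self):
        for target, lo, hi in (("onset", 0.3, 0.66), ("offset", 0.72, 1.09)):
            rrs = np.linspace(lo, hi, 40)
            wins = [search_window(5000, float(rr), FS, target, PARAMS) for rr in rrs]
            t1s, t2s = zip(*wins)
            assert all(np.diff(t1s) >= 0) and all(np.diff(t2s) >= 0)


class TestAreaIndicator:
    CFG = IndicatorConfig(window_w=0.030, window_w_onset=0.030)

    def test_constant_signal_gives_zero(self):
        sig = np.full(300, 2.5)
        for t in (50, 150, 250):
            assert area_indicator(sig, t, self.CFG, FS, "trailing") == 0.0
            assert area_indicator(sig, t, self.CFG, FS, "leading") == 0.0

    def test_ramp_closed_form(self):
        sig = np.arange(500, dtype=float)
        w = self.CFG.samples(FS, "trailing")
        assert area_indicator(sig, 250, self.CFG, FS, "trailing") == -w * (w - 1) / 2

    def test_offset_invariance_under_constant_shift(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=400)
        for t in (60, 200, 350):
            a = area_indicator(sig, t, self.CFG, FS, "trailing")
            b = area_indicator(sig + 7.3, t, self.CFG, FS, "trailing")
            assert b == pytest.approx(a, abs=1e-9)

    def test_window_outside_signal_is_range_error(self):
        sig = np.zeros(100)
        with pytest.raises(RangeError):
            area_indicator(sig, 5, self.CFG, FS, "trailing")
        with pytest.raises(RangeError):
            area_indicator(sig, 95, self.CFG, FS, "leading")

    def test_triangular_wave_argmax_at_return_to_baseline(self):
        # gentle rise (60 samples), steep fall (15 samples), then flat baseline
        sig = np.concatenate([np.zeros(100), np.linspace(0, 1, 61)[1:],
                              np.linspace(1, 0, 16)[1:], np.zeros(150)])
        cfg = IndicatorConfig(window_w=0.030, window_w_onset=0.030)
        end = 174  # first sample back at baseline
        found = brute_force_locate(sig, (130, 250), cfg, FS, "trailing")
        assert abs(found - end) <= 1


class TestLocate:
    def test_matches_brute_force_oracle_on_random_signals(self):
        rng = np.random.default_rng(7)
        cfg = IndicatorConfig()
        for _ in range(200):
            sig = rng.normal(size=600)
            t1 = int(rng.integers(60, 300))
            t2 = t1 + int(rng.integers(2, 120))
            assert locate_t_offset(sig, (t1, t2), cfg, FS) == brute_force_locate(
                sig, (t1, t2), cfg, FS, "trailing"
            )
            assert locate_t_onset(sig, (t1, t2), cfg, FS) == brute_force_locate(
                sig, (t1, t2), cfg, FS, "leading"
            )

    def test_flat_window_flags_no_t(self):
        sig = np.zeros(1000)
        assert locate_t_offset(sig, (300, 360), IndicatorConfig(), FS) is None
        assert locate_t_onset(sig, (260, 280), IndicatorConfig(), FS) is None

    def test_time_mirror_symmetry(self):
        rng = np.random.default_rng(11)
        sig = rng.normal(size=500)
        cfg = IndicatorConfig(window_w=0.025, window_w_onset=0.025)
        off = locate_t_offset(sig, (100, 400), cfg, FS)
        rev = sig[::-1].copy()
        on = locate_t_onset(rev, (sig.size - 400, sig.size - 100), cfg, FS)
        assert on == sig.size - 1 - off


class TestDelineateRecord:
    def test_clean_record_boundary_error_below_20ms(self, clean_delineated):
        synth, det = clean_delineated
        truth = synth.annotations
        for lead in ("II", "V3"):
            on_err = np.abs(det.t_onsets[lead] - truth.t_onsets[lead])
            off_err = np.abs(det.t_offsets[lead] - truth.t_offsets[lead])
            assert np.nanmean(on_err) <= 20.0
            assert np.nanmean(off_err) <= 20.0
            assert np.isnan(det.t_onsets[lead]).sum() <= 2

    def test_inverted_t_located_as_accurately_as_upright(self, clean_delineated):
        synth, det = clean_delineated
        truth = synth.annotations
        err_up = np.nanmean(np.abs(det.t_offsets["II"] - truth.t_offsets["II"]))
        err_inv = np.nanmean(np.abs(det.t_offsets["aVR"] - truth.t_offsets["aVR"]))
        assert err_inv == pytest.approx(err_up, abs=2.0)

    def test_constant_shift_leaves_boundaries_unchanged(self, clean_delineated):
        synth, det = clean_delineated
        shifted = EcgRecord(
            synth.record.signal + 10.0, synth.record.fs, synth.record.lead_names
        )
        det2 = delineate_record(shifted, synth.annotations.r_peaks)
        for lead in synth.record.lead_names:
            np.testing.assert_array_equal(det.t_onsets[lead], det2.t_onsets[lead])
            np.testing.assert_array_equal(det.t_offsets[lead], det2.t_offsets[lead])

    def test_zero_t_amplitude_flags_every_beat(self):
        params = BeatModelParams(t_wave=(0.0, 0.285, 0.006), rr_jitter_sd=0.0)
        out = synthesize_record(params, 10.0, FS, 0)
        det = delineate_record(out.record, out.annotations.r_peaks)
        assert np.isnan(det.t_onsets["II"]).all()

    def test_needs_two_r_peaks(self, clean_synth):
        with pytest.raises(InsufficientDataError):
            delineate_record(clean_synth.record, clean_synth.annotations.r_peaks[:1])

    def test_r_t_ordering_enforced(self, clean_delineated):
        synth, det = clean_delineated
        for lead in synth.record.lead_names:
            on, off = det.t_onsets[lead], det.t_offsets[lead]
            ok = ~np.isnan(on)
            assert np.all(on[ok] > synth.annotations.r_peaks[ok])
            assert np.all(off[ok] > on[ok])


class TestRPeaks:
    def test_flat_signal_gives_empty_result(self):
        rec = EcgRecord(np.zeros((5000, 1)), FS, ("II",))
        assert detect_r_peaks(rec).size == 0

    def test_clean_record_within_5ms_of_truth(self, clean_synth):
        det = detect_r_peaks(clean_synth.record)
        truth = clean_synth.annotations.r_peaks
        for r in truth:
            assert np.min(np.abs(det - r)) <= 5

    def test_noisy_record_rr_error_below_10ms(self):
        out = synthesize_record(BeatModelParams(), 15.0, FS, 5, noise_sd=0.05)
        det = detect_r_peaks(out.record)
        truth = out.annotations.r_peaks
        matched = np.array([det[np.argmin(np.abs(det - r))] for r in truth])
        assert np.max(np.abs(np.diff(matched) - np.diff(truth))) <= 10

    def test_missing_lead_falls_back(self, clean_synth):
        rec = clean_synth.record
        sub = EcgRecord(rec.signal[:, :1], rec.fs, ("I",))
        assert detect_r_peaks(sub, lead="II").size > 0


class TestFitSearchBoundaries:
    def test_recovers_three_cluster_thresholds(self):
        rng = np.random.default_rng(2)
        centers = [0.5, 0.9, 1.4]
        rr = np.concatenate([rng.normal(c, 0.03, 150) for c in centers])
        rt = np.concatenate(
            [rng.normal(0.20 + 0.1 * i, 0.01, 150) for i in range(3)]
        )
        fit = fit_search_boundaries(rr, rt, k=3, seed=0)
        assert len(fit.rr_thresholds) == 2
        assert abs(fit.rr_thresholds[0] - 0.7) <= 0.05
        assert abs(fit.rr_thresholds[1] - 1.15) <= 0.05
        assert len(fit.rt_ranges) == 3

    def test_k1_single_case_spans_all(self):
        rr = np.linspace(0.5, 1.5, 20)
        rt = np.linspace(0.2, 0.4, 20)
        fit = fit_search_boundaries(rr, rt, k=1)
        assert fit.rr_thresholds == ()
        assert fit.rt_ranges == ((0.2, 0.4),)

    def test_identical_points_degenerate(self):
        rr = np.full(10, 0.8)
        rt = np.full(10, 0.3)
        with pytest.raises(InsufficientDataError):
            fit_search_boundaries(rr, rt, k=3)


@pytest.fixture(scope="module")
def annotated_records():
    records = []
    for seed in range(6):
        out = synthesize_record(
            BeatModelParams(), 15.0, FS, seed, noise_sd=0.0, lead_names=("II",)
        )
        records.append((out.record, out.annotations))
    return records


class TestTuneWindowParams:
    def test_selects_generating_coefficients(self, annotated_records):
        grid = {"onset_a": [0.4, 0.6], "onset_b": [0.1, 0.2, 0.5]}
        result = tune_window_params(
            annotated_records, grid, folds=5, tolerance=0.010, seed=0
        )
        assert result.best == {"onset_a": 0.4, "onset_b": 0.2}
        assert result.mean_sensitivity > 0.9

    def test_single_point_grid_returns_it(self, annotated_records):
        result = tune_window_params(
            annotated_records, {"offset_a": [0.2]}, folds=3, tolerance=0.010, seed=0
        )
        assert result.best == {"offset_a": 0.2}
        assert 0.0 <= result.mean_sensitivity <= 1.0

    def test_leave_one_out_partition(self, annotated_records):
        result = tune_window_params(
            annotated_records, {"offset_a": [0.2]}, folds=len(annotated_records),
            tolerance=0.010, seed=0,
        )
        assert len(result.per_fold_sensitivity) == len(annotated_records)

    def test_empty_grid_rejected(self, annotated_records):
        with pytest.raises(ValueError):
            tune_window_params(annotated_records, {}, folds=2)
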
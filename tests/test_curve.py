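import numpy as np
import pytest

from twac import (
    BaselineConfig,
    BeatAnnotations,
    BeatModelParams,
    EcgRecord,
    build_twac,
    local_baseline,
    synthesize_beat,
    t_wave_area,
)
from twac.errors import EmptyOutputError, RangeError

FS = 1000.0


class TestLocalBaseline:
    def test_constant_signal_returns_constant(self):
        sig = np.full(200, 3.7)
        for placement in ("preceding", "centered"):
            cfg = BaselineConfig(placement=placement)
            assert local_baseline(sig, 100, cfg, FS) == pytest.approx(3.7)

    def test_centered_window_on_ramp_returns_anchor_value(self):
        sig = 0.01 * np.arange(200)
        cfg = BaselineConfig(placement="centered")
        assert local_baseline(sig, 100, cfg, FS) == pytest.approx(sig[100])

    def test_preceding_window_on_ramp_returns_midpoint_of_prefix(self):
        sig = 0.01 * np.arange(200)
        cfg = BaselineConfig()
        h = cfg.half_width_samples(FS)
        assert local_baseline(sig, 100, cfg, FS) == pytest.approx(sig[100 - h])

    def test_window_is_33_samples_at_default_p(self):
        cfg = BaselineConfig()
        assert 2 * cfg.half_width_samples(FS) + 1 == 33

    def test_window_outside_signal_is_range_error(self):
        with pytest.raises(RangeError):
            local_baseline(np.zeros(100), 5, BaselineConfig(placement="centered"), FS)


class TestTWaveArea:
    def test_constant_with_matching_baseline_is_zero(self):
        sig = np.full(300, 1.2)
        assert t_wave_area(sig, 50, 200, 1.2) == 0.0

    def test_half_sine_closed_form(self):
        sig = np.sin(np.pi * np.arange(101) / 100)
        area = t_wave_area(sig, 0, 100, 0.0)
        assert area == pytest.approx(1.0 / np.tan(np.pi / 200), rel=1e-12)
        assert area == pytest.approx(63.657, abs=5e-4)

    def test_shift_invariance_with_recomputed_baseline(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=400)
        cfg = BaselineConfig()
        a1 = t_wave_area(sig, 100, 180, local_baseline(sig, 100, cfg, FS))
        shifted = sig + 10.0
        a2 = t_wave_area(shifted, 100, 180, local_baseline(shifted, 100, cfg, FS))
        assert a2 == pytest.approx(a1, abs=1e-9)

    def test_linearity_in_the_signal(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=300)
        a = t_wave_area(sig, 40, 120, 0.0)
        assert t_wave_area(2.5 * sig, 40, 120, 0.0) == pytest.approx(2.5 * a, rel=1e-12)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            t_wave_area(np.zeros(100), 50, 50, 0.0)

    def test_sign_preserved_for_inverted_wave(self):
        sig = -np.sin(np.pi * np.arange(101) / 100)
        assert t_wave_area(sig, 0, 100, 0.0) < 0


def _beat_train_record(t_amps, fs=1000.0):
    """Concatenate beats whose T amplitudes are scaled per beat."""
    chunks, r_peaks, onsets, offsets = [], [], [], []
    offset = 0
    for amp in t_amps:
        params = BeatModelParams(t_wave=(amp, 0.285, 0.006))
        samples, bounds = synthesize_beat(params, fs)
        r_idx = int(round(params.pre_s * fs))
        chunks.append(samples)
        r_peaks.append(offset + r_idx)
        onsets.append(offset + bounds[0])
        offsets.append(offset + bounds[1])
        offset += samples.size
    signal = np.concatenate(chunks)
    record = EcgRecord(signal[:, None], fs, ("II",))
    ann = BeatAnnotations(
        np.array(r_peaks), fs,
        {"II": np.array(onsets, dtype=float)}, {"II": np.array(offsets, dtype=float)},
    )
    return record, ann


class TestBuildTwac:
    def test_per_beat_t_scaling_gives_proportional_areas(self):
        record, ann = _beat_train_record([0.3, 0.6, 0.9])
        series = build_twac(record, ann)
        areas = series.areas[:, 0]
        np.testing.assert_allclose(areas / areas[0], [1.0, 2.0, 3.0], rtol=0.01)

    def test_twelve_leads_in_record_order(self, clean_synth, clean_series):
        assert clean_series.lead_names == clean_synth.record.lead_names
        assert clean_series.areas.shape[1] == 12

    def test_adding_constant_to_one_lead_leaves_its_curve_unchanged(self, clean_synth):
        record, ann = clean_synth.record, clean_synth.annotations
        base = build_twac(record, ann)
        shifted_signal = record.signal.copy()
        shifted_signal[:, 3] += 5.0
        shifted = EcgRecord(shifted_signal, record.fs, record.lead_names)
        out = build_twac(shifted, ann)
        np.testing.assert_allclose(out.areas, base.areas, atol=1e-9)

    def test_concatenating_records_concatenates_series(self):
        r1, a1 = _beat_train_record([0.3, 0.5])
        r2, a2 = _beat_train_record([0.7, 0.2])
        joint_signal = np.concatenate([r1.signal, r2.signal])
        shift = r1.n_samples
        joint_ann = BeatAnnotations(
            np.concatenate([a1.r_peaks, a2.r_peaks + shift]), r1.fs,
            {"II": np.concatenate([a1.t_onsets["II"], a2.t_onsets["II"] + shift])},
            {"II": np.concatenate([a1.t_offsets["II"], a2.t_offsets["II"] + shift])},
        )
        joint = build_twac(EcgRecord(joint_signal, r1.fs, ("II",)), joint_ann)
        parts = np.concatenate([build_twac(r1, a1).areas, build_twac(r2, a2).areas])
        np.testing.assert_allclose(joint.areas, parts, atol=1e-9)

    def test_normalize_divides_by_fs(self):
        record, ann = _beat_train_record([0.3])
        raw = build_twac(record, ann).areas
        norm = build_twac(record, ann, BaselineConfig(normalize=True)).areas
        np.testing.assert_allclose(norm, raw / record.fs)

    def test_zero_beats_is_error(self, clean_synth):
        record = clean_synth.record
        empty = BeatAnnotations(np.array([], dtype=int), record.fs, {}, {})
        with pytest.raises(EmptyOutputError):
            build_twac(record, empty)
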
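"""EMG chain: filtering closed forms, segmentation, maxima, generator."""

import numpy as np
import pytest

from mirrorface.emg import (
    GESTURES,
    MUSCLES,
    ChainOptions,
    EmgRecording,
    EmgSpec,
    bandpass,
    generate_emg,
    load_emg_csv,
    moving_rms,
    rectify,
    save_emg_csv,
    scale_x1000,
    segment_protocol,
    summarize,
)
from mirrorface.errors import ParameterError

RATE = 1000.0


def tone(freq, amp=1.0, duration=10.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def rec_of(x, rate=RATE):
    return EmgRecording(samples=np.tile(x, (3, 1)), rate=rate)


class TestBandpass:
    def test_dc_rejection(self):
        rec = rec_of(np.full(10000, 3.5))
        out = bandpass(rec)
        trimmed = out.samples[:, 500:-500]
        assert np.abs(trimmed).max() < 1e-6 * 3.5

    def test_in_band_tone_preserved(self):
        rec = rec_of(tone(100.0))
        out = bandpass(rec, 20, 450, 4)
        trimmed = out.samples[0, 1000:-1000]  # whole periods after edge trim
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean(trimmed**2))
        assert amplitude == pytest.approx(1.0, rel=0.01)

    def test_low_tone_attenuated(self):
        rec = rec_of(tone(5.0))
        out = bandpass(rec, 20, 450, 4)
        trimmed = out.samples[0, 2000:-2000]
        assert np.abs(trimmed).max() < 0.1  # >= 90% attenuation

    def test_cutoff_at_nyquist_rejected(self):
        rec = rec_of(tone(100.0))
        with pytest.raises(ParameterError):
            bandpass(rec, 20, 500, 4)
        with pytest.raises(ParameterError):
            bandpass(rec, 0, 450, 4)


class TestRectify:
    def test_elementwise_absolute_value(self):
        rec = EmgRecording(samples=np.array([[-1.0, 2.0, -3.0]]),
                           channel_names=("orbicularis",))
        assert np.array_equal(rectify(rec).samples, [[1.0, 2.0, 3.0]])

    def test_idempotent(self, rng):
        rec = rec_of(rng.standard_normal(5000))
        once = rectify(rec)
        assert np.array_equal(rectify(once).samples, once.samples)


class TestMovingRms:
    def test_constant_signal(self):
        rec = rec_of(np.full(2000, -4.0))
        env = moving_rms(rec, 0.1, 0.05)
        assert np.allclose(env.values, 4.0)

    def test_sine_over_whole_periods(self):
        amp = 2.5
        rec = rec_of(tone(10.0, amp=amp))  # 0.2 s window = 2 whole periods
        env = moving_rms(rec, 0.2, 0.05)
        assert np.allclose(env.values, amp / np.sqrt(2), atol=1e-6)

    def test_homogeneity(self, rng):
        x = rng.standard_normal(3000)
        env1 = moving_rms(rec_of(x), 0.1, 0.05)
        env2 = moving_rms(rec_of(7.0 * x), 0.1, 0.05)
        assert np.allclose(env2.values, 7.0 * env1.values, rtol=1e-12)

    def test_timestamps_at_window_centers(self):
        rec = rec_of(np.zeros(1000))
        env = moving_rms(rec, 0.1, 0.05)
        assert env.times_s[0] == pytest.approx((100 - 1) / 2 / RATE)
        assert np.allclose(np.diff(env.times_s), 0.05)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ParameterError):
            moving_rms(rec_of(np.zeros(50)), 0.1, 0.05)


class TestSegmentation:
    def test_protocol_at_1khz(self):
        rec = rec_of(np.zeros(40000))
        cycles = segment_protocol(rec, t0_s=0.0)
        spans = [(c.gesture, c.start_sample, c.end_sample) for c in cycles]
        assert spans == [
            ("kiss", 0, 5000), ("smile", 15000, 20000), ("eyebrows", 30000, 35000)
        ]

    def test_unit_conversion_at_500hz(self):
        rec = rec_of(np.zeros(20000), rate=500.0)
        cycles = segment_protocol(rec, t0_s=2.0)
        assert (cycles[0].start_sample, cycles[0].end_sample) == (1000, 3500)

    def test_short_recording_rejected(self):
        rec = rec_of(np.zeros(20000))  # 20 s < 35 s
        with pytest.raises(ParameterError):
            segment_protocol(rec)

    def test_cycles_non_overlapping_half_open(self):
        rec = rec_of(np.zeros(40000))
        cycles = segment_protocol(rec, t0_s=1.25)
        for a, b in zip(cycles, cycles[1:]):
            assert a.end_sample <= b.start_sample


class TestGeneratorAndSummary:
    SPEC = EmgSpec(amplitudes={
        "kiss": {"orbicularis": 0.042},
        "smile": {"buccinator": 0.030},
        "eyebrows": {"frontalis": 0.050},
    })

    def test_zero_amplitudes_near_silent(self):
        spec = EmgSpec(amplitudes={})
        rec, _ = generate_emg(spec, seed=1)
        assert np.sqrt(np.mean(rec.samples**2)) < 3 * spec.baseline_noise_mV

    def test_programmed_peak_recovered_within_2pct(self):
        rec, expected = generate_emg(self.SPEC, seed=11)
        summ = summarize(rec, segment_protocol(rec, t0_s=self.SPEC.t0_s))
        peak = summ.values_mV[("kiss", "orbicularis")]
        assert peak == pytest.approx(0.042 / np.sqrt(2), rel=0.02)
        assert peak == pytest.approx(expected[("kiss", "orbicularis")], rel=0.02)

    def test_silent_channel_below_one_table_unit(self):
        rec, _ = generate_emg(self.SPEC, seed=11)
        summ = summarize(rec, segment_protocol(rec, t0_s=self.SPEC.t0_s))
        assert summ.values_mV[("kiss", "frontalis")] * 1000 < 1.0
        assert summ.scaled("kiss", "frontalis") <= 1

    def test_generator_deterministic(self):
        a, _ = generate_emg(self.SPEC, seed=5)
        b, _ = generate_emg(self.SPEC, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_identical_recordings_identical_summaries(self):
        rec, _ = generate_emg(self.SPEC, seed=2)
        cycles = segment_protocol(rec, t0_s=self.SPEC.t0_s)
        s1 = summarize(rec, cycles, condition="without")
        s2 = summarize(rec, cycles, condition="with")
        assert s1.values_mV == s2.values_mV

    def test_synkinesis_coupling_ratio(self):
        coupling = np.eye(3)
        coupling[0, 2] = 0.8  # orbicularis carrier bleeds into frontalis
        spec = EmgSpec(amplitudes={"kiss": {"orbicularis": 0.042}}, coupling=coupling)
        rec, _ = generate_emg(spec, seed=3)
        summ = summarize(rec, segment_protocol(rec, t0_s=spec.t0_s))
        ratio = (summ.values_mV[("kiss", "frontalis")]
                 / summ.values_mV[("kiss", "orbicularis")])
        assert ratio == pytest.approx(0.8, rel=0.10)

    def test_chain_homogeneity(self):
        rec, _ = generate_emg(self.SPEC, seed=4)
        cycles = segment_protocol(rec, t0_s=self.SPEC.t0_s)
        base = summarize(rec, cycles)
        scaled_rec = EmgRecording(samples=3.0 * rec.samples, rate=rec.rate)
        scaled = summarize(scaled_rec, cycles)
        for key, v in base.values_mV.items():
            assert scaled.values_mV[key] == pytest.approx(3.0 * v, rel=1e-9)

    def test_amplitude_ratio_recovery_across_seeds(self):
        spec = EmgSpec(amplitudes={
            "kiss": {"orbicularis": 0.040, "buccinator": 0.020},
            "smile": {"orbicularis": 0.010},
            "eyebrows": {"frontalis": 0.050},
        })
        for seed in range(10):
            rec, expected = generate_emg(spec, seed=seed)
            summ = summarize(rec, segment_protocol(rec, t0_s=spec.t0_s))
            for key, true in expected.items():
                if true > 0:
                    assert summ.values_mV[key] == pytest.approx(true, rel=0.10)

    def test_raw_max_option_exceeds_envelope_max(self):
        rec, _ = generate_emg(self.SPEC, seed=6)
        cycles = segment_protocol(rec, t0_s=self.SPEC.t0_s)
        env = summarize(rec, cycles)
        raw = summarize(rec, cycles, ChainOptions(raw_max=True))
        key = ("kiss", "orbicularis")
        assert raw.values_mV[key] > env.values_mV[key]

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ParameterError):
            EmgSpec(amplitudes={}, coupling=np.full((3, 3), 2.0)).coupling_matrix()


class TestScaleAndIO:
    def test_table_scale_round_half_up(self):
        assert scale_x1000(0.0205) == 21  # 20.5 rounds up
        assert scale_x1000(0.042) == 42

    def test_csv_round_trip(self, tmp_path):
        rec, _ = generate_emg(
            EmgSpec(amplitudes={"kiss": {"orbicularis": 0.04}}), seed=9
        )
        path = tmp_path / "emg.csv"
        save_emg_csv(rec, path)
        back = load_emg_csv(path)
        assert back.rate == pytest.approx(rec.rate)
        assert back.channel_names == rec.channel_names
        assert np.allclose(back.samples, rec.samples, atol=1e-6)

    def test_nonuniform_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,orbicularis\n0.0,1\n0.001,2\n0.005,3\n")
        with pytest.raises(ParameterError):
            load_emg_csv(path)
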
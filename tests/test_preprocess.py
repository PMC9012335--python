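import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uemg.core import Recording, Segment
from uemg.preprocess import (
    PreprocessParams,
    downsample,
    lowpass_filter,
    preprocess_segment,
    segment_recording,
    subtract_mean,
)
from uemg.synth import generate_recording, pp_preset

from conftest import make_tone_segment
from oracles import direct_dft_power_onesided


def make_recording(duration_min: float, fs: float = 256.0, n_channels: int = 2) -> Recording:
    n = int(round(duration_min * 60 * fs))
    rng = np.random.default_rng(0)
    return Recording(samples=rng.standard_normal((n_channels, n)), sampling_rate=fs,
                     recording_id="r0")


class TestSegmentRecording:
    def test_twelve_minutes_capped_at_two(self):
        segments = segment_recording(make_recording(12))
        assert len(segments) == 2

    def test_seven_minutes_gives_one(self):
        segments = segment_recording(make_recording(7))
        assert len(segments) == 1
        assert segments[0].duration == pytest.approx(300.0)
        # covers minutes 0-5
        rec = make_recording(7)
        np.testing.assert_array_equal(segments[0].samples, rec.samples[0][: 300 * 256])

    def test_four_minutes_gives_none(self):
        assert segment_recording(make_recording(4)) == []

    def test_invalid_channel(self):
        with pytest.raises(IndexError):
            segment_recording(make_recording(6), channel=5)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            segment_recording(make_recording(6), segment_duration=0)

    def test_segments_are_consecutive_and_indexed(self):
        rec = make_recording(12)
        segs = segment_recording(rec)
        assert [s.segment_index for s in segs] == [0, 1]
        n = 300 * 256
        np.testing.assert_array_equal(segs[1].samples, rec.samples[0][n : 2 * n])


class TestSubtractMean:
    def test_arithmetic(self):
        seg = Segment([1.0, 2.0, 3.0], sampling_rate=1.0)
        np.testing.assert_allclose(subtract_mean(seg).samples, [-1.0, 0.0, 1.0])

    def test_constant_to_zero(self):
        seg = Segment(np.full(100, 7.3), sampling_rate=10.0)
        np.testing.assert_allclose(subtract_mean(seg).samples, 0.0, atol=1e-12)

    def test_idempotent_on_centered(self):
        x = np.array([-1.5, 0.5, 1.0])
        seg = Segment(x, sampling_rate=1.0)
        np.testing.assert_allclose(subtract_mean(seg).samples, x, atol=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=500))
    @settings(max_examples=50, deadline=None)
    def test_mean_within_tolerance(self, values):
        seg = Segment(np.array(values), sampling_rate=1.0)
        out = subtract_mean(seg)
        scale = max(1.0, np.max(np.abs(out.samples), initial=0.0))
        assert abs(out.samples.mean()) < 1e-9 * scale


class TestLowpassFilter:
    def test_zero_in_zero_out(self):
        seg = Segment(np.zeros(1000), sampling_rate=256.0)
        np.testing.assert_array_equal(lowpass_filter(seg).samples, 0.0)

    def test_50hz_tone_suppressed_over_80db(self):
        seg = make_tone_segment(50.0, amplitude=100.0, fs=256.0, duration=300.0)
        out = lowpass_filter(seg)
        rms_in = np.sqrt(np.mean(seg.samples**2))
        rms_out = np.sqrt(np.mean(out.samples[seg.samples.size // 2 :] ** 2))
        assert rms_out < 1e-4 * rms_in

    def test_attenuation_at_twice_cutoff(self):
        # analytic 8th-order Butterworth: -10*log10(1 + 2^16) = 48.16 dB at 2*fc
        seg = make_tone_segment(0.2, amplitude=100.0, fs=256.0, duration=600.0)
        out = lowpass_filter(seg)
        half = seg.samples.size // 2  # steady state only
        rms_in = np.sqrt(np.mean(seg.samples[half:] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[half:] ** 2))
        attenuation_db = 20 * np.log10(rms_in / rms_out)
        assert attenuation_db == pytest.approx(48.2, abs=1.0)

    def test_cutoff_above_nyquist_rejected(self):
        seg = Segment(np.ones(100), sampling_rate=32.0)
        with pytest.raises(ValueError):
            lowpass_filter(seg, cutoff=16.0)
        with pytest.raises(ValueError):
            lowpass_filter(seg, cutoff=20.0)

    def test_length_preserved(self):
        seg = Segment(np.random.default_rng(1).standard_normal(12345), sampling_rate=256.0)
        assert lowpass_filter(seg).n_samples == 12345

    def test_zero_phase_mode(self):
        seg = make_tone_segment(0.04, amplitude=50.0, fs=256.0, duration=300.0)
        out = lowpass_filter(seg, zero_phase=True)
        assert out.n_samples == seg.n_samples
        # passband tone survives
        assert np.sqrt(np.mean(out.samples**2)) > 0.9 * np.sqrt(np.mean(seg.samples**2))


class TestDownsample:
    def test_canonical_lengths(self):
        seg = Segment(np.arange(76_800, dtype=float), sampling_rate=256.0)
        out = downsample(seg, factor=8)
        assert out.n_samples == 9_600
        assert out.sampling_rate == 32.0

    def test_keeps_every_kth_from_first(self):
        seg = Segment(np.arange(32, dtype=float), sampling_rate=8.0)
        np.testing.assert_array_equal(downsample(seg, 8).samples, [0, 8, 16, 24])

    def test_factor_one_identity(self):
        seg = Segment(np.random.default_rng(0).standard_normal(100), sampling_rate=256.0)
        out = downsample(seg, factor=1)
        np.testing.assert_array_equal(out.samples, seg.samples)
        assert out.sampling_rate == seg.sampling_rate

    def test_constant_stays_constant(self):
        seg = Segment(np.full(80, 2.5), sampling_rate=256.0)
        out = downsample(seg, 8)
        np.testing.assert_array_equal(out.samples, np.full(10, 2.5))

    def test_invalid_factor(self):
        seg = Segment(np.ones(10), sampling_rate=256.0)
        with pytest.raises(ValueError):
            downsample(seg, 0)

    def test_non_divisible_length_floors(self):
        seg = Segment(np.arange(77, dtype=float), sampling_rate=256.0)
        assert downsample(seg, 8).n_samples == 10  # floor(77/8) + start sample


class TestPreprocessSegment:
    def test_zero_to_zero(self):
        seg = Segment(np.zeros(76_800), sampling_rate=256.0)
        out = preprocess_segment(seg)
        np.testing.assert_array_equal(out.samples, 0.0)
        assert out.n_samples == 9_600

    def test_offset_removed_tone_preserved(self):
        seg = make_tone_segment(0.04, amplitude=100.0, fs=256.0, duration=300.0)
        seg_off = seg.with_samples(seg.samples + 500.0)
        out = preprocess_segment(seg_off)
        freqs, power = direct_dft_power_onesided(out.samples, out.sampling_rate)
        k = int(round(0.04 * out.n_samples / out.sampling_rate))
        # offset (500 uV -> 250,000 uV^2 of DC power) is gone up to the
        # causal filter's startup residue
        assert power[0] < 0.005 * power[k]
        assert power[k] > 0.95 * power.sum()  # tone survives in its bin
        assert power[k] == pytest.approx(100.0**2 / 2, rel=1e-3)  # passband gain ~1

    def test_pp_segment_band_limited(self):
        # short clean-scale run so the O(N^2) oracle stays cheap
        cfg = pp_preset(duration=60.0, n_channels=1, seed=2)
        rec = generate_recording(cfg)
        seg = segment_recording(rec, segment_duration=60.0)[0]
        out = preprocess_segment(seg)
        freqs, power = direct_dft_power_onesided(out.samples, out.sampling_rate)
        above = power[freqs > 0.2].sum()
        assert above < 0.01 * power.sum()

    def test_linearity(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(4096)
        y = rng.standard_normal(4096)
        a, b = 2.5, -1.25
        seg = lambda v: Segment(v, sampling_rate=256.0)  # noqa: E731
        combined = preprocess_segment(seg(a * x + b * y)).samples
        separate = a * preprocess_segment(seg(x)).samples + b * preprocess_segment(seg(y)).samples
        np.testing.assert_allclose(combined, separate, rtol=1e-9, atol=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(4096)
        base = preprocess_segment(Segment(x, sampling_rate=256.0)).samples
        shifted = preprocess_segment(Segment(x + 1e4, sampling_rate=256.0)).samples
        np.testing.assert_allclose(shifted, base, atol=1e-7)

    def test_anti_aliasing(self):
        # broadband input: post-downsample power above 0.15 Hz stays < 2%
        # (evaluated past the documented startup transient of the causal pass)
        rng = np.random.default_rng(9)
        seg = Segment(rng.standard_normal(76_800), sampling_rate=256.0)
        out = preprocess_segment(seg)
        steady = out.samples[int(60 * out.sampling_rate) :]
        spec = np.abs(np.fft.rfft(steady)) ** 2
        freqs = np.fft.rfftfreq(steady.size, d=1 / out.sampling_rate)
        assert spec[freqs > 0.15].sum() < 0.02 * spec.sum()

    def test_anti_aliasing_zero_phase(self):
        rng = np.random.default_rng(10)
        seg = Segment(rng.standard_normal(76_800), sampling_rate=256.0)
        out = preprocess_segment(seg, PreprocessParams(zero_phase=True))
        spec = np.abs(np.fft.rfft(out.samples)) ** 2
        freqs = np.fft.rfftfreq(out.n_samples, d=1 / out.sampling_rate)
        assert spec[freqs > 0.15].sum() < 0.02 * spec.sum()

    def test_metadata_preserved(self):
        seg = Segment(
            np.random.default_rng(0).standard_normal(76_800),
            sampling_rate=256.0,
            source_recording_id="recA",
            segment_index=1,
            phase="LP",
        )
        out = preprocess_segment(seg)
        assert out.source_recording_id == "recA"
        assert out.segment_index == 1
        assert out.phase.value == "LP"

    def test_params_from_dict_ignores_unknown(self):
        p = PreprocessParams.from_dict({"cutoff_hz": 0.2, "bogus": 1})
        assert p.cutoff_hz == 0.2
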
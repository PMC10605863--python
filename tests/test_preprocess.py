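"""BMI arithmetic, FIR design/response, R-peak detection and beat
extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from pedecg import preprocess, synthcohort
from pedecg.preprocess import (BEAT_LENGTH, FilterSpec, Beat, classify_bmi,
                               compute_bmi, design_fir_bandpass,
                               detect_r_peaks, extract_beats, filter_signal)


class TestBMI:
    def test_standard_formula(self):
        assert compute_bmi(45.0, 1.5) == pytest.approx(20.0)

    @pytest.mark.parametrize("w,h", [(50, 0), (0, 1.5), (-3, 1.2)])
    def test_nonpositive_inputs_rejected(self, w, h):
        with pytest.raises(ValueError):
            compute_bmi(w, h)

    @given(w=st.floats(20, 120), h=st.floats(1.0, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, w, h):
        assert compute_bmi(4 * w, 2 * h) == pytest.approx(compute_bmi(w, h))

    @pytest.mark.parametrize("bmi,sex,expected", [
        (22.7, "female", "obese"),
        (18.4, "male", "normal"),
        (18.9, "female", "normal"),
        (22.61, "female", "obese"),
        (20.0, "male", "overweight"),
        # cutoff values themselves fall to the middle class
        (21.4, "male", "overweight"),
        (19.0, "female", "overweight"),
    ])
    def test_sex_specific_categories(self, bmi, sex, expected):
        assert classify_bmi(bmi, sex) == expected

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            classify_bmi(20.0, "unknown")


class TestFIR:
    def gain_at(self, taps, freq_hz):
        _, h = sps.freqz(taps, worN=[freq_hz], fs=500)
        return float(np.abs(h[0]))

    def test_midband_gain_near_unity(self):
        taps = design_fir_bandpass()
        assert 0.95 <= self.gain_at(taps, 10.0) <= 1.05

    def test_dc_strongly_attenuated(self):
        taps = design_fir_bandpass()
        assert self.gain_at(taps, 0.0) <= 0.01

    def test_impulse_response_support_equals_num_taps(self):
        spec = FilterSpec(num_taps=301)
        taps = design_fir_bandpass(spec)
        impulse = np.zeros(2000)
        impulse[0] = 1.0
        out = sps.lfilter(taps, [1.0], impulse)
        assert np.any(out[:301] != 0)
        assert np.allclose(out[301:], 0.0)

    @pytest.mark.parametrize("low,high", [(0, 40), (40, 0.5), (0.5, 300)])
    def test_invalid_band_edges_rejected(self, low, high):
        with pytest.raises(ValueError):
            design_fir_bandpass(FilterSpec(low_cut_hz=low, high_cut_hz=high))

    def test_even_tap_count_rejected(self):
        with pytest.raises(ValueError):
            design_fir_bandpass(FilterSpec(num_taps=500))


class TestFilterSignal:
    taps = design_fir_bandpass()
    t = np.arange(5000) / 500.0

    def test_10hz_amplitude_preserved_no_delay(self):
        x = np.sin(2 * np.pi * 10 * self.t)
        y = filter_signal(x, self.taps)
        mid = slice(1500, 3500)
        assert np.max(np.abs(y[mid] - x[mid])) < 0.05

    def test_dc_removed(self):
        y = filter_signal(np.full(5000, 3.7), self.taps)
        assert np.abs(y[1500:3500]).max() <= 0.037

    def test_zeros_map_to_zeros(self):
        assert np.allclose(filter_signal(np.zeros(5000), self.taps), 0.0)

    def test_linearity_and_time_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 5000))
        lhs = filter_signal(2.0 * a - 3.0 * b, self.taps)
        rhs = 2.0 * filter_signal(a, self.taps) - 3.0 * filter_signal(b, self.taps)
        assert np.allclose(lhs, rhs, atol=1e-9)
        shifted = filter_signal(np.roll(a, 100), self.taps)
        assert np.allclose(shifted[1500:3500],
                           np.roll(filter_signal(a, self.taps), 100)[1500:3500],
                           atol=1e-9)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            filter_signal(np.zeros(100), self.taps)


class TestDetector:
    def test_flat_signal_gives_no_peaks(self):
        assert detect_r_peaks(np.zeros(5000)).size == 0

    def test_refractory_suppresses_close_doublet(self):
        # two identical sharp peaks 80 ms (40 samples) apart
        x = np.zeros(5000)
        for c in (2000, 2040):
            x += np.exp(-0.5 * ((np.arange(5000) - c) / 5.0) ** 2)
        peaks = detect_r_peaks(x)
        assert np.sum((peaks > 1900) & (peaks < 2140)) == 1

    def test_sensitivity_on_default_noise_profile(self):
        """Hamilton-style detection recovers >= 99% of true R peaks at
        the generator's default noise level (50 records)."""
        records, _ = synthcohort.generate_cohort(25, ("normal", "obese"),
                                                 seed=31)
        taps = design_fir_bandpass()
        hits = total = 0
        for rec in records:
            detected = detect_r_peaks(filter_signal(rec.signal, taps))
            inside = rec.r_truth[(rec.r_truth >= 100)
                                 & (rec.r_truth < 4900)]
            total += inside.size
            for r in inside:
                if detected.size and np.min(np.abs(detected - r)) <= 5:
                    hits += 1
        assert hits / total >= 0.99

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(10))


class TestBeats:
    sig = np.sin(np.arange(5000) / 30.0)

    def test_window_boundaries(self):
        kept, discarded = extract_beats(self.sig, [99, 100, 2500, 4800, 4801])
        assert [b.r_index for b in kept] == [100, 2500, 4800]
        assert [d["r_index"] for d in discarded] == [99, 4801]
        assert {d["reason"] for d in discarded} == {"incomplete_head",
                                                    "incomplete_tail"}
        first = kept[0]
        np.testing.assert_array_equal(first.samples, self.sig[0:300])

    def test_conservation_and_length(self):
        r = np.arange(0, 5000, 37)
        kept, discarded = extract_beats(self.sig, r)
        assert len(kept) + len(discarded) == r.size
        assert all(b.samples.size == BEAT_LENGTH for b in kept)

    def test_r_peak_at_local_index_100_on_clean_beat(self):
        rec = synthcohort.synth_record(
            synthcohort.sample_subject(np.random.default_rng(0), "normal",
                                       "male"),
            synthcohort.build_template("normal", 1.0),
            synthcohort.ZERO_NOISE, (60.0, 60.0), np.random.default_rng(1))
        taps = design_fir_bandpass()
        filtered = filter_signal(rec.signal, taps)
        kept, _ = extract_beats(filtered, detect_r_peaks(filtered))
        for beat in kept:
            assert np.argmax(beat.samples) == 100

    def test_wrong_length_beat_rejected(self):
        with pytest.raises(ValueError):
            Beat(record_ref="x", r_index=100, samples=np.zeros(299))
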
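"""Generator contracts: label consistency, determinism, morphology
locality and the record/cohort bookkeeping."""

import numpy as np
import pytest

from pedecg import preprocess, synthcohort
from pedecg.ingest import compute_age_years
from pedecg.preprocess import classify_bmi, compute_bmi
from pedecg.synthcohort import (DIFF_WINDOW_MS, ZERO_NOISE, build_template,
                                generate_cohort, sample_subject,
                                synth_record, write_cohort)


@pytest.mark.parametrize("target", ["normal", "overweight", "obese"])
@pytest.mark.parametrize("sex", ["male", "female"])
def test_sampled_subject_recovers_target_class(target, sex):
    for seed in range(5):
        s = sample_subject(np.random.default_rng(seed), target, sex)
        bmi = compute_bmi(s.weight_kg, s.height_m)
        assert classify_bmi(bmi, sex) == target


def test_sampled_subject_bmi_sides_of_cutoffs():
    s = sample_subject(np.random.default_rng(1), "obese", "female")
    assert compute_bmi(s.weight_kg, s.height_m) > 22.6
    s = sample_subject(np.random.default_rng(1), "normal", "male")
    assert compute_bmi(s.weight_kg, s.height_m) < 18.5


def test_sampled_subject_age_band_and_determinism():
    for seed in (0, 7, 123):
        a = sample_subject(np.random.default_rng(seed), "normal", "female")
        b = sample_subject(np.random.default_rng(seed), "normal", "female")
        assert a == b
        age = compute_age_years(a.birth_date,
                                synthcohort._COLLECTION_ANCHOR)
        assert age in (9, 10, 11)


class TestTemplates:
    def test_zero_effect_classes_identical(self):
        assert (build_template("normal", 0.0).components
                == build_template("obese", 0.0).components)

    def test_obese_t_amplitude_reduced(self):
        normal = build_template("normal", 1.0)
        obese = build_template("obese", 1.0)
        assert (obese.component("T").amplitude_mv
                < normal.component("T").amplitude_mv)

    def test_difference_confined_to_window(self):
        normal = build_template("normal", 1.0)
        obese = build_template("obese", 1.0)
        t = np.arange(-200.0, 400.0, 0.5)
        diff = np.abs(normal.evaluate(t) - obese.evaluate(t))
        lo, hi = DIFF_WINDOW_MS
        outside = (t < lo) | (t >= hi)
        assert diff[outside].max() < 1e-3      # mV; ±4 sigma containment
        assert diff[~outside].max() > 0.05     # the effect itself is there

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            build_template("obese", -0.5)

    def test_r_peak_is_global_maximum(self):
        tpl = build_template("normal", 1.0)
        t = np.arange(-200.0, 400.0, 2.0)
        wave = tpl.evaluate(t)
        assert t[np.argmax(wave)] == pytest.approx(0.0, abs=2.0)


class TestSynthRecord:
    def make(self, noise=ZERO_NOISE, hr=(60.0, 60.0), seed=3):
        rng = np.random.default_rng(seed)
        subject = sample_subject(rng, "normal", "male")
        return synth_record(subject, build_template("normal", 1.0), noise,
                            hr, rng)

    def test_signal_length_is_5000(self):
        assert self.make().signal.size == 5000

    def test_fixed_60_bpm_gives_uniform_beats(self):
        rec = self.make()
        assert rec.r_truth.size in (10, 11)
        assert np.all(np.diff(rec.r_truth) == 500)

    def test_detector_recovers_ground_truth_on_clean_record(self):
        rec = self.make(hr=(70.0, 100.0), seed=9)
        taps = preprocess.design_fir_bandpass()
        filtered = preprocess.filter_signal(rec.signal, taps)
        detected = preprocess.detect_r_peaks(filtered)
        inside = rec.r_truth[(rec.r_truth >= 100) & (rec.r_truth < 4900)]
        for r in inside:
            assert np.min(np.abs(detected - r)) <= 5

    def test_empty_heart_rate_range_rejected(self):
        with pytest.raises(ValueError):
            self.make(hr=(30.0, 20.0))


class TestCohort:
    def test_write_cohort_counts(self, tmp_path):
        manifest = write_cohort(5, ("normal", "obese"), tmp_path, seed=7)
        assert len(manifest) == 10
        assert len(list(tmp_path.glob("*.xml"))) == 10

    def test_rerun_is_byte_identical(self, tmp_path):
        write_cohort(2, ("normal",), tmp_path / "a", seed=5)
        write_cohort(2, ("normal",), tmp_path / "b", seed=5)
        for fa, fb in zip(sorted((tmp_path / "a").glob("*.xml")),
                          sorted((tmp_path / "b").glob("*.xml"))):
            assert fa.read_bytes() == fb.read_bytes()

    def test_invalid_fraction_allocation(self):
        _, manifest = generate_cohort(10, ("normal", "obese"), seed=1,
                                      invalid_fraction=0.2)
        per_class = manifest[manifest.invalid != ""].groupby(
            "target_class").size()
        assert per_class.to_dict() == {"normal": 2, "obese": 2}

    def test_class_locality_of_mean_beats(self):
        """With zero noise the pointwise class-mean difference is nonzero
        only inside the configured difference window."""
        recs, _ = generate_cohort(3, ("normal", "obese"), seed=2,
                                  noise_spec=ZERO_NOISE)
        means = {}
        for cls in ("normal", "obese"):
            beats = []
            for rec in recs:
                cls_rec = classify_bmi(
                    compute_bmi(rec.weight_kg, rec.height_cm / 100), rec.sex)
                if cls_rec != cls:
                    continue
                for r in rec.r_truth:
                    if 100 <= r and r + 200 <= 5000:
                        beats.append(rec.signal_mv()[r - 100:r + 200])
            means[cls] = np.mean(beats, axis=0)
        diff = np.abs(means["normal"] - means["obese"])
        window = slice(175, 275)           # +150..+350 ms after R
        outside = np.ones(300, bool)
        outside[window] = False
        assert diff[outside].max() < 2e-3   # uV quantisation floor
        assert diff[window].max() > 0.05
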
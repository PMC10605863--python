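"""Synthetic paediatric ECG cohort generator.

Emulates the statistical structure the downstream analysis assumes:
10-s, 500-Hz single-lead records with PQRST morphology, heart-rate
variability, baseline wander / powerline / motion noise, anthropometry
consistent with a target BMI class, ages 9–11, and (on request) invalid
or abnormal-report records to exercise the ingest filters.

The beat model is a sum of five Gaussians (P, Q, R, S, T), one per
deflection.  The obese class differs from the normal class only inside
a configurable *difference window* — by default the T-wave region,
+150 to +350 ms after the R peak — where the T amplitude is scaled
down (and slightly delayed) in proportion to ``effect_size``.  Where
real obese/normal beats differ is unknown; the window is a simulation
parameter, not a biological claim.

Reproducibility: one root seed; each record draws from an independent
substream spawned as ``SeedSequence([root_seed, class_index, record_index])``,
so cohorts are byte-identical across runs and invariant to generation
order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (DEFAULT_CUTOFFS, BMICutoffs, bmi_interval,
                         classify_bmi, compute_bmi)
from .records import (RECORD_LENGTH, SAMPLING_RATE_HZ, ECGRecord,
                      write_record)

# ----------------------------------------------------------------------
# Morphology
# ----------------------------------------------------------------------

WAVE_LABELS = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian deflection of the PQRST complex."""

    label: str           # P, Q, R, S or T
    center_ms: float     # offset from the R peak; negative = before
    width_ms: float      # Gaussian standard deviation
    amplitude_mv: float  # signed peak amplitude

    def __post_init__(self):
        if self.label not in WAVE_LABELS:
            raise ValueError(f"unknown wave label {self.label!r}")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if not (-200 <= self.center_ms < 400):
            raise ValueError("center_ms must lie in [-200, 400) ms")


# Baseline paediatric lead-I morphology (amplitudes in mV).  The T wave
# is centred at +250 ms with a 25 ms width so that ±4 standard
# deviations stay inside the default difference window below.
_BASE_COMPONENTS = (
    WaveComponent("P", -140.0, 22.0, 0.12),
    WaveComponent("Q", -22.0, 9.0, -0.10),
    WaveComponent("R", 0.0, 11.0, 1.00),
    WaveComponent("S", 24.0, 9.0, -0.18),
    WaveComponent("T", 250.0, 25.0, 0.30),
)

# Difference window: T-wave region, relative to the R peak.
DIFF_WINDOW_MS = (150.0, 350.0)


@dataclass(frozen=True)
class MorphologyTemplate:
    """Class-conditional beat shape: five Gaussian components."""

    components: tuple[WaveComponent, ...]
    class_label: str

    def __post_init__(self):
        labels = sorted(c.label for c in self.components)
        if labels != sorted(WAVE_LABELS):
            raise ValueError("template needs exactly one P, Q, R, S, T")
        r = self.component("R")
        if any(abs(c.amplitude_mv) > abs(r.amplitude_mv)
               for c in self.components):
            raise ValueError("R must carry the largest |amplitude|")

    def component(self, label: str) -> WaveComponent:
        return next(c for c in self.components if c.label == label)

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Waveform (mV) at offsets ``t_ms`` from the R peak."""
        t = np.asarray(t_ms, dtype=np.float64)
        out = np.zeros_like(t)
        for c in self.components:
            out += c.amplitude_mv * np.exp(-0.5 * ((t - c.center_ms)
                                                   / c.width_ms) ** 2)
        return out


def build_template(class_label: str, effect_size: float = 1.0,
                   diff_window_ms: tuple[float, float] = DIFF_WINDOW_MS
                   ) -> MorphologyTemplate:
    """Class-conditional template; the two classes are identical except
    inside ``diff_window_ms``, where the obese T wave is flattened.

    At ``effect_size = 0`` the classes coincide; at 1 the obese T
    amplitude is halved and its peak delayed by 15 ms.  The modified T
    component is constrained to keep its ±4-sigma support inside the
    window, so the pointwise class difference outside the window is
    below 1e-3 of the T amplitude.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if class_label not in ("normal", "obese"):
        raise ValueError(f"unknown class label {class_label!r}")
    components = list(_BASE_COMPONENTS)
    if class_label == "obese" and effect_size > 0:
        t_idx = next(i for i, c in enumerate(components) if c.label == "T")
        t = components[t_idx]
        scale = max(0.0, 1.0 - 0.5 * min(effect_size, 1.8))
        shifted = t.center_ms + 15.0 * min(effect_size, 1.0)
        lo, hi = diff_window_ms
        # keep ±4 sigma of the modified T inside the window
        shifted = min(max(shifted, lo + 4 * t.width_ms),
                      hi - 4 * t.width_ms)
        components[t_idx] = replace(t, amplitude_mv=t.amplitude_mv * scale,
                                    center_ms=shifted)
    return MorphologyTemplate(tuple(components), class_label)


# ----------------------------------------------------------------------
# Noise
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: white sensor noise, respiratory baseline
    wander, powerline pickup and occasional motion artifacts."""

    gaussian_sd_mv: float = 0.02
    baseline_wander_amp_mv: float = 0.10
    baseline_wander_freq_hz: float = 0.25
    powerline_amp_mv: float = 0.02
    powerline_freq_hz: float = 50.0
    artifact_rate_per_record: float = 0.3
    artifact_amp_mv: float = 0.6
    artifact_duration_s: float = 0.15

    def __post_init__(self):
        if min(self.gaussian_sd_mv, self.baseline_wander_amp_mv,
               self.powerline_amp_mv, self.artifact_rate_per_record,
               self.artifact_amp_mv) < 0:
            raise ValueError("noise amplitudes/rates must be >= 0")
        if min(self.baseline_wander_freq_hz, self.powerline_freq_hz) <= 0:
            raise ValueError("noise frequencies must be positive")


DEFAULT_NOISE = NoiseSpec()
ZERO_NOISE = NoiseSpec(0.0, 0.0, 0.25, 0.0, 50.0, 0.0, 0.0)

# Abnormality vocabulary used for injected abnormal reports; mirrors the
# terms a paediatric cardiologist used in the source reports.
ABNORMAL_REPORTS = (
    "sinus arrhythmia",
    "early repolarisation pattern",
    "sinus bradycardia",
    "auriculoventricular heart block",
    "ventricular hypertrophy",
    "left electrical axis deviation",
)


# ----------------------------------------------------------------------
# Subjects
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    sex: str
    birth_date: date
    height_m: float
    weight_kg: float
    target_class: str

    def __post_init__(self):
        if not (0.5 < self.height_m < 2.5):
            raise ValueError("implausible height")
        if not (5 < self.weight_kg < 150):
            raise ValueError("implausible weight")


# study-era anchor for collection visits
_COLLECTION_ANCHOR = datetime(2015, 6, 15, 9, 0, 0)

# height (m) for 9–11-year-olds: sex-specific normals
_HEIGHT_MEAN = {"male": 1.41, "female": 1.40}
_HEIGHT_SD = 0.065


def sample_subject(rng: np.random.Generator, target_class: str, sex: str,
                   cutoffs: BMICutoffs = DEFAULT_CUTOFFS) -> SubjectMeta:
    """Draw one subject whose recomputed BMI category equals
    ``target_class`` and whose age at the anchor collection date is
    9, 10 or 11 completed years.

    Height is drawn from a sex-specific normal distribution; the BMI is
    drawn uniformly inside the target category's interval (with a small
    margin off the open boundaries) and the weight solved from the two,
    which guarantees label consistency by construction.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    lo, hi = bmi_interval(target_class, sex, cutoffs)
    margin = 0.15 * (hi - lo)
    bmi = rng.uniform(lo + margin, hi - margin)
    height = float(np.clip(rng.normal(_HEIGHT_MEAN[sex], _HEIGHT_SD),
                           1.20, 1.65))
    weight = bmi * height ** 2
    age_years = int(rng.integers(9, 12))
    # birthday strictly more than `age_years` and less than `age_years`+1
    # years before the anchor date
    offset_days = int(round(age_years * 365.25)) + int(rng.integers(30, 330))
    birth = (_COLLECTION_ANCHOR - timedelta(days=offset_days)).date()
    subject_id = f"GX-{int(rng.integers(0, 10 ** 8)):08d}"
    subject = SubjectMeta(subject_id=subject_id, sex=sex, birth_date=birth,
                          height_m=height, weight_kg=weight,
                          target_class=target_class)
    got = classify_bmi(compute_bmi(subject.weight_kg, subject.height_m),
                       sex, cutoffs)
    if got != target_class:  # pragma: no cover - construction guarantees it
        raise AssertionError(f"sampled subject classifies as {got}, "
                             f"wanted {target_class}")
    return subject


# ----------------------------------------------------------------------
# Records
# ----------------------------------------------------------------------

def synth_record(subject: SubjectMeta, template: MorphologyTemplate,
                 noise_spec: NoiseSpec = DEFAULT_NOISE,
                 hr_bpm_range: tuple[float, float] = (70.0, 100.0),
                 rng: np.random.Generator | None = None,
                 abnormal_report: str | None = None,
                 collection_date: datetime = _COLLECTION_ANCHOR
                 ) -> ECGRecord:
    """Synthesise one 5000-sample lead-I record for ``subject``.

    Per-beat heart rate is drawn uniformly from ``hr_bpm_range`` (a
    degenerate range gives perfectly regular rhythm); ground-truth R
    positions are kept on the record (``r_truth``) for oracle tests but
    never serialised into the XML.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo_bpm, hi_bpm = hr_bpm_range
    if not (40 <= lo_bpm <= hi_bpm <= 200):
        raise ValueError("hr_bpm_range must lie within [40, 200] bpm")

    fs = SAMPLING_RATE_HZ
    n = RECORD_LENGTH
    t_ms = np.arange(n) / fs * 1000.0

    # R-peak times: start offset then per-beat RR from the HR range
    r_times_s = [rng.uniform(0.25, 0.60)]
    while True:
        rr = 60.0 / rng.uniform(lo_bpm, hi_bpm)
        nxt = r_times_s[-1] + rr
        if nxt >= RECORD_LENGTH / fs:
            break
        r_times_s.append(nxt)
    r_idx = np.round(np.asarray(r_times_s) * fs).astype(np.int64)
    r_idx = r_idx[r_idx < n]

    signal_mv = np.zeros(n)
    for r in r_idx:
        offsets = t_ms - t_ms[r]
        mask = (offsets >= -250.0) & (offsets < 450.0)
        signal_mv[mask] += template.evaluate(offsets[mask])

    ns = noise_spec
    if ns.gaussian_sd_mv > 0:
        signal_mv += rng.normal(0.0, ns.gaussian_sd_mv, n)
    if ns.baseline_wander_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal_mv += ns.baseline_wander_amp_mv * np.sin(
            2 * np.pi * ns.baseline_wander_freq_hz * t_ms / 1000.0 + phase)
    if ns.powerline_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal_mv += ns.powerline_amp_mv * np.sin(
            2 * np.pi * ns.powerline_freq_hz * t_ms / 1000.0 + phase)
    if ns.artifact_rate_per_record > 0:
        for _ in range(rng.poisson(ns.artifact_rate_per_record)):
            start = int(rng.integers(0, n))
            width = int(ns.artifact_duration_s * fs)
            seg = slice(start, min(n, start + width))
            signal_mv[seg] += (ns.artifact_amp_mv
                               * rng.normal(0.0, 1.0, seg.stop - seg.start))

    signal_uv = np.round(signal_mv * 1000.0).astype(np.int64)
    return ECGRecord(
        subject_id=subject.subject_id,
        birth_date=subject.birth_date,
        collection_date=collection_date,
        sex=subject.sex,
        weight_kg=round(subject.weight_kg, 1),
        height_cm=round(subject.height_m * 100.0, 1),
        signal=signal_uv,
        report_text=abnormal_report if abnormal_report else "normal",
        r_truth=r_idx,
    )


# ----------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------

def _record_rng(seed: int, class_index: int, record_index: int
                ) -> np.random.Generator:
    """Per-record substream: independent of generation order."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, class_index, record_index]))


def generate_cohort(n_per_class: int,
                    class_list: tuple[str, ...] = ("normal", "obese"),
                    seed: int = 0,
                    effect_size: float = 1.0,
                    noise_spec: NoiseSpec = DEFAULT_NOISE,
                    hr_bpm_range: tuple[float, float] = (70.0, 100.0),
                    invalid_fraction: float = 0.0,
                    abnormal_fraction: float = 0.0,
                    diff_window_ms: tuple[float, float] = DIFF_WINDOW_MS
                    ) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Generate ``n_per_class`` records for every class in ``class_list``.

    Deterministic invalid/abnormal allocation: within each class the
    first ``round(invalid_fraction * n)`` records are made invalid
    (alternating missing-signal and implausible-height defects) and the
    next ``round(abnormal_fraction * n)`` get an abnormal report drawn
    from the cardiology vocabulary.  Returns the records and a manifest
    with one row per record (file names filled in by ``write_cohort``).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    records: list[ECGRecord] = []
    rows: list[dict] = []
    n_invalid = int(round(invalid_fraction * n_per_class))
    n_abnormal = int(round(abnormal_fraction * n_per_class))
    for ci, cls in enumerate(class_list):
        template = build_template(cls if cls != "overweight" else "normal",
                                  effect_size, diff_window_ms)
        for ri in range(n_per_class):
            rng = _record_rng(seed, ci, ri)
            sex = "male" if rng.random() < 0.51 else "female"
            subject = sample_subject(rng, cls, sex)
            invalid_kind = ""
            abnormal = None
            if ri < n_invalid:
                invalid_kind = ("missing_signal" if ri % 2 == 0
                                else "invalid_anthropometry")
            elif ri < n_invalid + n_abnormal:
                abnormal = ABNORMAL_REPORTS[ri % len(ABNORMAL_REPORTS)]
            rec = synth_record(subject, template, noise_spec, hr_bpm_range,
                               rng, abnormal_report=abnormal)
            if invalid_kind == "missing_signal":
                rec.signal = np.empty(0, dtype=np.int64)
                rec.r_truth = np.empty(0, dtype=np.int64)
            elif invalid_kind == "invalid_anthropometry":
                rec.height_cm = 999.0
            records.append(rec)
            rows.append({
                "file": "",
                "subject_id": rec.subject_id,
                "target_class": cls,
                "sex": sex,
                "invalid": invalid_kind,
                "abnormal_report": int(abnormal is not None),
                "r_truth": ";".join(str(int(v)) for v in
                                    (rec.r_truth if rec.r_truth is not None
                                     else [])),
            })
    return records, pd.DataFrame(rows)


def write_cohort(n_per_class: int,
                 class_list: tuple[str, ...],
                 out_dir: str | Path,
                 seed: int,
                 **kwargs) -> pd.DataFrame:
    """Generate a cohort and write one XML file per record plus a
    ``manifest.csv`` (columns: file, subject_id, target_class, sex,
    invalid, abnormal_report, r_truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, manifest = generate_cohort(n_per_class, class_list, seed,
                                        **kwargs)
    files = []
    for i, rec in enumerate(records):
        name = f"ecg_{i:05d}_{rec.subject_id}.xml"
        write_record(rec, out_dir / name)
        files.append(name)
    manifest["file"] = files
    manifest.to_csv(out_dir / "manifest.csv", index=False,
                    quoting=csv.QUOTE_MINIMAL)
    return manifest
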
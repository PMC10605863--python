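"""Inclusion/exclusion rules, beat labelling and train/val/test splits.

Exclusions mirror the study design: overweight subjects are dropped (the
contrast of interest is normal vs obese) and so is any record whose
cardiologist report matches an abnormality lexicon — the classifier
should learn BMI-related morphology, not arrhythmias or conduction
defects.

Splitting is stratified by class and, by default, performed at the
*subject* level, so no child contributes beats to more than one split.
A beat-level mode is provided for compatibility with pipelines that
split the pooled beats directly; beat-level splitting lets beats from
one subject appear on both sides of the train/test divide and therefore
inflates accuracy estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Beat, classify_bmi, compute_bmi
from .records import ECGRecord

SPLIT_NAMES = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.70, 0.20, 0.10)

# Case-insensitive substring lexicon for abnormal cardiology reports;
# seeded from the abnormalities the source reports actually mention.
ABNORMALITY_LEXICON = (
    "arrhythmia",
    "early repolarisation",
    "early repolarization",
    "bradycardia",
    "tachycardia",
    "heart block",
    "auriculoventricular",
    "atrioventricular",
    "hypertrophy",
    "axis deviation",
)


def report_is_abnormal(report_text: str,
                       lexicon=ABNORMALITY_LEXICON) -> bool:
    text = (report_text or "").lower()
    return any(term in text for term in lexicon)


def record_bmi_class(record: ECGRecord) -> str:
    return classify_bmi(compute_bmi(record.weight_kg, record.height_m),
                        record.sex)


def apply_exclusions(records: list[ECGRecord],
                     lexicon=ABNORMALITY_LEXICON
                     ) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Drop overweight subjects and abnormal-report records.

    Returns (kept records, exclusion report).  The report has one row
    per input record with columns record_ref / bmi_class / kept /
    reason, so input count = kept + excluded-by-reason counts.
    """
    kept: list[ECGRecord] = []
    rows: list[dict] = []
    for rec in records:
        bmi_class = record_bmi_class(rec)
        reason = ""
        if bmi_class == "overweight":
            reason = "overweight"
        elif report_is_abnormal(rec.report_text, lexicon):
            reason = "abnormal_report"
        if not reason:
            kept.append(rec)
        rows.append({"record_ref": rec.source_path or rec.subject_id,
                     "subject_id": rec.subject_id,
                     "bmi_class": bmi_class,
                     "kept": not reason,
                     "reason": reason})
    return kept, pd.DataFrame(rows)


@dataclass
class BeatDataset:
    """Labelled beats with subject grouping and split assignment.

    ``X`` holds the beat waveforms (n_beats × 300) in millivolts;
    ``y`` the integer labels (0 = normal, 1 = obese); ``subjects`` the
    subject id of each beat; ``splits`` the split name (empty before
    ``split_dataset`` runs).
    """

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    beats: list[Beat] = field(default_factory=list)
    splits: np.ndarray | None = None
    class_names: tuple[str, str] = ("normal", "obese")

    def __len__(self) -> int:
        return len(self.y)

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if self.splits is None:
            raise ValueError("dataset has no split assignment yet")
        mask = self.splits == name
        return self.X[mask], self.y[mask]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"label": [self.class_names[v] for v in self.y],
                           "subject": self.subjects,
                           "split": (self.splits if self.splits is not None
                                     else "")})
        return (df.groupby(["split", "label"])
                  .agg(beats=("subject", "size"),
                       subjects=("subject", "nunique"))
                  .reset_index())


def label_beats(records: list[ECGRecord], beats_by_record: dict[str, list[Beat]],
                uv_to_mv: float = 1e-3) -> BeatDataset:
    """Attach each record's BMI class to its beats and assemble arrays.

    Every beat must come from a record that survived the exclusions;
    beats referencing unknown records are a pipeline defect and raise.
    A single-class dataset is legal but degenerate, so it warns.
    """
    by_id = {rec.subject_id: rec for rec in records}
    waveforms, labels, subjects, flat = [], [], [], []
    for subject_id, beats in beats_by_record.items():
        if subject_id not in by_id:
            raise ValueError(f"beats reference excluded or unknown record "
                             f"{subject_id!r}")
        cls = record_bmi_class(by_id[subject_id])
        if cls == "overweight":
            raise ValueError(f"record {subject_id!r} is overweight; "
                             "exclusions must run before labelling")
        for beat in beats:
            beat.class_label = cls
            waveforms.append(beat.samples * uv_to_mv)
            labels.append(0 if cls == "normal" else 1)
            subjects.append(subject_id)
            flat.append(beat)
    X = (np.asarray(waveforms, dtype=np.float64) if waveforms
         else np.empty((0, 300)))
    y = np.asarray(labels, dtype=np.int64)
    if len(y) and np.unique(y).size < 2:
        warnings.warn("single-class beat dataset", stacklevel=2)
    return BeatDataset(X=X, y=y,
                       subjects=np.asarray(subjects, dtype=object),
                       beats=flat)


def _allocate(n: int, fractions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder allocation of n units to the fractions."""
    exact = np.asarray(fractions) * n
    counts = np.floor(exact).astype(np.int64)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def split_dataset(ds: BeatDataset,
                  fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                  level: str = "subject",
                  seed: int = 0) -> BeatDataset:
    """Assign train/val/test, stratified by class.

    ``level='subject'`` (default) assigns whole subjects, preventing
    leakage; ``level='beat'`` assigns beats independently.  Achieved
    counts are exact to ±1 unit at the chosen granularity per class
    (largest-remainder allocation of shuffled units).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if level not in ("subject", "beat"):
        raise ValueError("level must be 'subject' or 'beat'")
    rng = np.random.default_rng(seed)
    splits = np.empty(len(ds), dtype=object)

    for cls in np.unique(ds.y):
        cls_mask = ds.y == cls
        if level == "subject":
            units = np.unique(ds.subjects[cls_mask])
        else:
            units = np.flatnonzero(cls_mask)
        units = np.array(sorted(units, key=str), dtype=object)
        rng.shuffle(units)
        counts = _allocate(len(units), fractions)
        bounds = np.cumsum(counts)
        for si, name in enumerate(SPLIT_NAMES):
            lo = 0 if si == 0 else bounds[si - 1]
            chunk = units[lo:bounds[si]]
            if level == "subject":
                member = np.isin(ds.subjects, chunk) & cls_mask
                splits[member] = name
            else:
                splits[chunk.astype(np.int64)] = name
    ds.splits = splits.astype(str)
    return ds
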
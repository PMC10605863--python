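"""End-to-end pipeline helpers tying the stage modules together.

These are thin orchestration functions used by the analysis drivers,
the test-suite and the acceptance script; every computation lives in
the stage modules.
"""

from __future__ import annotations

import numpy as np

from . import dataset as ds_mod
from . import ingest, preprocess, synthcohort
from .records import ECGRecord


def preprocess_records(records: list[ECGRecord],
                       filter_spec: preprocess.FilterSpec | None = None
                       ) -> dict[str, list[preprocess.Beat]]:
    """Filter each record, detect R peaks and extract complete beats,
    keyed by subject id."""
    spec = filter_spec or preprocess.DEFAULT_FILTER
    taps = preprocess.design_fir_bandpass(spec)
    beats_by_record: dict[str, list[preprocess.Beat]] = {}
    for rec in records:
        filtered = preprocess.filter_signal(rec.signal, taps)
        r_peaks = preprocess.detect_r_peaks(filtered)
        kept, _ = preprocess.extract_beats(filtered, r_peaks,
                                           record_ref=rec.subject_id)
        beats_by_record[rec.subject_id] = kept
    return beats_by_record


def cohort_to_dataset(records: list[ECGRecord],
                      split_fractions=ds_mod.DEFAULT_FRACTIONS,
                      split_level: str = "subject",
                      seed: int = 0,
                      filter_spec: preprocess.FilterSpec | None = None
                      ) -> tuple[ds_mod.BeatDataset, dict]:
    """Validate → exclude → segment → label → split.

    Returns the split dataset and a dict of stage reports.
    """
    results = ingest.validate_records(records)
    valid = [r for r, v in zip(records, results) if v.status == "valid"]
    kept, exclusion_report = ds_mod.apply_exclusions(valid)
    beats = preprocess_records(kept, filter_spec)
    beat_ds = ds_mod.label_beats(kept, beats)
    beat_ds = ds_mod.split_dataset(beat_ds, split_fractions,
                                   level=split_level, seed=seed)
    reports = {
        "validation": ingest.validation_report(results),
        "exclusions": exclusion_report,
        "summary": beat_ds.summary(),
    }
    return beat_ds, reports


def synthetic_dataset(n_per_class: int, seed: int,
                      effect_size: float = 1.0,
                      noise_spec: synthcohort.NoiseSpec | None = None,
                      split_level: str = "subject",
                      shuffle_labels: bool = False
                      ) -> ds_mod.BeatDataset:
    """Generate a two-class synthetic cohort and run it through the
    full preprocessing path.

    ``shuffle_labels=True`` permutes the beat labels at the subject
    level after the pipeline (the permutation-null control).
    """
    records, _ = synthcohort.generate_cohort(
        n_per_class, ("normal", "obese"), seed=seed,
        effect_size=effect_size,
        noise_spec=noise_spec or synthcohort.DEFAULT_NOISE)
    beat_ds, _ = cohort_to_dataset(records, seed=seed,
                                   split_level=split_level)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 17)
        subjects = np.unique(beat_ds.subjects)
        labels = {}
        subj_label = [beat_ds.y[beat_ds.subjects == s][0] for s in subjects]
        permuted = rng.permutation(subj_label)
        labels = dict(zip(subjects, permuted))
        beat_ds.y = np.asarray([labels[s] for s in beat_ds.subjects],
                               dtype=np.int64)
    return beat_ds
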
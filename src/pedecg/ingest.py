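"""Record ingestion: XML parsing, age derivation, validity scanning and
cohort/age filtering.

Validation classifies rather than raises: every record receives exactly
one status, assigned by the first failing check in a fixed order —
duplicate → missing_signal → abnormal_signal → invalid_dates →
invalid_anthropometry.  The operational thresholds behind
"abnormal signal" (flatline run length, clipping fraction, amplitude
bound) and the anthropometry plausibility bounds are explicit guesses,
kept configurable, because no gold standard exists for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .records import RECORD_LENGTH, ECGRecord, SchemaError, parse_record

__all__ = ["parse_record", "SchemaError", "ValidationResult",
           "SignalSanityLimits", "compute_age_years", "validate_record",
           "validate_records", "filter_cohort", "load_directory"]

STATUSES = ("valid", "duplicate", "missing_signal", "abnormal_signal",
            "invalid_dates", "invalid_anthropometry")


@dataclass(frozen=True)
class SignalSanityLimits:
    """Heuristic limits for the abnormal-signal scan (all configurable)."""

    expected_length: int = RECORD_LENGTH
    max_abs_uv: float = 10_000.0        # |amplitude| beyond this is non-physiological
    max_flat_run: int = 500             # >= 1 s of perfectly constant signal
    max_clip_fraction: float = 0.05     # fraction of samples pinned at min/max
    min_height_cm: float = 90.0
    max_height_cm: float = 210.0
    min_weight_kg: float = 10.0
    max_weight_kg: float = 130.0


DEFAULT_LIMITS = SignalSanityLimits()


@dataclass
class ValidationResult:
    record_ref: str
    status: str
    detail: str = ""


def compute_age_years(birth_date: date, collection_date: date | datetime) -> int:
    """Completed years between birth and collection (birthday arithmetic)."""
    if isinstance(collection_date, datetime):
        collection_date = collection_date.date()
    if isinstance(birth_date, datetime):
        birth_date = birth_date.date()
    if collection_date < birth_date:
        raise ValueError("collection date precedes birth date")
    years = collection_date.year - birth_date.year
    if (collection_date.month, collection_date.day) < (birth_date.month,
                                                       birth_date.day):
        years -= 1
    return years


def _longest_constant_run(x: np.ndarray) -> int:
    if x.size == 0:
        return 0
    change = np.flatnonzero(np.diff(x) != 0)
    edges = np.concatenate(([-1], change, [x.size - 1]))
    return int(np.max(np.diff(edges)))


def validate_record(record: ECGRecord, seen_ids: set,
                    limits: SignalSanityLimits = DEFAULT_LIMITS
                    ) -> ValidationResult:
    """Classify one record; mutates ``seen_ids`` with the duplicate key
    ``(subject_id, collection_date)``."""
    ref = record.source_path or record.subject_id
    key = (record.subject_id, record.collection_date)
    if key in seen_ids:
        return ValidationResult(ref, "duplicate",
                                f"repeated key {key}")
    seen_ids.add(key)

    sig = np.asarray(record.signal)
    if sig.size != limits.expected_length:
        return ValidationResult(
            ref, "missing_signal",
            f"signal has {sig.size} samples, expected {limits.expected_length}")

    if np.max(np.abs(sig)) > limits.max_abs_uv:
        return ValidationResult(ref, "abnormal_signal",
                                "amplitude outside physiological range")
    if _longest_constant_run(sig) >= limits.max_flat_run:
        return ValidationResult(ref, "abnormal_signal", "flatline segment")
    clip = np.mean((sig == sig.max()) | (sig == sig.min()))
    if sig.max() != sig.min() and clip > limits.max_clip_fraction:
        return ValidationResult(ref, "abnormal_signal", "clipping")

    try:
        age = compute_age_years(record.birth_date, record.collection_date)
    except ValueError:
        return ValidationResult(ref, "invalid_dates",
                                "collection precedes birth")
    if age > 120:
        return ValidationResult(ref, "invalid_dates", "implausible age")

    if not (limits.min_height_cm <= record.height_cm <= limits.max_height_cm
            and limits.min_weight_kg <= record.weight_kg
            <= limits.max_weight_kg):
        return ValidationResult(ref, "invalid_anthropometry",
                                f"height {record.height_cm} cm / "
                                f"weight {record.weight_kg} kg")
    return ValidationResult(ref, "valid")


def validate_records(records: list[ECGRecord],
                     limits: SignalSanityLimits = DEFAULT_LIMITS
                     ) -> list[ValidationResult]:
    seen: set = set()
    return [validate_record(r, seen, limits) for r in records]


def filter_cohort(records: list[ECGRecord], cohort_id_list,
                  age_min: int = 9, age_max: int = 11
                  ) -> tuple[list[ECGRecord], dict[str, int]]:
    """Keep records whose subject is on the cohort list and whose age at
    collection lies in the inclusive completed-years band
    [age_min, age_max].  Returns (kept, per-reason counts); every input
    record lands in exactly one count."""
    ids = set(cohort_id_list)
    if not ids:
        raise ValueError("cohort id list must be non-empty")
    kept: list[ECGRecord] = []
    counts = {"kept": 0, "not_in_cohort": 0, "age_out_of_band": 0}
    for rec in records:
        if rec.subject_id not in ids:
            counts["not_in_cohort"] += 1
            continue
        age = compute_age_years(rec.birth_date, rec.collection_date)
        if not (age_min <= age <= age_max):
            counts["age_out_of_band"] += 1
            continue
        kept.append(rec)
        counts["kept"] += 1
    return kept, counts


def load_directory(in_dir: str | Path, pattern: str = "*.xml"
                   ) -> list[ECGRecord]:
    """Parse every XML record in a directory (sorted for determinism)."""
    return [parse_record(p) for p in sorted(Path(in_dir).glob(pattern))]


def validation_report(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([{"record_ref": r.record_ref, "status": r.status,
                          "detail": r.detail} for r in results])
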
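#!/usr/bin/env python
"""Stage 2 — parse the cohort XML, scan validity and apply the
cohort/age filters.

Reads the stage-1 output directory, classifies every record
(duplicates, missing/abnormal signal, implausible dates or
anthropometry), restricts to subjects on the manifest id list aged
9-11 at collection, and writes the per-status report.
"""

import argparse
from pathlib import Path

import pandas as pd

from pedecg import ingest


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--in-dir", type=Path, default=Path("results/cohort"))
    p.add_argument("--out", type=Path, default=Path("results/ingest"))
    args = p.parse_args()

    records = ingest.load_directory(args.in_dir)
    manifest = pd.read_csv(args.in_dir / "manifest.csv")
    results = ingest.validate_records(records)
    report = ingest.validation_report(results)

    valid = [r for r, v in zip(records, results) if v.status == "valid"]
    kept, counts = ingest.filter_cohort(valid, manifest.subject_id.tolist())

    args.out.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out / "validation_report.csv", index=False)
    pd.Series({**report.status.value_counts().to_dict(), **counts}).to_csv(
        args.out / "counts.csv", header=["count"])
    print(f"parsed {len(records)} records: "
          f"{report.status.value_counts().to_dict()}")
    print(f"cohort/age filter kept {counts['kept']} "
          f"(excluded: {counts['not_in_cohort']} off-cohort, "
          f"{counts['age_out_of_band']} outside 9-11)")


if __name__ == "__main__":
    main()
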
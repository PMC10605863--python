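#!/usr/bin/env python
"""Stage 1 — simulate a paediatric ECG cohort.

Writes one XML record per subject visit (normal and obese classes, a
strong T-wave class effect by default) plus a manifest, including a
small fraction of deliberately invalid and abnormal-report records so
the downstream filters have something to do.
"""

import argparse
from pathlib import Path

from pedecg import synthcohort


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--n-per-class", type=int, default=100)
    p.add_argument("--classes", default="normal,obese")
    p.add_argument("--effect-size", type=float, default=1.0)
    p.add_argument("--invalid-fraction", type=float, default=0.1)
    p.add_argument("--abnormal-fraction", type=float, default=0.1)
    p.add_argument("--seed", type=int, default=5)
    p.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = p.parse_args()

    classes = tuple(args.classes.split(","))
    manifest = synthcohort.write_cohort(
        args.n_per_class, classes, args.out, seed=args.seed,
        effect_size=args.effect_size,
        invalid_fraction=args.invalid_fraction,
        abnormal_fraction=args.abnormal_fraction)
    n_invalid = int((manifest.invalid != "").sum())
    n_abnormal = int(manifest.abnormal_report.sum())
    print(f"wrote {len(manifest)} records to {args.out} "
          f"({', '.join(classes)}; {n_invalid} invalid, "
          f"{n_abnormal} abnormal reports)")


if __name__ == "__main__":
    main()
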
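#!/usr/bin/env python
"""Stage 6 — assemble the run report.

Collects the class-mean beat profiles, the confusion/accuracy tables
and the CAM profiles from the earlier stages and renders the CSV/JSON
tables and PNG figures.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pedecg.model import ConfusionMatrix
from pedecg.report import mean_beat_profile, render_report


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--data", type=Path, default=Path("results/beats"))
    p.add_argument("--model", type=Path, default=Path("results/model"))
    p.add_argument("--explain", type=Path, default=Path("results/explain"))
    p.add_argument("--out", type=Path, default=Path("results/report"))
    args = p.parse_args()

    data = np.load(args.data / "beats.npz", allow_pickle=False)
    beats_by_class = {name: data["X"][data["y"] == i]
                      for i, name in enumerate(("normal", "obese"))}
    profiles = mean_beat_profile(beats_by_class)

    metrics_in = json.loads((args.model / "metrics.json").read_text())
    metrics = {"accuracy": metrics_in["accuracy"],
               "confusion_validation": ConfusionMatrix(
                   metrics_in["confusion"]["val"])}

    cam_df = pd.read_csv(args.explain / "cam_profiles.csv")
    cams = {k: cam_df[k].to_numpy() for k in ("normal", "obese", "overlap")}

    files = render_report(metrics, profiles, cams, args.out)
    print(f"report written to {args.out}:")
    for f in files:
        print(f"  {f}")


if __name__ == "__main__":
    main()
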
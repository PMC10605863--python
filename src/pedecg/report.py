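"""Figures and tables for a pipeline run: class-mean beats with
standard-deviation error bands, CAM histograms per class, the overlap
profile, a composite figure overlaying both, and the confusion-matrix /
accuracy tables.

Every figure is regenerated from the persisted CSV tables, so tests
compare numbers, never pixels.  All statistics are computed on the
unbinned 300-sample vectors; the CAM histograms bin the axis (default
30 bins) for display only.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import ConfusionMatrix, confusion_accuracy

REPORT_FILES = (
    "tables/accuracy.csv",
    "tables/confusion_validation.csv",
    "tables/cam_profiles.csv",
    "tables/mean_beats.csv",
    "metrics.json",
    "figures/mean_beats.png",
    "figures/cam_normal.png",
    "figures/cam_obese.png",
    "figures/cam_overlap.png",
    "figures/composite.png",
)


def mean_beat_profile(beats_by_class: dict[str, np.ndarray]
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and standard deviation per class over the
    300-sample beat axis; needs at least two beats per class for the
    SD band to be defined."""
    out = {}
    for label, beats in beats_by_class.items():
        arr = np.asarray(beats, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("beats must be an (n_beats, length) array")
        if arr.shape[0] < 2:
            raise ValueError(
                f"class {label!r} has fewer than 2 beats; SD undefined")
        out[label] = (arr.mean(axis=0), arr.std(axis=0, ddof=1))
    return out


def _cam_histogram(ax, cam: np.ndarray, n_bins: int, color: str,
                   label: str):
    edges = np.linspace(0, cam.size, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    binned = [cam[int(a):int(b)].mean() for a, b in zip(edges[:-1],
                                                        edges[1:])]
    ax.bar(centers, binned, width=np.diff(edges), color=color, alpha=0.6,
           label=label, edgecolor="none")
    ax.set_xlabel("beat sample (R peak at 100)")
    ax.set_ylabel("mean relevance")


def render_report(metrics: dict, profiles: dict, cams: dict,
                  out_dir: str | Path, n_bins: int = 30) -> list[str]:
    """Write the full deterministic report file set.

    Parameters
    ----------
    metrics : dict with keys ``accuracy`` (mapping split -> fraction)
        and ``confusion_validation`` (a :class:`ConfusionMatrix`).
    profiles : mapping class label -> (mean, sd) beat profile.
    cams : dict with keys ``normal``, ``obese``, ``overlap`` holding
        300-length vectors.
    """
    for key, obj in (("accuracy", metrics.get("accuracy")),
                     ("confusion_validation",
                      metrics.get("confusion_validation")),
                     ("profiles", profiles), ("cams", cams)):
        if obj is None or (hasattr(obj, "__len__") and len(obj) == 0):
            raise ValueError(f"missing report input: {key}")

    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(parents=True, exist_ok=True)

    # accuracy table (train/val/test, percent like the printed table)
    acc = metrics["accuracy"]
    acc_df = pd.DataFrame(
        {split: [f"{round(100 * value)}%"] for split, value in acc.items()},
        index=["model_accuracy"])
    acc_df.to_csv(out / "tables/accuracy.csv")

    cm: ConfusionMatrix = metrics["confusion_validation"]
    cm_df = cm.to_frame()
    _, percent = confusion_accuracy(cm)
    cm_df["accuracy"] = [f"{percent}%", ""]
    cm_df.to_csv(out / "tables/confusion_validation.csv")

    cam_df = pd.DataFrame({"sample": np.arange(len(cams["overlap"])),
                           "normal": cams["normal"],
                           "obese": cams["obese"],
                           "overlap": cams["overlap"]})
    cam_df.to_csv(out / "tables/cam_profiles.csv", index=False)

    rows = {}
    for label, (mean, sd) in profiles.items():
        rows[f"{label}_mean"] = mean
        rows[f"{label}_sd"] = sd
    pd.DataFrame(rows).to_csv(out / "tables/mean_beats.csv", index=False)

    with open(out / "metrics.json", "w") as fh:
        json.dump({"accuracy": {k: float(v) for k, v in acc.items()},
                   "confusion_validation": cm.counts.tolist(),
                   "validation_accuracy_percent": percent},
                  fh, indent=2, sort_keys=True)

    # figures -- regenerated from the tables just written
    colors = {"normal": "tab:orange", "obese": "tab:blue"}
    fig, ax = plt.subplots(figsize=(7, 4))
    x_axis = np.arange(next(iter(profiles.values()))[0].size)
    for label, (mean, sd) in profiles.items():
        ax.plot(x_axis, mean, label=f"{label} mean",
                color=colors.get(label), ls="--" if label == "normal" else "-")
        ax.fill_between(x_axis, mean - sd, mean + sd,
                        color=colors.get(label), alpha=0.2)
    ax.set_xlabel("beat sample (R peak at 100)")
    ax.set_ylabel("amplitude (mV)")
    ax.legend()
    fig.savefig(out / "figures/mean_beats.png", dpi=110)
    plt.close(fig)

    for label in ("normal", "obese", "overlap"):
        fig, ax = plt.subplots(figsize=(7, 3))
        _cam_histogram(ax, np.asarray(cams[label]), n_bins,
                       colors.get(label, "tab:green"), label)
        ax.legend()
        fig.savefig(out / f"figures/cam_{label}.png", dpi=110)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for label, (mean, sd) in profiles.items():
        ax.plot(x_axis, mean, color=colors.get(label), label=f"{label} mean")
        ax.fill_between(x_axis, mean - sd, mean + sd,
                        color=colors.get(label), alpha=0.15)
    ax2 = ax.twinx()
    _cam_histogram(ax2, np.asarray(cams["overlap"]), n_bins, "tab:green",
                   "overlap relevance")
    ax2.set_ylabel("relevance")
    ax.set_ylabel("amplitude (mV)")
    ax.legend(loc="upper right")
    fig.savefig(out / "figures/composite.png", dpi=110)
    plt.close(fig)

    return [str(p) for p in REPORT_FILES]
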
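#!/usr/bin/env python
"""Stage 4 — train the canonical 1D CNN beat classifier.

Builds the four-block architecture, trains with Adam / categorical
cross-entropy / early stopping on validation accuracy, and writes the
training history, the per-split confusion matrices and accuracies, and
the model weights.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pedecg.model import (TrainConfig, build_model, canonical_spec,
                          evaluate, train)


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--data", type=Path, default=Path("results/beats"))
    p.add_argument("--out", type=Path, default=Path("results/model"))
    p.add_argument("--max-epochs", type=int, default=30)
    p.add_argument("--patience", type=int, default=12)
    p.add_argument("--seed", type=int, default=0)
    args = p.parse_args()

    data = np.load(args.data / "beats.npz", allow_pickle=False)
    splits = {name: (data["X"][data["splits"] == name],
                     data["y"][data["splits"] == name])
              for name in ("train", "val", "test")}

    cfg = TrainConfig(max_epochs=args.max_epochs,
                      early_stop_patience=args.patience, seed=args.seed)
    net = build_model(canonical_spec(), cfg)
    fitted = train(net, splits["train"], splits["val"], cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    fitted.history.to_csv(args.out / "history.csv", index=False)
    np.savez(args.out / "weights.npz", *fitted.net.get_state())

    metrics = {"config": {"learning_rate": cfg.learning_rate,
                          "batch_size": cfg.batch_size,
                          "max_epochs": cfg.max_epochs,
                          "patience": cfg.early_stop_patience,
                          "seed": cfg.seed},
               "best_epoch": fitted.best_epoch, "accuracy": {},
               "confusion": {}}
    for name, split in splits.items():
        cm, acc = evaluate(fitted, split)
        metrics["accuracy"][name] = acc
        metrics["confusion"][name] = cm.counts.tolist()
        print(f"{name:>5}: accuracy {acc:.3f} on {cm.total} beats")
    (args.out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    print(f"best epoch {fitted.best_epoch}; artefacts in {args.out}")


if __name__ == "__main__":
    main()
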
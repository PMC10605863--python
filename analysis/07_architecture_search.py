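#!/usr/bin/env python
"""Stage 7 (optional) — desk-scale architecture search.

Runs the random or genetic search harness over a reduced
hyperparameter space on the stage-3 beats.  The full-scale reference
budget (400 trials / 200 epochs / 20x20 genetic) is available as the
``paper`` preset but takes hours; the default desk preset finishes in
minutes.
"""

import argparse
from pathlib import Path

import numpy as np

from pedecg.nas import (DESK_BUDGET, PAPER_BUDGET, SearchSpace,
                        genetic_search, random_search)


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--data", type=Path, default=Path("results/beats"))
    p.add_argument("--strategy", default="random",
                   choices=["random", "genetic"])
    p.add_argument("--budget-preset", default="desk",
                   choices=["desk", "paper"])
    p.add_argument("--out", type=Path, default=Path("results/nas"))
    args = p.parse_args()

    data = np.load(args.data / "beats.npz", allow_pickle=False)
    splits = {name: (data["X"][data["splits"] == name],
                     data["y"][data["splits"] == name])
              for name in ("train", "val")}
    space = SearchSpace(n_blocks=(1, 2, 3), filters=(4, 8, 16, 32),
                        dense_units=(16, 32), batch_sizes=(100, 200))
    budget = DESK_BUDGET if args.budget_preset == "desk" else PAPER_BUDGET

    search = random_search if args.strategy == "random" else genetic_search
    (spec, config, fitness), log = search(
        space, budget, (splits["train"], splits["val"]))

    args.out.mkdir(parents=True, exist_ok=True)
    log.to_csv(args.out / f"{args.strategy}_trials.csv", index=False)
    print(f"{args.strategy} search ({args.budget_preset} budget): "
          f"best validation accuracy {fitness:.3f}")
    print(f"best architecture: "
          f"{[(b.filters, b.activation, b.dropout_rate) for b in spec.blocks]}"
          f", dense {spec.dense_units}, lr {config.learning_rate}, "
          f"batch {config.batch_size}")


if __name__ == "__main__":
    main()
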
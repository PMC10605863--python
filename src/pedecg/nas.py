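"""A desk-scale neural-architecture-search harness.

Searches the structural/training hyperparameter space of the beat
classifier with either pure random sampling or a small genetic
algorithm (tournament selection, blockwise crossover, per-field
mutation, elitism), maximising validation accuracy.  Two budget
presets exist: ``desk`` (10 trials × 10 epochs — what the test-suite
and drivers use) and ``paper`` (200 epochs, 400 trials, 20 generations
of population 20 — the full-scale reference budget, long-running and
provided for completeness only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (ConvBlockSpec, ModelSpec, TrainConfig, build_model,
                    train)


@dataclass(frozen=True)
class SearchSpace:
    n_blocks: tuple[int, ...] = (2, 3, 4)
    filters: tuple[int, ...] = (8, 16, 32, 64, 128)
    kernel_sizes: tuple[int, ...] = (3,)
    strides: tuple[int, ...] = (1,)
    activations: tuple[str, ...] = ("relu", "sigmoid")
    dropout_range: tuple[float, float] = (0.0, 0.5)
    batch_norm: tuple[bool, ...] = (False, True)
    dense_units: tuple[int, ...] = (16, 32, 64)
    learning_rates: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    batch_sizes: tuple[int, ...] = (50, 100, 200)

    def contains(self, spec: ModelSpec, config: TrainConfig) -> bool:
        lo, hi = self.dropout_range
        return (len(spec.blocks) in self.n_blocks
                and spec.dense_units in self.dense_units
                and config.learning_rate in self.learning_rates
                and config.batch_size in self.batch_sizes
                and all(b.filters in self.filters
                        and b.kernel_size in self.kernel_sizes
                        and b.stride in self.strides
                        and b.activation in self.activations
                        and b.batch_norm in self.batch_norm
                        and lo <= b.dropout_rate <= hi
                        for b in spec.blocks))


@dataclass(frozen=True)
class SearchBudget:
    max_trials: int = 10
    epochs_per_trial: int = 10
    generations: int = 5
    population_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if min(self.max_trials, self.epochs_per_trial, self.generations,
               self.population_size) < 1:
            raise ValueError("budget fields must be >= 1")


DESK_BUDGET = SearchBudget()
# Full-scale reference search settings; hours of CPU, not used by tests.
PAPER_BUDGET = SearchBudget(max_trials=400, epochs_per_trial=200,
                            generations=20, population_size=20)


def sample_spec(space: SearchSpace, rng: np.random.Generator
                ) -> tuple[ModelSpec, TrainConfig]:
    """Draw one (architecture, training config) pair from the space."""
    def choice(options):
        return options[int(rng.integers(len(options)))]

    blocks = tuple(
        ConvBlockSpec(filters=choice(space.filters),
                      kernel_size=choice(space.kernel_sizes),
                      stride=choice(space.strides),
                      activation=choice(space.activations),
                      batch_norm=choice(space.batch_norm),
                      dropout_rate=float(np.round(
                          rng.uniform(*space.dropout_range), 3)))
        for _ in range(choice(space.n_blocks)))
    spec = ModelSpec(blocks=blocks, dense_units=choice(space.dense_units))
    config = TrainConfig(learning_rate=choice(space.learning_rates),
                         batch_size=choice(space.batch_sizes),
                         seed=int(rng.integers(2 ** 31)))
    return spec, config


def _spec_to_row(spec: ModelSpec, config: TrainConfig) -> dict:
    return {
        "blocks": "|".join(
            f"{b.filters}:{b.activation}:{'bn' if b.batch_norm else '-'}"
            f":{b.dropout_rate}" for b in spec.blocks),
        "dense_units": spec.dense_units,
        "learning_rate": config.learning_rate,
        "batch_size": config.batch_size,
    }


def _evaluate(spec: ModelSpec, config: TrainConfig, data_splits,
              epochs: int) -> float:
    """Fitness: validation accuracy at the early-stopped epoch."""
    train_split, val_split = data_splits
    cfg = replace(config, max_epochs=epochs,
                  early_stop_patience=max(2, epochs // 3),
                  batch_size=min(config.batch_size, len(train_split[1])))
    net = build_model(spec, cfg)
    fitted = train(net, train_split, val_split, cfg)
    return float(fitted.history["val_accuracy"].max())


def random_search(space: SearchSpace, budget: SearchBudget, data_splits,
                  evaluate=_evaluate):
    """Best-of-N random sampling; failed trials are logged and skipped."""
    rng = np.random.default_rng(budget.seed)
    log: list[dict] = []
    best = None
    for trial in range(budget.max_trials):
        spec, config = sample_spec(space, rng)
        row = {"trial": trial, **_spec_to_row(spec, config)}
        try:
            fitness = evaluate(spec, config, data_splits,
                               budget.epochs_per_trial)
            row.update(val_accuracy=fitness, status="ok")
            if best is None or fitness > best[2]:
                best = (spec, config, fitness)
        except Exception as exc:  # noqa: BLE001 - trial isolation
            row.update(val_accuracy=np.nan, status=f"failed: {exc}")
        log.append(row)
    if best is None:
        raise RuntimeError("every trial failed")
    return best, pd.DataFrame(log)


def _crossover(a, b, rng) -> tuple[ModelSpec, TrainConfig]:
    """Blockwise crossover: each conv block and each scalar gene comes
    from one parent."""
    spec_a, cfg_a = a
    spec_b, cfg_b = b
    n = len(spec_a.blocks) if rng.random() < 0.5 else len(spec_b.blocks)
    blocks = []
    for i in range(n):
        pool = [s.blocks[i] for s in (spec_a, spec_b) if i < len(s.blocks)]
        blocks.append(pool[int(rng.integers(len(pool)))])
    spec = ModelSpec(blocks=tuple(blocks),
                     dense_units=(spec_a if rng.random() < 0.5
                                  else spec_b).dense_units)
    config = TrainConfig(
        learning_rate=(cfg_a if rng.random() < 0.5 else cfg_b).learning_rate,
        batch_size=(cfg_a if rng.random() < 0.5 else cfg_b).batch_size,
        seed=int(rng.integers(2 ** 31)))
    return spec, config


def _mutate(individual, space: SearchSpace, rng, rate: float
            ) -> tuple[ModelSpec, TrainConfig]:
    """Resample each gene independently with probability ``rate``."""
    spec, config = individual
    fresh_spec, fresh_cfg = sample_spec(space, rng)
    hits = [bool(rng.random() < rate)
            for _ in range(len(spec.blocks) + 3)]
    blocks = tuple(
        fb if hit else b
        for hit, b, fb in zip(hits, spec.blocks,
                              (fresh_spec.blocks * 4)[:len(spec.blocks)]))
    spec = ModelSpec(
        blocks=blocks,
        dense_units=(fresh_spec.dense_units if hits[-3]
                     else spec.dense_units))
    config = TrainConfig(
        learning_rate=(fresh_cfg.learning_rate if hits[-2]
                       else config.learning_rate),
        batch_size=(fresh_cfg.batch_size if hits[-1]
                    else config.batch_size),
        seed=int(rng.integers(2 ** 31)) if any(hits) else config.seed)
    return spec, config


def genetic_search(space: SearchSpace, budget: SearchBudget, data_splits,
                   mutation_rate: float = 0.2,
                   crossover_probability: float = 0.9,
                   evaluate=_evaluate):
    """Elitist genetic search; per-generation best is non-decreasing."""
    if budget.population_size < 2:
        raise ValueError("population must be >= 2")
    rng = np.random.default_rng(budget.seed)
    population = [sample_spec(space, rng)
                  for _ in range(budget.population_size)]

    def fitness_of(ind):
        try:
            return evaluate(ind[0], ind[1], data_splits,
                            budget.epochs_per_trial)
        except Exception:  # noqa: BLE001
            return -np.inf

    log: list[dict] = []
    scores = [fitness_of(ind) for ind in population]
    for gen in range(budget.generations):
        order = np.argsort(scores)[::-1]
        elite = population[order[0]]
        elite_score = scores[order[0]]
        for rank in order:
            log.append({"generation": gen, "val_accuracy": scores[rank],
                        **_spec_to_row(*population[rank])})

        def tournament():
            i, j = rng.integers(len(population), size=2)
            return population[i if scores[i] >= scores[j] else j]

        children = [elite]
        while len(children) < budget.population_size:
            if rng.random() < crossover_probability:
                child = _crossover(tournament(), tournament(), rng)
            else:
                child = tournament()
            children.append(_mutate(child, space, rng, mutation_rate))
        population = children
        scores = [elite_score] + [fitness_of(ind)
                                  for ind in population[1:]]

    order = np.argsort(scores)[::-1]
    best = population[order[0]]
    return (best[0], best[1], scores[order[0]]), pd.DataFrame(log)
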
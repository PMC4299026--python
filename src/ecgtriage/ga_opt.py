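"""Genetic optimization of the ternary projection matrix.

Random projection matrices are not equally informative in practice, so the
projection and the classifier are optimized jointly: each candidate matrix
is scored by training a neuro-fuzzy classifier on its projected balanced
training split (train_set_1), tuning the defuzzification coefficient on a
larger split (train_set_2) to meet the ARR floor, and reading off the NDR
there.  Tournament selection, row-wise uniform crossover and per-entry
resampling mutation evolve the population under elitism, so the best
fitness never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ecgtriage import nfc
from ecgtriage.dimreduce import AchlioptasMatrix, project_rp, sample_achlioptas

_TERNARY = np.array([-1, 0, 1], dtype=np.int8)
_TERNARY_P = [1 / 6, 2 / 3, 1 / 6]


@dataclass(frozen=True)
class GaConfig:
    """Hyperparameters of the joint projection/classifier optimization."""

    population_size: int = 20
    generations: int = 30
    arr_min: float = 0.95
    mutation_rate: float = 0.02
    crossover_rate: float = 0.9
    elitism: int = 2
    tournament_size: int = 3
    nfc_epochs: int = 200
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be < population_size")


#: desk-scale configuration used by the default tests and examples
DESK_GA = GaConfig(population_size=10, generations=10)


@dataclass
class GaResult:
    best_matrix: AchlioptasMatrix
    best_model: nfc.NfcModel
    best_alpha: float
    #: per-generation best fitness: the NDR for feasible candidates
    #: (penalized by -1 when the ARR floor was unreachable)
    fitness_history: list
    final_ndr: float
    final_arr: float
    arr_feasible: bool
    generation_log: list = field(default_factory=list)  # (gen, best, mean)


def fitness(P: AchlioptasMatrix, train1_windows, train1_labels,
            train2_windows, train2_labels, arr_min: float = 0.95,
            nfc_epochs: int = 200, learning_rate: float = 0.05):
    """Score one candidate matrix.

    Returns (score, ndr, arr, model, alpha, feasible).  The score equals
    the NDR on train_set_2 at the tuned alpha for feasible candidates; a
    candidate whose alpha tuning cannot reach arr_min is penalized below
    every feasible one (score = ndr - 1 at alpha = 1).
    """
    for lbls, name in ((train1_labels, "train1"), (train2_labels, "train2")):
        present = set(np.asarray(lbls).tolist())
        if not {"N", "V", "L"} <= present:
            raise ValueError(f"{name} must contain all three classes, has {present}")
    u1 = project_rp(P, np.asarray(train1_windows))
    u2 = project_rp(P, np.asarray(train2_windows))
    model = nfc.init_model(u1, train1_labels, reducer_id=f"rp{P.k}")
    model = nfc.train_model(model, u1, train1_labels,
                            epochs=nfc_epochs, learning_rate=learning_rate)
    alpha, feasible = nfc.tune_alpha(model, u2, train2_labels, arr_min=arr_min)
    model.alpha_train = alpha

    from ecgtriage.evaluate import compute_ndr_arr

    report = compute_ndr_arr(nfc.classify_batch(model, u2, alpha), train2_labels)
    score = report.ndr if feasible else report.ndr - 1.0
    return score, report.ndr, report.arr, model, alpha, feasible


def crossover(parent_a: AchlioptasMatrix, parent_b: AchlioptasMatrix,
              seed: int) -> AchlioptasMatrix:
    """Row-wise uniform mix: each child row comes from one parent (fair coin)."""
    if parent_a.entries.shape != parent_b.entries.shape:
        raise ValueError("parents must have identical shapes")
    rng = np.random.default_rng(seed)
    take_a = rng.random(parent_a.k) < 0.5
    child = np.where(take_a[:, None], parent_a.entries, parent_b.entries)
    return AchlioptasMatrix(child)


def mutate(P: AchlioptasMatrix, rate: float, seed: int) -> AchlioptasMatrix:
    """Resample each entry from the ternary law independently with prob. rate."""
    rng = np.random.default_rng(seed)
    mask = rng.random(P.entries.shape) < rate
    fresh = rng.choice(_TERNARY, size=P.entries.shape, p=_TERNARY_P)
    return AchlioptasMatrix(np.where(mask, fresh, P.entries))


def evolve(cfg: GaConfig, train1_windows, train1_labels,
           train2_windows, train2_labels, k: int, d: int) -> GaResult:
    """Run the genetic optimization; fully reproducible given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)

    def spawn() -> int:
        return int(rng.integers(0, 2**31))

    population = [sample_achlioptas(k, d, spawn()) for _ in range(cfg.population_size)]

    def evaluate_pop(pop):
        return [fitness(P, train1_windows, train1_labels,
                        train2_windows, train2_labels, cfg.arr_min,
                        cfg.nfc_epochs, cfg.learning_rate) for P in pop]

    scores = evaluate_pop(population)
    best_idx = int(np.argmax([s[0] for s in scores]))
    best = (population[best_idx], scores[best_idx])
    history = [best[1][0]]
    gen_log = [(0, best[1][1], float(np.mean([s[1] for s in scores])))]

    for gen in range(1, cfg.generations + 1):
        order = np.argsort([-s[0] for s in scores])
        elites = [population[i] for i in order[:cfg.elitism]]
        children = list(elites)
        while len(children) < cfg.population_size:
            idx_a = min(rng.integers(0, cfg.population_size, cfg.tournament_size),
                        key=lambda i: -scores[i][0])
            idx_b = min(rng.integers(0, cfg.population_size, cfg.tournament_size),
                        key=lambda i: -scores[i][0])
            child = crossover(population[idx_a], population[idx_b], spawn()) \
                if rng.random() < cfg.crossover_rate else population[idx_a]
            children.append(mutate(child, cfg.mutation_rate, spawn()))
        population = children
        scores = evaluate_pop(population)
        gen_best = int(np.argmax([s[0] for s in scores]))
        if scores[gen_best][0] > best[1][0]:
            best = (population[gen_best], scores[gen_best])
        history.append(best[1][0])
        gen_log.append((gen, best[1][1], float(np.mean([s[1] for s in scores]))))

    P_best, (_, ndr, arr, model, alpha, feasible) = best
    return GaResult(P_best, model, alpha, history, ndr, arr, feasible, gen_log)
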
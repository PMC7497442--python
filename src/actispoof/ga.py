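"""Real-coded genetic algorithm for generating impersonator examples.

An impersonator example for target user ``t`` is the maximizer

    x* = argmax_{x in [0,1]^d} f(x, t)

where ``f`` is the identification model's confidence score, observable
only through black-box queries.  The GA maintains a population of
candidate profiles in [0,1]^d, uses the queried confidences as fitness,
and applies linear-rank selection, per-gene convex blend crossover and
single-gene uniform-reset mutation, with elitism so the best fitness
never decreases.  Search stops at a generation cap or after ``patience``
consecutive generations without strict improvement.

All operators keep genomes inside [0,1]^d by construction, and the
attacker's query budget is exactly ``population_size * generations_run``
(elites are re-evaluated each generation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata as sps_rankdata

__all__ = [
    "AttackResult",
    "GAConfig",
    "PRESETS",
    "attack_all_users",
    "blend_crossover",
    "evaluate",
    "init_population",
    "preset_config",
    "rank_selection_probabilities",
    "run_attack",
    "select",
    "step_generation",
    "uniform_reset_mutation",
]


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; defaults follow the attack's standard setup."""

    population_size: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_fraction: float = 0.05
    max_generations: int = 1500
    patience: int = 100
    dimension: int = 24
    seed: int = 0
    per_gene_mutation: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob", "elitism_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.patience > self.max_generations:
            raise ValueError("patience must not exceed max_generations")
        if self.dimension < 1 or self.max_generations < 1 or self.patience < 1:
            raise ValueError("dimension, max_generations and patience must be >= 1")

    @property
    def n_elites(self) -> int:
        """max(1, elitism_fraction * n) with half-up rounding."""
        return max(1, math.floor(self.elitism_fraction * self.population_size + 0.5))


#: Attack strengths: population size (and, for the escalated retry used in
#: failure analysis, a raised generation cap).
PRESETS: dict[str, dict] = {
    "weak": {"population_size": 10, "max_generations": 1500},
    "medium": {"population_size": 20, "max_generations": 1500},
    "strong": {"population_size": 50, "max_generations": 1500},
    "escalated": {"population_size": 100, "max_generations": 2000},
}


def preset_config(name: str, seed: int = 0, **overrides) -> GAConfig:
    """Build a GAConfig for a named attack strength."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return GAConfig(seed=seed, **{**PRESETS[name], **overrides})


@dataclass
class AttackResult:
    """Outcome of one attack run against one target user."""

    target_user: str
    best_genome: np.ndarray
    best_fitness: float
    generations_run: int
    query_count: int
    fitness_trace: np.ndarray  # all-time best after each generation

    def __post_init__(self) -> None:
        self.fitness_trace = np.asarray(self.fitness_trace, dtype=float)
        if np.any(np.diff(self.fitness_trace) < 0):
            raise ValueError("fitness trace must be non-decreasing")


def init_population(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """n random genomes, genes i.i.d. uniform on [0, 1]."""
    if n < 2:
        raise ValueError("population must have at least 2 individuals")
    return rng.random((n, d))


def evaluate(population: np.ndarray, oracle, t: str) -> np.ndarray:
    """Fitness = oracle confidence of each genome for target t (one batch)."""
    return np.atleast_1d(oracle.query(population, t))


def rank_selection_probabilities(fitness: np.ndarray) -> np.ndarray:
    """Linear-rank selection weights: p_i = 2 r_i / (n (n+1)).

    r_i is the 1-based fitness rank (1 = worst, n = best), with tied
    fitnesses sharing their average rank — so an all-equal population is
    selected uniformly, and for n = 2 distinct fitnesses the better
    individual is picked 2/3 of the time.
    """
    ranks = sps_rankdata(fitness, method="average")
    n = len(ranks)
    return 2.0 * ranks / (n * (n + 1))


def select(fitness: np.ndarray, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Draw parent indices with linear-rank probabilities."""
    probs = rank_selection_probabilities(np.asarray(fitness, dtype=float))
    return rng.choice(len(probs), size=size if size is not None else len(probs), p=probs)


def blend_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    crossover_prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene convex blend: child = alpha*a + (1-alpha)*b, alpha ~ U(0,1).

    With probability 1 - crossover_prob the parents are copied unchanged.
    Children always stay inside the per-gene interval spanned by the
    parents, hence inside [0,1]^d.
    """
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must have equal dimension")
    if rng.random() >= crossover_prob:
        return parent_a.copy(), parent_b.copy()
    alpha = rng.random(parent_a.shape)
    child_a = alpha * parent_a + (1.0 - alpha) * parent_b
    child_b = (1.0 - alpha) * parent_a + alpha * parent_b
    return child_a, child_b


def uniform_reset_mutation(
    genome: np.ndarray,
    mutation_prob: float,
    rng: np.random.Generator,
    per_gene: bool = False,
) -> np.ndarray:
    """Resample one uniformly chosen gene with probability ``mutation_prob``.

    In ``per_gene`` mode each gene is independently resampled with that
    probability instead (the alternative rate semantics).
    """
    genome = genome.copy()
    if per_gene:
        mask = rng.random(genome.shape) < mutation_prob
        genome[mask] = rng.random(int(mask.sum()))
        return genome
    if rng.random() < mutation_prob:
        gene = int(rng.integers(len(genome)))
        genome[gene] = rng.random()
    return genome


def _breed(
    population: np.ndarray,
    fitness: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce the next (unevaluated) population: elites + offspring."""
    n = config.population_size
    e = config.n_elites
    elite_idx = np.argsort(-fitness, kind="stable")[:e]
    children: list[np.ndarray] = [population[i].copy() for i in elite_idx]
    while len(children) < n:
        pa, pb = select(fitness, rng, size=2)
        ca, cb = blend_crossover(
            population[pa], population[pb], config.crossover_prob, rng
        )
        for child in (ca, cb):
            if len(children) < n:
                children.append(
                    uniform_reset_mutation(
                        child, config.mutation_prob, rng, config.per_gene_mutation
                    )
                )
    return np.stack(children)


def step_generation(
    population: np.ndarray,
    fitness: np.ndarray,
    oracle,
    t: str,
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One generation: elitism + select/crossover/mutate, then re-evaluate.

    Elites are carried over unchanged (and re-evaluated with the rest, so
    query accounting stays population_size per generation).
    """
    new_pop = _breed(population, fitness, config, rng)
    return new_pop, evaluate(new_pop, oracle, t)


class _AttackState:
    """Bookkeeping for one in-flight attack run (used for lockstep batching)."""

    def __init__(self, oracle, t: str, config: GAConfig):
        self.oracle = oracle
        self.t = str(t)
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.population = init_population(
            config.population_size, config.dimension, self.rng
        )
        # Confidence scores are bounded below by 0, so 0 is the neutral
        # starting "best": a run that never exceeds it (e.g. a flat binary
        # oracle) exhausts its patience budget and stops.
        self.best_fitness = 0.0
        self.best_genome: np.ndarray | None = None
        self.stall = 0
        self.generations = 0
        self.trace: list[float] = []
        self.done = False

    def absorb(self, fitness: np.ndarray) -> None:
        """Account one evaluated generation."""
        self.generations += 1
        i = int(np.argmax(fitness))
        if fitness[i] > self.best_fitness or self.best_genome is None:
            if fitness[i] > self.best_fitness:
                self.stall = 0
            else:
                self.stall += 1
            self.best_fitness = float(max(self.best_fitness, fitness[i]))
            self.best_genome = self.population[i].copy()
        else:
            self.stall += 1
        self.trace.append(self.best_fitness)
        if self.stall >= self.config.patience or self.generations >= self.config.max_generations:
            self.done = True

    def next_population(self, fitness: np.ndarray) -> np.ndarray:
        self.population = _breed(self.population, fitness, self.config, self.rng)
        return self.population

    def result(self) -> AttackResult:
        assert self.best_genome is not None
        return AttackResult(
            target_user=self.t,
            best_genome=self.best_genome,
            best_fitness=self.best_fitness,
            generations_run=self.generations,
            query_count=self.config.population_size * self.generations,
            fitness_trace=np.array(self.trace),
        )


def run_attack(oracle, t: str, config: GAConfig) -> AttackResult:
    """Generate an impersonator example for target user ``t``.

    Loops generations until ``max_generations`` is reached or the
    all-time best fitness has not strictly improved for ``patience``
    consecutive generations; returns the all-time best genome as x*.
    """
    state = _AttackState(oracle, t, config)
    fitness = evaluate(state.population, oracle, state.t)
    state.absorb(fitness)
    while not state.done:
        state.next_population(fitness)
        fitness = evaluate(state.population, oracle, state.t)
        state.absorb(fitness)
    return state.result()


def derive_user_seeds(master_seed: int, n: int) -> list[int]:
    """Per-target child seeds fanned out from one master seed."""
    return [int(s) % 2**31 for s in np.random.SeedSequence(master_seed).generate_state(n)]


def attack_all_users(
    oracle,
    users: Sequence[str],
    config: GAConfig,
) -> list[AttackResult]:
    """Run one independent attack per target user.

    Each target gets its own child seed derived from ``config.seed``.  The
    runs are stepped in lockstep and their populations stacked into a
    single oracle batch per generation — each run draws from its own
    random stream, so results are identical to sequential
    :func:`run_attack` calls while sharing per-query model overhead.
    """
    seeds = derive_user_seeds(config.seed, len(users))
    states = [
        _AttackState(oracle, u, replace(config, seed=s))
        for u, s in zip(users, seeds)
    ]
    fitnesses: dict[int, np.ndarray] = {}
    while True:
        active = [i for i, s in enumerate(states) if not s.done]
        if not active:
            break
        for i in active:
            if i in fitnesses:  # breed from the previous generation
                states[i].next_population(fitnesses[i])
        stacked = np.vstack([states[i].population for i in active])
        targets = np.concatenate(
            [np.repeat(states[i].t, len(states[i].population)) for i in active]
        )
        batch = np.atleast_1d(oracle.query(stacked, targets))
        offset = 0
        for i in active:
            n = len(states[i].population)
            fitnesses[i] = batch[offset : offset + n]
            offset += n
            states[i].absorb(fitnesses[i])
    return [s.result() for s in states]
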
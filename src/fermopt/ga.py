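"""Binary-chromosome genetic algorithm maximizing the surrogate's prediction.

Each candidate fermentation condition is a 36-bit chromosome: six bits per
factor, plain binary, most-significant bit first.  A field value b in 0..63
decodes linearly onto the factor's axial range, ``low + (high-low) * b / 63``,
so the search lattice always stays inside the experimental box.

The generational loop is: fitness-proportional (roulette) selection on
min-shifted fitness, single-point crossover with probability ``crossover_prob``
per mating pair, independent per-bit flip mutation with probability
``mutation_prob``, and elitism (the best individuals carried over unchanged,
which makes the best-ever fitness trace non-decreasing).  Everything is driven
by one seeded generator, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import DesignError, FactorSpec
from .ffnn import SurrogateModel

__all__ = [
    "GAConfig",
    "OptimizationResult",
    "decode_chromosome",
    "evaluate_fitness",
    "evolve",
]


@dataclass(frozen=True)
class GAConfig:
    chromosome_length: int = 36
    population_size: int = 36
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01  # per bit
    max_generations: int = 500
    bits_per_factor: int = 6
    elitism: int = 1
    top_k: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_length < 1 or self.population_size < 2:
            raise ValueError("need chromosome_length >= 1 and population_size >= 2")
        if not (0.0 <= self.crossover_prob <= 1.0 and 0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.max_generations < 1 or self.bits_per_factor < 1:
            raise ValueError("max_generations and bits_per_factor must be >= 1")
        if self.elitism < 0 or self.elitism > self.population_size:
            raise ValueError("elitism must be in [0, population_size]")


@dataclass
class OptimizationResult:
    best_chromosome: np.ndarray
    best_conditions_natural: np.ndarray
    best_predicted_activity: float
    best_trace: np.ndarray  # best-ever fitness per generation
    mean_trace: np.ndarray  # population mean fitness per generation
    top_conditions: list[tuple[np.ndarray, float]]  # distinct decoded shortlist
    n_evaluations: int

    def to_dict(self, factor_names: Sequence[str] | None = None) -> dict:
        def cond(c: np.ndarray) -> dict | list:
            if factor_names is None:
                return c.tolist()
            return dict(zip(factor_names, c.tolist()))

        return {
            "best_chromosome": self.best_chromosome.tolist(),
            "best_conditions": cond(self.best_conditions_natural),
            "best_predicted_activity": self.best_predicted_activity,
            "top_conditions": [
                {"conditions": cond(c), "predicted_activity": f} for c, f in self.top_conditions
            ],
            "n_evaluations": self.n_evaluations,
            "best_trace": self.best_trace.tolist(),
            "mean_trace": self.mean_trace.tolist(),
        }


def decode_chromosome(
    bits, factors: Sequence[FactorSpec], bits_per_factor: int = 6
) -> np.ndarray:
    """Decode bit-string(s) into natural-unit factor settings.

    Accepts a single chromosome (length L) or a population (m, L); each
    ``bits_per_factor``-bit field, MSB first, maps linearly onto its factor's
    [low, high] interval.
    """
    arr = np.asarray(bits, dtype=np.int64)
    single = arr.ndim == 1
    pop = arr[None, :] if single else arr
    k = len(factors)
    B = bits_per_factor
    if pop.shape[1] != k * B:
        raise DesignError(f"expected {k * B} bits, got {pop.shape[1]}")
    weights = 2 ** np.arange(B - 1, -1, -1)
    ints = pop.reshape(pop.shape[0], k, B) @ weights  # (m, k) in 0..2^B-1
    lows = np.array([f.low for f in factors])
    highs = np.array([f.high for f in factors])
    natural = lows + (highs - lows) * ints / (2**B - 1)
    return natural[0] if single else natural


def evaluate_fitness(
    model: SurrogateModel, bits, factors: Sequence[FactorSpec], bits_per_factor: int = 6
):
    """Predicted activity (U/mL) of the condition(s) a chromosome encodes.

    This is exactly the network forward pass — the output-weight combination
    of tansig hidden responses plus the output bias — applied to the decoded,
    scaled input vector; it agrees with ``model.predict_natural`` to machine
    precision by construction.
    """
    natural = decode_chromosome(bits, factors, bits_per_factor)
    return model.predict_natural(natural)


def _roulette_probs(fitness: np.ndarray) -> np.ndarray:
    w = fitness - fitness.min()
    total = w.sum()
    if total <= 0:  # all-equal fitness -> uniform selection
        return np.full(fitness.shape[0], 1.0 / fitness.shape[0])
    return w / total


def evolve(
    model: SurrogateModel,
    factors: Sequence[FactorSpec],
    config: GAConfig = GAConfig(),
) -> OptimizationResult:
    """Run the genetic algorithm and return the best condition found.

    The shortlist ``top_conditions`` holds the ``config.top_k`` best distinct
    decoded conditions seen across the whole run (archive of every evaluated
    individual), mirroring the practice of carrying several GA candidates
    forward to wet-lab validation.
    """
    k = len(factors)
    if config.chromosome_length != k * config.bits_per_factor:
        raise ValueError("chromosome_length must equal bits_per_factor * number of factors")
    rng = np.random.default_rng(config.seed)
    N, L = config.population_size, config.chromosome_length

    pop = rng.integers(0, 2, size=(N, L), dtype=np.int8)
    archive: dict[tuple, tuple[float, np.ndarray]] = {}
    best_trace = np.empty(config.max_generations)
    mean_trace = np.empty(config.max_generations)
    best_fit = -np.inf
    best_bits = pop[0].copy()
    n_eval = 0

    for gen in range(config.max_generations):
        natural = decode_chromosome(pop, factors, config.bits_per_factor)
        fitness = np.asarray(model.predict_natural(natural), dtype=float)
        n_eval += N
        for i in range(N):
            key = tuple(natural[i])
            if key not in archive or fitness[i] > archive[key][0]:
                archive[key] = (float(fitness[i]), pop[i].copy())
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best_bits = pop[gen_best].copy()
        best_trace[gen] = best_fit
        mean_trace[gen] = float(fitness.mean())

        if gen == config.max_generations - 1:
            break

        order = np.argsort(-fitness)
        elites = pop[order[: config.elitism]].copy()
        probs = _roulette_probs(fitness)
        children: list[np.ndarray] = []
        while len(children) < N - config.elitism:
            i, j = rng.choice(N, size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if L > 1 and rng.random() < config.crossover_prob:
                cut = int(rng.integers(1, L))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            children.append(a)
            children.append(b)
        child_arr = np.asarray(children[: N - config.elitism], dtype=np.int8).reshape(-1, L)
        if child_arr.size and config.mutation_prob > 0:
            flip = rng.random(child_arr.shape) < config.mutation_prob
            child_arr ^= flip.astype(np.int8)
        pop = np.vstack([elites, child_arr]) if config.elitism else child_arr

    shortlist = sorted(archive.values(), key=lambda t: -t[0])[: config.top_k]
    top = [(decode_chromosome(bits, factors, config.bits_per_factor), fit) for fit, bits in shortlist]
    return OptimizationResult(
        best_chromosome=best_bits,
        best_conditions_natural=decode_chromosome(best_bits, factors, config.bits_per_factor),
        best_predicted_activity=best_fit,
        best_trace=best_trace,
        mean_trace=mean_trace,
        top_conditions=top,
        n_evaluations=n_eval,
    )
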
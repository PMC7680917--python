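"""Evolutionary optimization of the network genome against MI fitness.

A real-valued genetic algorithm with elitism: each generation keeps the top
``elite_fraction`` of genomes unchanged and fills the rest with offspring of
two distinct parents drawn uniformly from the top ``parent_pool_fraction``,
recombined gene-by-gene (uniform crossover) and mutated so that on average
one gene changes per genome, each change bounded to ±10% of the current
value.  Fitness is the maximum over oscillators of the mutual information
between the labels and that oscillator's maxima counts.

A single seeded RNG stream drives initialization, parent choice, crossover
and mutation, in that order, so runs are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import ROLE3_CHOICES, NetworkGenome, respond_batch
from .datasets import LabeledDataset
from .dynamics import (IntegratorConfig, OregonatorParams, PeakConfig,
                       SimulationError)
from .infotheory import network_fitness

__all__ = ["GAConfig", "EvolutionLog", "init_population", "recombine",
           "mutate", "evolve", "DEFAULT_GENE_RANGES", "CONTINUOUS_GENES"]

#: continuous genes, in their fixed crossover/mutation order
CONTINUOUS_GENES = ("t_ilum3", "t_start", "t_end", "t_max", "alpha", "beta")

#: initialization intervals; "t_end" is (minimum gap above t_start, maximum)
DEFAULT_GENE_RANGES: dict[str, tuple[float, float]] = {
    "t_ilum3": (0.0, 30.0),
    "t_start": (0.0, 10.0),
    "t_end": (0.5, 40.0),
    "t_max": (5.0, 50.0),
    "alpha": (0.0, 1.5),
    "beta": (0.0, 1.0),
}


@dataclass
class GAConfig:
    """Population and operator settings of the evolutionary search."""

    population_size: int = 200
    elite_fraction: float = 0.20
    parent_pool_fraction: float = 0.50
    generations: int = 1000
    expected_mutations_per_genome: float = 1.0
    max_relative_mutation: float = 0.10
    rng_seed: int = 0
    gene_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_RANGES))

    def __post_init__(self) -> None:
        if not 0 < self.elite_fraction < self.parent_pool_fraction <= 1:
            raise ValueError(
                "need 0 < elite_fraction < parent_pool_fraction <= 1")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 < self.max_relative_mutation < 1:
            raise ValueError("max_relative_mutation must lie in (0, 1)")
        missing = set(DEFAULT_GENE_RANGES) - set(self.gene_ranges)
        if missing:
            raise ValueError(f"gene_ranges missing {sorted(missing)}")
        for k, (lo, hi) in self.gene_ranges.items():
            if not lo < hi:
                raise ValueError(f"empty range for gene {k!r}")

    @property
    def n_elite(self) -> int:
        return max(1, round(self.population_size * self.elite_fraction))

    @property
    def n_parents(self) -> int:
        return max(2, round(self.population_size * self.parent_pool_fraction))


@dataclass
class EvolutionLog:
    """Per-generation best/mean fitness and the best genome snapshot."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_genome: list[NetworkGenome] = field(default_factory=list)

    def append(self, fits: np.ndarray, best: NetworkGenome) -> None:
        self.best_fitness.append(float(fits.max()))
        self.mean_fitness.append(float(fits.mean()))
        self.best_genome.append(dataclasses.replace(best))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "generation": np.arange(1, len(self.best_fitness) + 1),
            "best_fitness_bits": self.best_fitness,
            "mean_fitness_bits": self.mean_fitness,
        })


def _repair(vals: dict[str, float]) -> dict[str, float]:
    """Restore t_start < t_end by swapping; nudge apart exact ties."""
    if vals["t_end"] < vals["t_start"]:
        vals["t_start"], vals["t_end"] = vals["t_end"], vals["t_start"]
    if vals["t_end"] == vals["t_start"]:
        vals["t_end"] = vals["t_start"] + 1e-9 + 1e-9 * vals["t_start"]
    return vals


def init_population(cfg: GAConfig,
                    rng: np.random.Generator | None = None) -> list[NetworkGenome]:
    """K genomes sampled uniformly from the configured gene ranges; role3
    uniform over its three categories and t_end drawn above t_start."""
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    pop = []
    for _ in range(cfg.population_size):
        vals: dict[str, float] = {}
        role3 = ROLE3_CHOICES[rng.integers(3)]
        for gene in CONTINUOUS_GENES:
            lo, hi = cfg.gene_ranges[gene]
            if gene == "t_end":
                lo = vals["t_start"] + lo  # gap above the sampled t_start
            vals[gene] = float(rng.uniform(lo, hi))
        pop.append(NetworkGenome(role3=role3, **vals))
    return pop


def recombine(parent_a: NetworkGenome, parent_b: NetworkGenome,
              rng: np.random.Generator) -> NetworkGenome:
    """Uniform crossover: each of the 7 genes copied from either parent with
    probability 1/2; t_start/t_end repaired by swapping if needed."""
    vals: dict[str, float] = {}
    role3 = parent_a.role3 if rng.random() < 0.5 else parent_b.role3
    for gene in CONTINUOUS_GENES:
        src = parent_a if rng.random() < 0.5 else parent_b
        vals[gene] = getattr(src, gene)
    return NetworkGenome(role3=role3, **_repair(vals))


def mutate(genome: NetworkGenome, cfg: GAConfig,
           rng: np.random.Generator) -> NetworkGenome:
    """Mutate each gene independently with probability p = expected/7.

    Continuous genes are perturbed by a uniform draw within ±10% (the
    configured cap) of their current value, so a gene at exactly zero is
    immobile; role3, when selected, is resampled from the other two roles.
    """
    p = cfg.expected_mutations_per_genome / 7.0
    role3 = genome.role3
    if rng.random() < p:
        others = [r for r in ROLE3_CHOICES if r != role3]
        role3 = others[rng.integers(2)]
    vals: dict[str, float] = {}
    cap = cfg.max_relative_mutation
    for gene in CONTINUOUS_GENES:
        v = getattr(genome, gene)
        if rng.random() < p:
            v = float(v + rng.uniform(-cap, cap) * abs(v))
        vals[gene] = v
    return NetworkGenome(role3=role3, **_repair(vals))


def _evaluate(genome: NetworkGenome, dataset: LabeledDataset,
              params: OregonatorParams, h: float, store_stride: int,
              pk: PeakConfig) -> float:
    cfg = IntegratorConfig(t_max=genome.t_max, h=h, store_stride=store_stride)
    try:
        table = respond_batch(genome, dataset, params, cfg, pk)
    except SimulationError:
        return 0.0  # pathological genome: penalize, keep evolving
    return network_fitness(table).fitness_bits


def evolve(cfg: GAConfig, dataset: LabeledDataset,
           params: OregonatorParams = OregonatorParams(),
           integrator: IntegratorConfig | None = None,
           peaks: PeakConfig = PeakConfig(),
           progress: bool = False) -> tuple[NetworkGenome, EvolutionLog]:
    """Run the GA and return the best genome ever evaluated plus the log.

    ``integrator`` contributes its step size and storage stride; the window
    always comes from each genome's own t_max.  Elites keep their cached
    fitness and are never re-simulated.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    h = integrator.h if integrator is not None else 1e-4
    stride = integrator.store_stride if integrator is not None else 100
    rng = np.random.default_rng(cfg.rng_seed)
    pop = init_population(cfg, rng)
    fits = np.array([_evaluate(g, dataset, params, h, stride, peaks)
                     for g in pop])
    log = EvolutionLog()
    gens = range(cfg.generations)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm
        gens = tqdm(gens, desc="evolving")
    for gen in gens:
        order = np.argsort(-fits, kind="stable")
        pop = [pop[i] for i in order]
        fits = fits[order]
        log.append(fits, pop[0])
        if gen == cfg.generations - 1:
            break
        parents = pop[:cfg.n_parents]
        next_pop = pop[:cfg.n_elite]
        next_fits = list(fits[:cfg.n_elite])
        for _ in range(cfg.population_size - cfg.n_elite):
            i, j = rng.choice(len(parents), size=2, replace=False)
            child = mutate(recombine(parents[i], parents[j], rng), cfg, rng)
            next_pop.append(child)
            next_fits.append(_evaluate(child, dataset, params, h, stride,
                                       peaks))
        pop = next_pop
        fits = np.array(next_fits)
    best_gen = int(np.argmax(log.best_fitness))
    return log.best_genome[best_gen], log
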
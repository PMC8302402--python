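"""Genetic search over filter-parameter chromosomes minimizing the NIQE score.

A chromosome is the seven-gene vector (type, hsize, radius, sigma, alpha,
length, theta): a secondary-filter recipe plus a motion-blur hypothesis.
The population protocol follows the study design this package implements:
ten randomly initialized chromosomes, fitness = NIQE of the enhanced image
(smaller is better), single-point crossover at the boundary before the
``length`` gene, one mutant per generation drawn from the best 80% of the
population, elitism, roughly a thousand generations.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .enhancement import RestorationConfig, enhance
from .niqe import NIQEModel, niqe_score

__all__ = [
    "GENE_ORDER",
    "GENE_BOUNDS",
    "Chromosome",
    "GAConfig",
    "GenerationRecord",
    "FitnessTrajectory",
    "init_population",
    "evaluate_population",
    "crossover",
    "mutate",
    "evolve",
]

logger = logging.getLogger(__name__)

#: gene order of the vector form, fixed across the package
GENE_ORDER = ("type", "hsize", "radius", "sigma", "alpha", "length", "theta")

#: inclusive search bounds per gene; the length bound matches the range used
#: to generate motion blur, theta the observed range of camera tilt
GENE_BOUNDS: dict[str, tuple[float, float]] = {
    "type": (1, 8),
    "hsize": (3, 15),
    "radius": (1.0, 10.0),
    "sigma": (0.1, 1.0),
    "alpha": (0.1, 1.0),
    "length": (9.0, 100.0),
    "theta": (0.0, 5.0),
}

_INTEGER_GENES = frozenset({"type", "hsize"})
_CROSSOVER_POINT = GENE_ORDER.index("length")  # split before the length gene


@dataclass(frozen=True)
class Chromosome:
    """Seven-gene filter-parameter vector; all genes within their bounds."""

    type: int
    hsize: int
    radius: float
    sigma: float
    alpha: float
    length: float
    theta: float

    def __post_init__(self) -> None:
        for gene in GENE_ORDER:
            value = getattr(self, gene)
            lo, hi = GENE_BOUNDS[gene]
            if not (lo <= value <= hi):
                raise ValueError(f"gene {gene}={value} outside bounds [{lo}, {hi}]")
        if self.hsize % 2 == 0:
            raise ValueError(f"hsize must be odd, got {self.hsize}")
        if self.type != int(self.type):
            raise ValueError(f"type must be an integer, got {self.type}")

    def to_vector(self) -> np.ndarray:
        """The chromosome in its 7-vector form, e.g. [3, 6, 10, 0.7, 0.2, 19.18, 3.0]."""
        return np.array([float(getattr(self, g)) for g in GENE_ORDER])

    @classmethod
    def from_vector(cls, vec) -> "Chromosome":
        vals = dict(zip(GENE_ORDER, vec))
        return cls(
            type=int(round(vals["type"])),
            hsize=int(round(vals["hsize"])),
            radius=float(vals["radius"]),
            sigma=float(vals["sigma"]),
            alpha=float(vals["alpha"]),
            length=float(vals["length"]),
            theta=float(vals["theta"]),
        )


@dataclass(frozen=True)
class GAConfig:
    """Genetic-search protocol parameters."""

    population_size: int = 10
    generations: int = 1000
    elite_count: int = 1
    mutation_rate: float = 1.0
    mutation_pool_fraction: float = 0.8
    seed: int = 0
    early_stop_patience: int | None = None  # generations without > tol improvement
    early_stop_tol: float = 1e-4
    restoration: RestorationConfig = field(default_factory=RestorationConfig)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.mutation_pool_fraction <= 1:
            raise ValueError("mutation_pool_fraction must lie in (0, 1]")
        if not 0 < self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in (0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must lie in [0, population_size)")


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_score: float
    mean_score: float
    best_chromosome: Chromosome


@dataclass
class FitnessTrajectory:
    """Per-generation record of population fitness and the best chromosome."""

    records: list[GenerationRecord] = field(default_factory=list)

    def append(self, record: GenerationRecord) -> None:
        self.records.append(record)

    @property
    def best_scores(self) -> np.ndarray:
        return np.array([r.best_score for r in self.records])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "generation": r.generation,
                "best_score": r.best_score,
                "mean_score": r.mean_score,
            }
            row.update(
                {g: float(getattr(r.best_chromosome, g)) for g in GENE_ORDER}
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _round_gene(gene: str, value: float) -> float | int:
    lo, hi = GENE_BOUNDS[gene]
    value = min(max(value, lo), hi)
    if gene == "hsize":
        odd = int(round((value - 3) / 2)) * 2 + 3  # nearest odd in [3, 15]
        return int(min(max(odd, 3), 15))
    if gene in _INTEGER_GENES:
        return int(round(value))
    return float(value)


def _random_chromosome(rng: np.random.Generator) -> Chromosome:
    genes = {
        g: _round_gene(g, rng.uniform(*GENE_BOUNDS[g])) for g in GENE_ORDER
    }
    return Chromosome(**genes)


def init_population(config: GAConfig, rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Sample ``population_size`` chromosomes uniformly within the gene bounds."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [_random_chromosome(rng) for _ in range(config.population_size)]


def evaluate_population(
    population: list[Chromosome],
    image: np.ndarray,
    model: NIQEModel,
    restoration: RestorationConfig | None = None,
    cache: dict[Chromosome, float] | None = None,
) -> list[tuple[Chromosome, float]]:
    """Score every chromosome; returns (chromosome, NIQE) sorted best-first.

    A chromosome whose enhancement fails is assigned infinite (worst)
    fitness rather than aborting the generation.
    """
    scored = []
    for chrom in population:
        if cache is not None and chrom in cache:
            fitness = cache[chrom]
        else:
            try:
                fitness = float(niqe_score(enhance(image, chrom, restoration), model))
            except Exception:  # degraded individual, not a fatal error
                logger.warning("enhancement failed for %s; assigning worst fitness", chrom)
                fitness = math.inf
            if cache is not None:
                cache[chrom] = fitness
        scored.append((chrom, fitness))
    scored.sort(key=lambda pair: pair[1])
    return scored


def crossover(parent_a: Chromosome, parent_b: Chromosome) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover at the boundary before the ``length`` gene."""
    head = GENE_ORDER[:_CROSSOVER_POINT]
    tail = GENE_ORDER[_CROSSOVER_POINT:]
    child_a = Chromosome(
        **{g: getattr(parent_a, g) for g in head},
        **{g: getattr(parent_b, g) for g in tail},
    )
    child_b = Chromosome(
        **{g: getattr(parent_b, g) for g in head},
        **{g: getattr(parent_a, g) for g in tail},
    )
    return child_a, child_b


def mutate(
    population_sorted: list[Chromosome],
    config: GAConfig,
    rng: np.random.Generator,
) -> Chromosome:
    """Perturb one gene of one chromosome from the best pool.

    The source is drawn uniformly from the best
    ``ceil(mutation_pool_fraction * N)`` individuals of the (best-first)
    population.  The chosen gene is, with equal probability, either redrawn
    uniformly within its bound (global exploration) or shifted by a uniform
    step of at most 10% of the bound width (local refinement), then clipped
    and re-rounded.
    """
    pool = math.ceil(config.mutation_pool_fraction * len(population_sorted))
    source = population_sorted[int(rng.integers(pool))]
    gene = GENE_ORDER[int(rng.integers(len(GENE_ORDER)))]
    lo, hi = GENE_BOUNDS[gene]
    if rng.random() < 0.5:
        raw = rng.uniform(lo, hi)
    else:
        raw = float(getattr(source, gene)) + rng.uniform(-0.1, 0.1) * (hi - lo)
    return dataclasses.replace(source, **{gene: _round_gene(gene, raw)})


def evolve(
    image: np.ndarray,
    model: NIQEModel,
    config: GAConfig,
) -> tuple[Chromosome, np.ndarray, FitnessTrajectory]:
    """Run the generational loop; returns (best chromosome, enhanced image, trajectory).

    Each generation: evaluate, sort ascending by NIQE, carry the elite, fill
    the next generation with single-point crossover offspring of uniformly
    random parent pairs from the whole population, and inject one mutant
    (replacing the worst slot).  Fully reproducible from ``config.seed``.
    """
    if config.generations < 0:
        raise ValueError("generations must be >= 0")
    rng = np.random.default_rng(config.seed)
    cache: dict[Chromosome, float] = {}
    trajectory = FitnessTrajectory()

    population = init_population(config, rng)
    scored = evaluate_population(population, image, model, config.restoration, cache)
    best_chrom, best_score = scored[0]

    def record(gen: int) -> None:
        finite = [s for _, s in scored if math.isfinite(s)]
        mean = float(np.mean(finite)) if finite else math.inf
        trajectory.append(GenerationRecord(gen, best_score, mean, best_chrom))
        logger.info("generation %d: best %.4f mean %.4f", gen, best_score, mean)

    record(0)
    stall = 0
    for gen in range(1, config.generations + 1):
        n = config.population_size
        next_pop: list[Chromosome] = [c for c, _ in scored[: config.elite_count]]
        n_mutants = 1 if rng.random() < config.mutation_rate else 0
        while len(next_pop) < n - n_mutants:
            i, j = rng.integers(n), rng.integers(n)
            child_a, child_b = crossover(scored[int(i)][0], scored[int(j)][0])
            next_pop.append(child_a)
            if len(next_pop) < n - n_mutants:
                next_pop.append(child_b)
        for _ in range(n_mutants):
            next_pop.append(mutate([c for c, _ in scored], config, rng))

        scored = evaluate_population(next_pop, image, model, config.restoration, cache)
        improvement = best_score - scored[0][1]
        if scored[0][1] < best_score:
            best_chrom, best_score = scored[0]
        record(gen)

        if config.early_stop_patience is not None:
            stall = 0 if improvement > config.early_stop_tol else stall + 1
            if stall >= config.early_stop_patience:
                logger.info("early stop at generation %d", gen)
                break

    return best_chrom, enhance(image, best_chrom, config.restoration), trajectory
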
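"""One generation of the invasion life cycle.

Each generation applies, in order: the extinction lottery (an external
catastrophe wiping the whole population with probability ``e``), promiscuous
random mating with Poisson fecundity, symmetric biallelic mutation, and
density regulation to the carrying capacity ``K``.  Placing the lottery first
means the per-generation extinction probability applies to every generation
including the first, so survival curves decline from generation 1.

Two regulation modes are supported.  ``ceiling`` truncates the offspring pool
at ``K`` (a uniform random subset of exactly ``K`` survives when the pool
overshoots).  ``logistic`` instead computes the discrete logistic target
``N* = N_t + r N_t (1 - N_t / K)`` from the parent census and keeps a uniform
subset of at most ``N*`` offspring; with fecundity far above replacement the
census then tracks the logistic map until it saturates at ``K``.

Demographic extinction — no individuals, no mating pair, or zero offspring —
is tracked as a cause distinct from the lottery, because for tiny propagules
the two have very different interpretations.

Implementation note: :func:`step_generation` decides which offspring survive
regulation *before* synthesizing their genotypes.  Regulation keeps a uniform
subset chosen independently of genotype, and symmetric per-copy mutation
commutes with subset selection, so this fused path has exactly the same
distribution as the literal reproduce → mutate → regulate composition while
touching only ``min(pool, K)`` genomes per generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .population import FEMALE, MALE, Population

__all__ = [
    "DemographyParams",
    "StepRecord",
    "reproduce",
    "mutate",
    "regulate",
    "extinction_lottery",
    "step_generation",
    "CAUSE_LOTTERY",
    "CAUSE_DEMOGRAPHIC",
]

CAUSE_LOTTERY = "lottery"
CAUSE_DEMOGRAPHIC = "demographic"


@dataclass(frozen=True)
class DemographyParams:
    """Demographic constants of the simulated species.

    Defaults follow the crab-like study organism: mean fecundity ``f = 100``
    offspring per female, carrying capacity ``K = 96,000`` (96 individuals/m²
    over 1,000 m²), symmetric mutation at ``μ = 5e-6`` per allele copy per
    generation, and a per-generation extinction probability ``e``.
    ``logistic_r`` is used only in logistic growth mode.
    """

    fecundity_mean: float = 100.0
    carrying_capacity: int = 96_000
    growth_mode: Literal["ceiling", "logistic"] = "ceiling"
    logistic_r: float = 1.0
    mutation_rate: float = 5e-6
    extinction_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.extinction_rate <= 1.0:
            raise ValueError("extinction_rate must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")
        if self.fecundity_mean <= 0:
            raise ValueError("fecundity_mean must be > 0")
        if self.growth_mode not in ("ceiling", "logistic"):
            raise ValueError(f"unknown growth_mode {self.growth_mode!r}")
        if self.growth_mode == "logistic" and self.logistic_r < 0:
            raise ValueError("logistic_r must be >= 0")


@dataclass(frozen=True)
class StepRecord:
    """Outcome of one generation step: census after regulation and, if the
    replicate died this generation, the cause ("lottery" or "demographic")."""

    generation: int
    census: int
    cause: Optional[str] = None

    @property
    def alive(self) -> bool:
        return self.census > 0


def _transmit(genotypes: np.ndarray, parent_ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per offspring: a uniformly chosen allele copy per locus."""
    g = genotypes[parent_ids]  # (M, L, 2)
    which = rng.integers(0, 2, size=g.shape[:2], dtype=np.bool_)
    return np.where(which, g[:, :, 1], g[:, :, 0])


def _make_offspring(
    pop: Population,
    mother_ids: np.ndarray,
    father_ids: np.ndarray,
    rng: np.random.Generator,
) -> Population:
    maternal = _transmit(pop.genotypes, mother_ids, rng)
    paternal = _transmit(pop.genotypes, father_ids, rng)
    genotypes = np.stack([maternal, paternal], axis=2)
    sexes = rng.integers(0, 2, size=len(mother_ids), dtype=np.int8)
    return Population(genotypes, sexes, generation_index=pop.generation_index + 1)


def reproduce(pop: Population, params: DemographyParams, rng: np.random.Generator) -> Population:
    """Promiscuous random mating with Poisson fecundity.

    Every female draws a Poisson(``fecundity_mean``) offspring count; every
    offspring receives one gamete from its mother and one from an
    independently, uniformly chosen father, and a fair-coin sex.  A population
    without a mating pair returns the empty population (demographic
    extinction).
    """
    females = np.flatnonzero(pop.sexes == FEMALE)
    males = np.flatnonzero(pop.sexes == MALE)
    if len(females) == 0 or len(males) == 0:
        return Population.empty(pop.n_loci, generation_index=pop.generation_index + 1)
    counts = rng.poisson(params.fecundity_mean, size=len(females))
    total = int(counts.sum())
    if total == 0:
        return Population.empty(pop.n_loci, generation_index=pop.generation_index + 1)
    mother_ids = np.repeat(females, counts)
    father_ids = rng.choice(males, size=total, replace=True)
    return _make_offspring(pop, mother_ids, father_ids, rng)


def mutate(pop: Population, mutation_rate: float, rng: np.random.Generator) -> Population:
    """Flip each allele copy 0↔1 independently with probability ``mutation_rate``.

    The number of flips is drawn as a Binomial over all copies and placed at
    uniformly chosen positions, which is exact and avoids a dense uniform
    draw per copy at realistic mutation rates.
    """
    n_copies = pop.genotypes.size
    if n_copies == 0 or mutation_rate == 0.0:
        return pop
    flat = pop.genotypes.copy().reshape(-1)
    n_flips = rng.binomial(n_copies, mutation_rate)
    if n_flips:
        idx = rng.choice(n_copies, size=n_flips, replace=False)
        flat[idx] ^= 1
    return Population(flat.reshape(pop.genotypes.shape), pop.sexes, pop.generation_index)


def _regulation_target(params: DemographyParams, parent_census: int) -> int:
    """Post-regulation census target: K in ceiling mode, the discrete
    logistic step from the parent census in logistic mode (capped at K)."""
    K = params.carrying_capacity
    if params.growth_mode == "ceiling":
        return K
    n = parent_census
    target = int(round(n + params.logistic_r * n * (1.0 - n / K)))
    return max(0, min(target, K))


def regulate(
    offspring: Population,
    params: DemographyParams,
    parent_census: int,
    rng: np.random.Generator,
) -> Population:
    """Cull the offspring pool to the regulation target with a uniform subset."""
    target = _regulation_target(params, parent_census)
    if offspring.size <= target:
        return offspring
    keep = rng.choice(offspring.size, size=target, replace=False)
    return Population(
        offspring.genotypes[keep], offspring.sexes[keep], offspring.generation_index
    )


def extinction_lottery(extinction_rate: float, rng: np.random.Generator) -> bool:
    """True (whole-population extinction this generation) with probability ``e``."""
    if not 0.0 <= extinction_rate <= 1.0:
        raise ValueError("extinction_rate must lie in [0, 1]")
    return bool(rng.random() < extinction_rate)


def _random_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2, size=n, dtype=np.int8)


def step_generation(
    pop: Population, params: DemographyParams, rng: np.random.Generator
) -> tuple[Population, StepRecord]:
    """Advance one generation: lottery → reproduction → mutation → regulation.

    Returns the next generation and a :class:`StepRecord`.  Stepping an
    already-extinct population is an error; extinction is reported through the
    record's ``cause`` ("lottery" for the external catastrophe, "demographic"
    for a missing mating pair or an empty offspring pool).
    """
    if pop.is_extinct:
        raise ValueError("replicate already extinct")
    gen = pop.generation_index + 1

    if extinction_lottery(params.extinction_rate, rng):
        return Population.empty(pop.n_loci, gen), StepRecord(gen, 0, CAUSE_LOTTERY)

    n_f, n_m = pop.n_females, pop.n_males
    if n_f == 0 or n_m == 0:
        return Population.empty(pop.n_loci, gen), StepRecord(gen, 0, CAUSE_DEMOGRAPHIC)

    target = _regulation_target(params, pop.size)

    if pop.n_loci == 0:
        # Survival-only fast path: no genomes, so only the census matters.
        # The offspring pool total is Poisson(n_f * f) (sum of the per-female
        # Poisson counts) and survivor sexes are iid fair coins.
        total = int(rng.poisson(params.fecundity_mean * n_f))
        if total == 0:
            return Population.empty(0, gen), StepRecord(gen, 0, CAUSE_DEMOGRAPHIC)
        n_next = min(total, target)
        nxt = Population(
            np.empty((n_next, 0, 2), dtype=np.int8), _random_sexes(n_next, rng), gen
        )
        return nxt, StepRecord(gen, n_next)

    females = np.flatnonzero(pop.sexes == FEMALE)
    males = np.flatnonzero(pop.sexes == MALE)
    counts = rng.poisson(params.fecundity_mean, size=n_f)
    total = int(counts.sum())
    if total == 0:
        return Population.empty(pop.n_loci, gen), StepRecord(gen, 0, CAUSE_DEMOGRAPHIC)

    mother_pool = np.repeat(females, counts)
    if total > target:
        mother_ids = mother_pool[rng.choice(total, size=target, replace=False)]
    else:
        mother_ids = mother_pool
    father_ids = rng.choice(males, size=len(mother_ids), replace=True)

    nxt = _make_offspring(pop, mother_ids, father_ids, rng)
    nxt = mutate(nxt, params.mutation_rate, rng)
    return nxt, StepRecord(gen, nxt.size)
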
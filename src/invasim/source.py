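"""Synthesis of the ancestral source population at a target heterozygosity.

The invasion scenarios all start from a large random-mating source population
in Hardy–Weinberg equilibrium carrying 5,000 biallelic neutral SNPs at an
observed heterozygosity of 0.5, 0.3 or 0.1.  Rather than burning in a huge
population for a thousand generations, the source is constructed directly:
per-locus allele frequencies are chosen so the expected heterozygote fraction
equals the target, and genotypes are drawn under Hardy–Weinberg proportions
(each allele copy an independent Bernoulli draw at the locus frequency).

Two frequency spectra are available:

* ``two-point`` (default) — every locus at the single frequency solving
  ``2 p (1 - p) = Ho``, mirrored to ``1 - p`` at random per locus.  Exact and
  oracle-friendly.
* ``beta-spectrum`` — frequencies drawn from a symmetric Beta(α, α) whose
  mean heterozygosity matches the target (``α = Ho / (1 - 2 Ho)``), mimicking
  a dispersed site-frequency spectrum.

An optional scaled burn-in evolves the synthesized source for a number of
generations of random mating (constant census, with mutation) before it is
returned, for users who want drift-mutation conditioning rather than exact
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .demography import DemographyParams, step_generation
from .population import Population

__all__ = ["SourceSpec", "solve_allele_frequency", "beta_concentration", "build_source_population"]


@dataclass(frozen=True)
class SourceSpec:
    """Recipe for the ancestral source population.

    ``n_source`` defaults to 10,000: sampling a propagule of at most 1,000
    from 10,000 Hardy–Weinberg individuals is statistically indistinguishable
    from sampling from the study's nominal million, at these heterozygosities.
    """

    target_ho: float
    n_source: int = 10_000
    n_loci: int = 5_000
    frequency_mode: Literal["two-point", "beta-spectrum"] = "two-point"
    burn_in_generations: int = 0
    mutation_rate: float = 5e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_ho <= 0.5:
            raise ValueError("target_ho exceeds biallelic maximum 0.5 (or is negative)")
        if self.n_source < 2:
            raise ValueError("n_source must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.frequency_mode not in ("two-point", "beta-spectrum"):
            raise ValueError(f"unknown frequency_mode {self.frequency_mode!r}")
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")


def solve_allele_frequency(target_ho: float) -> float:
    """Minor-allele frequency whose Hardy–Weinberg heterozygosity is ``target_ho``.

    Inverts ``2 p (1 - p) = Ho``; returns the minor root
    ``(1 - sqrt(1 - 2 Ho)) / 2``.  Callers may mirror to ``1 - p`` per locus.
    """
    if target_ho < 0.0 or target_ho > 0.5:
        raise ValueError("target heterozygosity exceeds biallelic maximum 0.5")
    return (1.0 - math.sqrt(1.0 - 2.0 * target_ho)) / 2.0


def beta_concentration(target_ho: float) -> float:
    """Shape α of the symmetric Beta(α, α) frequency spectrum with mean
    heterozygosity ``target_ho`` (uses E[2p(1-p)] = α / (2α + 1))."""
    if not 0.0 < target_ho < 0.5:
        raise ValueError(
            "beta-spectrum mode needs 0 < target_ho < 0.5: "
            "the mean heterozygosity alpha/(2*alpha + 1) cannot reach the endpoints"
        )
    return target_ho / (1.0 - 2.0 * target_ho)


def _locus_frequencies(spec: SourceSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.frequency_mode == "two-point":
        p = solve_allele_frequency(spec.target_ho)
        freqs = np.full(spec.n_loci, p)
        mirror = rng.random(spec.n_loci) < 0.5
        freqs[mirror] = 1.0 - freqs[mirror]
        return freqs
    if spec.target_ho == 0.0:
        return np.zeros(spec.n_loci)
    alpha = beta_concentration(spec.target_ho)
    return rng.beta(alpha, alpha, size=spec.n_loci)


def build_source_population(spec: SourceSpec) -> Population:
    """Draw the Hardy–Weinberg source population described by ``spec``.

    Genotypes: both allele copies at locus ``l`` are independent
    Bernoulli(``p_l``) draws, which is Hardy–Weinberg by construction.  Sexes
    are fair-coin.  If ``burn_in_generations > 0`` the population is then
    evolved that many generations of random mating at constant census with
    mutation before being returned.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = _locus_frequencies(spec, rng)
    genotypes = (
        rng.random((spec.n_source, spec.n_loci, 2)) < freqs[None, :, None]
    ).astype(np.int8)
    sexes = rng.integers(0, 2, size=spec.n_source, dtype=np.int8)
    pop = Population(genotypes, sexes, generation_index=0)

    if spec.burn_in_generations:
        # Constant-census conditioning: ceiling regulation at exactly n_source
        # keeps the census fixed while drift and mutation act.
        params = DemographyParams(
            carrying_capacity=spec.n_source,
            mutation_rate=spec.mutation_rate,
            extinction_rate=0.0,
        )
        for _ in range(spec.burn_in_generations):
            pop, record = step_generation(pop, params, rng)
            if not record.alive:  # same-sex census collapse at tiny n_source
                raise RuntimeError(
                    "source burn-in went demographically extinct; "
                    "use a larger n_source"
                )
        pop = Population(pop.genotypes, pop.sexes, generation_index=0)
    return pop
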
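"""Diploid biallelic populations and the genetic summary statistics computed on them.

A population is a dense tensor of allele copies: ``genotypes[i, l, c]`` is the
``c``-th allele copy (0 or 1) carried by individual ``i`` at locus ``l``.  Loci
are neutral, unlinked and biallelic, so this minimal coding is lossless.  An
empty population (``N == 0``) encodes a demographically extinct replicate.

Two heterozygosity statistics are provided:

* observed heterozygosity ``Ho`` — the fraction of individuals whose two
  allele copies differ at a locus, averaged across loci;
* expected heterozygosity ``He`` (Nei's gene diversity) — ``2 p (1 - p)``
  at allele frequency ``p``, averaged across loci.

``Ho`` is the statistic the simulator reports; ``He`` is what the analytic
drift expectations predict, and both are kept so the two surfaces can be
compared.  Monomorphic loci stay in the panel and contribute zero, so
retention ratios ``Ho_t / Ho_0`` always refer to a fixed locus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FEMALE",
    "MALE",
    "Population",
    "GeneticSummary",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "summarize",
]

#: Integer sex labels used in :attr:`Population.sexes`.
FEMALE: int = 0
MALE: int = 1


@dataclass
class Population:
    """All living individuals of one replicate at one point in time.

    Parameters
    ----------
    genotypes
        Array of shape ``(N, L, 2)`` with each allele copy coded 0/1.
    sexes
        Array of shape ``(N,)`` with entries :data:`FEMALE` or :data:`MALE`.
    generation_index
        Number of completed generations since founding (0 for founders).
    """

    genotypes: np.ndarray
    sexes: np.ndarray
    generation_index: int = 0

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sexes = np.asarray(self.sexes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError(
                f"genotypes must have shape (N, L, 2), got {self.genotypes.shape}"
            )
        if self.sexes.shape != (self.genotypes.shape[0],):
            raise ValueError(
                f"sexes has length {self.sexes.shape}, expected ({self.genotypes.shape[0]},)"
            )
        if self.generation_index < 0:
            raise ValueError("generation_index must be >= 0")

    @property
    def size(self) -> int:
        """Census size ``N``."""
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_females(self) -> int:
        return int(np.count_nonzero(self.sexes == FEMALE))

    @property
    def n_males(self) -> int:
        return int(np.count_nonzero(self.sexes == MALE))

    @property
    def is_extinct(self) -> bool:
        return self.size == 0

    def validate_alleles(self) -> None:
        """Raise if any allele copy is not exactly 0 or 1 (O(N*L) scan)."""
        if self.size and not np.isin(self.genotypes, (0, 1)).all():
            raise ValueError("allele copies must be exactly 0 or 1")

    @classmethod
    def empty(cls, n_loci: int, generation_index: int = 0) -> "Population":
        """An extinct population (``N == 0``) over ``n_loci`` loci."""
        return cls(
            genotypes=np.empty((0, n_loci, 2), dtype=np.int8),
            sexes=np.empty((0,), dtype=np.int8),
            generation_index=generation_index,
        )


@dataclass(frozen=True)
class GeneticSummary:
    """Multilocus diversity summary of one population.

    ``expected_het`` is the mean over loci of ``2 p (1 - p)`` and is therefore
    bounded by 0.5; ``allele_freqs`` holds the per-locus frequency of allele 1.
    """

    observed_het: float
    expected_het: float
    allele_freqs: np.ndarray = field(repr=False)


def _require_individuals(pop: Population) -> None:
    if pop.size == 0:
        raise ValueError("no individuals: population is extinct")


def allele_frequencies(pop: Population) -> np.ndarray:
    """Per-locus frequency of allele 1, i.e. allele-1 copy count over ``2N``."""
    _require_individuals(pop)
    return pop.genotypes.sum(axis=(0, 2), dtype=np.float64) / (2.0 * pop.size)


def observed_heterozygosity(pop: Population) -> float:
    """Mean over loci of the fraction of heterozygous individuals.

    Because every locus is scored on the same ``N`` individuals this equals
    the mean heterozygote indicator over all individual-locus pairs.
    """
    _require_individuals(pop)
    if pop.n_loci == 0:
        raise ValueError("no loci: observed heterozygosity undefined")
    het = pop.genotypes[:, :, 0] != pop.genotypes[:, :, 1]
    return float(het.mean())


def expected_heterozygosity(pop: Population) -> float:
    """Mean over loci of ``2 p (1 - p)`` (Nei's gene diversity)."""
    _require_individuals(pop)
    if pop.n_loci == 0:
        raise ValueError("no loci: expected heterozygosity undefined")
    p = allele_frequencies(pop)
    return float(np.mean(2.0 * p * (1.0 - p)))


def summarize(pop: Population) -> GeneticSummary:
    """Compute :class:`GeneticSummary` (Ho, He and the frequency vector) in one pass."""
    p = allele_frequencies(pop)
    return GeneticSummary(
        observed_het=observed_heterozygosity(pop),
        expected_het=float(np.mean(2.0 * p * (1.0 - p))),
        allele_freqs=p,
    )
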
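"""The generation cycle: mating, mutation, regulation, extinction lottery."""

import numpy as np
import pytest

from invasim import (
    FEMALE,
    MALE,
    DemographyParams,
    Population,
    allele_frequencies,
    extinction_lottery,
    mutate,
    observed_heterozygosity,
    regulate,
    reproduce,
    step_generation,
)
from invasim.demography import CAUSE_DEMOGRAPHIC, CAUSE_LOTTERY, _regulation_target


def pair_population(mother_geno, father_geno):
    """One female + one male with the given single-locus genotypes."""
    genotypes = np.array([[mother_geno], [father_geno]], dtype=np.int8)
    sexes = np.array([FEMALE, MALE], dtype=np.int8)
    return Population(genotypes, sexes)


def hwe_population(n, L, p, rng, balanced=True):
    genotypes = (rng.random((n, L, 2)) < p).astype(np.int8)
    if balanced:
        sexes = np.tile([FEMALE, MALE], n // 2 + 1)[:n].astype(np.int8)
    else:
        sexes = rng.integers(0, 2, size=n, dtype=np.int8)
    return Population(genotypes, sexes)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"extinction_rate": 1.5},
            {"mutation_rate": -1e-9},
            {"carrying_capacity": 0},
            {"fecundity_mean": 0},
            {"growth_mode": "exponential"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DemographyParams(**kwargs)


class TestReproduce:
    def test_poisson_fecundity_mean(self, rng):
        # One mating pair at f = 100: mean offspring over trials ~ 100.
        params = DemographyParams(fecundity_mean=100.0)
        pop = pair_population([0, 0], [0, 0])
        counts = [reproduce(pop, params, rng).size for _ in range(300)]
        se = 10.0 / np.sqrt(300)  # Poisson sd 10
        assert abs(np.mean(counts) - 100.0) < 3 * se

    def test_homozygous_parents_transmit_no_variation(self, rng):
        pop = pair_population([0, 0], [0, 0])
        off = reproduce(pop, DemographyParams(mutation_rate=0.0), rng)
        assert off.size > 0
        assert not off.genotypes.any()

    def test_mendelian_segregation_from_double_heterozygotes(self, rng):
        # 0/1 x 0/1 -> genotype counts (1/4, 1/2, 1/4)
        pop = pair_population([0, 1], [0, 1])
        off = reproduce(pop, DemographyParams(fecundity_mean=10_000.0), rng)
        dosages = off.genotypes.sum(axis=2)[:, 0]
        n = off.size
        freqs = np.bincount(dosages, minlength=3) / n
        for observed, expected in zip(freqs, (0.25, 0.5, 0.25)):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 4 * se

    def test_single_sex_population_goes_demographically_extinct(self, rng):
        genotypes = np.zeros((4, 2, 2), dtype=np.int8)
        sexes = np.full(4, FEMALE, dtype=np.int8)
        off = reproduce(Population(genotypes, sexes), DemographyParams(), rng)
        assert off.is_extinct
        assert off.generation_index == 1

    def test_offspring_generation_index_increments(self, rng):
        pop = pair_population([0, 1], [0, 1])
        off = reproduce(pop, DemographyParams(), rng)
        assert off.generation_index == pop.generation_index + 1


class TestMutate:
    def test_zero_rate_is_identity(self, rng):
        pop = hwe_population(20, 10, 0.4, rng)
        out = mutate(pop, 0.0, rng)
        np.testing.assert_array_equal(out.genotypes, pop.genotypes)

    def test_rate_one_is_an_involution(self, rng):
        pop = hwe_population(15, 8, 0.4, rng)
        flipped = mutate(pop, 1.0, rng)
        assert (flipped.genotypes == 1 - pop.genotypes).all()
        restored = mutate(flipped, 1.0, rng)
        np.testing.assert_array_equal(restored.genotypes, pop.genotypes)

    def test_expected_flip_count(self, rng):
        # 2*N*L*mu expected flips; binomial 4-sigma envelope on one draw.
        n, L, mu = 1_000, 500, 1e-3
        pop = hwe_population(n, L, 0.0, rng)
        out = mutate(pop, mu, rng)
        flips = int((out.genotypes != pop.genotypes).sum())
        expected = 2 * n * L * mu
        sd = np.sqrt(expected * (1 - mu))
        assert abs(flips - expected) < 4 * sd


class TestRegulate:
    def test_under_capacity_all_survive(self, rng):
        pop = hwe_population(50, 3, 0.5, rng)
        out = regulate(pop, DemographyParams(carrying_capacity=96_000), 10, rng)
        assert out.size == 50

    def test_ceiling_truncates_to_capacity(self, rng):
        pop = hwe_population(2_000, 2, 0.5, rng)
        out = regulate(pop, DemographyParams(carrying_capacity=300), 100, rng)
        assert out.size == 300

    def test_logistic_fixed_point_at_capacity(self):
        params = DemographyParams(growth_mode="logistic", logistic_r=0.8, carrying_capacity=500)
        assert _regulation_target(params, 500) == 500

    def test_logistic_target_follows_the_map(self, rng):
        params = DemographyParams(growth_mode="logistic", logistic_r=1.0, carrying_capacity=1_000)
        # N* = 100 + 1.0 * 100 * (1 - 0.1) = 190
        assert _regulation_target(params, 100) == 190
        pop = hwe_population(800, 2, 0.5, rng)
        out = regulate(pop, params, 100, rng)
        assert out.size == 190


class TestLottery:
    def test_boundary_rates(self, rng):
        assert not any(extinction_lottery(0.0, rng) for _ in range(100))
        assert all(extinction_lottery(1.0, rng) for _ in range(100))

    def test_rate_is_respected(self, rng):
        draws = sum(extinction_lottery(0.2, rng) for _ in range(10_000))
        se = np.sqrt(0.2 * 0.8 / 10_000)
        assert abs(draws / 10_000 - 0.2) < 3 * se

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            extinction_lottery(1.2, rng)


class TestStepGeneration:
    def test_stepping_extinct_population_is_an_error(self, rng):
        with pytest.raises(ValueError, match="already extinct"):
            step_generation(Population.empty(3), DemographyParams(), rng)

    def test_certain_lottery_kills_with_cause(self, rng):
        pop = hwe_population(10, 2, 0.5, rng)
        nxt, record = step_generation(pop, DemographyParams(extinction_rate=1.0), rng)
        assert nxt.is_extinct
        assert record.cause == CAUSE_LOTTERY
        assert record.census == 0 and not record.alive

    def test_single_sex_is_demographic_extinction(self, rng):
        pop = Population(
            np.zeros((6, 2, 2), dtype=np.int8), np.full(6, MALE, dtype=np.int8)
        )
        nxt, record = step_generation(pop, DemographyParams(), rng)
        assert nxt.is_extinct
        assert record.cause == CAUSE_DEMOGRAPHIC

    def test_one_step_growth_and_heterozygosity(self, rng):
        # 500 founders at Ho ~ 0.5, no lottery: census grows toward capacity
        # and one generation of drift moves Ho by O(1/N) only.
        pop = hwe_population(500, 100, 0.5, rng)
        params = DemographyParams(extinction_rate=0.0, carrying_capacity=100_000, mutation_rate=0.0)
        nxt, record = step_generation(pop, params, rng)
        assert record.alive
        # pool ~ Poisson(250 * 100); 4 sigma around the mean
        assert abs(record.census - 25_000) < 4 * np.sqrt(25_000)
        assert abs(observed_heterozygosity(nxt) - 0.5) < 0.01

    def test_census_never_exceeds_capacity(self, rng):
        pop = hwe_population(200, 4, 0.5, rng)
        params = DemographyParams(carrying_capacity=450, extinction_rate=0.0)
        for _ in range(5):
            pop, record = step_generation(pop, params, rng)
            assert record.census <= 450
        assert record.census == 450

    def test_allele_frequency_is_a_martingale(self, rng):
        # Mean next-generation frequency equals the parental frequency.
        p0, reps = 0.3, 500
        params = DemographyParams(carrying_capacity=20, extinction_rate=0.0, mutation_rate=0.0)
        means = []
        for _ in range(reps):
            pop = hwe_population(20, 25, p0, rng)
            start = float(allele_frequencies(pop).mean())
            nxt, _ = step_generation(pop, params, rng)
            means.append(float(allele_frequencies(nxt).mean()) - start)
        drift = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(drift) < 3 * max(se, 1e-6)

    def test_fused_step_matches_literal_composition(self, rng):
        """step_generation culls before genotype synthesis; its census and Ho
        moments must match the literal reproduce -> mutate -> regulate chain."""
        params = DemographyParams(
            fecundity_mean=5.0, carrying_capacity=60, extinction_rate=0.0, mutation_rate=0.01
        )
        trials = 400
        fused_census, fused_ho = [], []
        composed_census, composed_ho = [], []
        for _ in range(trials):
            pop = hwe_population(30, 40, 0.4, rng)
            nxt, record = step_generation(pop, params, rng)
            fused_census.append(record.census)
            if record.alive:
                fused_ho.append(observed_heterozygosity(nxt))
            off = reproduce(pop, params, rng)
            off = mutate(off, params.mutation_rate, rng)
            off = regulate(off, params, pop.size, rng)
            composed_census.append(off.size)
            if off.size:
                composed_ho.append(observed_heterozygosity(off))
        for a, b in ((fused_census, composed_census), (fused_ho, composed_ho)):
            a, b = np.asarray(a, float), np.asarray(b, float)
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert abs(a.mean() - b.mean()) < 4 * max(se, 1e-9)
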
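"""YAML run configuration: the machine form of the simulation-scheme diagram.

A config names the source recipe, the grid axes (propagule sizes, target
heterozygosities, extinction rates), the demographic constants and the
replicate/generation counts.  ``load_config`` validates strictly — unknown
keys are rejected by name — and the packaged ``study.yaml`` reproduces the
study design: a 4 × 3 × 4 grid (propagules 2/10/100/1,000 × Ho 0.5/0.3/0.1 ×
extinction 2/5/10/20%), 20 replicates, 30 generations, fecundity 100,
K = 96,000, mutation 5e-6, 5,000 loci.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .demography import DemographyParams
from .scenario import ScenarioSpec
from .source import SourceSpec

__all__ = ["RunConfig", "load_config", "default_config", "config_to_dict"]


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run description."""

    source: SourceSpec
    propagule_sizes: Sequence[int]
    target_ho: Sequence[float]
    extinction_rates: Sequence[float]
    demography: DemographyParams
    n_replicates: int = 20
    n_generations: int = 30
    sex_balance: bool = True
    survival_only: bool = False
    output_dir: str = "runs/invasim"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.propagule_sizes or not self.target_ho or not self.extinction_rates:
            raise ValueError("grid axes must be non-empty lists")
        for n in self.propagule_sizes:
            if n < 2:
                raise ValueError(f"propagule size {n} below the minimum mating pair of 2")
        for ho in self.target_ho:
            if not 0.0 <= ho <= 0.5:
                raise ValueError(f"target_ho {ho} outside [0, 0.5]")
        for e in self.extinction_rates:
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"extinction_rate {e} outside [0, 1]")
        if self.n_replicates < 1 or self.n_generations < 1:
            raise ValueError("n_replicates and n_generations must be >= 1")

    def scenarios(self) -> list[ScenarioSpec]:
        """Expand the grid axes into one ScenarioSpec per cell."""
        specs = []
        for ho in self.target_ho:
            for n in self.propagule_sizes:
                for e in self.extinction_rates:
                    demo = dataclasses.replace(self.demography, extinction_rate=e)
                    specs.append(
                        ScenarioSpec(
                            propagule_size=n,
                            target_ho=ho,
                            demography=demo,
                            n_generations=self.n_generations,
                            n_replicates=self.n_replicates,
                            sex_balance=self.sex_balance,
                            base_seed=self.base_seed,
                        )
                    )
        return specs


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def _build(raw: Mapping[str, Any]) -> RunConfig:
    _check_keys(
        raw,
        {
            "source", "grid", "demography", "n_replicates", "n_generations",
            "sex_balance", "survival_only", "output_dir", "base_seed",
        },
        "top level",
    )
    src = dict(raw.get("source", {}))
    _check_keys(
        src,
        {"n_source", "n_loci", "frequency_mode", "burn_in_generations", "mutation_rate", "seed"},
        "source",
    )
    grid = dict(raw.get("grid", {}))
    _check_keys(grid, {"propagule_sizes", "target_ho", "extinction_rates"}, "grid")
    demo = dict(raw.get("demography", {}))
    _check_keys(
        demo,
        {"fecundity_mean", "carrying_capacity", "growth_mode", "logistic_r", "mutation_rate"},
        "demography",
    )
    base_seed = int(raw.get("base_seed", 0))
    demography = DemographyParams(**demo)
    # target_ho on SourceSpec is per-Ho-level; stored at 0 here and replaced
    # per grid cell when sources are built.
    source = SourceSpec(
        target_ho=0.0,
        n_source=int(src.get("n_source", 10_000)),
        n_loci=int(src.get("n_loci", 5_000)),
        frequency_mode=src.get("frequency_mode", "two-point"),
        burn_in_generations=int(src.get("burn_in_generations", 0)),
        mutation_rate=float(src.get("mutation_rate", demography.mutation_rate)),
        seed=int(src.get("seed", base_seed)),
    )
    return RunConfig(
        source=source,
        propagule_sizes=tuple(int(n) for n in grid.get("propagule_sizes", ())),
        target_ho=tuple(float(h) for h in grid.get("target_ho", ())),
        extinction_rates=tuple(float(e) for e in grid.get("extinction_rates", ())),
        demography=demography,
        n_replicates=int(raw.get("n_replicates", 20)),
        n_generations=int(raw.get("n_generations", 30)),
        sex_balance=bool(raw.get("sex_balance", True)),
        survival_only=bool(raw.get("survival_only", False)),
        output_dir=str(raw.get("output_dir", "runs/invasim")),
        base_seed=base_seed,
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} is not a YAML mapping")
    return _build(raw)


def default_config() -> RunConfig:
    """The packaged study-design config (4 × 3 × 4 grid, 20 replicates)."""
    text = resources.files("invasim.configs").joinpath("study.yaml").read_text()
    return _build(yaml.safe_load(text))


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    """Round-trippable plain-dict form (the manifest / YAML layout)."""
    return {
        "source": {
            "n_source": config.source.n_source,
            "n_loci": config.source.n_loci,
            "frequency_mode": config.source.frequency_mode,
            "burn_in_generations": config.source.burn_in_generations,
            "mutation_rate": config.source.mutation_rate,
            "seed": config.source.seed,
        },
        "grid": {
            "propagule_sizes": list(config.propagule_sizes),
            "target_ho": list(config.target_ho),
            "extinction_rates": list(config.extinction_rates),
        },
        "demography": {
            "fecundity_mean": config.demography.fecundity_mean,
            "carrying_capacity": config.demography.carrying_capacity,
            "growth_mode": config.demography.growth_mode,
            "logistic_r": config.demography.logistic_r,
            "mutation_rate": config.demography.mutation_rate,
        },
        "n_replicates": config.n_replicates,
        "n_generations": config.n_generations,
        "sex_balance": config.sex_balance,
        "survival_only": config.survival_only,
        "output_dir": config.output_dir,
        "base_seed": config.base_seed,
    }
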
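"""The factorial invasion experiment: propagule size × initial Ho × extinction rate.

A *scenario cell* fixes one combination of propagule size, source
heterozygosity and per-generation extinction rate.  Each of its replicates
samples a fresh propagule from the (shared) source population, then steps the
life cycle for 30 generations or until extinction, recording census and
observed heterozygosity each generation.  The two response surfaces of the
study are computed from the resulting trajectories:

* **survival rate** at generation t — the fraction of replicates still alive;
* **retention** at generation t — the mean, over replicates alive at t, of
  ``Ho_t / Ho_0`` where ``Ho_0`` is the founding propagule's observed
  heterozygosity.  Conditioning on survival is explicit: the survivor count
  is always reported alongside the mean.

Replicate seeds are derived deterministically from
``(base_seed, scenario_id, replicate_index)``, so any single trajectory can
be reproduced in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .demography import DemographyParams, step_generation
from .population import FEMALE, MALE, Population, observed_heterozygosity
from .source import SourceSpec, build_source_population

__all__ = [
    "ScenarioSpec",
    "Trajectory",
    "GridResult",
    "RetentionResult",
    "sample_propagule",
    "run_replicate",
    "run_grid",
    "survival_rate",
    "retention",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid."""

    propagule_size: int
    target_ho: float
    demography: DemographyParams
    n_generations: int = 30
    n_replicates: int = 20
    sex_balance: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.propagule_size < 2:
            raise ValueError("propagule_size must be >= 2")
        if self.n_generations < 1 or self.n_replicates < 1:
            raise ValueError("n_generations and n_replicates must be >= 1")

    @property
    def scenario_id(self) -> str:
        return (
            f"n{self.propagule_size}_ho{self.target_ho:g}"
            f"_e{self.demography.extinction_rate:g}"
        )

    def replicate_rng(self, replicate_index: int) -> np.random.Generator:
        """Deterministic per-replicate generator derived from
        (base_seed, scenario_id, replicate_index)."""
        tag = zlib.crc32(self.scenario_id.encode())
        ss = np.random.SeedSequence([self.base_seed, tag, replicate_index])
        return np.random.default_rng(ss)


@dataclass
class Trajectory:
    """Per-generation record of one replicate.

    Arrays cover generations 0..T.  After extinction the census stays 0, the
    alive flag stays False and Ho is NaN; ``cause`` is non-empty only at the
    generation the replicate died.
    """

    scenario_id: str
    replicate: int
    founder_ho: float
    census: np.ndarray
    ho: np.ndarray
    alive: np.ndarray
    cause: list[str] = field(repr=False)

    @property
    def n_generations(self) -> int:
        return len(self.census) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario_id": self.scenario_id,
                "replicate": self.replicate,
                "generation": np.arange(len(self.census)),
                "census": self.census,
                "ho": self.ho,
                "alive": self.alive,
                "cause": self.cause,
                "founder_ho": self.founder_ho,
            }
        )


@dataclass(frozen=True)
class RetentionResult:
    """Retention summary at one generation; ``mean`` is NaN when no replicate
    survived (a distinguished outcome, not zero retention)."""

    mean: float
    per_replicate: np.ndarray
    n_survivors: int

    @property
    def no_survivors(self) -> bool:
        return self.n_survivors == 0


class GridResult:
    """All trajectories of a grid run plus the scenario specs that produced them."""

    def __init__(self, specs: Sequence[ScenarioSpec], trajectories: Iterable[Trajectory]):
        self.specs: Mapping[str, ScenarioSpec] = {s.scenario_id: s for s in specs}
        self.trajectories = list(trajectories)
        frames = [t.to_frame() for t in self.trajectories]
        self.frame = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=[
                    "scenario_id", "replicate", "generation", "census",
                    "ho", "alive", "cause", "founder_ho",
                ]
            )
        )

    def _cell(self, scenario_id: str) -> pd.DataFrame:
        if scenario_id not in self.specs:
            raise KeyError(f"unknown scenario {scenario_id!r}")
        return self.frame[self.frame["scenario_id"] == scenario_id]

    def survival_curve(self, scenario_id: str) -> np.ndarray:
        """Empirical survival fraction at each generation 0..T."""
        cell = self._cell(scenario_id)
        return (
            cell.groupby("generation")["alive"].mean().sort_index().to_numpy(dtype=float)
        )

    def summary(self) -> pd.DataFrame:
        """Per scenario × generation: survival rate, mean retention among
        survivors, survivor count, and mean census among survivors."""
        rows = []
        for sid, spec in self.specs.items():
            cell = self._cell(sid)
            for gen, sub in cell.groupby("generation"):
                alive = sub[sub["alive"]]
                ret = (
                    float((alive["ho"] / alive["founder_ho"]).mean())
                    if len(alive) and alive["ho"].notna().all()
                    else float("nan")
                )
                rows.append(
                    {
                        "scenario_id": sid,
                        "propagule_size": spec.propagule_size,
                        "target_ho": spec.target_ho,
                        "extinction_rate": spec.demography.extinction_rate,
                        "generation": int(gen),
                        "survival_rate": float(sub["alive"].mean()),
                        "n_survivors": int(sub["alive"].sum()),
                        "mean_retention": ret,
                        "mean_ho": float(alive["ho"].mean()) if len(alive) else float("nan"),
                        "mean_census": float(alive["census"].mean()) if len(alive) else 0.0,
                    }
                )
        return pd.DataFrame(rows)


def sample_propagule(
    source: Population,
    propagule_size: int,
    sex_balance: bool,
    rng: np.random.Generator,
) -> Population:
    """Found a propagule by sampling individuals from the source without replacement.

    With ``sex_balance`` the sample is stratified: ⌊n/2⌋ females and ⌈n/2⌉
    males, guaranteeing a mating pair even at n = 2.  Without it the sample
    is uniform over individuals and small propagules can be single-sex.
    """
    n = propagule_size
    if n > source.size:
        raise ValueError(f"propagule size {n} exceeds source census {source.size}")
    if sex_balance:
        females = np.flatnonzero(source.sexes == FEMALE)
        males = np.flatnonzero(source.sexes == MALE)
        n_f, n_m = n // 2, n - n // 2
        if n_f > len(females) or n_m > len(males):
            raise ValueError("source lacks enough individuals of one sex for a balanced propagule")
        idx = np.concatenate(
            [rng.choice(females, size=n_f, replace=False),
             rng.choice(males, size=n_m, replace=False)]
        )
    else:
        idx = rng.choice(source.size, size=n, replace=False)
    return Population(source.genotypes[idx], source.sexes[idx], generation_index=0)


def run_replicate(
    spec: ScenarioSpec, source: Population, replicate_index: int
) -> Trajectory:
    """Run one replicate of a scenario cell to 30 generations or extinction.

    Deterministic in (base_seed, scenario_id, replicate_index).
    """
    rng = spec.replicate_rng(replicate_index)
    pop = sample_propagule(source, spec.propagule_size, spec.sex_balance, rng)
    has_loci = pop.n_loci > 0
    founder_ho = observed_heterozygosity(pop) if has_loci else float("nan")

    T = spec.n_generations
    census = np.zeros(T + 1, dtype=np.int64)
    ho = np.full(T + 1, np.nan)
    alive = np.zeros(T + 1, dtype=bool)
    cause = [""] * (T + 1)

    census[0], alive[0] = pop.size, True
    ho[0] = founder_ho
    for t in range(1, T + 1):
        pop, record = step_generation(pop, spec.demography, rng)
        census[t] = record.census
        alive[t] = record.alive
        if not record.alive:
            cause[t] = record.cause or ""
            break
        if has_loci:
            ho[t] = observed_heterozygosity(pop)

    return Trajectory(
        scenario_id=spec.scenario_id,
        replicate=replicate_index,
        founder_ho=founder_ho,
        census=census,
        ho=ho,
        alive=alive,
        cause=cause,
    )


def _survival_only_source(n_source: int, seed: int) -> Population:
    rng = np.random.default_rng(seed)
    return Population(
        np.empty((n_source, 0, 2), dtype=np.int8),
        rng.integers(0, 2, size=n_source, dtype=np.int8),
        generation_index=0,
    )


def run_grid(
    specs: Sequence[ScenarioSpec],
    *,
    source_spec: Optional[SourceSpec] = None,
    sources: Optional[Mapping[float, Population]] = None,
    survival_only: bool = False,
    out_dir: Optional[Path] = None,
    progress: bool = False,
) -> GridResult:
    """Run every scenario cell × replicate of the grid.

    One source population is built per distinct target Ho (seeded from
    ``source_spec.seed``) and shared by that Ho level's cells; each replicate
    resamples its own propagule from it.  ``survival_only`` disables the
    genetics (zero loci), which makes large-replicate demographic runs cheap.
    If ``out_dir`` is given, trajectories are appended to
    ``out_dir/trajectories.csv`` as each replicate completes, so memory stays
    bounded for big grids.
    """
    if not specs:
        raise ValueError("empty scenario collection")
    ids = [s.scenario_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scenario ids in grid")

    pool: dict[float, Population] = dict(sources) if sources else {}
    stream_path: Optional[Path] = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stream_path = out_dir / "trajectories.csv"
        stream_path.unlink(missing_ok=True)

    trajectories: list[Trajectory] = []
    for spec in specs:
        key = spec.target_ho
        if key not in pool:
            if survival_only:
                base = source_spec.seed if source_spec is not None else 0
                n_src = max(
                    source_spec.n_source if source_spec is not None else 10_000,
                    2 * spec.propagule_size,
                )
                pool[key] = _survival_only_source(n_src, base + int(key * 1000))
            else:
                if source_spec is None:
                    raise ValueError("run_grid needs source_spec or explicit sources")
                from dataclasses import replace

                pool[key] = build_source_population(
                    replace(
                        source_spec,
                        target_ho=key,
                        seed=source_spec.seed + int(key * 1000),
                    )
                )
        source = pool[key]
        cell_trajs = [
            run_replicate(spec, source, rep) for rep in range(spec.n_replicates)
        ]
        trajectories.extend(cell_trajs)
        if stream_path is not None:
            frame = pd.concat([t.to_frame() for t in cell_trajs], ignore_index=True)
            frame.to_csv(
                stream_path, mode="a", header=not stream_path.exists() or stream_path.stat().st_size == 0, index=False
            )
        if progress:
            n_dead = sum(not t.alive[-1] for t in cell_trajs)
            print(
                f"{spec.scenario_id}: {spec.n_replicates} replicates, "
                f"{n_dead} extinct by generation {spec.n_generations}"
            )
    return GridResult(specs, trajectories)


def survival_rate(result: GridResult, scenario_id: str, t: int) -> float:
    """Fraction of a scenario's replicates alive at generation ``t``."""
    curve = result.survival_curve(scenario_id)
    if not 0 <= t < len(curve):
        raise ValueError(f"generation {t} outside 0..{len(curve) - 1}")
    return float(curve[t])


def retention(result: GridResult, scenario_id: str, t: int) -> RetentionResult:
    """Mean ``Ho_t / Ho_0`` over replicates alive at generation ``t``.

    Survivor count is reported alongside; with no survivors the mean is NaN
    (a distinguished outcome rather than zero).
    """
    cell = result._cell(scenario_id)
    sub = cell[(cell["generation"] == t) & cell["alive"]]
    if not 0 <= t <= result.specs[scenario_id].n_generations:
        raise ValueError(f"generation {t} outside scenario range")
    values = (sub["ho"] / sub["founder_ho"]).to_numpy(dtype=float)
    if len(values) == 0:
        return RetentionResult(float("nan"), values, 0)
    return RetentionResult(float(values.mean()), values, int(len(values)))
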
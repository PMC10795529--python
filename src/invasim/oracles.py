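"""Closed-form expectations used to verify the stochastic engine.

These are the textbook neutral-theory results for the model's three moving
parts, at expectation level:

* survival under an independent per-generation Bernoulli extinction lottery
  is geometric, ``S(t) = (1 - e)^t``;
* expected heterozygosity under pure drift through a census trajectory
  ``N_1, ..., N_t`` is retained by the factor ``prod_i (1 - 1/(2 N_i))``;
* the discrete logistic census map is
  ``N_{t+1} = N_t + r N_t (1 - N_t / K)``, rounded and capped at ``K``.

They form the trustable verification surface: the individual-based engine is
tested against them rather than against other simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["OracleCurve", "survival_curve", "he_retention_curve", "logistic_census"]


@dataclass(frozen=True)
class OracleCurve:
    """A per-generation expected-value curve; ``values[t]`` is generation ``t``."""

    kind: Literal["survival", "he_retention", "census"]
    values: np.ndarray
    params: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Tidy form matching the trajectory CSV schema (scenario_id = "oracle:<kind>")."""
        return pd.DataFrame(
            {
                "scenario_id": f"oracle:{self.kind}",
                "generation": np.arange(len(self.values)),
                "value": self.values,
            }
        )


def survival_curve(extinction_rate: float, n_generations: int) -> OracleCurve:
    """Geometric survival ``(1 - e)^t`` for t = 0..n_generations."""
    if not 0.0 <= extinction_rate <= 1.0:
        raise ValueError("extinction_rate must lie in [0, 1]")
    t = np.arange(n_generations + 1)
    return OracleCurve(
        "survival", (1.0 - extinction_rate) ** t, {"extinction_rate": extinction_rate}
    )


def he_retention_curve(census_trajectory: Sequence[int]) -> OracleCurve:
    """Expected He retained relative to the source: ``prod_{i<=t} (1 - 1/(2 N_i))``.

    ``census_trajectory`` lists the census sizes of generations 1..T; the
    returned curve has T+1 entries with value 1 at generation 0.
    """
    census = np.asarray(census_trajectory, dtype=float)
    if census.size and census.min() < 1:
        raise ValueError("census trajectory must be >= 1 everywhere (no extinct generations)")
    factors = 1.0 - 1.0 / (2.0 * census)
    values = np.concatenate([[1.0], np.cumprod(factors)])
    return OracleCurve("he_retention", values, {"n_generations": float(census.size)})


def logistic_census(n0: int, r: float, carrying_capacity: int, n_generations: int) -> OracleCurve:
    """Iterate the discrete logistic map from ``n0`` (values for t = 0..T)."""
    if n0 < 1 or carrying_capacity < 1 or r < 0:
        raise ValueError("need n0 >= 1, carrying_capacity >= 1, r >= 0")
    K = carrying_capacity
    values = np.empty(n_generations + 1)
    n = float(n0)
    values[0] = n
    for t in range(1, n_generations + 1):
        n = min(float(round(n + r * n * (1.0 - n / K))), float(K))
        values[t] = n
    return OracleCurve("census", values, {"n0": n0, "r": r, "carrying_capacity": K})
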
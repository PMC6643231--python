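"""Reaction-rate laws for the stochastic logistic birth-death model.

The model describes a self-limiting population as a continuous-time Markov
chain with two reactions:

* birth,  N -> N + 1, at rate ``b * N`` (asexual) or
  ``b * N * (1 - exp(-2 pi R^2 V N / 3))`` when reproduction requires a mate
  encounter (individuals moving at speed ``V`` detect mates within radius
  ``R``, assuming random motion in three dimensions);
* death,  N -> N - 1, at rate ``d * N**2`` (per-capita death rate grows
  linearly with density, giving logistic self-limitation).

The deterministic skeleton ``dN/dt = bN - dN^2`` has carrying capacity
``b/d``; the stochastic chain fluctuates around that density until a
fluctuation absorbs it at ``N = 0``.

All quantities are in dimensionless model units (density is individuals per
unit volume, time in units of the inverse birth rate scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SearchParams",
    "PopulationParams",
    "encounter_probability",
    "birth_event_rate",
    "death_event_rate",
    "immigration_event_rate",
    "prob_next_event_is_death",
    "deterministic_equilibrium",
]


@dataclass(frozen=True)
class SearchParams:
    """Mate-search ability: detection radius ``R`` and movement speed ``V``.

    The encounter kernel depends on R and V only through the product
    ``V * R**2``, so any reparameterization holding that product fixed is
    equivalent.
    """

    R: float
    V: float

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.V > 0):
            raise ValueError(
                f"search radius and speed must be positive, got R={self.R}, V={self.V}"
            )

    @property
    def encounter_coefficient(self) -> float:
        """Coefficient c in P(encounter) = 1 - exp(-c N), c = 2 pi R^2 V / 3."""
        return 2.0 * math.pi * self.R * self.R * self.V / 3.0


@dataclass(frozen=True)
class PopulationParams:
    """Demographic law of one taxon.

    b : intrinsic per-capita birth rate (individuals / individual / time)
    d : death-rate constant; per-capita death rate is d*N
    search : mate-search parameters; ``None`` means asexual reproduction
        (no mate limitation).
    """

    b: float
    d: float
    search: SearchParams | None = None

    def __post_init__(self) -> None:
        if not self.b >= 0:
            raise ValueError(f"birth rate b must be nonnegative, got {self.b}")
        if not self.d > 0:
            raise ValueError(f"death constant d must be positive, got {self.d}")

    @property
    def mate_limited(self) -> bool:
        return self.search is not None


def _check_size(N: float) -> None:
    if N < 0:
        raise ValueError(f"population size must be nonnegative, got {N}")


def encounter_probability(search: SearchParams, N: int | float) -> float:
    """Probability that an individual encounters at least one mate.

    ``P = 1 - exp(-2 pi R^2 V N / 3)`` for a population of density N whose
    members move randomly in three dimensions. Returns 0 at N=0 and
    saturates at 1 for large, fast or far-seeing populations.
    """
    _check_size(N)
    return -math.expm1(-search.encounter_coefficient * N)


def birth_event_rate(params: PopulationParams, N: int | float) -> float:
    """Population-level rate of the birth reaction N -> N+1.

    ``b*N`` for asexual taxa; multiplied by the mate-encounter probability
    when a :class:`SearchParams` is present. Always 0 at N=0 (absorbing).
    """
    _check_size(N)
    rate = params.b * N
    if params.search is not None:
        rate *= encounter_probability(params.search, N)
    return rate


def death_event_rate(params: PopulationParams, N: int | float) -> float:
    """Population-level rate of the death reaction N -> N-1: ``d * N**2``."""
    _check_size(N)
    return params.d * N * N


def immigration_event_rate(i: float, current_diversity: int, pool_size: int) -> float:
    """Community-level colonization rate ``(pool_size - S) * i``.

    Each of the ``pool_size`` potential colonists that is currently absent
    immigrates at per-taxon rate ``i``, so the aggregate rate declines
    linearly with current diversity S and hits 0 when the pool is full.
    """
    if i < 0:
        raise ValueError(f"immigration constant must be nonnegative, got {i}")
    if not 0 <= current_diversity <= pool_size:
        raise ValueError(
            f"diversity {current_diversity} outside [0, pool_size={pool_size}]"
        )
    return (pool_size - current_diversity) * i


def prob_next_event_is_death(params: PopulationParams, N: int | float) -> float:
    """P(next event is a death) = d_rate / (b_rate + d_rate) for a lone population.

    Undefined at N=0, where the population is already absorbed.
    """
    if N == 0:
        raise ValueError("next-event probability undefined at N=0 (absorbed state)")
    br = birth_event_rate(params, N)
    dr = death_event_rate(params, N)
    return dr / (br + dr)


def deterministic_equilibrium(params: PopulationParams) -> float | None:
    """Positive density where the birth and death rates balance.

    Asexual case: exactly ``b/d``. Mate-limited case: the largest positive
    root of ``b*P(N) = d*N`` found numerically (relative tolerance 1e-10).
    With strong mate limitation the curves may also cross at a low-density
    Allee threshold; the upper (stable) crossing is returned. ``None`` if no
    positive root exists.
    """
    if params.search is None:
        return params.b / params.d

    c = params.search.encounter_coefficient

    def f(n: float) -> float:
        # per-capita balance: b * P(n) - d * n
        return -params.b * math.expm1(-c * n) - params.d * n

    upper = 10.0 * params.b / params.d
    grid = np.linspace(1e-9, upper, 4096)
    vals = np.array([f(x) for x in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_changes) == 0:
        return None
    k = sign_changes[-1]  # upper crossing = stable equilibrium
    return float(brentq(f, grid[k], grid[k + 1], xtol=1e-12, rtol=1e-10))
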
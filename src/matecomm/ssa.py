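"""Exact stochastic simulation (Gillespie direct method).

Single populations follow the two-reaction birth-death chain of
:mod:`matecomm.rates`; communities couple one such chain per taxon with an
aggregate immigration reaction. All simulations are exact-SSA: one reaction
fires at a time, waiting times are exponential in the summed rates, and
each event consumes exactly two uniform draws (waiting time + reaction
selection). Identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .rates import PopulationParams

__all__ = [
    "Trajectory",
    "CommunityTimeSeries",
    "EventLog",
    "StalledSimulationWarning",
    "draw_next_event",
    "simulate_population",
    "simulate_community",
]

EVENT_KIND_LABELS = ("birth", "death", "immigration", "extinction")


class StalledSimulationWarning(UserWarning):
    """All reaction rates hit zero before the schedule completed."""


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce a seed or Generator to a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    # numba's legacy MT seeding wants a modest positive int
    return int(rng.integers(1, 2**31 - 1))


@dataclass
class Trajectory:
    """Event-time series of one population.

    ``times[0] == 0`` with ``sizes[0]`` the initial size; each subsequent
    entry is the state just after an event. ``extinction_time`` is None for
    censored runs.
    """

    times: np.ndarray
    sizes: np.ndarray
    extinction_time: float | None
    censored: bool
    params: PopulationParams | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "size": self.sizes})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EventLog:
    """Chronological record of discrete community events.

    ``kinds`` holds integer codes indexing :data:`EVENT_KIND_LABELS`.
    Birth/death records are present only when the simulation was run with
    ``record_events=True``; immigration and extinction records are always
    kept (extinction = the death that emptied a population).
    """

    times: np.ndarray
    taxa: np.ndarray
    kinds: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def extinction_times(self) -> np.ndarray:
        return self.times[self.kinds == _kernels.KIND_EXTINCTION]

    @property
    def immigration_times(self) -> np.ndarray:
        return self.times[self.kinds == _kernels.KIND_IMMIGRATION]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "taxon": self.taxa,
                "event": [EVENT_KIND_LABELS[k] for k in self.kinds],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CommunityTimeSeries:
    """Sampled abundance vectors of a taxon pool (rows = samples)."""

    abundances: np.ndarray  # (n_samples, pool_size) int
    sample_times: np.ndarray
    sample_events: np.ndarray  # cumulative event count at each sample
    b_values: np.ndarray  # per-taxon intrinsic birth rates
    stalled: bool = False
    total_events: int = 0
    final_time: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def pool_size(self) -> int:
        return self.abundances.shape[1]

    def diversity(self) -> np.ndarray:
        """Richness (count of extant taxa) per sample."""
        return (self.abundances > 0).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.abundances,
            columns=[f"taxon_{k}" for k in range(self.pool_size)],
        )
        df.insert(0, "event_count", self.sample_events)
        df.insert(0, "time", self.sample_times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def draw_next_event(
    rates: Sequence[float], rng: np.random.Generator | int | None
) -> tuple[float, int]:
    """One step of the Gillespie direct method.

    Draws the exponential waiting time until the next reaction and selects
    which reaction fires, consuming exactly two uniforms: ``dt =
    -log(1-u1)/total`` and the index k with probability ``rates[k]/total``.
    """
    rng = as_rng(rng)
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("reaction rates must be nonnegative")
    total = rates.sum()
    if total <= 0:
        raise RuntimeError("all reaction rates are zero: the system is stalled")
    u1, u2 = rng.random(2)
    dt = -np.log1p(-u1) / total
    index = int(np.searchsorted(np.cumsum(rates), u2 * total, side="right"))
    return dt, min(index, len(rates) - 1)


def simulate_population(
    params: PopulationParams,
    n0: int,
    rng: np.random.Generator | int | None = None,
    t_max: float = 1e6,
    record: bool = True,
) -> Trajectory:
    """Simulate one population until absorption at N=0 or censoring at t_max.

    Birth and death rates are updated after every event. With
    ``record=False`` only the endpoint is kept (faster for extinction-time
    work; see :mod:`matecomm.mte` for batched replicates).
    """
    if n0 < 1:
        raise ValueError(f"initial size must be >= 1, got {n0}")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = as_rng(rng)
    c = params.search.encounter_coefficient if params.search is not None else 0.0
    times, sizes, t_final, censored = _kernels.population_kernel(
        params.b, params.d, c, n0, t_max, _kernel_seed(rng), record
    )
    return Trajectory(
        times=times,
        sizes=sizes,
        extinction_time=None if censored else t_final,
        censored=bool(censored),
        params=params,
    )


def simulate_community(
    pool: Sequence[PopulationParams],
    i: float,
    colonize_size: int,
    schedule: tuple[int, int, int],
    rng: np.random.Generator | int | None = None,
    record_events: bool = False,
) -> tuple[CommunityTimeSeries, EventLog]:
    """Simulate a coupled multi-taxon reaction network with immigration.

    Parameters
    ----------
    pool
        Demographic parameters of every potential colonist. Extinct taxa
        may recolonize with their original parameters.
    i
        Per-taxon immigration constant; the aggregate immigration rate is
        ``(len(pool) - diversity) * i`` and a firing sets one uniformly
        chosen absent taxon to ``colonize_size``.
    schedule
        ``(burn_in_events, sample_interval_events, n_samples)``: abundance
        snapshots are taken every ``sample_interval_events`` after the
        burn-in, counted in events, not time.
    record_events
        Keep birth/death records in the event log (memory-heavy for long
        schedules). Immigrations and extinctions are always logged.

    The community starts empty; if every rate reaches zero (possible only
    with ``i == 0``) the run terminates early with a
    :class:`StalledSimulationWarning` and the samples collected so far.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("taxon pool must be nonempty")
    if colonize_size < 1:
        raise ValueError("colonize_size must be >= 1")
    burn_in, interval, n_samples = (int(x) for x in schedule)
    if burn_in < 0 or interval <= 0 or n_samples <= 0:
        raise ValueError(f"invalid schedule {schedule}")
    if i < 0:
        raise ValueError("immigration constant must be nonnegative")
    rng = as_rng(rng)

    b_vec = np.array([p.b for p in pool], dtype=float)
    d_vec = np.array([p.d for p in pool], dtype=float)
    c_vec = np.array(
        [p.search.encounter_coefficient if p.search is not None else 0.0 for p in pool],
        dtype=float,
    )

    (
        samples,
        sample_times,
        sample_events,
        n_sampled,
        log_t,
        log_taxon,
        log_kind,
        _n_log,
        stalled,
        events,
        t_final,
    ) = _kernels.community_kernel(
        b_vec,
        d_vec,
        c_vec,
        float(i),
        int(colonize_size),
        burn_in,
        interval,
        n_samples,
        _kernel_seed(rng),
        record_events,
    )
    if stalled:
        warnings.warn(
            f"community stalled (all rates zero) after {events} events at "
            f"t={t_final:.6g}; collected {n_sampled}/{n_samples} samples",
            StalledSimulationWarning,
            stacklevel=2,
        )
    ts = CommunityTimeSeries(
        abundances=samples[:n_sampled],
        sample_times=sample_times[:n_sampled],
        sample_events=sample_events[:n_sampled],
        b_values=b_vec,
        stalled=bool(stalled),
        total_events=int(events),
        final_time=float(t_final),
    )
    log = EventLog(times=log_t, taxa=log_taxon, kinds=log_kind)
    return ts, log
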
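"""Forward-time individual-based simulation of nest-height evolution under
stochastic flooding.

The model population is haploid and asexual, with discrete non-overlapping
generations (an overlapping-generations variant is available).  Each
individual carries a heritable nest-height phenotype ``z`` on [0, 1].
Nesting low is safer from aerial predators — per-attempt reproductive
success declines linearly with height — but floods destroy every nest below
the water level ``h``:

    W(z; h) = 1 - z   if z >= h
              0       if z <  h

Each generation consists of ``n`` breeding attempts.  A population-wide
flood occurs independently in each attempt with probability ``p``; during a
flood, each nest is independently affected with probability ``s`` (the
event's *scope*).  Lifetime reproductive success is the sum of
``c * W(z; h_ik)`` over attempts, rounded once to the nearest integer (half
up), where ``c`` is the maximum clutch size.  Offspring inherit the parental
phenotype, mutating with probability ``m`` by a Normal(0, m_size) deviate
clamped to [0, 1], and are culled uniformly at random down to the carrying
capacity ``K``.

All stochasticity flows through a single ``numpy.random.Generator`` per
replicate, consumed in a fixed order (flood draws, then per-attempt scope
draws, then mutation, then adult survival under the overlap variant, then
recruitment), so a seed fully determines a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentRegime",
    "LifeHistory",
    "SimulationConfig",
    "FloodSchedule",
    "PopulationState",
    "ReplicateResult",
    "nest_fitness",
    "draw_flood_schedule",
    "lifetime_reproductive_success",
    "mutate_offspring",
    "recruit",
    "initialize_population",
    "step_generation",
    "run_replicate",
]


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class EnvironmentRegime:
    """Flooding regime: per-attempt frequency ``p``, scope ``s``, height ``h``.

    ``flood_height_sd`` switches on the time-varying flood-height variant:
    each realized flood height is drawn from a normal centred on ``h`` with
    this standard deviation, truncated to [0, 1].  ``None`` (default) keeps
    flood height constant.
    """

    p: float = 0.1
    s: float = 1.0
    h: float = 0.4
    flood_height_sd: Optional[float] = None

    def __post_init__(self) -> None:
        _check_probability("p", self.p)
        _check_probability("s", self.s)
        _check_probability("h", self.h)
        if self.flood_height_sd is not None and self.flood_height_sd <= 0:
            raise ValueError("flood_height_sd must be positive when set")


@dataclass(frozen=True)
class LifeHistory:
    """Breeding attempts per lifetime ``n`` and clutch constant ``c``.

    ``overlap`` enables overlapping generations: adults survive to the next
    year with probability ``adult_survival`` and count against the carrying
    capacity together with recruits.  With ``adult_mortality`` set, floods
    additionally kill adults whose nest was destroyed (by default extremes
    affect only nestling survival).
    """

    n: int = 1
    c: float = 5.0
    overlap: bool = False
    adult_survival: float = 0.5
    adult_mortality: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        _check_probability("adult_survival", self.adult_survival)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete configuration of one simulation replicate."""

    regime: EnvironmentRegime = field(default_factory=EnvironmentRegime)
    life_history: LifeHistory = field(default_factory=LifeHistory)
    n0: int = 5000
    k: int = 5000
    m: float = 0.001
    m_size: float = 0.05
    generations: int = 2000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("n0 must be non-negative")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        _check_probability("m", self.m)
        if not self.m_size > 0:
            raise ValueError("m_size must be positive")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class FloodSchedule:
    """Realized population-wide flood indicators for one generation.

    ``flooded[k]`` says whether breeding attempt ``k`` saw a flood;
    ``heights[k]`` is the realized water level of that event (0 where no
    flood occurred).
    """

    flooded: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        if self.flooded.shape != self.heights.shape:
            raise ValueError("flooded and heights must have equal length")
        if np.any(self.heights < 0) or np.any(self.heights > 1):
            raise ValueError("flood heights must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationState:
    """Phenotype vector (plus ages under the overlap variant) at one
    generation."""

    phenotypes: np.ndarray
    generation: int = 0
    ages: Optional[np.ndarray] = None

    @property
    def size(self) -> int:
        return int(self.phenotypes.size)

    @property
    def extinct(self) -> bool:
        return self.size == 0


@dataclass
class ReplicateResult:
    """Per-generation summaries of a single replicate run.

    Trajectories include the initial generation and are truncated at
    extinction.  ``flood_events`` logs every realized flood as
    (generation, attempt, height) rows.
    """

    mean_z: np.ndarray
    sd_z: np.ndarray
    pop_size: np.ndarray
    extinct: bool
    extinction_generation: Optional[int]
    seed: Optional[int]
    config: SimulationConfig
    flood_events: np.ndarray
    final_state: PopulationState = field(repr=False, default=None)

    @property
    def final_mean_z(self) -> float:
        return float(self.mean_z[-1])

    def trajectory(self) -> pd.DataFrame:
        """Long-format trajectory: generation, mean_z, sd_z, pop_size."""
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.mean_z)),
                "mean_z": self.mean_z,
                "sd_z": self.sd_z,
                "pop_size": self.pop_size,
            }
        )


def nest_fitness(z, water_level):
    """Per-attempt reproductive success: ``1 - z`` above water, 0 below.

    ``water_level = 0`` encodes "no flood", leaving only the linear
    predation cost of nesting high.  Accepts scalars or arrays.
    """
    zv = np.asarray(z, dtype=float)
    if np.any(zv < 0) or np.any(zv > 1):
        raise ValueError("phenotype z must lie in [0, 1]")
    out = np.where(zv >= water_level, 1.0 - zv, 0.0)
    return float(out) if np.isscalar(z) else out


def draw_flood_schedule(
    regime: EnvironmentRegime, n: int, rng: np.random.Generator
) -> FloodSchedule:
    """Draw the n independent population-wide flood indicators of one
    generation, with realized heights.

    Heights are the constant ``regime.h`` unless the time-varying variant is
    enabled, in which case each event's height is a truncated normal on
    [0, 1] centred on ``h``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    flooded = rng.random(n) < regime.p
    heights = np.zeros(n)
    k = int(flooded.sum())
    if k:
        if regime.flood_height_sd is None:
            heights[flooded] = regime.h
        else:
            draws = rng.normal(regime.h, regime.flood_height_sd, size=k)
            # redraw out-of-range heights: truncation, not clamping, so no
            # probability mass piles up at the boundaries
            bad = (draws < 0) | (draws > 1)
            while np.any(bad):
                draws[bad] = rng.normal(regime.h, regime.flood_height_sd, int(bad.sum()))
                bad = (draws < 0) | (draws > 1)
            heights[flooded] = draws
    return FloodSchedule(flooded=flooded, heights=heights)


def lifetime_reproductive_success(
    z: float,
    schedule: FloodSchedule,
    s: float,
    c: float,
    rng: np.random.Generator,
) -> int:
    """Integer lifetime reproductive success of one individual.

    For each flooded attempt the nest is independently affected with
    probability ``s``; an affected nest experiences the flood's water level,
    an unaffected (or unflooded) one experiences level 0.  The summed clutch
    output ``sum_k c * W(z; h_k)`` is rounded once, half away from zero
    upward.
    """
    total = 0.0
    for k in range(schedule.flooded.size):
        level = 0.0
        if schedule.flooded[k] and rng.random() < s:
            level = float(schedule.heights[k])
        total += c * nest_fitness(z, level)
    return int(np.floor(total + 0.5))


def _reproduce(
    z: np.ndarray,
    schedule: FloodSchedule,
    s: float,
    c: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Eq-5 fitness for a whole population.

    Returns integer offspring counts and the mask of individuals whose nest
    was destroyed in at least one attempt (used by the adult-mortality
    variant).  Scope draws consume one uniform vector per flooded attempt.
    """
    base = c * (1.0 - z)
    w = np.zeros_like(z)
    nest_destroyed = np.zeros(z.size, dtype=bool)
    for k in range(schedule.flooded.size):
        if schedule.flooded[k]:
            affected = rng.random(z.size) < s
            destroyed = affected & (z < schedule.heights[k])
            w += np.where(destroyed, 0.0, base)
            nest_destroyed |= destroyed
        else:
            w += base
    counts = np.floor(w + 0.5).astype(np.int64)
    return counts, nest_destroyed


def mutate_offspring(
    parent_z: float, m: float, m_size: float, rng: np.random.Generator
) -> float:
    """Offspring phenotype: parental value, mutated with probability ``m``
    by a Normal(0, m_size) deviate and clamped to [0, 1]."""
    if rng.random() < m:
        return float(np.clip(parent_z + rng.normal(0.0, m_size), 0.0, 1.0))
    return float(parent_z)


def _mutate(
    z: np.ndarray, m: float, m_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized mutation: mask draw first, then deviates for mutants only."""
    if z.size == 0 or m == 0.0:
        return z
    mutate = rng.random(z.size) < m
    k = int(mutate.sum())
    if k:
        z = z.copy()
        z[mutate] = np.clip(z[mutate] + rng.normal(0.0, m_size, k), 0.0, 1.0)
    return z


def recruit(
    offspring: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Cap recruitment at the carrying capacity by uniform random removal.

    Offspring from different nesting attempts compete equally; when the pool
    exceeds ``k``, a uniform subset of exactly ``k`` survives.
    """
    if k < 0:
        raise ValueError("carrying capacity must be non-negative")
    if offspring.size <= k:
        return offspring
    idx = rng.choice(offspring.size, size=k, replace=False)
    idx.sort()
    return offspring[idx]


def initialize_population(
    config: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """Found the population: n0 individuals with z ~ Uniform(0, 1)."""
    z = rng.random(config.n0)
    ages = np.zeros(config.n0, dtype=np.int64) if config.life_history.overlap else None
    return PopulationState(phenotypes=z, generation=0, ages=ages)


def _step(
    state: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[PopulationState, Optional[FloodSchedule]]:
    if state.extinct:
        return (
            PopulationState(
                phenotypes=state.phenotypes,
                generation=state.generation + 1,
                ages=state.ages,
            ),
            None,
        )
    lh = config.life_history
    regime = config.regime
    z = state.phenotypes
    schedule = draw_flood_schedule(regime, lh.n, rng)
    counts, nest_destroyed = _reproduce(z, schedule, regime.s, lh.c, rng)
    offspring = np.repeat(z, counts)
    offspring = _mutate(offspring, config.m, config.m_size, rng)
    if lh.overlap:
        survive = rng.random(z.size) < lh.adult_survival
        if lh.adult_mortality:
            survive &= ~nest_destroyed
        adults = z[survive]
        adult_ages = state.ages[survive] + 1
        room = max(config.k - adults.size, 0)
        recruits = recruit(offspring, room, rng)
        new_z = np.concatenate([adults, recruits])
        new_ages = np.concatenate(
            [adult_ages, np.zeros(recruits.size, dtype=np.int64)]
        )
    else:
        new_z = recruit(offspring, config.k, rng)
        new_ages = None
    return (
        PopulationState(
            phenotypes=new_z, generation=state.generation + 1, ages=new_ages
        ),
        schedule,
    )


def step_generation(
    state: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """Advance the population one generation.

    One shared flood schedule, per-individual integer reproductive success,
    independent mutation of every offspring, recruitment to at most ``k``.
    Stepping an extinct population returns an empty population.
    """
    new_state, _ = _step(state, config, rng)
    return new_state


def run_replicate(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    initial_state: Optional[PopulationState] = None,
    generations: Optional[int] = None,
) -> ReplicateResult:
    """Run one replicate and record per-generation summaries.

    When ``rng`` is omitted a fresh generator is seeded from
    ``config.seed``.  ``initial_state`` allows continuing an earlier run
    (used by the two-stage climate-change experiments); ``generations``
    overrides the configured run length.  The run stops early at extinction,
    recording the extinction generation as the final trajectory row.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gens = config.generations if generations is None else generations
    state = initial_state if initial_state is not None else initialize_population(
        config, rng
    )

    mean_z, sd_z, pop_size = [], [], []
    events: list[tuple[int, int, float]] = []

    def record(st: PopulationState) -> None:
        if st.size:
            mean_z.append(float(st.phenotypes.mean()))
            sd_z.append(float(st.phenotypes.std()))
        else:
            mean_z.append(np.nan)
            sd_z.append(np.nan)
        pop_size.append(st.size)

    record(state)
    extinct = state.extinct
    extinction_generation = state.generation if extinct else None
    for _ in range(gens):
        if extinct:
            break
        state, schedule = _step(state, config, rng)
        if schedule is not None:
            for att in np.flatnonzero(schedule.flooded):
                events.append(
                    (state.generation, int(att), float(schedule.heights[att]))
                )
        record(state)
        if state.extinct:
            extinct = True
            extinction_generation = state.generation
    return ReplicateResult(
        mean_z=np.asarray(mean_z),
        sd_z=np.asarray(sd_z),
        pop_size=np.asarray(pop_size, dtype=np.int64),
        extinct=extinct,
        extinction_generation=extinction_generation,
        seed=config.seed,
        config=config,
        flood_events=np.asarray(events, dtype=float).reshape(-1, 3),
        final_state=state,
    )
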
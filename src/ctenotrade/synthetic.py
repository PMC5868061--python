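"""Synthetic arena-experiment generator.

Emulates the blocked spawning design: animals are collected, measured
(oral/aboral axis to the nearest mm), sorted by size and grouped into
blocks of five so that size-dependent fecundity is balanced across
treatments.  Each block supplies one solitary animal, one free pair
(no barrier) and one permeable-barrier pair; sealed-barrier pairs are
size-matched separately, mirroring their independent collection.

The behavioural model of interest is conspecific suppression: when a
pair can exchange chemical cues, one partner (the "dominant", chosen by
fair coin or by size) spawns normally while the other's output is
binomially thinned with retention 1 - gamma.  gamma = 0 reproduces fully
independent spawning (the sealed-barrier situation); gamma = 1 silences
the suppressed partner entirely.  Egg drift across the perforated
barrier, and reduced viability of self-fertilised eggs, are layered on
top so downstream analyses see data with the same structure as the real
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .replicates import PairedSpawnReplicate, Treatment

__all__ = [
    "Animal",
    "Block",
    "SimulationConfig",
    "TreatmentAssignment",
    "SyntheticExperiment",
    "sample_animals",
    "form_blocks",
    "assign_treatments",
    "expected_fecundity",
    "draw_egg_count",
    "simulate_pair",
    "apply_drift",
    "simulate_viability",
    "generate_experiment",
    "simulate_permeable_pairs",
]

BLOCK_SIZE = 5

#: synthetic dates: the blocked arms and the sealed arm ran in different seasons
_BLOCK_DATE = "2016-08-01"
_SEALED_DATE = "2017-05-01"


@dataclass(frozen=True)
class Animal:
    animal_id: str
    size_mm: float

    def __post_init__(self) -> None:
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")


@dataclass(frozen=True)
class Block:
    """Five size-matched animals, ordered largest to smallest."""

    block_id: str
    animals: tuple[Animal, ...]

    def __post_init__(self) -> None:
        if len(self.animals) != BLOCK_SIZE:
            raise ValueError(f"a block holds exactly {BLOCK_SIZE} animals")
        sizes = [a.size_mm for a in self.animals]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("block animals must be size-sorted, largest first")


@dataclass(frozen=True)
class TreatmentAssignment:
    solitary: Animal
    no_barrier: tuple[Animal, Animal]
    permeable: tuple[Animal, Animal]


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    Size parameters follow the collected population (mean 38.8 mm,
    SD 6.7 mm, range 30-57 mm).  Fecundity is log-linear in body size
    with negative-binomial noise; the defaults put a ~39 mm animal at a
    few hundred eggs.  ``gamma`` is the suppression strength: the
    fraction of the non-dominant partner's eggs withheld when the pair
    can exchange cues.  ``drift_rate`` is the per-egg probability of
    crossing the permeable barrier overnight (measured at 2.3%).
    Self-fertilised eggs develop at ``viability_self`` < outcrossed
    ``viability_outcross``.
    """

    n_animals: int = 145
    n_sealed_pairs: int = 26
    size_mean_mm: float = 38.8
    size_sd_mm: float = 6.7
    size_min_mm: float = 30.0
    size_max_mm: float = 57.0
    fecundity_intercept: float = 3.5
    fecundity_slope_per_mm: float = 0.06
    dispersion: float = 1.0
    gamma: float = 0.75
    spawner_choice: str = "fair_coin"  # or "size_weighted"
    drift_rate: float = 0.023
    viability_outcross: float = 0.7
    viability_self: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 <= self.drift_rate <= 1.0:
            raise ValueError("drift_rate must be in [0, 1]")
        if not 0.0 <= self.viability_self < self.viability_outcross <= 1.0:
            raise ValueError(
                "need 0 <= viability_self < viability_outcross <= 1"
            )
        if self.size_min_mm >= self.size_max_mm:
            raise ValueError("size_min_mm must be below size_max_mm")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.spawner_choice not in ("fair_coin", "size_weighted"):
            raise ValueError("spawner_choice must be 'fair_coin' or 'size_weighted'")


@lru_cache(maxsize=64)
def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal location whose [lo, hi]-truncation has the given mean.

    The reported size statistics describe the *observed* (truncated)
    population, so the latent location must be solved for; with
    asymmetric bounds it differs from the target mean by over a mm.
    """

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    from scipy.optimize import brentq

    return float(brentq(lambda m: truncated_mean(m) - mean, lo - 3 * sd, hi + 3 * sd))


def _truncnorm(config: SimulationConfig):
    loc = _truncnorm_loc(
        config.size_mean_mm, config.size_sd_mm,
        config.size_min_mm, config.size_max_mm,
    )
    a = (config.size_min_mm - loc) / config.size_sd_mm
    b = (config.size_max_mm - loc) / config.size_sd_mm
    return stats.truncnorm(a, b, loc=loc, scale=config.size_sd_mm)


def _sample_sizes(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.size_sd_mm == 0:
        return np.full(n, round(config.size_mean_mm), dtype=float)
    raw = _truncnorm(config).rvs(size=n, random_state=rng)
    return np.round(raw)


def sample_animals(
    n: int, config: SimulationConfig, rng: np.random.Generator, prefix: str = "A"
) -> list[Animal]:
    """Draw ``n`` animals with sizes from the truncated-normal population,
    rounded to the nearest mm as in the measurement protocol."""
    if n < 0:
        raise ValueError("n must be >= 0")
    sizes = _sample_sizes(n, config, rng)
    return [Animal(f"{prefix}{i + 1:03d}", float(s)) for i, s in enumerate(sizes)]


def form_blocks(animals: list[Animal]) -> list[Block]:
    """Sort animals by size (largest first) and partition into blocks of 5.

    Any trailing remainder after sorting is dropped; the five largest
    animals form block 1, the next five block 2, and so on.
    """
    ordered = sorted(animals, key=lambda a: a.size_mm, reverse=True)
    n_blocks = len(ordered) // BLOCK_SIZE
    return [
        Block(
            block_id=f"B{i + 1:02d}",
            animals=tuple(ordered[i * BLOCK_SIZE : (i + 1) * BLOCK_SIZE]),
        )
        for i in range(n_blocks)
    ]


def assign_treatments(block: Block, rng: np.random.Generator) -> TreatmentAssignment:
    """Randomly allocate the five block members to the three in-block
    treatments: 1 solitary, 2 no-barrier, 2 permeable-barrier."""
    order = rng.permutation(BLOCK_SIZE)
    a = [block.animals[i] for i in order]
    return TreatmentAssignment(
        solitary=a[0], no_barrier=(a[1], a[2]), permeable=(a[3], a[4])
    )


def expected_fecundity(size_mm: float, config: SimulationConfig) -> float:
    """Mean egg count mu = exp(intercept + slope * size); reproductive
    output increases with body size when the slope is positive."""
    if size_mm <= 0:
        raise ValueError("size_mm must be positive")
    return float(
        np.exp(config.fecundity_intercept + config.fecundity_slope_per_mm * size_mm)
    )


# beyond this the negative binomial is numerically Poisson
_POISSON_DISPERSION = 1e8


def draw_egg_count(
    mu: float, dispersion: float, rng: np.random.Generator
) -> int:
    """Overdispersed egg count: negative binomial with mean ``mu`` and
    variance mu + mu^2 / dispersion (Poisson in the large-dispersion
    limit)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if dispersion >= _POISSON_DISPERSION:
        return int(rng.poisson(mu))
    p = dispersion / (dispersion + mu)
    return int(rng.negative_binomial(dispersion, p))


def simulate_pair(
    animal_1: Animal,
    animal_2: Animal,
    gamma: float,
    spawner_choice: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Spawn a pair under suppression strength ``gamma``.

    Both animals draw a baseline count from their size-dependent
    fecundity; one is designated dominant (fair coin, or probability
    proportional to size) and the other's count is binomially thinned
    with retention 1 - gamma.  gamma = 0 leaves both draws untouched.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    counts = [
        draw_egg_count(expected_fecundity(a.size_mm, config), config.dispersion, rng)
        for a in (animal_1, animal_2)
    ]
    if gamma == 0.0:
        return counts[0], counts[1]
    if spawner_choice == "size_weighted":
        p_first = animal_1.size_mm / (animal_1.size_mm + animal_2.size_mm)
    else:
        p_first = 0.5
    dominant = 0 if rng.random() < p_first else 1
    suppressed = 1 - dominant
    counts[suppressed] = int(rng.binomial(counts[suppressed], 1.0 - gamma))
    return counts[0], counts[1]


def apply_drift(
    eggs_a: int, eggs_b: int, drift_rate: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Let each egg independently cross the permeable barrier with
    probability ``drift_rate``; the combined total is conserved."""
    if not 0.0 <= drift_rate <= 1.0:
        raise ValueError("drift_rate must be in [0, 1]")
    if drift_rate == 0.0:
        return eggs_a, eggs_b
    a_to_b = int(rng.binomial(eggs_a, drift_rate))
    b_to_a = int(rng.binomial(eggs_b, drift_rate))
    return eggs_a - a_to_b + b_to_a, eggs_b - b_to_a + a_to_b


def simulate_viability(
    eggs: int, selfed: bool, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Number of eggs showing development 24 h post-fertilisation:
    binomial with the self- or outcross-viability probability."""
    if eggs < 0:
        raise ValueError("eggs must be >= 0")
    p = config.viability_self if selfed else config.viability_outcross
    return int(rng.binomial(eggs, p))


_CSV_COLUMNS = [
    "replicate_id", "treatment", "side", "animal_id", "size_mm",
    "eggs", "eggs_developed", "block_id", "date",
]


@dataclass
class SyntheticExperiment:
    """A complete simulated experiment in the long CSV layout (one row
    per arena side; undivided arenas use a single row with side A)."""

    rows: pd.DataFrame
    config: SimulationConfig

    def replicates(self, treatment: Treatment | str) -> list[PairedSpawnReplicate]:
        from .io import replicates_from_frame

        return replicates_from_frame(self.rows, treatment)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def generate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Simulate the full four-treatment experiment.

    Blocked arms: each block of five contributes one solitary arena
    (one combined count), one no-barrier pair (one combined count) and
    one permeable-barrier pair (two per-side counts, suppression gamma,
    drift across the barrier).  The sealed arm is generated separately
    from size-matched pairs with gamma = 0 and no drift; its eggs (like
    the solitary arm's) are self-fertilised, so they develop at the
    lower selfing viability.  Reproducible bit-for-bit from
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_animals, rng_assign, rng_spawn, rng_via, rng_sealed = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    animals = sample_animals(config.n_animals, config, rng_animals, prefix="A")
    blocks = form_blocks(animals)
    records: list[dict] = []

    def add(replicate_id, treatment, side, animal_id, size_mm, eggs, developed,
            block_id, date):
        records.append(dict(
            replicate_id=replicate_id, treatment=treatment, side=side,
            animal_id=animal_id, size_mm=size_mm, eggs=int(eggs),
            eggs_developed=int(developed), block_id=block_id, date=date,
        ))

    for block in blocks:
        assign = assign_treatments(block, rng_assign)

        sol = assign.solitary
        eggs = draw_egg_count(
            expected_fecundity(sol.size_mm, config), config.dispersion, rng_spawn
        )
        dev = simulate_viability(eggs, selfed=True, config=config, rng=rng_via)
        add(f"{block.block_id}-SOL", Treatment.SOLITARY.value, "A", sol.animal_id,
            sol.size_mm, eggs, dev, block.block_id, _BLOCK_DATE)

        nb1, nb2 = assign.no_barrier
        e1, e2 = simulate_pair(
            nb1, nb2, config.gamma, config.spawner_choice, config, rng_spawn
        )
        total = e1 + e2
        dev = simulate_viability(total, selfed=False, config=config, rng=rng_via)
        add(f"{block.block_id}-NB", Treatment.NO_BARRIER.value, "A",
            f"{nb1.animal_id}+{nb2.animal_id}",
            round((nb1.size_mm + nb2.size_mm) / 2, 1),
            total, dev, block.block_id, _BLOCK_DATE)

        pb1, pb2 = assign.permeable
        e1, e2 = simulate_pair(
            pb1, pb2, config.gamma, config.spawner_choice, config, rng_spawn
        )
        e1, e2 = apply_drift(e1, e2, config.drift_rate, rng_spawn)
        for side, animal, eggs_side in (("A", pb1, e1), ("B", pb2, e2)):
            dev = simulate_viability(eggs_side, selfed=False, config=config, rng=rng_via)
            add(f"{block.block_id}-PB", Treatment.PERMEABLE.value, side,
                animal.animal_id, animal.size_mm, eggs_side, dev,
                block.block_id, _BLOCK_DATE)

    # sealed arm: separately collected, size-matched pairs, no communication
    sealed_animals = sample_animals(
        2 * config.n_sealed_pairs, config, rng_sealed, prefix="S"
    )
    ordered = sorted(sealed_animals, key=lambda a: a.size_mm, reverse=True)
    for i in range(config.n_sealed_pairs):
        s1, s2 = ordered[2 * i], ordered[2 * i + 1]
        e1, e2 = simulate_pair(s1, s2, 0.0, config.spawner_choice, config, rng_sealed)
        for side, animal, eggs_side in (("A", s1, e1), ("B", s2, e2)):
            dev = simulate_viability(eggs_side, selfed=True, config=config, rng=rng_sealed)
            add(f"SB{i + 1:02d}", Treatment.SEALED.value, side, animal.animal_id,
                animal.size_mm, eggs_side, dev, None, _SEALED_DATE)

    rows = pd.DataFrame.from_records(records, columns=_CSV_COLUMNS)
    return SyntheticExperiment(rows=rows, config=config)


def simulate_permeable_pairs(
    n_pairs: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    gamma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised permeable-arm simulator for calibration studies.

    Reproduces the blocked structure (5*n_pairs animals, size-sorted
    into blocks, a random pair per block) and the suppression + drift
    model, returning per-side egg-count arrays.  Used by the power and
    type-I studies, where the full per-row experiment table would be
    needless overhead.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    g = config.gamma if gamma is None else gamma
    if not 0.0 <= g <= 1.0:
        raise ValueError("gamma must be in [0, 1]")

    sizes = np.sort(_sample_sizes(BLOCK_SIZE * n_pairs, config, rng))[::-1]
    sizes = sizes.reshape(n_pairs, BLOCK_SIZE)
    pick = rng.permuted(
        np.tile(np.arange(BLOCK_SIZE), (n_pairs, 1)), axis=1
    )[:, :2]
    s1 = np.take_along_axis(sizes, pick[:, :1], axis=1)[:, 0]
    s2 = np.take_along_axis(sizes, pick[:, 1:], axis=1)[:, 0]

    mu1 = np.exp(config.fecundity_intercept + config.fecundity_slope_per_mm * s1)
    mu2 = np.exp(config.fecundity_intercept + config.fecundity_slope_per_mm * s2)
    k = config.dispersion
    if k >= _POISSON_DISPERSION:
        e1 = rng.poisson(mu1)
        e2 = rng.poisson(mu2)
    else:
        e1 = rng.negative_binomial(k, k / (k + mu1))
        e2 = rng.negative_binomial(k, k / (k + mu2))

    if g > 0.0:
        if config.spawner_choice == "size_weighted":
            p_first = s1 / (s1 + s2)
        else:
            p_first = np.full(n_pairs, 0.5)
        first_dominant = rng.random(n_pairs) < p_first
        thin1 = rng.binomial(e1, 1.0 - g)
        thin2 = rng.binomial(e2, 1.0 - g)
        e1 = np.where(first_dominant, e1, thin1)
        e2 = np.where(first_dominant, thin2, e2)

    if config.drift_rate > 0.0:
        a_to_b = rng.binomial(e1, config.drift_rate)
        b_to_a = rng.binomial(e2, config.drift_rate)
        e1, e2 = e1 - a_to_b + b_to_a, e2 - b_to_a + a_to_b

    return e1.astype(np.int64), e2.astype(np.int64)
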
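"""SAGA: a hybrid simulated-annealing / genetic-algorithm minimizer.

A population of candidate parameter vectors (guesses) evolves by crossover
and mutation; the annealing temperature both attenuates mutation magnitude
and gates Metropolis acceptance of children against the current worst
population member.  The optimizer is general purpose: it minimizes any
energy function over a box, and is the workhorse behind moiety-model
fitting where the energy is an objective comparing calculated and observed
isotopologue profiles.

Schedule and acceptance rules (documented package choices):

* cooling law  ``T = T0 * (1 - steps_done / step_number) ** alpha``,
  updated every `temperature_step_size` steps;
* mutation perturbs a Poisson(`mutation_rate`)-distributed number of
  elements (at least one), each displaced by
  ``uniform(-1, 1) * (T / T0) * (high - low)`` and clamped to bounds;
* each step crosses two uniformly chosen parents, mutates the child, and
  replaces the current worst member if the energy change is non-positive,
  otherwise with probability ``exp(-dE / T)``.

All randomness flows through one :class:`numpy.random.Generator`, so runs
are bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "ElementDescription",
    "Guess",
    "Population",
    "SagaSettings",
    "mutate",
    "crossover",
    "run",
]


@dataclass(frozen=True)
class ElementDescription:
    """One optimizable parameter: a name and box bounds."""

    name: str
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"element {self.name!r}: low must be < high")


@dataclass
class Guess:
    """A candidate parameter vector with its (possibly unset) energy."""

    values: np.ndarray
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class Population:
    """The current guess ensemble with its summary bookkeeping."""

    elements: tuple[ElementDescription, ...]
    guesses: list[Guess]

    @property
    def energies(self) -> np.ndarray:
        return np.array([g.energy for g in self.guesses])

    @property
    def best(self) -> Guess:
        return min(self.guesses, key=lambda g: g.energy)

    @property
    def lowest_energy(self) -> float:
        return float(min(g.energy for g in self.guesses))

    @property
    def highest_energy(self) -> float:
        return float(max(g.energy for g in self.guesses))

    def value_ranges(self) -> list[tuple[float, float]]:
        """Per-element (min, max) spread across the population."""
        arr = np.array([g.values for g in self.guesses])
        return list(zip(arr.min(axis=0).tolist(), arr.max(axis=0).tolist()))


@dataclass(frozen=True)
class SagaSettings:
    """Hyperparameters of the annealing/genetic search.

    Defaults follow the published reference configuration: 100000 steps,
    temperature updated every 100 steps, linear cooling (alpha = 1),
    crossover rate 0.05, mutation rate 3, population of 20, starting
    temperature 0.5.
    """

    step_number: int = 100_000
    temperature_step_size: int = 100
    alpha: float = 1.0
    crossover_rate: float = 0.05
    mutation_rate: float = 3.0
    population_size: int = 20
    start_temperature: float = 0.5
    crossover_variant: str = "uniform"  # or "single_point"

    def __post_init__(self) -> None:
        if self.step_number < 0:
            raise ValueError("step_number must be >= 0")
        if self.temperature_step_size <= 0:
            raise ValueError("temperature_step_size must be positive")
        if not 0.0 < self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in (0, 1]")
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be positive")
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        if self.start_temperature <= 0:
            raise ValueError("start_temperature must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.crossover_variant not in ("uniform", "single_point"):
            raise ValueError(f"unknown crossover variant {self.crossover_variant!r}")


def mutate(
    guess: Guess,
    elements: Sequence[ElementDescription],
    temperature_fraction: float,
    settings: SagaSettings,
    rng: np.random.Generator,
) -> Guess:
    """Perturb a Poisson(`mutation_rate`)-distributed number of elements.

    Each chosen element is displaced by ``uniform(-1, 1) *
    temperature_fraction * (high - low)`` and clamped to its bounds; at
    temperature fraction 0 the values are unchanged.  The child's energy is
    unset until re-evaluated.
    """
    n = len(elements)
    count = min(n, max(1, int(rng.poisson(settings.mutation_rate))))
    idx = rng.choice(n, size=count, replace=False)
    disp = rng.uniform(-1.0, 1.0, size=count)
    lows = np.array([elements[j].low for j in idx])
    highs = np.array([elements[j].high for j in idx])
    values = guess.values.copy()
    values[idx] = np.clip(
        values[idx] + disp * temperature_fraction * (highs - lows), lows, highs
    )
    return Guess(values=values, energy=None)


def crossover(
    parent_a: Guess,
    parent_b: Guess,
    settings: SagaSettings,
    rng: np.random.Generator,
) -> Guess:
    """Create a child from two parents.

    ``uniform``: walk the elements copying from the current parent,
    switching parents with probability `crossover_rate` at each element
    (rate 0 would reproduce parent_a).  ``single_point``: prefix from
    parent_a, suffix from parent_b, split at a uniform interior point.
    """
    a, b = parent_a.values, parent_b.values
    if a.shape != b.shape:
        raise ValueError("parents have different element counts")
    n = a.shape[0]
    if settings.crossover_variant == "single_point":
        p = int(rng.integers(1, n)) if n > 1 else 1
        values = np.concatenate([a[:p], b[p:]])
    else:
        switches = rng.random(n) < settings.crossover_rate
        use_b = np.logical_xor.accumulate(switches)
        values = np.where(use_b, b, a)
    return Guess(values=values, energy=None)


def run(
    energy_fn: Callable[[np.ndarray], float],
    elements: Sequence[ElementDescription],
    settings: SagaSettings,
    seed: int | np.random.SeedSequence | Sequence[int] = 0,
    callback: Optional[Callable[[int, float], None]] = None,
) -> tuple[Guess, Population, list[float]]:
    """Minimize `energy_fn` over the elements' box.

    Returns the best-ever guess, the final population, and the per-step
    trace of the best-ever energy (non-increasing by construction).
    Non-finite energies are treated as +inf and never accepted as best.
    """
    rng = np.random.default_rng(seed)
    elements = tuple(elements)
    lows = np.array([e.low for e in elements])
    highs = np.array([e.high for e in elements])

    def evaluate(values: np.ndarray) -> float:
        e = float(energy_fn(values))
        return e if math.isfinite(e) else math.inf

    guesses = []
    for _ in range(settings.population_size):
        v = rng.uniform(lows, highs)
        guesses.append(Guess(values=v, energy=evaluate(v)))
    population = Population(elements=elements, guesses=guesses)

    best = min(guesses, key=lambda g: g.energy)
    best = Guess(values=best.values.copy(), energy=best.energy)
    trace: list[float] = []

    n_steps = settings.step_number
    temperature = settings.start_temperature
    temp_fraction = 1.0
    for step in range(n_steps):
        if step % settings.temperature_step_size == 0:
            temp_fraction = (1.0 - step / n_steps) ** settings.alpha
            temperature = settings.start_temperature * temp_fraction

        ia, ib = rng.integers(0, settings.population_size, size=2)
        child = crossover(guesses[ia], guesses[ib], settings, rng)
        child = mutate(child, elements, temp_fraction, settings, rng)
        child.energy = evaluate(child.values)

        worst_i = int(np.argmax([g.energy for g in guesses]))
        d_e = child.energy - guesses[worst_i].energy
        accept = d_e <= 0 or (
            temperature > 0
            and math.isfinite(d_e)
            and rng.random() < math.exp(-d_e / temperature)
        )
        if accept:
            guesses[worst_i] = child
            if child.energy < best.energy:
                best = Guess(values=child.values.copy(), energy=child.energy)
        trace.append(best.energy)
        if callback is not None:
            callback(step, best.energy)

    return best, population, trace
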
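"""Model optimization: objectives, datasets, and the fitting drivers.

A :class:`Dataset` holds one mass spectrum's worth of observed relative
isotopologue intensities per molecule (typically one timepoint).  Fitting
minimizes an objective comparing observed and calculated profiles either
*split* (an independent parameter block per dataset) or *combined* (one
joint search over concatenated per-dataset blocks).  The stochastic SAGA
search can be polished by a bounded local method from scipy.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from . import saga
from .errors import GridMismatchError, ModelDefinitionError
from .model import Molecule, MoietyModel, content_grid, parse_state_label
from .profile import IsotopologueProfile, ProfileEvaluator

__all__ = [
    "PENALTY_ENERGY",
    "Observation",
    "Dataset",
    "ObjectiveSpec",
    "OptimizationSettings",
    "Repetition",
    "OptimizationResult",
    "loss",
    "optimize",
    "local_refine",
    "EnergyFunction",
]

logger = logging.getLogger(__name__)

#: Energy assigned to parameter vectors whose expansion leaves the simplex.
PENALTY_ENERGY = 1e6

SCIPY_METHODS = ("TNC", "SLSQP", "L-BFGS-B")


@dataclass(frozen=True)
class Observation:
    """One observed isotopologue: labeling-state label, height, height SE."""

    labeling_isotopes: str
    height: float
    height_se: float = 0.0

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(
                f"observed height for {self.labeling_isotopes!r} is negative"
            )


@dataclass
class Dataset:
    """Observed isotopologues for one mass spectrum (e.g. one timepoint).

    `observations` maps molecule name to a list of :class:`Observation`.
    Grid entries a dataset does not list are imputed as zero when the
    dataset is aligned to a molecule's content grid.
    """

    name: str
    observations: dict[str, list[Observation]]

    def observed_profile(self, molecule: Molecule) -> IsotopologueProfile:
        """Align this dataset's entries for `molecule` onto its full grid."""
        grid = content_grid(molecule)
        index = {c: i for i, c in enumerate(grid)}
        isotopes = molecule.isotopes
        heights = np.zeros(len(grid))
        errs = np.zeros(len(grid))
        for obs in self.observations.get(molecule.name, []):
            contents = parse_state_label(obs.labeling_isotopes)
            unknown = set(contents) - set(isotopes)
            if unknown:
                raise GridMismatchError(
                    f"dataset {self.name!r}: label {obs.labeling_isotopes!r} uses "
                    f"isotopes {sorted(unknown)} not tracked by {molecule.name!r}"
                )
            key = tuple(contents.get(iso, 0) for iso in isotopes)
            if key not in index:
                raise GridMismatchError(
                    f"dataset {self.name!r}: label {obs.labeling_isotopes!r} is "
                    f"outside the content grid of {molecule.name!r}"
                )
            heights[index[key]] = obs.height
            errs[index[key]] = obs.height_se
        return IsotopologueProfile(
            molecule_name=molecule.name,
            isotopes=isotopes,
            contents=tuple(grid),
            intensities=heights,
            std_err=errs,
        )


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective function choice.

    kind
        ``absolute_difference``: sum |obs - calc|;
        ``square_difference``: sum (obs - calc)^2;
        ``log_difference``: sum |ln max(obs, eps) - ln max(calc, eps)|.
    epsilon
        Floor applied to both profiles inside the log objective; guards
        zeros from detection-limit thresholding.
    """

    kind: str = "absolute_difference"
    epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if self.kind not in ("absolute_difference", "log_difference", "square_difference"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def loss(
    observed: IsotopologueProfile,
    calculated: IsotopologueProfile,
    spec: ObjectiveSpec,
) -> float:
    """Objective value between two profiles on the same content grid."""
    observed.check_same_grid(calculated)
    o, c = observed.intensities, calculated.intensities
    if spec.kind == "absolute_difference":
        return float(np.abs(o - c).sum())
    if spec.kind == "square_difference":
        return float(((o - c) ** 2).sum())
    eps = spec.epsilon
    return float(
        np.abs(np.log(np.maximum(o, eps)) - np.log(np.maximum(c, eps))).sum()
    )


@dataclass(frozen=True)
class OptimizationSettings:
    """How a model is fit to datasets.

    method
        ``"SAGA"`` or a scipy bounded local method (``"TNC"``, ``"SLSQP"``,
        ``"L-BFGS-B"``; for these, each repetition is one local run from a
        random start).
    dataset_mode
        ``"split"``: independent fit per dataset. ``"combined"``: one joint
        search over concatenated per-dataset parameter blocks (set
        `combined_shared` to share a single block across datasets instead).
    polish
        After SAGA, refine the best guess with `polish_method`.
    renormalize_observed
        Rescale each observed profile to sum to 1 before comparison
        (off by default: raw heights are compared as given).
    """

    method: str = "SAGA"
    saga: saga.SagaSettings = field(default_factory=saga.SagaSettings)
    repetitions: int = 100
    dataset_mode: str = "split"
    objective: ObjectiveSpec = field(default_factory=ObjectiveSpec)
    seed: int = 0
    polish: bool = False
    polish_method: str = "L-BFGS-B"
    combined_shared: bool = False
    renormalize_observed: bool = False

    def __post_init__(self) -> None:
        if self.method != "SAGA" and self.method not in SCIPY_METHODS:
            raise ValueError(f"unknown optimization method {self.method!r}")
        if self.polish_method not in SCIPY_METHODS:
            raise ValueError(f"unknown polish method {self.polish_method!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.dataset_mode not in ("split", "combined"):
            raise ValueError(f"unknown dataset mode {self.dataset_mode!r}")


@dataclass
class Repetition:
    """Best parameter vector and energy of one optimization repetition."""

    params: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)


@dataclass
class OptimizationResult:
    """Fit results for one model.

    In split mode `blocks` maps each dataset name to its repetition list;
    in combined mode the single key ``"combined"`` holds repetitions whose
    parameter vectors concatenate the per-dataset blocks (dataset order =
    input order), or a single shared block when `combined_shared` was set.
    """

    model_name: str
    dataset_names: list[str]
    blocks: dict[str, list[Repetition]]
    settings: OptimizationSettings
    all_infeasible: bool = False

    def best(self, block: str) -> Repetition:
        return min(self.blocks[block], key=lambda r: r.energy)


class EnergyFunction:
    """Objective energy of a model against one dataset.

    Maps a free-parameter vector to the summed loss over all model
    molecules present in the dataset; infeasible expansions (any state
    fraction outside [0, 1]) receive :data:`PENALTY_ENERGY` so the search
    sees the feasibility boundary rather than an exception.
    """

    def __init__(
        self,
        model: MoietyModel,
        dataset: Dataset,
        objective: ObjectiveSpec,
        renormalize_observed: bool = False,
    ):
        self.model = model
        self.objective = objective
        self._pairs: list[tuple[ProfileEvaluator, np.ndarray]] = []
        for molecule in model.molecules:
            if molecule.name not in dataset.observations:
                continue
            observed = dataset.observed_profile(molecule).intensities
            if renormalize_observed and observed.sum() > 0:
                observed = observed / observed.sum()
            self._pairs.append((ProfileEvaluator(model, molecule), observed))
        if not self._pairs:
            raise ModelDefinitionError(
                f"dataset {dataset.name!r} contains no molecule of model "
                f"{model.name!r}"
            )
        self.n_observations = sum(len(obs) for _, obs in self._pairs)

    def _raw_loss(self, o: np.ndarray, c: np.ndarray) -> float:
        kind = self.objective.kind
        if kind == "absolute_difference":
            return float(np.abs(o - c).sum())
        if kind == "square_difference":
            return float(((o - c) ** 2).sum())
        eps = self.objective.epsilon
        return float(np.abs(np.log(np.maximum(o, eps)) - np.log(np.maximum(c, eps))).sum())

    def __call__(self, params: np.ndarray) -> float:
        v, feasible = self.model.expand_array(params)
        if not feasible:
            return PENALTY_ENERGY
        return sum(self._raw_loss(obs, ev.intensities(v)) for ev, obs in self._pairs)

    def residual_ss(self, params: np.ndarray) -> float:
        """Residual sum of squares at `params` (independent of `objective`)."""
        v, _ = self.model.expand_array(params)
        return sum(float(((obs - ev.intensities(v)) ** 2).sum()) for ev, obs in self._pairs)

    def calculated_profiles(self, params: np.ndarray) -> list[IsotopologueProfile]:
        v, _ = self.model.expand_array(params)
        return [ev.profile(v) for ev, _ in self._pairs]

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        """A random *feasible* parameter vector for local-method restarts.

        Uniform draws over the box land outside the per-moiety simplex for
        most models (where gradient methods cannot leave the penalty
        plateau), so states are drawn from a flat Dirichlet per moiety
        instead; falls back to a uniform draw if relationships keep the
        expansion infeasible.
        """
        from .model import StateValues  # local import avoids cycle at module load

        model = self.model
        for _ in range(50):
            values: dict[tuple[str, str], float] = {}
            for m in model.moieties:
                fractions = rng.dirichlet(np.ones(len(m.states)))
                for s, f in zip(m.states, fractions):
                    values[(m.name, s.label)] = float(f)
            params = model.extract_free_parameters(StateValues(values))
            _, feasible = model.expand_array(params)
            if feasible:
                return params
        return rng.uniform(0.0, 1.0, size=model.free_parameter_count)


class _CombinedEnergy:
    """Summed energy over per-dataset blocks (shared or concatenated)."""

    def __init__(self, energies: list[EnergyFunction], k: int, shared: bool):
        self.energies = energies
        self.k = k
        self.shared = shared
        self.n_params = k if shared else k * len(energies)

    def __call__(self, params: np.ndarray) -> float:
        if self.shared:
            return sum(e(params) for e in self.energies)
        total = 0.0
        for i, e in enumerate(self.energies):
            total += e(params[i * self.k : (i + 1) * self.k])
        return total

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        if self.shared:
            return self.energies[0].random_start(rng)
        return np.concatenate([e.random_start(rng) for e in self.energies])


def local_refine(
    model: MoietyModel,
    dataset: Dataset,
    start: np.ndarray,
    method: str = "L-BFGS-B",
    objective: ObjectiveSpec | None = None,
    renormalize_observed: bool = False,
) -> tuple[np.ndarray, float]:
    """Box-constrained local refinement from `start`.

    Returns the refined (params, energy); if the local optimizer fails or
    worsens the energy, `start` is returned unchanged (with a warning
    logged on failure).
    """
    energy = EnergyFunction(model, dataset, objective or ObjectiveSpec(),
                            renormalize_observed=renormalize_observed)
    return _refine_energy(energy, np.asarray(start, dtype=float), method)


def _refine_energy(energy, start: np.ndarray, method: str) -> tuple[np.ndarray, float]:
    start_e = float(energy(start))
    n = start.shape[0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scipy.optimize.minimize(
                energy, start, method=method, bounds=[(0.0, 1.0)] * n
            )
        cand = np.clip(res.x, 0.0, 1.0)
        cand_e = float(energy(cand))
    except Exception as exc:  # pragma: no cover - scipy failure path
        logger.warning("local refinement (%s) failed: %s", method, exc)
        return start, start_e
    if cand_e <= start_e + 1e-12:
        return cand, cand_e
    return start, start_e


def _run_one(
    energy, n_params: int, settings: OptimizationSettings, seed_key
) -> Repetition:
    if settings.method == "SAGA":
        elements = [saga.ElementDescription(f"p{i}") for i in range(n_params)]
        best, _, _ = saga.run(energy, elements, settings.saga, seed=seed_key)
        params, e = best.values, best.energy
        if settings.polish:
            params, e = _refine_energy(energy, params, settings.polish_method)
    else:
        rng = np.random.default_rng(seed_key)
        start = energy.random_start(rng)
        params, e = _refine_energy(energy, start, settings.method)
    return Repetition(params=params, energy=float(e))


def optimize(
    model: MoietyModel,
    datasets: Sequence[Dataset],
    settings: OptimizationSettings,
) -> OptimizationResult:
    """Fit `model` to `datasets` under `settings`.

    Repetition r of dataset block d is seeded from ``(seed, d, r)``, so
    results are reproducible and repetitions are independent.  Recorded
    energies always equal re-evaluating the recorded parameters.
    """
    if not datasets:
        raise ValueError("no datasets given")
    energies = [
        EnergyFunction(model, ds, settings.objective, settings.renormalize_observed)
        for ds in datasets
    ]
    k = model.free_parameter_count
    blocks: dict[str, list[Repetition]] = {}
    if settings.dataset_mode == "split":
        for di, (ds, energy) in enumerate(zip(datasets, energies)):
            reps = [
                _run_one(energy, k, settings, (settings.seed, di, r))
                for r in range(settings.repetitions)
            ]
            blocks[ds.name] = reps
    else:
        combined = _CombinedEnergy(energies, k, settings.combined_shared)
        blocks["combined"] = [
            _run_one(combined, combined.n_params, settings, (settings.seed, 0, r))
            for r in range(settings.repetitions)
        ]
    all_reps = [r for reps in blocks.values() for r in reps]
    all_infeasible = all(r.energy >= PENALTY_ENERGY for r in all_reps)
    if all_infeasible:
        logger.warning(
            "model %s: every repetition ended at the infeasibility penalty", model.name
        )
    return OptimizationResult(
        model_name=model.name,
        dataset_names=[ds.name for ds in datasets],
        blocks=blocks,
        settings=settings,
        all_infeasible=all_infeasible,
    )
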
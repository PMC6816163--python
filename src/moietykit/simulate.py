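"""Simulated single- and multi-tracer isotopologue datasets.

The fixtures encode the UDP-GlcNAc biosynthesis moiety model: four
moieties (glucose, ribose, acetyl, uracil) fed from labeled glucose, with
reference moiety-state fractions rounded from an optimized experimental
timepoint.  The multi-tracer variant uses 13C6/18O6 glucose as the
hypothetical source; oxygen follows its bonded carbon into the glucose,
ribose and acetyl moieties, while uracil biosynthesis sometimes breaks
18O-13C bonds, giving uracil a more varied joint-state set.

Simulated datasets are produced by adding independent Normal(0, sigma)
error to *every* entry of the molecule's content grid, zeroing entries
strictly below a hypothetical detection limit (0.005 by default; this also
removes all negatives), and renormalizing to a sum of one.  The average
pre-renormalization sum across a collection quantifies how thresholding
plus renormalization propagates error — dramatically so for multi-tracer
grids, where hundreds of near-zero isotopologues each have a chance of
drawing noise above the detection limit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ModelDefinitionError
from .model import (
    JointState,
    Moiety,
    MoietyModel,
    Molecule,
    StateValues,
    state_label,
)
from .modeling import Dataset, Observation
from .profile import IsotopologueProfile, calc_intensity_profile

__all__ = [
    "SimulationSpec",
    "build_fixture",
    "fixture_names",
    "perturb_profile",
    "generate_collection",
    "timecourse_state_values",
    "average_sum_before_renormalization",
    "profile_to_dataset",
    "collection_to_datasets",
]

DEFAULT_DETECTION_LIMIT = 0.005

# single-tracer reference moiety states and fractions (13C only)
_SINGLE = {
    "glucose": {"atoms": {"13C": 6}, "values": {0: 0.1, 6: 0.9}},
    "ribose": {"atoms": {"13C": 5}, "values": {0: 0.1, 5: 0.9}},
    "acetyl": {"atoms": {"13C": 2}, "values": {0: 0.7, 2: 0.3}},
    "uracil": {"atoms": {"13C": 4}, "values": {0: 0.2, 1: 0.2, 2: 0.5, 3: 0.1}},
}

# multi-tracer reference: joint (13C, 18O) states.  Moiety-level labellable
# oxygens follow the atom mapping from the glucose source: glucose 5,
# ribose 4, acetyl 1, uracil 2.
_MULTI = {
    "glucose": {"atoms": {"13C": 6, "18O": 5}, "values": {(0, 0): 0.1, (6, 5): 0.9}},
    "ribose": {"atoms": {"13C": 5, "18O": 4}, "values": {(0, 0): 0.1, (5, 4): 0.9}},
    "acetyl": {"atoms": {"13C": 2, "18O": 1}, "values": {(0, 0): 0.7, (2, 1): 0.3}},
    "uracil": {
        "atoms": {"13C": 4, "18O": 2},
        "values": {
            (0, 0): 0.2,
            (1, 0): 0.2,
            (2, 0): 0.25,
            (2, 1): 0.25,
            (3, 0): 0.05,
            (3, 1): 0.05,
        },
    },
}

_NICKNAMES = {"glucose": "g", "ribose": "r", "acetyl": "a", "uracil": "u"}
_BY_NICK = {v: k for k, v in _NICKNAMES.items()}

#: Molecule-wide atoms available for labeling.  Carbon: all 17 backbone
#: carbons.  Oxygen: the 12 tracer-accessible oxygens implied by the atom
#: mapping (5 + 4 + 1 + 2); the metabolite carries 17 oxygens in total, and
#: the full-elemental variant below counts them all.
_TOTAL_ATOMS = {
    "single": {"13C": 17},
    "multi": {"13C": 17, "18O": 12},
    "multi_full": {"13C": 17, "18O": 17},
}

_EXTRA_STATE = re.compile(r"^([grau])(\d+)$")


def fixture_names() -> list[str]:
    """The named fixtures (the perturbed family extends ``expert_single``
    with extra zero-abundance states, e.g. ``expert_single_g5``)."""
    return ["expert_single", "expert_multi", "expert_multi_full_grid"]


def _build(
    spec: dict, total_atoms: dict[str, int], model_name: str,
    extra_states: Iterable[tuple[str, tuple[int, ...]]] = (),
) -> tuple[MoietyModel, StateValues]:
    isotopes = list(next(iter(spec.values()))["atoms"].keys())
    extras: dict[str, list[tuple[int, ...]]] = {}
    for moiety_name, content in extra_states:
        extras.setdefault(moiety_name, []).append(content)

    moieties = []
    values: dict[tuple[str, str], float] = {}
    for name, cfg in spec.items():
        states = []
        for content, frac in cfg["values"].items():
            key = content if isinstance(content, tuple) else (content,)
            label = state_label(zip(isotopes, key))
            states.append(JointState.from_label(label))
            values[(name, label)] = frac
        for content in extras.get(name, []):
            label = state_label(zip(isotopes, content))
            if (name, label) in values:
                raise ModelDefinitionError(
                    f"perturbed state {label!r} already exists in moiety {name!r}"
                )
            states.append(JointState.from_label(label))
            values[(name, label)] = 0.0
        moieties.append(Moiety(name, cfg["atoms"], states, nickname=_NICKNAMES[name]))
    molecule = Molecule("UDP-GlcNAc", moieties, total_atoms)
    model = MoietyModel(model_name, moieties, [molecule])
    return model, StateValues(values)


def build_fixture(name: str) -> tuple[MoietyModel, StateValues]:
    """Construct a named fixture model with its reference state values.

    ``expert_single``
        The expert-derived single-tracer (13C) UDP-GlcNAc model, k = 6.
    ``expert_multi``
        The joint 13C/18O multi-tracer model, k = 8, on the
        tracer-accessible 18 x 13 content grid.
    ``expert_multi_full_grid``
        Same moieties and values, but counting all 17 oxygens of the
        metabolite as labellable (the 18 x 18 = 324-isotopologue grid).
    ``expert_single_<tok>[_<tok>...]``
        Over-parameterized perturbations of ``expert_single``: each token
        (e.g. ``g5``, ``r4``, ``a1``, ``u4``) adds one extra 13C state with
        reference abundance 0, raising k by one per token.
    """
    if name == "expert_single":
        return _build(_SINGLE, _TOTAL_ATOMS["single"], "6_G1R1A1U3")
    if name == "expert_multi":
        return _build(_MULTI, _TOTAL_ATOMS["multi"], "8_G1R1A1U5_13C_18O")
    if name == "expert_multi_full_grid":
        return _build(
            _MULTI, _TOTAL_ATOMS["multi_full"], "8_G1R1A1U5_13C_18O_full"
        )
    if name.startswith("expert_single_"):
        tokens = name[len("expert_single_") :].split("_")
        extra: list[tuple[str, tuple[int, ...]]] = []
        for tok in tokens:
            m = _EXTRA_STATE.match(tok)
            if not m:
                raise ValueError(f"unknown fixture name {name!r} (bad token {tok!r})")
            extra.append((_BY_NICK[m.group(1)], (int(m.group(2)),)))
        k = 6 + len(extra)
        suffix = "_".join(tokens)
        return _build(
            _SINGLE, _TOTAL_ATOMS["single"], f"{k}_{suffix}", extra_states=extra
        )
    raise ValueError(f"unknown fixture name {name!r}")


def timecourse_state_values(fixture: str, fraction: float) -> StateValues:
    """Reference state values at an intermediate point of the labeling
    timecourse.

    Scales every labeled-state fraction of the fixture's reference values
    by `fraction` (0 = fully unlabeled, 1 = the reference endpoint), with
    each moiety's unlabeled (first) state absorbing the remainder, so the
    per-moiety sum-to-one constraint is preserved.  Emulates earlier
    timepoints where the tracer has not yet saturated the moiety pools.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    model, values = build_fixture(fixture)
    scaled: dict[tuple[str, str], float] = {}
    for m in model.moieties:
        first = m.states[0].label
        labeled = 0.0
        for s in m.states[1:]:
            v = fraction * values.value(m.name, s.label)
            scaled[(m.name, s.label)] = v
            labeled += v
        scaled[(m.name, first)] = 1.0 - labeled
    return StateValues(scaled)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated-dataset collection.

    `enrichment_fraction` < 1 draws the base profile from an intermediate
    timecourse point (see :func:`timecourse_state_values`) instead of the
    fixture's reference endpoint values.
    """

    fixture: str = "expert_single"
    sigma: float = 0.001
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    n_datasets: int = 100
    seed: int = 0
    enrichment_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not 0.0 <= self.enrichment_fraction <= 1.0:
            raise ValueError("enrichment_fraction must be in [0, 1]")


def perturb_profile(
    base: IsotopologueProfile,
    sigma: float,
    detection_limit: float,
    rng: np.random.Generator,
) -> tuple[IsotopologueProfile, IsotopologueProfile]:
    """One noisy realization of a base profile.

    Adds independent Normal(0, sigma) error to every grid entry, zeroes
    entries strictly below the detection limit (all negatives included),
    and renormalizes.  Returns ``(pre_norm, final)``; the pre-normalization
    sum is the error-propagation diagnostic.

    Raises
    ------
    ValueError
        If every entry falls below the detection limit (degenerate draw).
    """
    noisy = base.intensities + rng.normal(0.0, sigma, size=base.intensities.shape) \
        if sigma > 0 else base.intensities.copy()
    noisy = np.where(noisy < detection_limit, 0.0, noisy)
    total = noisy.sum()
    if total <= 0:
        raise ValueError(
            "degenerate simulated dataset: every isotopologue fell below "
            "the detection limit"
        )
    pre = IsotopologueProfile(base.molecule_name, base.isotopes, base.contents, noisy)
    final = IsotopologueProfile(
        base.molecule_name, base.isotopes, base.contents, noisy / total
    )
    return pre, final


def generate_collection(
    spec: SimulationSpec,
) -> list[tuple[IsotopologueProfile, IsotopologueProfile]]:
    """Reproducibly generate `n_datasets` (pre_norm, final) profile pairs.

    Degenerate all-zero draws are regenerated from the next random
    substream rather than returned.
    """
    model, values = build_fixture(spec.fixture)
    if spec.enrichment_fraction < 1.0:
        values = timecourse_state_values(spec.fixture, spec.enrichment_fraction)
    molecule = model.molecules[0]
    base = calc_intensity_profile(molecule, values)
    rng = np.random.default_rng(spec.seed)
    out = []
    attempts = 0
    while len(out) < spec.n_datasets:
        if attempts > 10 * spec.n_datasets + 100:
            raise RuntimeError("too many degenerate simulated datasets")
        attempts += 1
        try:
            out.append(
                perturb_profile(base, spec.sigma, spec.detection_limit, rng)
            )
        except ValueError:
            continue
    return out


def average_sum_before_renormalization(
    collection: Sequence[tuple[IsotopologueProfile, IsotopologueProfile]],
) -> float:
    """Mean over datasets of the pre-renormalization intensity sum."""
    if not collection:
        raise ValueError("empty collection")
    return float(np.mean([pre.total for pre, _ in collection]))


def profile_to_dataset(profile: IsotopologueProfile, name: str) -> Dataset:
    """Convert a (final, renormalized) profile into an observed dataset.

    Only nonzero entries are listed; the grid alignment in the modeling
    layer imputes the rest as zero, so the conversion is lossless.
    """
    observations = [
        Observation(
            labeling_isotopes=state_label(zip(profile.isotopes, content)),
            height=float(h),
        )
        for content, h in zip(profile.contents, profile.intensities)
        if h > 0
    ]
    return Dataset(name=name, observations={profile.molecule_name: observations})


def collection_to_datasets(
    collection: Sequence[tuple[IsotopologueProfile, IsotopologueProfile]],
    prefix: str = "sim",
) -> list[Dataset]:
    return [
        profile_to_dataset(final, f"{prefix}_{i:03d}")
        for i, (_, final) in enumerate(collection)
    ]
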
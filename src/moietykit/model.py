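"""Moiety models: metabolite decomposition into isotope-enriched subunits.

A composite metabolite (e.g. UDP-GlcNAc) is decomposed into *moieties*
(glucose, ribose, acetyl, uracil) through which stable-isotope label flows
from a tracer source.  Each moiety occupies one of a small set of *joint
isotope-enrichment states* — a specific number of labeled atoms per tracer
isotope, such as ``13C_6`` or ``13C_6.18O_5`` — and the fractional abundance
of each state is a model parameter.  Per moiety the state fractions sum to
one, so one state per moiety (by convention the first listed, normally the
unlabeled state) is determined by the others.  Additional linear
*relationships* may tie a state to states of other moieties (e.g. the
glucose and ribose units deriving from a common precursor pool), removing
further free parameters.

This module owns the mapping between the free-parameter vector seen by an
optimizer and the full set of moiety-state fractional values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ModelDefinitionError

__all__ = [
    "JointState",
    "Moiety",
    "Relationship",
    "Molecule",
    "MoietyModel",
    "StateValues",
    "state_label",
    "parse_state_label",
    "free_parameter_names",
    "expand_state_values",
    "state_combinations",
    "possible_isotopologue_count",
    "content_grid",
]


def state_label(contents: Mapping[str, int] | Sequence[tuple[str, int]]) -> str:
    """Canonical text form of a joint state, e.g. ``"13C_6"`` or
    ``"13C_6.18O_5"``.  Isotopes appear in their declaration order."""
    items = contents.items() if isinstance(contents, Mapping) else contents
    return ".".join(f"{iso}_{n}" for iso, n in items)


def parse_state_label(label: str) -> dict[str, int]:
    """Parse ``"13C_6.18O_5"`` into ``{"13C": 6, "18O": 5}``.

    Raises
    ------
    ValueError
        If the label is not a dot-separated list of ``isotope_count`` parts.
    """
    contents: dict[str, int] = {}
    for part in label.split("."):
        iso, sep, num = part.rpartition("_")
        if not sep or not iso:
            raise ValueError(f"malformed isotope-state label part {part!r} in {label!r}")
        try:
            count = int(num)
        except ValueError:
            raise ValueError(f"non-integer isotope count in label part {part!r}") from None
        if count < 0:
            raise ValueError(f"negative isotope count in label part {part!r}")
        if iso in contents:
            raise ValueError(f"isotope {iso!r} repeated in label {label!r}")
        contents[iso] = count
    return contents


@dataclass(frozen=True)
class JointState:
    """One joint isotope-enrichment state of a moiety.

    Parameters
    ----------
    contents
        Number of incorporated atoms per tracer isotope, stored as an
        ordered tuple of ``(isotope, count)`` pairs in declaration order.
        A mapping is accepted and converted.
    """

    contents: tuple[tuple[str, int], ...]

    def __init__(self, contents: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = tuple(contents.items()) if isinstance(contents, Mapping) else tuple(contents)
        for iso, n in items:
            if not isinstance(n, int) or n < 0:
                raise ModelDefinitionError(
                    f"state content for isotope {iso!r} must be a non-negative "
                    f"integer, got {n!r}"
                )
        object.__setattr__(self, "contents", items)

    @classmethod
    def from_label(cls, label: str) -> "JointState":
        return cls(parse_state_label(label))

    @property
    def label(self) -> str:
        return state_label(self.contents)

    def content(self, isotope: str) -> int:
        """Atoms of `isotope` incorporated in this state (0 if untracked)."""
        return dict(self.contents).get(isotope, 0)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"JointState({self.label!r})"


@dataclass(frozen=True)
class Moiety:
    """A metabolic subunit with its labellable atoms and enrichment states.

    Parameters
    ----------
    name
        Full moiety name, e.g. ``"glucose"``.
    labellable_atoms
        Per-isotope count of atoms available for labeling in this moiety,
        e.g. ``{"13C": 6}`` or ``{"13C": 6, "18O": 5}``.
    states
        Ordered joint enrichment states.  The *first* state is the
        default-dependent one: its fraction is fixed by the sum-to-one
        constraint, so by convention the unlabeled state is listed first.
    nickname
        Short tag used in display names, e.g. ``"g"``.
    """

    name: str
    labellable_atoms: tuple[tuple[str, int], ...]
    states: tuple[JointState, ...]
    nickname: str = ""

    def __init__(
        self,
        name: str,
        labellable_atoms: Mapping[str, int],
        states: Sequence[JointState | Mapping[str, int] | str],
        nickname: str = "",
    ):
        atoms = tuple(labellable_atoms.items())
        parsed: list[JointState] = []
        for s in states:
            if isinstance(s, JointState):
                parsed.append(s)
            elif isinstance(s, str):
                parsed.append(JointState.from_label(s))
            else:
                parsed.append(JointState(s))
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "labellable_atoms", atoms)
        object.__setattr__(self, "states", tuple(parsed))
        object.__setattr__(self, "nickname", nickname or name[:1])
        self._validate()

    def _validate(self) -> None:
        if not self.states:
            raise ModelDefinitionError(f"moiety {self.name!r} has no states")
        atoms = dict(self.labellable_atoms)
        seen: set[str] = set()
        for s in self.states:
            if s.label in seen:
                raise ModelDefinitionError(
                    f"moiety {self.name!r} lists state {s.label!r} twice"
                )
            seen.add(s.label)
            for iso, n in s.contents:
                if iso not in atoms:
                    raise ModelDefinitionError(
                        f"moiety {self.name!r} state {s.label!r} uses isotope "
                        f"{iso!r} not in labellable_atoms"
                    )
                if n > atoms[iso]:
                    raise ModelDefinitionError(
                        f"moiety {self.name!r} state {s.label!r} exceeds the "
                        f"{atoms[iso]} labellable {iso!r} atoms"
                    )

    @property
    def isotopes(self) -> tuple[str, ...]:
        return tuple(iso for iso, _ in self.labellable_atoms)

    def state_labels(self) -> list[str]:
        return [s.label for s in self.states]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Moiety({self.name!r}, states={self.state_labels()})"


@dataclass(frozen=True)
class Relationship:
    """A linear dependency fixing one moiety state from others.

    ``dependent = sum(coefficient * value(moiety, state))`` over `terms`.
    Covers the identity form (g6 = r5), scaled single-term forms
    (g0 = 2 * a2), and multi-term forms (g3 = r2 + r3).

    Fields reference states as ``(moiety_name, state_label)`` pairs.
    """

    dependent: tuple[str, str]
    terms: tuple[tuple[str, str, float], ...]

    def __init__(
        self,
        dependent: tuple[str, str],
        terms: Iterable[tuple[str, str, float]],
    ):
        object.__setattr__(self, "dependent", (str(dependent[0]), str(dependent[1])))
        object.__setattr__(
            self, "terms", tuple((str(m), str(s), float(c)) for m, s, c in terms)
        )
        if not self.terms:
            raise ModelDefinitionError(
                f"relationship for {self.dependent} has no terms"
            )
        for m, s, _ in self.terms:
            if (m, s) == self.dependent:
                raise ModelDefinitionError(
                    f"relationship for {self.dependent} references itself"
                )


@dataclass(frozen=True)
class Molecule:
    """A metabolite built from an ordered list of moieties.

    `total_labellable_atoms` is the molecule-wide per-isotope atom count
    available for labeling (e.g. ``{"13C": 17}`` for UDP-GlcNAc); it defines
    the isotopologue content grid, which may exceed the union of moiety
    states (isotopologues that no moiety-state combination can reach are
    still part of the measured grid).
    """

    name: str
    moieties: tuple[Moiety, ...]
    total_labellable_atoms: tuple[tuple[str, int], ...]

    def __init__(
        self,
        name: str,
        moieties: Sequence[Moiety],
        total_labellable_atoms: Mapping[str, int],
    ):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "moieties", tuple(moieties))
        object.__setattr__(
            self, "total_labellable_atoms", tuple(total_labellable_atoms.items())
        )
        self._validate()

    def _validate(self) -> None:
        if not self.moieties:
            raise ModelDefinitionError(f"molecule {self.name!r} has no moieties")
        totals = dict(self.total_labellable_atoms)
        for iso, total in totals.items():
            if total < 0:
                raise ModelDefinitionError(
                    f"molecule {self.name!r}: negative atom count for {iso!r}"
                )
            in_moieties = sum(dict(m.labellable_atoms).get(iso, 0) for m in self.moieties)
            if in_moieties > total:
                raise ModelDefinitionError(
                    f"molecule {self.name!r}: moieties carry {in_moieties} "
                    f"labellable {iso!r} atoms, exceeding the molecule total {total}"
                )

    @property
    def isotopes(self) -> tuple[str, ...]:
        """Tracked isotopes in declaration order; fixes grid-axis order."""
        return tuple(iso for iso, _ in self.total_labellable_atoms)


@dataclass
class StateValues:
    """Fractional abundances keyed by ``(moiety_name, state_label)``.

    Feasible values lie in [0, 1] and sum to one within each moiety.
    """

    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def value(self, moiety: str, state: str) -> float:
        return self.values[(moiety, state)]

    def by_moiety(self, moiety: str) -> dict[str, float]:
        return {s: v for (m, s), v in self.values.items() if m == moiety}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StateValues):
            return NotImplemented
        return self.values == other.values


class MoietyModel:
    """A complete moiety model: moieties, molecules, and relationships.

    The model owns the free-parameter space: ``k = sum(|states| - 1) -
    #relationships``, with each moiety's first state absorbing the
    sum-to-one constraint and relationship-dependent states fixed by their
    linear combinations.

    Parameters
    ----------
    name
        Model identifier, e.g. ``"6_G1R1A1U3"``.
    moieties
        All moieties referenced by the molecules.
    molecules
        Metabolites whose isotopologue profiles the model explains.
    relationships
        Linear dependencies between moiety states (may be empty).
    """

    def __init__(
        self,
        name: str,
        moieties: Sequence[Moiety],
        molecules: Sequence[Molecule],
        relationships: Sequence[Relationship] = (),
    ):
        self.name = name
        self.moieties = tuple(moieties)
        self.molecules = tuple(molecules)
        self.relationships = tuple(relationships)
        self.extra: dict = {}  # unknown JSON fields, preserved on round-trip
        self._compile()

    # -- structural compilation ------------------------------------------

    def _compile(self) -> None:
        by_name: dict[str, Moiety] = {}
        for m in self.moieties:
            if m.name in by_name:
                raise ModelDefinitionError(f"duplicate moiety name {m.name!r}")
            by_name[m.name] = m
        self.moiety_by_name = by_name
        for mol in self.molecules:
            for m in mol.moieties:
                if by_name.get(m.name) is not m:
                    raise ModelDefinitionError(
                        f"molecule {mol.name!r} references moiety {m.name!r} "
                        "not declared in the model"
                    )

        # global state index, moiety declaration order then state order
        self.state_index: dict[tuple[str, str], int] = {}
        self._state_keys: list[tuple[str, str]] = []
        self._moiety_slices: dict[str, slice] = {}
        for m in self.moieties:
            start = len(self._state_keys)
            for s in m.states:
                key = (m.name, s.label)
                self.state_index[key] = len(self._state_keys)
                self._state_keys.append(key)
            self._moiety_slices[m.name] = slice(start, len(self._state_keys))
        self.n_states = len(self._state_keys)

        default_keys = {(m.name, m.states[0].label) for m in self.moieties}
        dep_keys: dict[tuple[str, str], Relationship] = {}
        for rel in self.relationships:
            dep = rel.dependent
            if dep not in self.state_index:
                raise ModelDefinitionError(
                    f"relationship dependent {dep} is not a declared moiety state"
                )
            if dep in default_keys:
                raise ModelDefinitionError(
                    f"relationship dependent {dep} is its moiety's "
                    "default-dependent (first) state"
                )
            if dep in dep_keys:
                raise ModelDefinitionError(f"state {dep} has two relationships")
            for term in rel.terms:
                tkey = (term[0], term[1])
                if tkey not in self.state_index:
                    raise ModelDefinitionError(
                        f"relationship term {tkey} is not a declared moiety state"
                    )
                if tkey in default_keys:
                    raise ModelDefinitionError(
                        f"relationship term {tkey} references a default-dependent "
                        "state; only free or relationship-dependent states may "
                        "appear as terms"
                    )
            dep_keys[dep] = rel
        self._dependent_rels = dep_keys

        # topological order of relationship evaluation (Kahn)
        order: list[Relationship] = []
        remaining = dict(dep_keys)
        resolved: set[tuple[str, str]] = set()
        while remaining:
            progressed = False
            for dep, rel in list(remaining.items()):
                needs = {
                    (t[0], t[1])
                    for t in rel.terms
                    if (t[0], t[1]) in dep_keys and (t[0], t[1]) not in resolved
                }
                if not needs:
                    order.append(rel)
                    resolved.add(dep)
                    del remaining[dep]
                    progressed = True
            if not progressed:
                cyc = ", ".join(str(d) for d in remaining)
                raise ModelDefinitionError(f"circular relationships among: {cyc}")
        self._relationship_order = order

        # free parameters: declaration order, skipping default-dependent
        # (first state) and relationship-dependent states
        self._free_keys = [
            (m.name, s.label)
            for m in self.moieties
            for s in m.states[1:]
            if (m.name, s.label) not in dep_keys
        ]
        self._free_idx = np.array(
            [self.state_index[k] for k in self._free_keys], dtype=np.intp
        )
        self._default_idx = np.array(
            [self.state_index[(m.name, m.states[0].label)] for m in self.moieties],
            dtype=np.intp,
        )
        # contiguous per-moiety slices; each starts at its default state
        self._moiety_starts = np.array(
            [self._moiety_slices[m.name].start for m in self.moieties], dtype=np.intp
        )
        self._rel_compiled = [
            (
                self.state_index[rel.dependent],
                np.array([self.state_index[(t[0], t[1])] for t in rel.terms], dtype=np.intp),
                np.array([t[2] for t in rel.terms]),
            )
            for rel in self._relationship_order
        ]

    # -- parameter space --------------------------------------------------

    @property
    def free_parameter_count(self) -> int:
        return len(self._free_keys)

    k = free_parameter_count

    def free_parameter_names(self) -> list[str]:
        """Deterministic identifiers of the free parameters, e.g.
        ``"glucose[13C_6]"``, in moiety declaration order then state order."""
        return [f"{m}[{s}]" for m, s in self._free_keys]

    def expand_array(self, params: np.ndarray) -> tuple[np.ndarray, bool]:
        """Expand a free-parameter vector to the full state-value vector.

        Returns ``(values, feasible)`` where `values` is aligned with the
        global state index and `feasible` is False when any expanded value
        falls outside [0, 1] (the caller typically maps that to a penalty
        energy rather than raising).
        """
        params = np.asarray(params, dtype=float)
        if params.shape != (len(self._free_keys),):
            raise ValueError(
                f"expected {len(self._free_keys)} free parameters, got {params.shape}"
            )
        v = np.zeros(self.n_states)
        v[self._free_idx] = params
        for dep_i, term_idx, coeffs in self._rel_compiled:
            v[dep_i] = coeffs @ v[term_idx]
        # default (first) states are still zero here, so per-moiety sums of
        # the remaining states come from one reduceat over the slices
        sums = np.add.reduceat(v, self._moiety_starts)
        v[self._default_idx] = 1.0 - sums
        feasible = bool(((v >= -1e-9) & (v <= 1.0 + 1e-9)).all())
        return v, feasible

    def expand_state_values(self, params: np.ndarray) -> tuple[StateValues, bool]:
        """Like :meth:`expand_array` but returning a keyed :class:`StateValues`."""
        v, feasible = self.expand_array(params)
        return StateValues({k: float(x) for k, x in zip(self._state_keys, v)}), feasible

    def values_to_array(self, sv: StateValues) -> np.ndarray:
        v = np.zeros(self.n_states)
        for key, idx in self.state_index.items():
            v[idx] = sv.values[key]
        return v

    def extract_free_parameters(self, sv: StateValues) -> np.ndarray:
        """Free-parameter vector of a full state-value assignment
        (inverse of :meth:`expand_state_values` on feasible values)."""
        return np.array([sv.values[k] for k in self._free_keys])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"MoietyModel({self.name!r}, k={self.free_parameter_count}, "
            f"moieties={[m.name for m in self.moieties]})"
        )


# -- module-level operations ----------------------------------------------


def free_parameter_names(model: MoietyModel) -> list[str]:
    """Ordered identifiers of the model's free parameters (length = k)."""
    return model.free_parameter_names()


def expand_state_values(
    model: MoietyModel, params: np.ndarray
) -> tuple[StateValues, bool]:
    """Map a free-parameter vector onto all moiety-state fractions.

    See :meth:`MoietyModel.expand_state_values`.
    """
    return model.expand_state_values(params)


def state_combinations(
    molecule: Molecule,
) -> list[tuple[JointState, ...]]:
    """Cartesian product of moiety states, one JointState per moiety, in
    deterministic (declaration) order."""
    return list(itertools.product(*(m.states for m in molecule.moieties)))


def possible_isotopologue_count(molecule: Molecule) -> int:
    """Size of the molecule's isotopologue content grid:
    ``prod(total_labellable_atoms[e] + 1)`` over tracked isotopes."""
    return math.prod(n + 1 for _, n in molecule.total_labellable_atoms)


def content_grid(molecule: Molecule) -> list[tuple[int, ...]]:
    """All content tuples of the molecule's grid in lexicographic order.

    Axis order follows the isotope declaration order of
    `total_labellable_atoms`; a molecule with no tracked isotopes has the
    single empty-content entry (the unlabeled species).
    """
    ranges = [range(n + 1) for _, n in molecule.total_labellable_atoms]
    return list(itertools.product(*ranges))
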
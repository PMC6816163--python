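"""Forward calculation of relative isotopologue intensities.

Given moiety-state fractions, the calculated intensity of the isotopologue
with isotope content x is the sum over all one-state-per-moiety
combinations whose contents add up to x of the product of the involved
state fractions:

    I_x,calc = sum_{v : content(v) = x} prod_j moiety_state_{j, v_j}

Because each moiety's fractions sum to one, the calculated profile sums to
one over the full content grid whenever the state values are feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GridMismatchError
from .model import Molecule, MoietyModel, StateValues, content_grid, state_combinations

__all__ = [
    "IsotopologueProfile",
    "isotopologue_components",
    "calc_intensity_profile",
    "ProfileEvaluator",
]


@dataclass
class IsotopologueProfile:
    """Relative intensities over a molecule's full isotopologue grid.

    Entries cover every content tuple of the grid (lexicographic order,
    axis order = isotope declaration order); unreachable or unobserved
    isotopologues carry intensity 0.
    """

    molecule_name: str
    isotopes: tuple[str, ...]
    contents: tuple[tuple[int, ...], ...]
    intensities: np.ndarray
    std_err: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.contents) != self.intensities.shape[0]:
            raise ValueError("contents and intensities lengths differ")
        if np.any(self.intensities < 0):
            raise ValueError("isotopologue intensities must be non-negative")

    def check_same_grid(self, other: "IsotopologueProfile") -> None:
        if self.contents != other.contents or self.isotopes != other.isotopes:
            raise GridMismatchError(
                f"profiles for {self.molecule_name!r} and "
                f"{other.molecule_name!r} are on different content grids"
            )

    def as_dict(self) -> dict[tuple[int, ...], float]:
        return dict(zip(self.contents, self.intensities.tolist()))

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


def isotopologue_components(
    molecule: Molecule, values: StateValues
) -> dict[tuple[int, ...], list[float]]:
    """Component products feeding each isotopologue intensity.

    For every one-state-per-moiety combination, the product of the involved
    state fractions is appended to the bucket of its summed isotope content.
    Buckets for unreachable contents are empty lists.
    """
    isotopes = molecule.isotopes
    buckets: dict[tuple[int, ...], list[float]] = {c: [] for c in content_grid(molecule)}
    for combo in state_combinations(molecule):
        content = tuple(
            sum(s.content(iso) for s in combo) for iso in isotopes
        )
        product = 1.0
        for m, s in zip(molecule.moieties, combo):
            product *= values.value(m.name, s.label)
        buckets[content].append(product)
    return buckets


def calc_intensity_profile(
    molecule: Molecule, values: StateValues
) -> IsotopologueProfile:
    """Calculated relative isotopologue profile for a molecule.

    Each grid entry is the sum of its component products; for feasible
    state values the entries sum to 1 (to within 1e-9).
    """
    buckets = isotopologue_components(molecule, values)
    contents = tuple(content_grid(molecule))
    intensities = np.array([sum(buckets[c]) for c in contents])
    # guard tiny negative rounding from relationship arithmetic
    intensities[np.abs(intensities) < 1e-300] = 0.0
    return IsotopologueProfile(
        molecule_name=molecule.name,
        isotopes=molecule.isotopes,
        contents=contents,
        intensities=intensities,
    )


class ProfileEvaluator:
    """Vectorized forward calculation bound to one (model, molecule) pair.

    Precomputes, for every moiety-state combination, the global state
    indices involved and the flat grid index of its summed content, so that
    a profile evaluation reduces to a gather, a row product and a bincount.
    Used by the optimizer where :func:`calc_intensity_profile` would be too
    slow; both paths are equivalent and tested against each other.
    """

    def __init__(self, model: MoietyModel, molecule: Molecule):
        self.model = model
        self.molecule = molecule
        self.contents = tuple(content_grid(molecule))
        self.n_grid = len(self.contents)
        grid_index = {c: i for i, c in enumerate(self.contents)}
        isotopes = molecule.isotopes
        combo_state_idx = []
        combo_grid_idx = []
        for combo in state_combinations(molecule):
            combo_state_idx.append(
                [model.state_index[(m.name, s.label)] for m, s in zip(molecule.moieties, combo)]
            )
            content = tuple(sum(s.content(iso) for s in combo) for iso in isotopes)
            combo_grid_idx.append(grid_index[content])
        self._state_idx = np.array(combo_state_idx, dtype=np.intp)
        self._grid_idx = np.array(combo_grid_idx, dtype=np.intp)

    def intensities(self, state_vector: np.ndarray) -> np.ndarray:
        """Profile over the flat grid from a global state-value vector."""
        products = state_vector[self._state_idx].prod(axis=1)
        return np.bincount(self._grid_idx, weights=products, minlength=self.n_grid)

    def profile(self, state_vector: np.ndarray) -> IsotopologueProfile:
        return IsotopologueProfile(
            molecule_name=self.molecule.name,
            isotopes=self.molecule.isotopes,
            contents=self.contents,
            intensities=self.intensities(state_vector),
        )
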
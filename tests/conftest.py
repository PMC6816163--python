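import numpy as np
import pytest

import moietykit as mk


@pytest.fixture
def expert_single():
    return mk.build_fixture("expert_single")


@pytest.fixture
def expert_multi():
    return mk.build_fixture("expert_multi")


def random_model(rng: np.random.Generator, max_moieties: int = 4):
    """A random small moiety model with feasible random state values.

    Used by normalization/round-trip property tests; state fractions are
    drawn from a Dirichlet so each moiety's states sum to one.
    """
    n_moieties = int(rng.integers(1, max_moieties + 1))
    isotopes = ["13C"] if rng.random() < 0.7 else ["13C", "18O"]
    moieties = []
    values = {}
    totals = {iso: 0 for iso in isotopes}
    for i in range(n_moieties):
        atoms = {iso: int(rng.integers(1, 5)) for iso in isotopes}
        max_states = int(np.prod([atoms[iso] + 1 for iso in isotopes]))
        n_states = int(rng.integers(1, min(4, max_states + 1)))
        contents = set()
        while len(contents) < n_states:
            contents.add(tuple(int(rng.integers(0, atoms[iso] + 1)) for iso in isotopes))
        states = [mk.state_label(zip(isotopes, c)) for c in sorted(contents)]
        name = f"m{i}"
        moieties.append(mk.Moiety(name, atoms, states))
        fracs = rng.dirichlet(np.ones(n_states))
        for label, f in zip(states, fracs):
            values[(name, label)] = float(f)
        for iso in isotopes:
            totals[iso] += atoms[iso]
    molecule = mk.Molecule("random_molecule", moieties, totals)
    model = mk.MoietyModel("random_model", moieties, [molecule])
    return model, mk.StateValues(values)


def brute_force_profile(molecule, values):
    """Independent forward-calculation oracle: naive enumeration of all
    state combinations into a plain dict, no shared code with the
    implementation's bucketing."""
    out = {c: 0.0 for c in mk.content_grid(molecule)}
    def walk(i, content, product):
        if i == len(molecule.moieties):
            out[tuple(content)] += product
            return
        m = molecule.moieties[i]
        for s in m.states:
            new_content = [
                c + s.content(iso) for c, iso in zip(content, molecule.isotopes)
            ]
            walk(i + 1, new_content, product * values.value(m.name, s.label))
    walk(0, [0] * len(molecule.isotopes), 1.0)
    return out
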
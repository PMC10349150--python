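import numpy as np
import pytest

from ripptide.molgraph import MolecularGraph
from ripptide.ptm import load_default_rules

_VALENCE = {"C": 4, "N": 3, "O": 2}


def random_molecule(rng: np.random.Generator, n_atoms: int,
                    elements: str = "CCCNO") -> MolecularGraph:
    """Random valence-legal connected molecular graph (heavy atoms only).

    Built as a random tree plus occasional extra ring bonds; bond orders
    1 or 2 where valence budgets allow.
    """
    g = MolecularGraph()
    budget = {}
    for i in range(n_atoms):
        el = str(rng.choice(list(elements)))
        g.add_atom(el)
        budget[i] = _VALENCE[el]
    order = list(range(n_atoms))
    for i in range(1, n_atoms):
        # attach to a previous atom with remaining valence
        choices = [j for j in order[:i] if budget[j] >= 1]
        if not choices:
            choices = order[:i]
        j = int(rng.choice(choices))
        bo = 2 if (budget[j] >= 2 and budget[i] >= 2 and rng.random() < 0.2) else 1
        g.add_bond(i, j, bo)
        budget[i] -= bo
        budget[j] -= bo
    # occasional ring closure
    if n_atoms >= 4 and rng.random() < 0.4:
        cands = [(i, j) for i in range(n_atoms) for j in range(i + 2, n_atoms)
                 if budget[i] >= 1 and budget[j] >= 1
                 and frozenset((i, j)) not in g.bonds]
        if cands:
            i, j = cands[int(rng.integers(len(cands)))]
            g.add_bond(i, j, 1)
            budget[i] -= 1
            budget[j] -= 1
    # fill implicit hydrogens to standard valence
    for i in range(n_atoms):
        g.set_implicit_h(i, max(0, budget[i]))
    return g


def relabel(g: MolecularGraph, perm: dict) -> MolecularGraph:
    out = MolecularGraph()
    for i, atom in g.atoms.items():
        out.add_atom(atom.element, atom.implicit_h, atom.charge, index=perm[i])
    for key, bo in g.bonds.items():
        i, j = tuple(key)
        out.add_bond(perm[i], perm[j], bo)
    return out


@pytest.fixture(scope="session")
def rules_db():
    return load_default_rules()
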
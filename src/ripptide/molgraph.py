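"""Molecular graphs, SMILES I/O, and peptide construction.

The molecular graph is the substrate for everything downstream: motif
matching, graph-edit modifications, and fragmentation.  Atoms are heavy
atoms with implicit hydrogen counts (explicit H nodes appear only
transiently, e.g. while a modification rule manipulates them); bonds carry
one of four classes — orders 1/2/3 plus a distinct aromatic class
(``AROMATIC``), so that an aromatic ring matches an aromatic motif as a
unit regardless of any particular Kekule assignment.  The bond classes the
fragmentation scorer breaks (C-C / O-C / N-C) are element-based and
independent of order.  Stereochemistry is parsed and dropped: all
downstream logic is constitution-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: monoisotopic (principal isotope) masses, from the NIST table
MONOISOTOPIC = {el: data[0][0] for el, data in _pmass.nist_mass.items()}
#: mass of a proton, for charge/neutral conversions
PROTON_MASS = 1.00727646688

#: bond-class marker for aromatic bonds (orders are otherwise 1/2/3)
AROMATIC = 4

_DEFAULT_VALENCE = {
    "C": 4, "N": 3, "O": 2, "S": 6, "P": 5, "H": 1,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 3, "Se": 6,
}


class MolGraphError(ValueError):
    pass


class SmilesParseError(MolGraphError):
    pass


@dataclass(frozen=True)
class Atom:
    element: str
    implicit_h: int = 0
    charge: int = 0


@dataclass
class MolecularGraph:
    """Labeled atom/bond graph with stable integer atom indices.

    ``atoms`` maps index -> Atom; ``bonds`` maps frozenset({i, j}) -> bond
    order.  Indices are arbitrary non-negative integers and survive copying
    and editing, which is what lets modification rules refer to atoms by
    index across a sequence of edits.
    """

    atoms: dict[int, Atom] = field(default_factory=dict)
    bonds: dict[frozenset, int] = field(default_factory=dict)
    residue_map: dict[int, set[int]] | None = None

    # -- construction helpers -------------------------------------------------

    def add_atom(self, element: str, implicit_h: int = 0, charge: int = 0,
                 index: int | None = None) -> int:
        if index is None:
            index = max(self.atoms, default=-1) + 1
        if index in self.atoms:
            raise MolGraphError(f"atom index {index} already present")
        if implicit_h < 0:
            raise MolGraphError("implicit hydrogen count must be non-negative")
        self.atoms[index] = Atom(element, implicit_h, charge)
        return index

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        if i == j or i not in self.atoms or j not in self.atoms:
            raise MolGraphError(f"bad bond endpoints ({i}, {j})")
        key = frozenset((i, j))
        if key in self.bonds:
            raise MolGraphError(f"bond ({i}, {j}) already present")
        self.bonds[key] = order

    def remove_atom(self, i: int) -> None:
        if i not in self.atoms:
            raise MolGraphError(f"no atom {i}")
        del self.atoms[i]
        for key in [k for k in self.bonds if i in k]:
            del self.bonds[key]
        if self.residue_map:
            for members in self.residue_map.values():
                members.discard(i)

    def remove_bond(self, i: int, j: int) -> None:
        key = frozenset((i, j))
        if key not in self.bonds:
            raise MolGraphError(f"no bond ({i}, {j})")
        del self.bonds[key]

    def set_implicit_h(self, i: int, count: int) -> None:
        if count < 0:
            raise MolGraphError("implicit hydrogen count must be non-negative")
        self.atoms[i] = replace(self.atoms[i], implicit_h=count)

    # -- queries --------------------------------------------------------------

    def neighbors(self, i: int) -> list[int]:
        return sorted(j for key in self.bonds if i in key
                      for j in key if j != i)

    def bond_order(self, i: int, j: int) -> int:
        return self.bonds[frozenset((i, j))]

    def degree(self, i: int) -> int:
        return sum(1 for key in self.bonds if i in key)

    def valence(self, i: int) -> int:
        """Total bond-order sum including implicit hydrogens."""
        s = sum(o for key, o in self.bonds.items() if i in key)
        return s + self.atoms[i].implicit_h

    def copy(self) -> "MolecularGraph":
        rmap = None
        if self.residue_map is not None:
            rmap = {pos: set(members) for pos, members in self.residue_map.items()}
        return MolecularGraph(dict(self.atoms), dict(self.bonds), rmap)

    def formula(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.atoms.values():
            counts[atom.element] = counts.get(atom.element, 0) + 1
            if atom.implicit_h:
                counts["H"] = counts.get("H", 0) + atom.implicit_h
        return {el: n for el, n in counts.items() if n}

    def check_valences(self) -> None:
        """Raise if any atom exceeds its maximum allowed valence.

        Atoms participating in aromatic bonds are skipped (their bonding is
        validated by the SMILES layer's aromaticity perception instead).
        """
        for i, atom in self.atoms.items():
            limit = _DEFAULT_VALENCE.get(atom.element)
            if limit is None:
                continue
            if any(o == AROMATIC for key, o in self.bonds.items() if i in key):
                continue
            v = self.valence(i) - atom.charge
            if v > limit or (atom.element == "H" and v != 1 and self.degree(i) > 0):
                raise MolGraphError(
                    f"valence {v} on atom {i} ({atom.element}) exceeds {limit}")

    def connected_components(self) -> list[set[int]]:
        seen: set[int] = set()
        comps = []
        for start in self.atoms:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                i = stack.pop()
                if i in comp:
                    continue
                comp.add(i)
                stack.extend(j for j in self.neighbors(i) if j not in comp)
            seen |= comp
            comps.append(comp)
        return comps


def monoisotopic_mass(g: MolecularGraph) -> float:
    """Sum of principal-isotope masses over all atoms, implicit H included."""
    total = 0.0
    for atom in g.atoms.values():
        try:
            total += MONOISOTOPIC[atom.element]
        except KeyError:
            raise MolGraphError(f"no monoisotopic mass for element {atom.element!r}")
        total += atom.implicit_h * MONOISOTOPIC["H"]
    return total


# -- rdkit bridge -------------------------------------------------------------

_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}
_RD_BONDS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
             3: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC}


def from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    g = MolecularGraph()
    for atom in mol.GetAtoms():
        g.add_atom(atom.GetSymbol(), atom.GetTotalNumHs(), atom.GetFormalCharge(),
                   index=atom.GetIdx())
    for bond in mol.GetBonds():
        order = _BOND_ORDERS.get(bond.GetBondType())
        if order is None:
            raise MolGraphError(f"unsupported bond type {bond.GetBondType()}")
        g.add_bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order)
    return g


def to_rdkit(g: MolecularGraph, sanitize: bool = True) -> Chem.Mol:
    rw = Chem.RWMol()
    order = sorted(g.atoms)
    remap = {}
    for i in order:
        atom = g.atoms[i]
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.charge)
        a.SetNumExplicitHs(atom.implicit_h)
        a.SetNoImplicit(True)
        remap[i] = rw.AddAtom(a)
    for key, bo in g.bonds.items():
        i, j = sorted(key)
        rw.AddBond(remap[i], remap[j], _RD_BONDS[bo])
        if bo == AROMATIC:
            for a in (remap[i], remap[j]):
                rw.GetAtomWithIdx(a).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(remap[i], remap[j]).SetIsAromatic(True)
    mol = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(mol)
    return mol


def parse_smiles(text: str) -> MolecularGraph:
    """Parse a SMILES string into a MolecularGraph.

    Stereochemistry marks are accepted and dropped with a warning; aromatic
    bonds keep their own bond class rather than a Kekule assignment.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        pos = _first_bad_position(text)
        where = f" near position {pos}" if pos is not None else ""
        raise SmilesParseError(f"cannot parse SMILES {text!r}{where}")
    if any(ch in text for ch in ("@", "/", "\\")):
        warnings.warn(f"stereochemistry in {text!r} is ignored", stacklevel=2)
        Chem.RemoveStereochemistry(mol)
    return from_rdkit(mol)


def _first_bad_position(text: str) -> int | None:
    allowed = set("ABCDEFGHIKLMNOPRSTUVWXYZabcdefghiklmnoprstuy0123456789"
                  "()[]{}=#-+/\\@%.*$:~")
    for pos, ch in enumerate(text):
        if ch not in allowed:
            return pos
    # syntactically bad but alphabet-clean: find the shortest unparseable prefix
    for pos in range(1, len(text) + 1):
        if Chem.MolFromSmiles(text[:pos]) is None and text[:pos].count("(") == text[:pos].count(")"):
            return pos - 1
    return None


def write_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES: isomorphic graphs give byte-identical strings."""
    return Chem.MolToSmiles(to_rdkit(g))
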
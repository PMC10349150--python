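"""Residue templates and peptide assembly.

Each proteinogenic residue is a small subgraph template (-NH-CHR-CO-) with a
designated backbone nitrogen and carbonyl carbon; peptides are assembled by
chaining templates N-to-C with amide bonds, leaving a free N-terminal amine
and a free C-terminal carboxylic acid.  Stereochemistry is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

from .molgraph import MolecularGraph, MolGraphError, parse_smiles

def _load_residue_smiles(path=None) -> dict:
    """Residue unit SMILES, from the packaged table or a user-supplied one.

    Each line: one-letter code, TAB, SMILES written so atom 0 is the
    backbone N and the backbone carbonyl C/O are the last two atoms.
    """
    if path is None:
        from importlib.resources import files
        text = files("ripptide.data").joinpath("residues.tsv").read_text()
    else:
        text = open(path).read()
    table = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        code, smiles = line.split("\t")
        table[code] = smiles
    return table


@dataclass(frozen=True)
class ResidueTemplate:
    code: str
    graph: MolecularGraph        # indices 0..n-1, atom 0 = backbone N
    n_atom: int                  # backbone nitrogen
    c_atom: int                  # backbone carbonyl carbon


class ResidueTemplateTable(dict):
    """Mapping one-letter code -> ResidueTemplate."""


def default_templates(path=None) -> ResidueTemplateTable:
    table = ResidueTemplateTable()
    for code, smi in _load_residue_smiles(path).items():
        g = parse_smiles(smi)
        n = len(g.atoms)
        # carbonyl C is second-to-last atom in the template SMILES by design
        table[code] = ResidueTemplate(code, g, n_atom=0, c_atom=n - 2)
    return table


_DEFAULT = None


def _templates() -> ResidueTemplateTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = default_templates()
    return _DEFAULT


def build_peptide(core: str, templates: ResidueTemplateTable | None = None) -> MolecularGraph:
    """Build the linear peptide graph for a core amino-acid sequence.

    Residues are joined by amide bonds N-to-C; the graph carries a residue
    map (0-based residue position -> atom index set) so that modification
    provenance can be traced back to sequence positions.
    """
    if not core:
        raise MolGraphError("core sequence is empty")
    templates = templates if templates is not None else _templates()
    pep = MolecularGraph(residue_map={})
    prev_c: int | None = None
    offset = 0
    for pos, letter in enumerate(core):
        tmpl = templates.get(letter)
        if tmpl is None:
            raise MolGraphError(f"unknown residue {letter!r} at position {pos}")
        remap = {}
        members = set()
        for i in sorted(tmpl.graph.atoms):
            atom = tmpl.graph.atoms[i]
            new = pep.add_atom(atom.element, atom.implicit_h, atom.charge,
                               index=offset + i)
            remap[i] = new
            members.add(new)
        for key, order in tmpl.graph.bonds.items():
            i, j = sorted(key)
            pep.add_bond(remap[i], remap[j], order)
        n_idx = remap[tmpl.n_atom]
        if prev_c is not None:
            # amide bond consumes one H on each side (templates parse as the
            # free-terminal forms: N-H2 amine, H-C=O aldehyde carbon)
            for idx, what in ((n_idx, "nitrogen"), (prev_c, "carbonyl carbon")):
                h = pep.atoms[idx].implicit_h
                if h < 1:
                    raise MolGraphError(
                        f"residue {letter!r} {what} has no H to form amide")
                pep.set_implicit_h(idx, h - 1)
            pep.add_bond(prev_c, n_idx)
        prev_c = remap[tmpl.c_atom]
        pep.residue_map[pos] = members
        offset += len(tmpl.graph.atoms)
    # free C-terminus: carbonyl carbon becomes a carboxylic acid
    pep.set_implicit_h(prev_c, pep.atoms[prev_c].implicit_h - 1)
    oh = pep.add_atom("O", implicit_h=1)
    pep.add_bond(prev_c, oh)
    pep.residue_map[len(core) - 1].add(oh)
    pep.check_valences()
    return pep
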
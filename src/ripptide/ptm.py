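"""Modification rules and combinatorial enumeration of mature RiPPs.

A tailoring enzyme is modeled as a rule: a chemical motif (SMILES, possibly
with explicit hydrogens so that actions can address them) plus an ordered
list of graph-edit actions in a four-verb grammar::

    disconnect I J      remove the bond between motif atoms I and J
    connect I J K       create (or re-order) a bond of order K
    remove I            delete atom I and its incident bonds
    add I FORMULA       attach a one-heavy-atom group (CH3, OH, H, ...) to I

Indices are 1-based positions in the motif SMILES atom order; atoms added
by ``add`` get the next indices in order of appearance.  Wherever the motif
embeds in a molecule (subgraph isomorphism, deduplicated by mapped atom
set), the rule may be applied; core2ripp enumerates every subset of the
optional (rule, site) pairs, which is what turns one core peptide into a
combinatorial family of hypothetical mature products — 10 feasible
modifications at distinct sites yield 2^10 = 1024 products.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations

from rdkit import Chem

from .molgraph import (MolecularGraph, MolGraphError, from_rdkit,
                       write_smiles)
from .motifs import find_embeddings, strip_hydrogens
from .residues import build_peptide

logger = logging.getLogger(__name__)

DEFAULT_CAP = 2 ** 16


class RuleError(ValueError):
    pass


@dataclass(frozen=True)
class Action:
    verb: str                      # add | remove | connect | disconnect
    atoms: tuple[int, ...]         # 1-based motif-frame indices
    order: int | None = None       # connect only
    fragment: str | None = None    # add only, e.g. "CH3"


@dataclass
class ModificationRule:
    name: str
    motif_smiles: str
    actions: list[Action]
    enzymes: frozenset[str] = frozenset()
    optional: bool = True
    # derived at validation time
    motif: MolecularGraph = None
    stripped: MolecularGraph = None
    h_owner: dict = None           # motif H atom idx -> heavy neighbor idx

    def formula_delta(self) -> dict[str, int]:
        """Net formula change, by replaying the actions on the bare motif."""
        before = self.motif.formula()
        after = _replay_on_motif(self).formula()
        delta = {}
        for el in set(before) | set(after):
            d = after.get(el, 0) - before.get(el, 0)
            if d:
                delta[el] = d
        return delta

    def mass_delta(self) -> float:
        from .molgraph import MONOISOTOPIC
        return sum(n * MONOISOTOPIC[el] for el, n in self.formula_delta().items())


@dataclass
class RuleDatabase:
    rules: list[ModificationRule] = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise RuleError("duplicate rule names")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)

    def by_name(self, name: str) -> ModificationRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)

    def licensed(self, enzyme_profiles: set[str]) -> list[ModificationRule]:
        """Rules whose enzyme profile set intersects the given profiles."""
        profiles = set(enzyme_profiles)
        return [r for r in self.rules if r.enzymes & profiles]


# -- rule file parsing --------------------------------------------------------

_FRAGMENT_RE = re.compile(r"^([A-Z][a-z]?)(H(\d*))?$")
_VERBS = {"add", "remove", "connect", "disconnect"}


def _parse_fragment(text: str) -> tuple[str, int]:
    """'CH3' -> ('C', 3); 'OH' -> ('O', 1); 'H' -> ('H', 0)."""
    text = text.replace("_", "")
    m = _FRAGMENT_RE.match(text)
    if not m:
        raise RuleError(f"cannot parse fragment formula {text!r}")
    el = m.group(1)
    if m.group(2) is None:
        nh = 0
    else:
        nh = int(m.group(3)) if m.group(3) else 1
    return el, nh


def parse_rule_file(text: str) -> RuleDatabase:
    """Parse the plain-text rule format (blank-line-separated blocks)."""
    rules = []
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            if block:
                rules.append(_parse_block(block))
                block = []
            continue
        block.append((lineno, line.strip()))
    if block:
        rules.append(_parse_block(block))
    return RuleDatabase(rules)


def _parse_block(block: list[tuple[int, str]]) -> ModificationRule:
    name = motif = None
    enzymes: frozenset[str] = frozenset()
    optional = True
    actions: list[Action] = []
    n_added = 0
    for lineno, line in block:
        low = line.lower()
        if low.startswith("name:"):
            name = line.split(":", 1)[1].strip()
            continue
        if low.startswith("motif:"):
            motif = line.split(":", 1)[1].strip()
            continue
        if low.startswith("enzymes:"):
            enzymes = frozenset(line.split(":", 1)[1].split())
            continue
        if low.startswith("optional:"):
            optional = line.split(":", 1)[1].strip().lower() in ("true", "yes", "1")
            continue
        parts = line.split()
        verb = parts[0].lower()
        if verb not in _VERBS:
            raise RuleError(f"line {lineno}: unknown verb {parts[0]!r}")
        try:
            if verb == "disconnect" and len(parts) == 3:
                actions.append(Action("disconnect", (int(parts[1]), int(parts[2]))))
            elif verb == "connect" and len(parts) == 4:
                actions.append(Action("connect", (int(parts[1]), int(parts[2])),
                                      order=int(parts[3])))
            elif verb == "remove" and len(parts) == 2:
                actions.append(Action("remove", (int(parts[1]),)))
            elif verb == "add" and len(parts) == 3:
                el, nh = _parse_fragment(parts[2])
                actions.append(Action("add", (int(parts[1]),), fragment=parts[2]))
                n_added += 1
            else:
                raise RuleError(f"line {lineno}: malformed action {line!r}")
        except ValueError as exc:
            raise RuleError(f"line {lineno}: {exc}") from None
    if name is None or motif is None:
        raise RuleError(f"rule block near line {block[0][0]} missing name/motif")
    rule = ModificationRule(name, motif, actions, enzymes, optional)
    _validate_rule(rule)
    return rule


def _parse_motif(smiles: str) -> MolecularGraph:
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise RuleError(f"motif SMILES does not parse: {smiles!r}")
    return from_rdkit(mol)


def _validate_rule(rule: ModificationRule) -> None:
    rule.motif = _parse_motif(rule.motif_smiles)
    rule.stripped, absorbed = strip_hydrogens(rule.motif)
    rule.h_owner = absorbed
    avail = len(rule.motif.atoms)
    for k, action in enumerate(rule.actions):
        for a in action.atoms:
            if not 1 <= a <= avail:
                raise RuleError(
                    f"rule {rule.name!r}: action {k + 1} index {a} out of range")
        if action.verb == "add":
            avail += 1
    # replay on the bare motif: must yield a valence-legal graph
    try:
        _replay_on_motif(rule)
    except MolGraphError as exc:
        raise RuleError(f"rule {rule.name!r} is not valence-legal on its motif: {exc}")


def _replay_on_motif(rule: ModificationRule) -> MolecularGraph:
    subject, _ = strip_hydrogens(rule.motif)
    site = Site(rule, {qi: qi for qi in rule.stripped.atoms},
                frozenset(rule.stripped.atoms))
    return apply_rule(subject, rule, site)


# -- site finding and application ---------------------------------------------

@dataclass(frozen=True)
class Site:
    rule: ModificationRule
    embedding: dict          # stripped-motif atom idx -> subject atom idx
    atoms: frozenset         # mapped subject atoms (dedup key)

    def __hash__(self):
        return hash((self.rule.name, self.atoms))


def find_sites(rule: ModificationRule, g: MolecularGraph) -> list[Site]:
    """Distinct atom-set placements of the rule motif in g, in deterministic order."""
    from collections import Counter
    embeddings = find_embeddings(rule.stripped, g)
    # the rule's explicit hydrogens must be available as implicit H on the
    # mapped subject atoms, or application is impossible
    need = Counter(rule.h_owner.values())
    seen: set[frozenset] = set()
    sites = []
    for emb in embeddings:
        if any(g.atoms[emb[q]].implicit_h < c for q, c in need.items()):
            continue
        atoms = frozenset(emb.values())
        if atoms in seen:
            continue
        seen.add(atoms)
        sites.append(Site(rule, emb, atoms))
    return sites


def apply_rule(g: MolecularGraph, rule: ModificationRule, site: Site) -> MolecularGraph:
    """Apply the rule's actions at a site.  The input graph is not modified."""
    work = g.copy()
    # frame: 1-based motif index -> atom index in work
    frame: dict[int, int] = {}
    for qi, sj in site.embedding.items():
        frame[qi + 1] = sj
    # materialize the motif's explicit hydrogens from implicit counts
    for h_idx in sorted(rule.h_owner):
        heavy_q = rule.h_owner[h_idx]
        heavy_s = frame.get(heavy_q + 1)
        if heavy_s is None:
            raise MolGraphError(
                f"rule {rule.name!r}: hydrogen owner atom not in embedding")
        if work.atoms[heavy_s].implicit_h < 1:
            raise MolGraphError(
                f"rule {rule.name!r}: no hydrogen available on atom {heavy_s}")
        work.set_implicit_h(heavy_s, work.atoms[heavy_s].implicit_h - 1)
        new = work.add_atom("H")
        work.add_bond(heavy_s, new)
        frame[h_idx + 1] = new

    next_frame = len(rule.motif.atoms) + 1
    for k, action in enumerate(rule.actions):
        try:
            resolved = []
            for a in action.atoms:
                if a not in frame:
                    raise MolGraphError(f"frame index {a} no longer exists")
                resolved.append(frame[a])
            if action.verb == "disconnect":
                work.remove_bond(*resolved)
            elif action.verb == "connect":
                key = frozenset(resolved)
                if key in work.bonds:
                    work.bonds[key] = action.order
                else:
                    work.add_bond(*resolved, order=action.order)
            elif action.verb == "remove":
                work.remove_atom(resolved[0])
                frame = {fi: ai for fi, ai in frame.items() if ai != resolved[0]}
            elif action.verb == "add":
                el, nh = _parse_fragment(action.fragment)
                new = work.add_atom(el, implicit_h=nh)
                work.add_bond(resolved[0], new)
                frame[next_frame] = new
                next_frame += 1
        except MolGraphError as exc:
            raise MolGraphError(
                f"rule {rule.name!r}, action {k + 1} ({action.verb}): {exc}")
    # re-collapse any hydrogens that survived, then validate
    out, _ = strip_hydrogens(work)
    out.check_valences()
    if site is not None and g.residue_map is not None:
        out.residue_map = {pos: set(members) & set(out.atoms)
                           for pos, members in g.residue_map.items()}
    return out


def _site_still_valid(g: MolecularGraph, site: Site) -> bool:
    rule = site.rule
    for qi, sj in site.embedding.items():
        if sj not in g.atoms or g.atoms[sj].element != rule.stripped.atoms[qi].element:
            return False
    for key, order in rule.stripped.bonds.items():
        i, j = tuple(key)
        if g.bonds.get(frozenset((site.embedding[i], site.embedding[j]))) != order:
            return False
    return True


@dataclass
class ProductSet:
    """Canonical SMILES of enumerated products, with a truncation flag."""
    smiles: frozenset
    truncated: bool = False

    def __iter__(self):
        return iter(sorted(self.smiles))

    def __len__(self):
        return len(self.smiles)

    def __contains__(self, s):
        return s in self.smiles


def enumerate_products(core_graph: MolecularGraph,
                       applicable: list[tuple[ModificationRule, Site]],
                       cap: int = DEFAULT_CAP) -> ProductSet:
    """One product per subset of the optional (rule, site) pairs.

    Sites are applied in deterministic order (rule name, then smallest mapped
    atom index); a subset whose later site no longer embeds after earlier
    edits is skipped, which keeps every product valence-legal.  Mandatory
    (non-optional) sites are part of every subset.
    """
    ordered = sorted(applicable, key=lambda rs: (rs[0].name, min(rs[1].atoms)))
    mandatory = [rs for rs in ordered if not rs[0].optional]
    optionals = [rs for rs in ordered if rs[0].optional]
    m = len(optionals)
    products: set[str] = set()
    truncated = False
    n_subsets = 0
    done = False
    for size in range(0, m + 1):
        if done:
            break
        for chosen in combinations(range(m), size):
            if n_subsets >= cap:
                truncated = True
                done = True
                break
            n_subsets += 1
            subset = sorted(mandatory + [optionals[i] for i in chosen],
                            key=lambda rs: (rs[0].name, min(rs[1].atoms)))
            g = core_graph
            ok = True
            for rule, site in subset:
                if not _site_still_valid(g, site):
                    ok = False
                    break
                try:
                    g = apply_rule(g, rule, site)
                except MolGraphError:
                    ok = False
                    break
            if ok:
                products.add(write_smiles(g))
    if truncated:
        logger.warning("enumeration cap %d reached; product set truncated", cap)
    return ProductSet(frozenset(products), truncated)


def collect_sites(core_graph: MolecularGraph,
                  rules: list[ModificationRule]) -> list[tuple[ModificationRule, Site]]:
    pairs = []
    for rule in sorted(rules, key=lambda r: r.name):
        for site in find_sites(rule, core_graph):
            pairs.append((rule, site))
    return pairs


def core2ripp(core: str, enzyme_profiles: set[str], rules: RuleDatabase,
              cap: int = DEFAULT_CAP) -> ProductSet:
    """Hypothetical mature products for a core given the BGC's enzymes."""
    g = build_peptide(core)
    licensed = rules.licensed(enzyme_profiles)
    return enumerate_products(g, collect_sites(g, licensed), cap=cap)


# -- packaged rule set --------------------------------------------------------

def load_default_rules() -> RuleDatabase:
    """The curated rule set shipped with the package."""
    from importlib.resources import files
    text = files("ripptide.data").joinpath("modifications.rules").read_text()
    return parse_rule_file(text)
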
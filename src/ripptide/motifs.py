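"""Subgraph isomorphism for chemical motif finding.

A modified Ullmann matcher: an m x n binary correspondence matrix is built
from element labels plus a neighborhood filter (the multiset of
(neighbor element, bond order) pairs of a query atom must be a sub-multiset
of the subject atom's), then embeddings are enumerated by backtracking over
a breadth-first spanning order of the query so each newly placed query atom
is adjacent to an already-placed one whenever the query is connected.
Hydrogens are stripped from both sides before matching.

``brute_force_embeddings`` is a deliberately naive oracle over all
injective maps, exported for verification.
"""

from __future__ import annotations

from collections import Counter, deque
from itertools import permutations

from .molgraph import MolecularGraph, MolGraphError

#: Embedding = dict query atom index -> subject atom index
Embedding = dict

MAX_QUERY_ATOMS = 50


def strip_hydrogens(g: MolecularGraph) -> tuple[MolecularGraph, dict[int, int]]:
    """Remove explicit H nodes, folding them into implicit counts.

    Returns the stripped graph and a map from H atom index to the heavy
    neighbor that absorbed it (free-floating H atoms are dropped).  Mass is
    conserved for H bound to exactly one heavy atom.
    """
    out = g.copy()
    absorbed: dict[int, int] = {}
    for i in [i for i, a in g.atoms.items() if a.element == "H"]:
        heavy = [j for j in out.neighbors(i) if out.atoms[j].element != "H"]
        if heavy:
            j = heavy[0]
            out.set_implicit_h(j, out.atoms[j].implicit_h + 1)
            absorbed[i] = j
        out.remove_atom(i)
    return out, absorbed


def _neighborhood(g: MolecularGraph, i: int) -> Counter:
    return Counter((g.atoms[j].element, g.bond_order(i, j)) for j in g.neighbors(i))


def _correspondence(query: MolecularGraph, subject: MolecularGraph):
    """Initial candidate sets: label equality + neighborhood sub-multiset."""
    subj_nbh = {j: _neighborhood(subject, j) for j in subject.atoms}
    cand = {}
    for qi in query.atoms:
        qn = _neighborhood(query, qi)
        cand[qi] = [
            sj for sj in sorted(subject.atoms)
            if subject.atoms[sj].element == query.atoms[qi].element
            and not qn - subj_nbh[sj]
        ]
    return cand

def _bfs_order(query: MolecularGraph) -> list[int]:
    """Breadth-first order from the lowest-index atom of each component."""
    order, seen = [], set()
    for root in sorted(query.atoms):
        if root in seen:
            continue
        dq = deque([root])
        seen.add(root)
        while dq:
            i = dq.popleft()
            order.append(i)
            for j in query.neighbors(i):
                if j not in seen:
                    seen.add(j)
                    dq.append(j)
    return order


def find_embeddings(query: MolecularGraph, subject: MolecularGraph) -> list[Embedding]:
    """All injective label- and bond-order-preserving maps of query into subject.

    Both graphs must be hydrogen-stripped.  Results are in deterministic
    lexicographic order of the mapped subject indices (in query-index order);
    automorphic duplicates are returned, not collapsed.
    """
    if any(a.element == "H" for a in query.atoms.values()) or \
       any(a.element == "H" for a in subject.atoms.values()):
        raise MolGraphError("strip hydrogens before matching")
    if len(query.atoms) > MAX_QUERY_ATOMS:
        raise MolGraphError(f"query exceeds {MAX_QUERY_ATOMS} atoms")
    if not query.atoms or len(query.atoms) > len(subject.atoms):
        return []
    cand = _correspondence(query, subject)
    if any(not c for c in cand.values()):
        return []
    order = _bfs_order(query)
    results: list[Embedding] = []
    mapping: dict[int, int] = {}
    used: set[int] = set()

    def place(k: int) -> None:
        if k == len(order):
            results.append(dict(mapping))
            return
        qi = order[k]
        placed_nb = [(qj, query.bond_order(qi, qj))
                     for qj in query.neighbors(qi) if qj in mapping]
        for sj in cand[qi]:
            if sj in used:
                continue
            ok = True
            for qj, bo in placed_nb:
                key = frozenset((mapping[qj], sj))
                if subject.bonds.get(key) != bo:
                    ok = False
                    break
            if ok:
                mapping[qi] = sj
                used.add(sj)
                place(k + 1)
                used.discard(sj)
                del mapping[qi]

    place(0)
    results.sort(key=lambda emb: tuple(emb[qi] for qi in sorted(emb)))
    return results


def brute_force_embeddings(query: MolecularGraph, subject: MolecularGraph) -> list[Embedding]:
    """Exhaustive oracle over all injective maps; subject must be small."""
    if len(subject.atoms) > 12:
        raise MolGraphError("brute-force oracle refuses subjects > 12 heavy atoms")
    q_idx = sorted(query.atoms)
    s_idx = sorted(subject.atoms)
    if not q_idx or len(q_idx) > len(s_idx):
        return []
    results = []
    for perm in permutations(s_idx, len(q_idx)):
        emb = dict(zip(q_idx, perm))
        if any(query.atoms[qi].element != subject.atoms[emb[qi]].element
               for qi in q_idx):
            continue
        ok = True
        for key, bo in query.bonds.items():
            i, j = tuple(key)
            if subject.bonds.get(frozenset((emb[i], emb[j]))) != bo:
                ok = False
                break
        if ok:
            results.append(emb)
    results.sort(key=lambda emb: tuple(emb[qi] for qi in sorted(emb)))
    return results
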
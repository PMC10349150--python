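"""Metabolite graph and fragmentation DAG (graph-based spectral model).

The molecule's C-C, O-C and N-C bonds (ring or chain, any order) are all
conceptually broken; the residual connected components are condensed into
metabolite-graph nodes, re-joined by the broken bonds.  Theoretical
fragments are the connected components obtained by removing a bridge or a
minimal 2-cut from the metabolite graph, recursively to a maximum depth.
Fragment neutral masses carry one hydrogen of cut compensation per broken
boundary bond (configurable), the common homolytic-plus-H convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .molgraph import MONOISOTOPIC, MolecularGraph, MolGraphError

BREAKABLE = {frozenset(("C", "C")), frozenset(("O", "C")), frozenset(("N", "C"))}
H_MASS = MONOISOTOPIC["H"]
DEFAULT_MAX_DEPTH = 2
DEFAULT_CUT_OFFSET = H_MASS  # per broken bond, added to each child


@dataclass(frozen=True)
class MetaboliteNode:
    id: int
    atoms: frozenset          # molecule atom indices condensed into this node
    mass: float               # monoisotopic mass incl. implicit hydrogens


@dataclass
class MetaboliteGraph:
    nodes: dict[int, MetaboliteNode]
    graph: nx.MultiGraph      # edges = previously broken bonds

    @property
    def total_mass(self) -> float:
        return sum(n.mass for n in self.nodes.values())


def build_metabolite_graph(g: MolecularGraph) -> MetaboliteGraph:
    """Break all C-C / O-C / N-C bonds; condense residual components."""
    residual = g.copy()
    broken = []
    for key, order in list(g.bonds.items()):
        i, j = tuple(key)
        pair = frozenset((g.atoms[i].element, g.atoms[j].element))
        if pair in BREAKABLE:
            residual.remove_bond(i, j)
            broken.append((i, j))
    comps = residual.connected_components()
    atom_to_node = {}
    nodes = {}
    for nid, comp in enumerate(sorted(comps, key=min)):
        mass = sum(MONOISOTOPIC[g.atoms[a].element]
                   + g.atoms[a].implicit_h * H_MASS for a in comp)
        nodes[nid] = MetaboliteNode(nid, frozenset(comp), mass)
        for a in comp:
            atom_to_node[a] = nid
    mg = nx.MultiGraph()
    mg.add_nodes_from(nodes)
    for i, j in broken:
        mg.add_edge(atom_to_node[i], atom_to_node[j], atoms=(i, j))
    return MetaboliteGraph(nodes, mg)


@dataclass(frozen=True)
class Fragment:
    nodes: frozenset          # metabolite-graph node ids
    depth: int
    mass: float               # neutral mass incl. cut compensation
    n_cut_bonds: int


@dataclass
class FragmentationGraph:
    """Rooted DAG: root = intact molecule; edges = produced-by-one-cut."""
    root: frozenset
    fragments: dict[frozenset, Fragment]
    children: dict[frozenset, set] = field(default_factory=dict)
    parents: dict[frozenset, set] = field(default_factory=dict)

    def __len__(self):
        return len(self.fragments)


def _adjacency(nodes, edges, skip=()):
    adj = {n: [] for n in nodes}
    for eid, u, v in edges:
        if eid in skip:
            continue
        adj[u].append((eid, v))
        adj[v].append((eid, u))
    return adj


def _components_fast(nodes, edges, skip=()):
    adj = _adjacency(nodes, edges, skip)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(m for _, m in adj[n] if m not in comp)
        seen |= comp
        comps.append(comp)
    return comps


def _bridges_fast(nodes, edges, skip=()):
    """Bridge edge ids of a connected multigraph (iterative lowpoint DFS).

    Parallel edges are never bridges; an edge used to enter a vertex may
    not serve as its own back edge (tracked by edge id).
    """
    adj = _adjacency(nodes, edges, skip)
    disc: dict = {}
    low: dict = {}
    bridges = []
    counter = [0]
    for root in nodes:
        if root in disc:
            continue
        stack = [(root, None, iter(adj[root]))]
        disc[root] = low[root] = counter[0]
        counter[0] += 1
        while stack:
            n, in_edge, it = stack[-1]
            advanced = False
            for eid, m in it:
                if eid == in_edge:
                    continue
                if m not in disc:
                    disc[m] = low[m] = counter[0]
                    counter[0] += 1
                    stack.append((m, eid, iter(adj[m])))
                    advanced = True
                    break
                low[n] = min(low[n], disc[m])
            if not advanced:
                stack.pop()
                if stack:
                    parent = stack[-1][0]
                    low[parent] = min(low[parent], low[n])
                    if low[n] > disc[parent]:
                        bridges.append(in_edge)
    return bridges


def _single_cuts(nodes, edges):
    """All bridges and minimal 2-cuts of a connected multigraph.

    ``edges`` is a list of (edge_id, u, v).  Yields (removed edge ids,
    components).  A 2-cut is an unordered pair of edges whose joint
    removal disconnects the graph while neither alone does.
    """
    bridges = set(_bridges_fast(nodes, edges))
    for eid in sorted(bridges):
        yield (eid,), _components_fast(nodes, edges, skip={eid})
    non_bridges = sorted(e[0] for e in edges if e[0] not in bridges)
    for e1 in non_bridges:
        # any non-bridge that becomes a bridge once e1 is gone pairs with it
        for e2 in _bridges_fast(nodes, edges, skip={e1}):
            if e2 in bridges or e2 <= e1:
                continue
            yield (e1, e2), _components_fast(nodes, edges, skip={e1, e2})


def enumerate_fragments(mg: MetaboliteGraph,
                        max_depth: int = DEFAULT_MAX_DEPTH,
                        cut_offset: float = DEFAULT_CUT_OFFSET) -> FragmentationGraph:
    """Recursive bridge/2-cut fragmentation, deduplicated by node subset."""
    if mg.graph.number_of_nodes() == 0:
        raise MolGraphError("empty metabolite graph")
    if nx.number_connected_components(mg.graph) != 1:
        raise MolGraphError("metabolite graph must be connected")

    all_edges = [(eid, u, v) for eid, (u, v, _k)
                 in enumerate(mg.graph.edges(keys=True))]

    def frag_mass(node_set: frozenset) -> tuple[float, int]:
        base = sum(mg.nodes[n].mass for n in node_set)
        boundary = sum(1 for _eid, u, v in all_edges
                       if (u in node_set) != (v in node_set))
        return base + boundary * cut_offset, boundary

    root = frozenset(mg.graph.nodes)
    mass, ncut = frag_mass(root)
    fg = FragmentationGraph(root, {root: Fragment(root, 0, mass, ncut)},
                            {root: set()}, {root: set()})
    frontier = [root]
    for depth in range(1, max_depth + 1):
        next_frontier = []
        for parent in frontier:
            sub_edges = [e for e in all_edges
                         if e[1] in parent and e[2] in parent]
            for _removed, comps in _single_cuts(parent, sub_edges):
                for comp in comps:
                    child = frozenset(comp)
                    if child == parent:
                        continue
                    if child not in fg.fragments:
                        m, nc = frag_mass(child)
                        fg.fragments[child] = Fragment(child, depth, m, nc)
                        fg.children[child] = set()
                        fg.parents[child] = set()
                        next_frontier.append(child)
                    fg.children[parent].add(child)
                    fg.parents[child].add(parent)
        frontier = next_frontier
    return fg


def brute_force_fragments(mg: MetaboliteGraph, max_depth: int = 1,
                          cut_offset: float = DEFAULT_CUT_OFFSET) -> set[frozenset]:
    """Oracle: exhaustive enumeration over all 1- and 2-edge removals.

    Returns the set of node subsets reachable at each recursion level,
    restricted to small graphs.
    """
    if mg.graph.number_of_nodes() > 8:
        raise MolGraphError("oracle refuses metabolite graphs > 8 nodes")

    def cuts_of(node_set):
        sub = mg.graph.subgraph(node_set)
        edges = list(sub.edges(keys=True))
        out = set()
        for r in (1, 2):
            for removed in combinations(edges, r):
                work = sub.copy()
                for e in removed:
                    work.remove_edge(*e)
                comps = list(nx.connected_components(work))
                if len(comps) < 2:
                    continue
                if r == 2:
                    # minimality: neither edge alone may disconnect
                    minimal = True
                    for e in removed:
                        w1 = sub.copy()
                        w1.remove_edge(*e)
                        if nx.number_connected_components(w1) > 1:
                            minimal = False
                    if not minimal:
                        continue
                for comp in comps:
                    out.add(frozenset(comp))
        return out

    levels = {frozenset(mg.graph.nodes)}
    all_frags = set(levels)
    for _ in range(max_depth):
        nxt = set()
        for parent in levels:
            nxt |= cuts_of(parent)
        nxt -= all_frags
        all_frags |= nxt
        levels = nxt
    return all_frags
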
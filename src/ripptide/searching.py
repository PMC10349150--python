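"""Molecule-vs-spectrum scoring and database search.

A fragment is annotated when some experimental peak's neutralized mass
falls within tolerance of the fragment's neutral mass; a root-to-fragment
path counts when every non-root fragment on it is annotated (the root is
annotated by convention).  The score is the number of peaks explaining at
least one fragment on such a fully annotated path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fragment import (DEFAULT_CUT_OFFSET, DEFAULT_MAX_DEPTH, FragmentationGraph,
                       build_metabolite_graph, enumerate_fragments)
from .molgraph import monoisotopic_mass, parse_smiles
from .spectra import Spectrum
from .stats import poisson_binomial_tail, uniform_null_probs

logger = logging.getLogger(__name__)

DEFAULT_TOL = 0.02


@dataclass(frozen=True)
class Psm:
    molecule_id: str
    spectrum_id: str
    score: int
    p_value: float
    precursor_error: float
    decoy: bool = False


def annotate_and_score(fg: FragmentationGraph, spectrum: Spectrum,
                       tol: float = DEFAULT_TOL,
                       charge: int = 1) -> tuple[int, set]:
    """(score, annotated peak indices on fully annotated paths)."""
    neutral = spectrum.neutral_peak_masses(charge)
    if neutral.size == 0:
        return 0, set()
    # fragment -> peak indices within tolerance
    frag_peaks: dict[frozenset, set] = {}
    for key, frag in fg.fragments.items():
        if key == fg.root:
            continue
        hits = np.flatnonzero(np.abs(neutral - frag.mass) <= tol)
        if hits.size:
            frag_peaks[key] = set(hits.tolist())
    # fragment reachable along a fully annotated path from the root
    reachable: dict[frozenset, bool] = {fg.root: True}
    by_depth = sorted((f.depth, key) for key, f in fg.fragments.items())
    for _, key in by_depth:
        if key == fg.root:
            continue
        ok = key in frag_peaks and any(reachable.get(p, False)
                                       for p in fg.parents.get(key, ()))
        reachable[key] = ok
    counted: set = set()
    for key, peaks in frag_peaks.items():
        if reachable.get(key, False):
            counted |= peaks
    return len(counted), counted


def score_molecule(smiles: str, spectrum: Spectrum, tol: float = DEFAULT_TOL,
                   max_depth: int = DEFAULT_MAX_DEPTH,
                   cut_offset: float = DEFAULT_CUT_OFFSET,
                   fg: FragmentationGraph | None = None) -> tuple[int, float]:
    """(score, p-value) of one molecule against one spectrum."""
    if fg is None:
        fg = fragmentation_graph(smiles, max_depth, cut_offset)
    score, _ = annotate_and_score(fg, spectrum, tol)
    n_frag = len(fg.fragments) - 1
    probs = uniform_null_probs(n_frag, len(spectrum.peaks), tol,
                               spectrum.precursor_neutral_mass)
    return score, poisson_binomial_tail(probs, score)


_FG_CACHE: dict[tuple, FragmentationGraph] = {}


def fragmentation_graph(smiles: str, max_depth: int = DEFAULT_MAX_DEPTH,
                        cut_offset: float = DEFAULT_CUT_OFFSET,
                        cache: bool = True) -> FragmentationGraph:
    """Build (or fetch from the in-process cache) a fragmentation graph."""
    key = (smiles, max_depth, round(cut_offset, 6))
    if cache and key in _FG_CACHE:
        return _FG_CACHE[key]
    g = parse_smiles(smiles)
    fg = enumerate_fragments(build_metabolite_graph(g), max_depth, cut_offset)
    if cache:
        _FG_CACHE[key] = fg
    return fg


def save_fragmentation_cache(path, graphs: dict[str, FragmentationGraph]) -> None:
    """Persist fragmentation graphs as JSON lines (one molecule per line)."""
    import json
    with open(path, "w") as fh:
        for smiles, fg in graphs.items():
            record = {
                "smiles": smiles,
                "root": sorted(fg.root),
                "fragments": [
                    {"nodes": sorted(k), "depth": f.depth, "mass": f.mass,
                     "n_cut_bonds": f.n_cut_bonds,
                     "parents": [sorted(p) for p in fg.parents.get(k, ())]}
                    for k, f in fg.fragments.items()],
            }
            fh.write(json.dumps(record) + "\n")


def load_fragmentation_cache(path) -> dict[str, FragmentationGraph]:
    import json
    from .fragment import Fragment
    out = {}
    with open(path) as fh:
        for line in fh:
            record = json.loads(line)
            root = frozenset(record["root"])
            fragments, parents, children = {}, {}, {}
            for entry in record["fragments"]:
                key = frozenset(entry["nodes"])
                fragments[key] = Fragment(key, entry["depth"], entry["mass"],
                                          entry["n_cut_bonds"])
                parents[key] = {frozenset(p) for p in entry["parents"]}
                children.setdefault(key, set())
            for key, ps in parents.items():
                for p in ps:
                    children.setdefault(p, set()).add(key)
            out[record["smiles"]] = FragmentationGraph(root, fragments,
                                                       children, parents)
    return out


@dataclass
class SearchConfig:
    precursor_tol: float = DEFAULT_TOL    # Da, on neutral mass
    fragment_tol: float = DEFAULT_TOL
    max_depth: int = DEFAULT_MAX_DEPTH
    cut_offset: float = DEFAULT_CUT_OFFSET


def search(spectra: list[Spectrum], molecules: list[tuple[str, str]],
           config: SearchConfig | None = None,
           decoy_ids: set[str] | None = None) -> list[Psm]:
    """Search spectra against a (molecule_id, SMILES) library.

    Molecules failing the precursor-mass filter are not scored; PSMs are
    sorted best-first (score descending, then p-value ascending).
    """
    config = config or SearchConfig()
    decoy_ids = decoy_ids or set()
    masses = {}
    for mol_id, smiles in molecules:
        try:
            masses[mol_id] = (smiles, monoisotopic_mass(parse_smiles(smiles)))
        except Exception as exc:  # unparseable molecules are skipped
            logger.warning("skipping molecule %s: %s", mol_id, exc)
    psms = []
    for spectrum in spectra:
        neutral = spectrum.precursor_neutral_mass
        for mol_id, (smiles, mol_mass) in masses.items():
            err = mol_mass - neutral
            if abs(err) > config.precursor_tol:
                continue
            fg = fragmentation_graph(smiles, config.max_depth, config.cut_offset)
            score, pval = score_molecule(smiles, spectrum, config.fragment_tol,
                                         fg=fg)
            psms.append(Psm(mol_id, spectrum.id, score, pval, err,
                            mol_id in decoy_ids))
    psms.sort(key=lambda p: (-p.score, p.p_value, p.molecule_id, p.spectrum_id))
    return psms


def psm_table(psms: list[Psm]):
    import pandas as pd
    return pd.DataFrame([{
        "molecule_id": p.molecule_id, "spectrum_id": p.spectrum_id,
        "score": p.score, "p_value": p.p_value,
        "precursor_error": p.precursor_error, "decoy": p.decoy} for p in psms])


def decoy_cores(cores: list[str], seed: int = 0) -> list[str]:
    """Decoys: seeded random shuffles of core residue order (composition-
    preserving, applied before modification)."""
    rng = np.random.default_rng(seed)
    out = []
    for core in cores:
        letters = list(core)
        for _ in range(20):
            rng.shuffle(letters)
            if "".join(letters) != core or len(set(letters)) == 1:
                break
        out.append("".join(letters))
    return out
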
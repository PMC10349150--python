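"""Spectrum I/O, annotation scoring, database search, and FDR wiring."""

import base64
import struct

import numpy as np
import pytest

from ripptide.fragment import build_metabolite_graph, enumerate_fragments
from ripptide.molgraph import PROTON_MASS, parse_smiles, write_smiles
from ripptide.residues import build_peptide
from ripptide.searching import (SearchConfig, annotate_and_score, decoy_cores,
                                fragmentation_graph, psm_table, score_molecule,
                                search)
from ripptide.spectra import (Spectrum, make_synthetic_spectrum, read_mgf,
                              read_mzml, write_mgf)


def _mgf_text(scans):
    out = []
    for title, pepmass, charge, peaks in scans:
        out.append("BEGIN IONS")
        out.append(f"TITLE={title}")
        out.append(f"PEPMASS={pepmass}")
        if charge:
            out.append(f"CHARGE={charge}")
        out += [f"{mz} {i}" for mz, i in peaks]
        out.append("END IONS")
        out.append("")
    return "\n".join(out)


def _mzml_text(scan_id, precursor_mz, charge, peaks):
    """Minimal mzML document with one MS2 scan (uncompressed 64-bit arrays)."""
    def b64(values):
        return base64.b64encode(
            struct.pack(f"<{len(values)}d", *values)).decode()

    mzs = [p[0] for p in peaks]
    intens = [p[1] for p in peaks]
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r">
    <spectrumList count="1">
      <spectrum index="0" id="{scan_id}" defaultArrayLength="{len(peaks)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor_mz}"/>
                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{charge}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(b64(mzs))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{b64(mzs)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(b64(intens))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{b64(intens)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


PEAKS = [(100.05, 10.0), (200.10, 20.0), (300.15, 5.0)]


class TestReaders:
    def test_mgf_two_spectra(self, tmp_path):
        path = tmp_path / "two.mgf"
        path.write_text(_mgf_text([("a", 500.25, "2+", PEAKS),
                                   ("b", 300.10, None, PEAKS[:1])]))
        spectra = read_mgf(path)
        assert len(spectra) == 2
        assert spectra[0].precursor_charge == 2
        assert spectra[1].precursor_charge == 1  # missing charge defaults 1+

    def test_mgf_empty_peak_list(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text(_mgf_text([("a", 500.25, "1+", [])]))
        (s,) = read_mgf(path)
        assert s.peaks == ()

    def test_mgf_roundtrip(self, tmp_path):
        original = Spectrum("x", 444.2211, 2, tuple(PEAKS))
        path = tmp_path / "rt.mgf"
        write_mgf(path, [original])
        (back,) = read_mgf(path)
        assert back.precursor_mz == pytest.approx(original.precursor_mz)
        assert np.allclose([p[0] for p in back.peaks],
                           [p[0] for p in original.peaks])

    def test_mgf_and_mzml_agree(self, tmp_path):
        mgf_path = tmp_path / "one.mgf"
        mgf_path.write_text(_mgf_text([("scan1", 500.25, "2+", PEAKS)]))
        mzml_path = tmp_path / "one.mzML"
        mzml_path.write_text(_mzml_text("scan1", 500.25, 2, PEAKS))
        (a,) = read_mgf(mgf_path)
        (b,) = read_mzml(mzml_path)
        assert a.precursor_charge == b.precursor_charge
        assert a.precursor_mz == pytest.approx(b.precursor_mz)
        assert np.allclose([p[0] for p in a.peaks], [p[0] for p in b.peaks])
        assert np.allclose([p[1] for p in a.peaks], [p[1] for p in b.peaks])


class TestAnnotateAndScore:
    def test_all_depth1_masses_score_full(self):
        smiles = write_smiles(build_peptide("GAS"))
        fg = fragmentation_graph(smiles, max_depth=1, cache=False)
        masses = sorted({f.mass for k, f in fg.fragments.items() if k != fg.root})
        spectrum = Spectrum("s", 1000.0, 1,
                            tuple((m + PROTON_MASS, 1.0) for m in masses))
        score, peaks = annotate_and_score(fg, spectrum)
        assert score == len(spectrum.peaks)

    def test_empty_spectrum_zero(self):
        fg = fragmentation_graph("CCO", cache=False)
        assert annotate_and_score(fg, Spectrum("s", 100.0, 1, ()))[0] == 0

    def test_orphan_depth2_fragment_not_counted(self):
        # ethanolamine chain O-C-C-N: the middle carbons appear only at
        # depth 2, and their masses collide with no depth-1 fragment
        fg = fragmentation_graph("OCCN", max_depth=2, cache=False)
        d1_masses = {f.mass for f in fg.fragments.values() if f.depth <= 1}
        orphan = next(k for k, f in fg.fragments.items()
                      if f.depth == 2
                      and all(abs(f.mass - m) > 0.1 for m in d1_masses))
        peak = (fg.fragments[orphan].mass + PROTON_MASS, 1.0)
        score, _ = annotate_and_score(fg, Spectrum("s", 500.0, 1, (peak,)))
        assert score == 0
        # annotating a depth-1 parent opens the path, and both peaks count
        parent = next(p for p in fg.parents[orphan]
                      if fg.fragments[p].depth == 1)
        peaks = (peak, (fg.fragments[parent].mass + PROTON_MASS, 1.0))
        score, _ = annotate_and_score(
            fg, Spectrum("s", 500.0, 1, tuple(sorted(peaks))))
        assert score == 2

    def test_score_monotone_in_peaks(self):
        smiles = write_smiles(build_peptide("GA"))
        fg = fragmentation_graph(smiles, cache=False)
        masses = sorted({f.mass for k, f in fg.fragments.items() if k != fg.root})
        peaks = [(m + PROTON_MASS, 1.0) for m in masses[:4]]
        scores = []
        for k in range(len(peaks) + 1):
            s, _ = annotate_and_score(
                fg, Spectrum("s", 500.0, 1, tuple(peaks[:k])))
            scores.append(s)
        assert scores == sorted(scores)


class TestSearch:
    def test_implanted_molecule_ranks_first(self):
        core = "GASWK"
        target = write_smiles(build_peptide(core))
        library = [("target", target)]
        for k, decoy in enumerate(decoy_cores([core] * 9, seed=3)):
            library.append((f"decoy{k}", write_smiles(build_peptide(decoy))))
        spectrum = make_synthetic_spectrum(target, noise_n=20, seed=5)
        psms = search([spectrum], library)
        assert psms[0].molecule_id == "target"

    def test_precursor_filter_empty_result(self):
        spectrum = Spectrum("s", 5000.0, 1, ((100.0, 1.0),))
        assert search([spectrum], [("m", "CCO")]) == []

    def test_cache_transparency(self):
        smiles = write_smiles(build_peptide("GAS"))
        spectrum = make_synthetic_spectrum(smiles, noise_n=5, seed=1)
        lib = [("m", smiles)]
        first = search([spectrum], lib)
        second = search([spectrum], lib)
        assert psm_table(first).equals(psm_table(second))

    def test_unparseable_molecule_skipped(self, caplog):
        spectrum = make_synthetic_spectrum("CCO", seed=1)
        psms = search([spectrum], [("bad", "C(C"), ("good", "CCO")])
        assert {p.molecule_id for p in psms} == {"good"}

    def test_pvalue_decreases_with_score(self):
        smiles = write_smiles(build_peptide("GAST"))
        spectrum = make_synthetic_spectrum(smiles, noise_n=0, seed=1)
        full_score, full_p = score_molecule(smiles, spectrum)
        empty = Spectrum("e", spectrum.precursor_mz, 1, ((60.0, 1.0),))
        low_score, low_p = score_molecule(smiles, empty)
        assert full_score > low_score
        assert full_p < low_p


class TestPvalueCalibration:
    def test_uniform_noise_pvalues_not_anticonservative(self):
        """On pure-noise spectra, P(p-value <= a) stays within 2a."""
        smiles = write_smiles(build_peptide("GAST"))
        fg = fragmentation_graph(smiles)
        from ripptide.molgraph import monoisotopic_mass
        mol_mass = monoisotopic_mass(parse_smiles(smiles))
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(1000):
            peaks = tuple(sorted((float(mz), 1.0)
                                 for mz in rng.uniform(50.0, mol_mass + 1.0, 25)))
            spectrum = Spectrum("n", mol_mass + PROTON_MASS, 1, peaks)
            _, p = score_molecule(smiles, spectrum, fg=fg)
            pvals.append(p)
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05):
            assert (pvals <= alpha).mean() <= 2 * alpha


class TestFragmentationCache:
    def test_jsonl_roundtrip_preserves_scores(self, tmp_path):
        from ripptide.searching import (load_fragmentation_cache,
                                        save_fragmentation_cache)
        smiles = write_smiles(build_peptide("GAS"))
        fg = fragmentation_graph(smiles, cache=False)
        path = tmp_path / "cache.jsonl"
        save_fragmentation_cache(path, {smiles: fg})
        back = load_fragmentation_cache(path)[smiles]
        assert set(back.fragments) == set(fg.fragments)
        spectrum = make_synthetic_spectrum(smiles, noise_n=5, seed=0)
        assert annotate_and_score(back, spectrum) == \
            annotate_and_score(fg, spectrum)


class TestDecoys:
    def test_composition_preserved(self):
        cores = ["GASWK", "MNQT"]
        for core, decoy in zip(cores, decoy_cores(cores, seed=1)):
            assert sorted(core) == sorted(decoy)
            assert core != decoy

    def test_seeded_reproducibility(self):
        assert decoy_cores(["GASWK"] * 5, seed=9) == decoy_cores(["GASWK"] * 5, seed=9)
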
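"""Tandem mass spectra: containers, MGF/mzML readers, synthetic generation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import PROTON_MASS


@dataclass(frozen=True)
class Spectrum:
    id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple  # ((m/z, intensity), ...) sorted by m/z

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        mzs = [mz for mz, _ in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks",
                               tuple(sorted(self.peaks, key=lambda p: p[0])))

    @property
    def precursor_neutral_mass(self) -> float:
        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON_MASS

    def neutral_peak_masses(self, charge: int = 1) -> np.ndarray:
        """Peak m/z converted to neutral fragment masses at the given charge."""
        mz = np.array([p[0] for p in self.peaks])
        return mz * charge - charge * PROTON_MASS


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file; missing charge defaults to 1+."""
    from pyteomics import mgf
    spectra = []
    with mgf.MGF(str(path)) as reader:
        for k, scan in enumerate(reader):
            params = scan["params"]
            title = str(params.get("title", f"scan{k}"))
            pepmass = params.get("pepmass", (0.0,))[0]
            charge = params.get("charge")
            z = int(charge[0]) if charge else 1
            peaks = tuple(zip(scan["m/z array"].tolist(),
                              scan["intensity array"].tolist()))
            try:
                spectra.append(Spectrum(title, float(pepmass), z, peaks))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed MGF block at scan {k}: {exc}")
    return spectra


def read_mzml(path) -> list[Spectrum]:
    """Minimal mzML reader for MS2 scans.

    Handles 32/64-bit float binary arrays, zlib-compressed or plain,
    identified by their PSI-MS cvParam accessions.
    """
    import base64
    import zlib
    from lxml import etree

    ns = {"m": "http://psi.hupo.org/ms/mzml"}
    tree = etree.parse(str(path))
    root = tree.getroot()
    spectra = []
    for k, scan in enumerate(root.iter("{http://psi.hupo.org/ms/mzml}spectrum")):
        params = {cv.get("accession"): cv.get("value")
                  for cv in scan.findall("m:cvParam", ns)}
        if params.get("MS:1000511") not in (None, "2"):
            continue
        ion = scan.find(".//m:selectedIon", ns)
        if ion is None:
            raise ValueError(f"malformed mzML scan {k}: no selected ion")
        ion_params = {cv.get("accession"): cv.get("value")
                      for cv in ion.findall("m:cvParam", ns)}
        try:
            mz = float(ion_params["MS:1000744"])
        except (KeyError, ValueError):
            raise ValueError(f"malformed mzML scan {k}: no precursor m/z")
        z = int(ion_params.get("MS:1000041", 1))
        arrays = {}
        for bda in scan.findall(".//m:binaryDataArray", ns):
            accs = {cv.get("accession") for cv in bda.findall("m:cvParam", ns)}
            binary = bda.find("m:binary", ns)
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in accs:           # zlib compression
                raw = zlib.decompress(raw)
            dtype = "<f4" if "MS:1000521" in accs else "<f8"
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accs:
                arrays["mz"] = values
            elif "MS:1000515" in accs:
                arrays["intensity"] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"malformed mzML scan {k}: missing peak arrays")
        peaks = tuple(zip(arrays["mz"].tolist(), arrays["intensity"].tolist()))
        spectra.append(Spectrum(scan.get("id", f"scan{k}"), mz, z, peaks))
    return spectra


def write_mgf(path, spectra: list[Spectrum]) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.2f}\n")
            fh.write("END IONS\n\n")


def make_synthetic_spectrum(smiles: str, noise_n: int = 0, seed: int = 0,
                            max_depth: int = 2, spectrum_id: str | None = None,
                            mz_range: tuple[float, float] = (50.0, None)) -> Spectrum:
    """Theoretical spectrum of a molecule: protonated fragment masses plus
    uniform noise peaks, deterministic per seed."""
    from .fragment import build_metabolite_graph, enumerate_fragments
    from .molgraph import monoisotopic_mass, parse_smiles

    g = parse_smiles(smiles)
    mol_mass = monoisotopic_mass(g)
    fg = enumerate_fragments(build_metabolite_graph(g), max_depth=max_depth)
    masses = sorted({f.mass for key, f in fg.fragments.items() if key != fg.root})
    peaks = [(m + PROTON_MASS, 100.0) for m in masses]
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    hi = hi if hi is not None else mol_mass + PROTON_MASS
    if hi <= lo:
        lo, hi = 1.0, max(hi, 2.0)
    for _ in range(noise_n):
        peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(1, 50))))
    peaks.sort(key=lambda p: p[0])
    return Spectrum(spectrum_id or f"synthetic:{seed}", mol_mass + PROTON_MASS, 1,
                    tuple(peaks))
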
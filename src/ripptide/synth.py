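"""Synthetic genome scenarios with implanted RiPP-like clusters.

Each scenario implants, at random positions of a random background genome,
an "enzyme" gene (whose translation is recognized by the fixture profile
table and emitted as a domain hit) and, nearby, a short precursor ORF of
the form leader + core + follower.  Everything is determined by the seed,
and a truth table records the implanted coordinates for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from Bio.Seq import Seq

from .mining import GenomeRecord, ProteinHit

AA_NO_AMBIG = "ACDEFGHIKLMNPQRSTVWY"
#: codon table (one codon per amino acid keeps reverse translation trivial)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

#: fixture enzyme proteins: profile id -> amino-acid sequence
FIXTURE_ENZYMES = {
    "PF05147": "M" + "LANTIDEHYDRATASE".replace("U", "V") * 3,
    "PF13649": "M" + "METHYLTRANSFERASE".replace("U", "V") * 3,
    "PF00733": "M" + "ASNSYNTHETASELIKE" * 3,
}


def reverse_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


@dataclass
class SyntheticScenario:
    seed: int = 0
    n_bgc: int = 3
    genome_length: int = 90_000
    enzyme_profiles: tuple[str, ...] = ("PF05147",)
    leader: str = "MKAQDLLSEE"
    follower: str = ""
    core_length: int = 6
    core_alphabet: str = "ACDEGIKLMNQSTV"
    orf_enzyme_gap: int = 1_000     # nt between enzyme gene and precursor ORF
    noise_peaks: int = 20
    mz_range: tuple = (50.0, None)


@dataclass
class ImplantTruth:
    bgc_index: int
    enzyme_profile: str
    enzyme_start: int
    enzyme_end: int
    orf_start: int
    orf_end: int
    precursor: str
    core: str
    core_start: int   # aa position within the precursor
    core_end: int


@dataclass
class SyntheticGenome:
    genome: GenomeRecord
    hits: list[ProteinHit]
    truths: list[ImplantTruth]

    def truth_table(self):
        import pandas as pd
        return pd.DataFrame([vars(t) for t in self.truths])


def make_synthetic_genome(scenario: SyntheticScenario) -> SyntheticGenome:
    """Deterministic genome with implanted enzyme + precursor pairs."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.genome_length
    base = rng.choice(list("ACGT"), size=n)
    # avoid chance ATG/GTG/TTG starts complicating nothing: background is fine
    genome = base.copy()

    slot = n // scenario.n_bgc
    truths = []
    hits = []
    for k in range(scenario.n_bgc):
        profile = scenario.enzyme_profiles[k % len(scenario.enzyme_profiles)]
        enzyme_prot = FIXTURE_ENZYMES[profile]
        core = "".join(rng.choice(list(scenario.core_alphabet),
                                  size=scenario.core_length, replace=False))
        precursor = scenario.leader + core + scenario.follower
        enzyme_nt = reverse_translate(enzyme_prot) + "TAA"
        orf_nt = reverse_translate(precursor) + "TAA"
        # place enzyme then precursor downstream with a gap
        start = slot * k + 2_000
        e_start, e_end = start, start + len(enzyme_nt)
        o_start = e_end + scenario.orf_enzyme_gap
        o_end = o_start + len(orf_nt)
        if o_end >= slot * (k + 1):
            raise ValueError("scenario does not fit: increase genome_length")
        genome[e_start:e_end] = list(enzyme_nt)
        genome[o_start:o_end] = list(orf_nt)
        truths.append(ImplantTruth(
            k, profile, e_start, e_end, o_start, o_end, precursor, core,
            len(scenario.leader), len(scenario.leader) + len(core)))
        # the enzyme gene is emitted as a domain hit (coding interval,
        # stop codon excluded), as a profile search over the frames would
        frame = e_start % 3
        hits.append(ProteinHit(profile, e_start, e_end - 3, strand=1,
                               frame=frame, evalue=1e-20))
    record = GenomeRecord("synthetic", "".join(genome))
    # scrub stray stop-free long ORFs is unnecessary: candidates are filtered
    hits.sort(key=lambda h: h.start)
    return SyntheticGenome(record, hits, truths)


def write_fasta(path, genome: GenomeRecord) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.seq), 70):
            fh.write(genome.seq[i:i + 70] + "\n")


def read_fasta(path) -> list[GenomeRecord]:
    from Bio import SeqIO
    return [GenomeRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
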
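"""Genome mining: six-frame translation, BGC windowing, ORF and core extraction.

Coordinates are 0-based half-open genome coordinates throughout.  RiPP
biosynthetic enzymes are located by profile-HMM hits (read from HMMER
tabular files, or produced live by the pyhmmer adapter); a window of
+/- 10 kb around each hit midpoint defines a candidate cluster, overlapping
windows are merged, and short ORFs near the enzymes become candidate
precursor peptides.  Core candidates come from exhaustive substring
enumeration or from the repeat-based leader/follower finder used for
cyanobactin-like and plant precursors.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

TRANSLATION_TABLE = 11
EVALUE_THRESHOLD = 1e-5
WINDOW = 10_000
MIN_ORF_AA = 11      # "longer than 10 aa"
MAX_ORF_AA = 200     # "below 200 amino acids"
START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeRecord:
    id: str
    seq: str

    def __post_init__(self):
        if not self.seq or set(self.seq) - set("ACGTN"):
            raise MiningError(f"genome {self.id!r}: alphabet must be ACGTN")


@dataclass(frozen=True)
class ProteinHit:
    profile: str
    start: int           # genome coordinates, 0-based half-open
    end: int
    strand: int          # +1 / -1
    frame: int           # 0..2 offset within strand
    evalue: float

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class BgcRecord:
    genome_id: str
    start: int
    end: int
    hits: tuple[ProteinHit, ...] = ()


@dataclass(frozen=True)
class OrfRecord:
    seq: str             # amino acids, no stop
    start: int           # genome coordinates of the coding interval
    end: int
    strand: int
    frame: int
    genome_id: str = ""
    bgc: tuple[int, int] | None = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CoreCandidate:
    seq: str
    orf_start: int       # position within the ORF (aa), 0-based
    orf_end: int
    strategy: str        # exhaustive | repeat | neural


# -- translation and coordinates ----------------------------------------------


def six_frame_translate(g: GenomeRecord) -> list[tuple[str, int, int]]:
    """Translate all six frames; returns (protein, strand, frame) triples.

    Stops are rendered '*'; ambiguous codons (with N) become 'X'.
    """
    out = []
    fwd = g.seq
    rev = str(Seq(g.seq).reverse_complement())
    for strand, seq in ((1, fwd), (-1, rev)):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            prot = str(Seq(sub).translate(table=TRANSLATION_TABLE)) if sub else ""
            out.append((prot, strand, frame))
    return out


def protein_to_genome(aa_start: int, aa_end: int, strand: int, frame: int,
                      genome_len: int) -> tuple[int, int]:
    """Map a protein interval [aa_start, aa_end) back to genome coordinates."""
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == 1:
        return nt_start, nt_end
    return genome_len - nt_end, genome_len - nt_start


def genome_to_protein(start: int, end: int, strand: int, frame: int,
                      genome_len: int) -> tuple[int, int]:
    if strand == 1:
        return (start - frame) // 3, (end - frame) // 3
    return (genome_len - end - frame) // 3, (genome_len - start - frame) // 3


# -- HMM hits -----------------------------------------------------------------


def read_domain_hits(path, genome: GenomeRecord,
                     evalue_threshold: float = EVALUE_THRESHOLD) -> list[ProteinHit]:
    """Read a HMMER tblout-dialect file of hits against six-frame translations.

    The target name must be '<genome_id>|<strand>|<frame>' and the file must
    carry per-domain alignment coordinates (amino acids, 1-based inclusive)
    in columns 5-6 after the standard tblout prefix.  Rows with E-value above
    the threshold are dropped (boundary kept).
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split()
            try:
                target, profile = parts[0], parts[1]
                evalue = float(parts[2])
                aa_from, aa_to = int(parts[3]), int(parts[4])
                gid, strand_s, frame_s = target.split("|")
                strand, frame = int(strand_s), int(frame_s)
            except (ValueError, IndexError):
                raise MiningError(f"{path}: malformed hit row at line {lineno}")
            if evalue > evalue_threshold:
                continue
            if gid != genome.id:
                continue
            start, end = protein_to_genome(aa_from - 1, aa_to, strand, frame,
                                           len(genome.seq))
            hits.append(ProteinHit(profile, start, end, strand, frame, evalue))
    hits.sort(key=lambda h: (h.start, h.end, h.profile))
    return hits


def write_domain_hits(path, hits: list[ProteinHit], genome: GenomeRecord) -> None:
    """Inverse of read_domain_hits, for fixtures and adapters."""
    with open(path, "w") as fh:
        fh.write("# target profile evalue aa_from aa_to\n")
        for h in hits:
            aa_from, aa_to = genome_to_protein(h.start, h.end, h.strand, h.frame,
                                               len(genome.seq))
            fh.write(f"{genome.id}|{h.strand}|{h.frame} {h.profile} "
                     f"{h.evalue:g} {aa_from + 1} {aa_to}\n")


def run_hmm_adapter(profiles, genome: GenomeRecord,
                    evalue_threshold: float = EVALUE_THRESHOLD) -> list[ProteinHit]:
    """Search pyhmmer profiles against the six-frame translations."""
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = []
    meta = []
    for prot, strand, frame in six_frame_translate(genome):
        name = f"{genome.id}|{strand}|{frame}".encode()
        seqs.append(pyhmmer.easel.TextSequence(name=name, sequence=prot.replace("*", "X"))
                    .digitize(alphabet))
        meta.append((strand, frame))
    hits = []
    for top in pyhmmer.hmmsearch(profiles, seqs, E=evalue_threshold):
        profile = top.query.name
        if isinstance(profile, bytes):
            profile = profile.decode()
        for hit in top:
            name = hit.name.decode() if isinstance(hit.name, bytes) else hit.name
            strand_s, frame_s = name.split("|")[1:]
            strand, frame = int(strand_s), int(frame_s)
            for dom in hit.domains.included:
                if dom.i_evalue > evalue_threshold:
                    continue
                ali = dom.alignment
                start, end = protein_to_genome(ali.target_from - 1, ali.target_to,
                                               strand, frame, len(genome.seq))
                hits.append(ProteinHit(profile, start, end, strand, frame,
                                       dom.i_evalue))
    hits.sort(key=lambda h: (h.start, h.end, h.profile))
    return hits


# -- BGC windowing ------------------------------------------------------------


def genome2bgc(genome: GenomeRecord, hits: list[ProteinHit],
               window: int = WINDOW) -> list[BgcRecord]:
    """+/- window around each hit midpoint, clipped and union-merged."""
    intervals = []
    for h in hits:
        mid = h.midpoint
        intervals.append((max(0, mid - window),
                          min(len(genome.seq), mid + window), h))
    intervals.sort(key=lambda t: (t[0], t[1]))
    merged: list[list] = []
    for start, end, h in intervals:
        if merged and start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2].append(h)
        else:
            merged.append([start, end, [h]])
    return [BgcRecord(genome.id, s, e, tuple(hs)) for s, e, hs in merged]


# -- ORF extraction -----------------------------------------------------------


def find_orfs(genome: GenomeRecord, region: tuple[int, int] | None = None,
              min_aa: int = MIN_ORF_AA, max_aa: int = MAX_ORF_AA) -> list[OrfRecord]:
    """All start-to-stop ORFs in six frames (every start codon per stop).

    An ORF runs from a start codon to the first in-frame stop; internal
    start codons yield their own (shorter) records since precursor starts
    are easily mispredicted.  Lengths are amino acids excluding the stop.
    """
    lo, hi = region if region else (0, len(genome.seq))
    n = len(genome.seq)
    orfs = []
    for prot, strand, frame in six_frame_translate(genome):
        seq = genome.seq if strand == 1 else str(Seq(genome.seq).reverse_complement())
        i = frame
        starts: list[int] = []
        aa_pos = 0
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                for s_aa in starts:
                    length = aa_pos - s_aa
                    if min_aa <= length <= max_aa:
                        aa_seq = prot[s_aa:aa_pos]
                        if "*" in aa_seq or "X" in aa_seq:
                            continue
                        gs, ge = protein_to_genome(s_aa, aa_pos + 1, strand, frame, n)
                        if gs >= lo and ge <= hi:
                            orfs.append(OrfRecord(aa_seq, gs, ge, strand, frame,
                                                  genome.id))
                starts = []
            elif codon in START_CODONS:
                starts.append(aa_pos)
            i += 3
            aa_pos += 1
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def extract_candidate_orfs(bgc: BgcRecord, genome: GenomeRecord,
                           max_dist: int = WINDOW,
                           min_aa: int = MIN_ORF_AA,
                           max_aa: int = MAX_ORF_AA) -> list[OrfRecord]:
    """ORFs whose midpoint lies within max_dist of an enzyme-hit midpoint."""
    orfs = find_orfs(genome, (bgc.start, bgc.end), min_aa, max_aa)
    mids = [h.midpoint for h in bgc.hits]
    out = []
    for orf in orfs:
        if any(abs(orf.midpoint - m) <= max_dist for m in mids):
            out.append(OrfRecord(orf.seq, orf.start, orf.end, orf.strand,
                                 orf.frame, orf.genome_id, (bgc.start, bgc.end)))
    return out


# -- core extraction ----------------------------------------------------------


def exhaustive_cores(orf: str | OrfRecord, min_len: int = 3,
                     max_len: int = 30) -> list[CoreCandidate]:
    """Every positioned substring of length min_len..max_len."""
    seq = orf.seq if isinstance(orf, OrfRecord) else orf
    out = []
    for length in range(min_len, min(max_len, len(seq)) + 1):
        for start in range(len(seq) - length + 1):
            out.append(CoreCandidate(seq[start:start + length], start,
                                     start + length, "exhaustive"))
    return out


def _repeated_substrings(seq: str, min_len: int = 6) -> list[tuple[str, list[int]]]:
    """Maximal repeated substrings of length >= min_len with >= 2 non-overlapping
    occurrences, as (substring, greedy occurrence starts)."""
    found: dict[str, list[int]] = {}
    n = len(seq)
    for length in range(min_len, n // 2 + 1):
        for i in range(n - length + 1):
            sub = seq[i:i + length]
            if sub in found:
                continue
            occ = []
            j = 0
            while True:
                k = seq.find(sub, j)
                if k < 0:
                    break
                occ.append(k)
                j = k + length
            if len(occ) >= 2:
                found[sub] = occ
    # keep only maximal ones (not extendable to a repeat with the same count)
    items = sorted(found.items(), key=lambda kv: (-len(kv[1]), -len(kv[0]), kv[1][0]))
    maximal = []
    for sub, occ in items:
        if any(sub in other and len(other) > len(sub) and len(oocc) >= len(occ)
               for other, oocc in found.items()):
            continue
        maximal.append((sub, occ))
    return maximal


def repeat_core_finder(orf: str | OrfRecord, min_pattern: int = 6,
                       min_len: int = 3, max_len: int = 30) -> list[CoreCandidate]:
    """Cores from repeated leader/follower patterns.

    The best repeated pattern (most occurrences, then longest) is taken as
    the leader; the segments between consecutive leader copies, plus the
    tail after the last copy, are core candidates after stripping a common
    repeated suffix (the follower) if one exists.
    """
    seq = orf.seq if isinstance(orf, OrfRecord) else orf
    repeats = _repeated_substrings(seq, min_pattern)
    if not repeats:
        return []
    leader, occ = repeats[0]
    segments = []
    for a, b in zip(occ, occ[1:] + [None]):
        start = a + len(leader)
        end = b if b is not None else len(seq)
        segments.append((start, end))
    # follower: longest common suffix (>= min_pattern) of all non-empty segments
    texts = [seq[s:e] for s, e in segments if e > s]
    follower_len = 0
    if len(texts) == len(segments) and texts:
        lcs = texts[0]
        for t in texts[1:]:
            while lcs and not t.endswith(lcs):
                lcs = lcs[1:]
        if len(lcs) >= min_pattern:
            follower_len = len(lcs)
    out = []
    for start, end in segments:
        end -= follower_len
        if min_len <= end - start <= max_len:
            out.append(CoreCandidate(seq[start:end], start, end, "repeat"))
    return out


# -- TSV / GFF3 output --------------------------------------------------------


def bgc_table(bgcs: list[BgcRecord]):
    import pandas as pd
    return pd.DataFrame(
        [{"genome_id": b.genome_id, "start": b.start, "end": b.end,
          "n_hits": len(b.hits),
          "profiles": ",".join(sorted({h.profile for h in b.hits}))}
         for b in bgcs])


def orf_table(orfs: list[OrfRecord]):
    import pandas as pd
    return pd.DataFrame(
        [{"genome_id": o.genome_id, "start": o.start, "end": o.end,
          "strand": o.strand, "frame": o.frame, "seq": o.seq} for o in orfs])


def write_gff3(path, genome: GenomeRecord, bgcs: list[BgcRecord],
               orfs: list[OrfRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, b in enumerate(bgcs):
            fh.write(f"{genome.id}\tripptide\tbiosynthetic_gene_cluster\t"
                     f"{b.start + 1}\t{b.end}\t.\t.\t.\tID=bgc{k}\n")
        for k, o in enumerate(orfs):
            strand = "+" if o.strand == 1 else "-"
            fh.write(f"{genome.id}\tripptide\tORF\t{o.start + 1}\t{o.end}\t.\t"
                     f"{strand}\t.\tID=orf{k}\n")
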
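# Methods

This note documents the models and numerical choices behind `ripptide`,
what the synthetic data emulates, and where the open design decisions were
settled.

## Molecular graphs and peptide construction

Molecules are labeled graphs: heavy atoms with implicit hydrogen counts and
bonds of four classes (orders 1/2/3 plus a distinct aromatic class).
Aromatic bonds are kept as their own class rather than a Kekulé assignment
so that an aromatic motif matches an aromatic ring as a unit (a kekulized
benzene would match a toluene ring in only 6 of its 12 symmetry-equivalent
ways, because alternating single/double assignments break half the ring
automorphisms).  Stereochemistry is parsed and discarded with a warning:
motif matching, modification, and fragmentation are all constitution-only.
SMILES parsing/writing and canonicalization delegate to rdkit; canonical
SMILES is the deduplication key for enumerated products.

Peptides are assembled from residue templates (the 20 proteinogenic
residues as `-NH-CHR-CO-` subgraphs with designated backbone N and carbonyl
C), joined N-to-C by amide bonds, with a free N-terminal amine and
C-terminal carboxylic acid.  A residue map (position → atom set) preserves
sequence provenance through modification.  Monoisotopic masses are sums of
principal-isotope masses (NIST table via pyteomics); the test suite checks
every residue and 50 random cores against pyteomics' independent peptide
mass calculator.

## Subgraph isomorphism

Motif location is a modified Ullmann search: a candidate (correspondence)
table admits a subject atom for a query atom when elements match and the
multiset of (neighbor element, bond class) pairs of the query atom is a
sub-multiset of the subject atom's; embeddings are then enumerated by
backtracking over a breadth-first order of the query (lowest-index atom
first, per connected component), so each newly placed atom is constrained
by an already-placed neighbor.  Hydrogens are stripped from both sides
first; explicit motif hydrogens are tracked separately so that rules can
address them.  Automorphic duplicates are returned by design — the rule
engine deduplicates placements by mapped atom set.  An exhaustive
brute-force matcher over all injective maps (subjects ≤ 12 atoms) is
exported as the independent oracle and the two are compared on hundreds of
random graph pairs in the tests.

## Modification rules and product enumeration

A tailoring enzyme is a rule: motif SMILES (with explicit `[H]` where
actions touch hydrogens), the licensing enzyme profile ids, and an ordered
action list in a four-verb grammar (`disconnect i j`, `connect i j k`,
`remove i`, `add i FORMULA`), indices being 1-based motif SMILES atom
positions.  At application time the motif's explicit hydrogens are
materialized from the subject's implicit counts, actions are replayed in
the site frame, and surviving hydrogens are re-collapsed; the result must
pass a maximum-valence check.  Every rule is validated at parse time by
replaying it on its own bare motif.

Enumeration takes every subset of the optional (rule, site) pairs, applies
them in a deterministic order (rule name, then smallest mapped atom index),
skips subsets whose later sites no longer embed after earlier edits, and
deduplicates by canonical SMILES — *m* pairwise disjoint sites give exactly
2^*m* products, the bare core always included.  The default cap is 2¹⁶
products per core; hitting it sets a `truncated` flag and logs a warning.
Site discovery happens once, on the unmodified core: rules whose motifs
only exist after another modification (e.g. lanthionine ring closure onto a
dehydroalanine) therefore fire only when given an already-dehydrated input;
iterated multi-pass application is a known limitation.

The shipped rule set covers Ser/Thr dehydration, N-terminal dimethylation,
lanthionine addition, macrolactam ring closure, oxidative decarboxylation,
and thiazoline formation; users can supply their own rule files in the same
plain-text format.

## Genome mining

Coordinates are 0-based half-open throughout.  Six-frame translation uses
translation table 11; enzyme hits are read from a HMMER-tabular-style file
(or produced live by the pyhmmer adapter) and filtered at E ≤ 10⁻⁵
(boundary kept).  Each hit midpoint seeds a ±10 kb window; strictly
overlapping windows merge into BGCs, making the merge idempotent with
pairwise-disjoint output.  ORFs run from any start codon (ATG/GTG/TTG) to
the next in-frame stop; all internal-start variants in 11–200 aa are kept,
since precursor starts are easily mispredicted.  Candidate precursors are
ORFs whose midpoint lies within 10 kb of a hit midpoint (midpoint-to-
midpoint, the unambiguous reading).  Exhaustive cores are all 3–30 aa
substrings with positions retained (the lower bound is configurable).

The repeat-based finder targets precursors with multiple cores
(cyanobactin-like and plant precursors): among maximal repeated substrings
of length ≥ 6 with ≥ 2 non-overlapping occurrences it picks the best
(most occurrences, then longest, then earliest) as the leader, takes the
segments between consecutive copies plus the tail, strips a common
repeated suffix (the follower) when present, and returns segments of core
length.  If two adjacent cores share their first letters the repeat can
absorb them; distinct core starts avoid this.

## Neural precursor models

Both sequence models share one encoder: tokens (20 amino acids + X + pad,
22 ids), sequences padded/truncated to 200 positions (configurable),
embedding size 100 by default.  Two 1-D convolution branches (kernel 5,
stride 1, 64 filters, ReLU) run over the embedded sequence — one along
sequence positions, one along embedding channels (the transposed matrix) —
and their outputs are concatenated with the raw embeddings into a
single-layer bidirectional LSTM (hidden size 64 per direction).

* The **precursor classifier** flattens the LSTM outputs into one dense
  sigmoid unit; decision cutoff 0.5, with the boundary classified positive.
  Training uses binary cross-entropy, Adam at 10⁻³ decayed ×0.9 every 40
  epochs, early stopping on validation loss (patience 25, max 400 epochs),
  81/9/10 train/validation/test splits, and negatives randomly subsampled
  to match the positives in every partition.
* The **cleavage tagger** replaces the head with dropout (p = 0.2) and a
  dense projection to 5 emissions per position for a linear-chain CRF over
  {start, before, core, after, end}; training minimizes the exact CRF
  negative log-likelihood (masked forward algorithm), prediction uses
  Viterbi with ties broken to the lowest label index at the earliest
  differing position, and a transition mask enforcing the
  start→before→core→after→end grammar is on by default.  N-/C-terminal
  cleavage sites are ranked by the forward-backward marginal probability of
  the before→core and core→after transitions; the top *k* of each combine
  into at most *k*² candidate cores.  Marginals (rather than k-best
  Viterbi) keep the two rankings independent, which is what the *k*²
  combination implies.

The embedding size is 100 by default with 25 available via configuration
(both appear in the literature for this architecture family); the sigmoid
single-logit head was chosen over a 2-class softmax as the smaller
equivalent.  All tensor math runs on a small reverse-mode autodiff engine
written on numpy (gradient-checked against finite differences in the
tests); single-threaded numpy makes training and decoding bit-for-bit
reproducible for a fixed seed.  Training corpora for real RiPPs are
user-supplied; the tests train on planted-motif synthetic data, which shows
the architecture and optimization work end-to-end but says nothing about
accuracy on real precursors.

## Fragmentation and spectral scoring

All C–C, O–C, and N–C bonds — ring or chain, any order — are broken; the
residual connected components condense into metabolite-graph nodes,
re-joined by the broken bonds.  Fragments are connected components after
removing a bridge or a minimal 2-cut (an unordered pair of edges whose
joint removal disconnects the graph while neither alone does), recursively
to depth 2 by default, deduplicated by node subset.  Bridges come from an
iterative lowpoint DFS on the multigraph (parallel edges are never
bridges); 2-cut partners of an edge are exactly the edges that become
bridges once it is removed.  A networkx-based exhaustive cut enumerator
serves as the oracle for graphs ≤ 8 nodes.

Fragment neutral mass = member-atom masses (implicit H included) + one
hydrogen per broken boundary bond (homolytic-plus-H convention; the offset
is configurable as 0 or ±1.00783, and is the main knob if scores are
compared against other implementations).  A peak at m/z *x* and charge *z*
neutralizes to *xz* − 1.00728·*z* (default *z* = 1); a fragment is
annotated when some neutralized peak lies within 0.02 Da.  The score is
the number of peaks annotating at least one fragment on a *fully
annotated* root-to-fragment path — every non-root fragment on the path
annotated, the root annotated by convention.  The null model treats each
fragment as a Bernoulli trial with p = min(1, n_peaks · 2·tol / precursor
mass); the p-value is the exact Poisson-Binomial upper tail by
dynamic-programming convolution (verified against 2¹⁵-term enumeration).
On pure-noise spectra the empirical p-value distribution stays within
2α at α = 0.01 and 0.05 over 1000 seeded trials.

Decoys are seeded shuffles of the core residue order (composition- and
mass-preserving) applied before modification; FDR(t) is the decoy/target
count ratio at threshold t, with q-values (running minima) available where
a monotone curve is required.

## Synthetic data

The genome generator implants, per cluster, a fixed "enzyme" gene (emitted
as a domain hit, as a profile search would) and a precursor ORF
(leader + core) ~1 kb downstream in a random background; three clusters in
90 kb by default, cores of 6 distinct residues.  The spectrum generator
emits the protonated masses of all depth-≤2 fragments plus seeded uniform
noise peaks.  Recovery trials use 5-residue cores drawn from the 14
non-aromatic, non-Pro residues, which keeps metabolite graphs acyclic and
fragmentation fast; 100 trials of a target against nine shuffled decoys
run in about a minute.  What these fixtures do not emulate: real HMM score
distributions, sequencing error, overlapping genes, isotope envelopes,
multiply charged fragments, intensity structure, or retention time — so
passing tests demonstrate algorithmic correctness, not field performance
on real genomes or spectra.

## Problem sizes and defaults

Tests and the acceptance script run at desk scale: planted-motif corpora of
100–200 sequences with reduced model sizes (pad 24–32, embedding 8–10,
8–16 filters, hidden 12), 100 spectral recovery trials, fragmentation
oracles on ≤ 8-node graphs.  Defaults elsewhere: window 10 kb, E ≤ 10⁻⁵,
ORFs 11–200 aa, cores 3–30 aa, k = 5, enumeration cap 2¹⁶, depth 2,
tolerances 0.02 Da, charge 1+.

## Known limitations

Single-pass rule application (no modification cascades); no multiply
charged or isotope-resolved fragment matching; naive ORF calling rather
than a gene finder; the repeat finder assumes exact repeats; Levenshtein
similarity is reference-normalized and deliberately asymmetric; the null
model's uniform per-fragment probability is a simplification that the
calibration test bounds but does not sharpen.
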
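# ripptide

Genome mining and tandem-MS identification of RiPPs — ribosomally
synthesized and post-translationally modified peptides — for natural-product
researchers who want to go from a bacterial genome to testable hypothetical
structures and from structures to peptide-spectrum matches.

RiPPs are made as short precursor ORFs (leader + core + follower) encoded
near their tailoring enzymes in a biosynthetic gene cluster (BGC); the core
is cleaved out and chemically modified.  `ripptide` implements the full
chain:

1. **genome → BGCs** — six-frame translation, profile-HMM enzyme hits
   (E ≤ 10⁻⁵), ±10 kb windows around hit midpoints, merged into BGCs.
2. **BGC → ORFs** — naive start-to-stop ORF calling (11–200 aa) near the
   enzymes, optionally filtered by a CNN–BiLSTM binary precursor classifier.
3. **ORF → cores** — exhaustive 3–30 aa substrings, a repeat-based
   leader/follower finder, or a CNN–BiLSTM–CRF cleavage tagger whose top-*k*
   N-/C-cleavage sites yield up to *k*² candidate cores.
4. **core → mature structures** — the core is built as a molecular graph;
   each tailoring enzyme is a rule (motif SMILES + add/remove/connect/
   disconnect actions) located by a modified Ullmann subgraph-isomorphism
   search; every subset of optional modifications is enumerated, so *m*
   disjoint sites give 2^*m* canonical products (10 sites → 1024).
5. **structure ↔ spectrum** — all C–C/O–C/N–C bonds are broken to form the
   metabolite graph; fragments are connected components after removing a
   bridge or a minimal 2-cut, recursively to depth 2.  The score of a match
   is the number of experimental peaks on fully annotated root-to-fragment
   paths; significance is the exact Poisson-Binomial tail
   P(X ≥ score) over per-fragment Bernoulli annotation probabilities, and
   confidence is controlled by target-decoy FDR.

## Worked example

```python
from ripptide import core2ripp, load_default_rules, monoisotopic_mass, parse_smiles

rules = load_default_rules()
products = core2ripp("GSG", {"PF05147"}, rules)   # lanthipeptide dehydratase
for smiles in products:
    print(f"{monoisotopic_mass(parse_smiles(smiles)):9.4f}  {smiles}")
```

```
 201.0750  C=C(NC(=O)CN)C(=O)NCC(=O)O
 219.0855  NCC(=O)NC(CO)C(=O)NCC(=O)O
```

The Gly-Ser-Gly core (219.0855 Da) carries one serine, so one dehydration
site: the enumeration returns the unmodified peptide and the dehydrated
product exactly 18.0106 Da (one water) lighter — the dehydroalanine
(`C=C(...)`) visible in the first SMILES.

Or from the shell, a full synthetic round-trip:

```sh
ripptide simulate --seed 3 --n-bgc 2      # genome + hit table + truth table
ripptide mine --genome synthetic.fasta --hits synthetic.hits.tsv
ripptide cores --orfs mine.orfs.tsv
ripptide enumerate --core GSG --enzymes PF05147
ripptide search --library library.tsv --mgf spectra.mgf
```

Every implanted precursor and core in the simulation is recovered by
`mine`/`cores`, and in spectral search the true molecule outranks
mass-matched shuffled-sequence decoys.

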
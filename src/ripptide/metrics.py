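"""Benchmark metrics: normalized Levenshtein similarity and Tanimoto.

The sequence metric normalizes edit distance by the *reference* length and
is therefore deliberately asymmetric; the structure metric is the Tanimoto
coefficient on hashed radius-2 Morgan (circular) fingerprints, 2048 bits.
"""

from __future__ import annotations

import edlib
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

FP_RADIUS = 2
FP_BITS = 2048


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - editdistance(a, b) / |b|, floored at 0; b is the reference."""
    if not b:
        raise ValueError("reference sequence must be non-empty")
    if not a:
        return 0.0
    d = edlib.align(a, b)["editDistance"]
    return max(0.0, 1.0 - d / len(b))


def morgan_bits(smiles: str, radius: int = FP_RADIUS, n_bits: int = FP_BITS) -> set[int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return set(gen.GetFingerprint(mol).GetOnBits())


def tanimoto_morgan(smiles1: str, smiles2: str, radius: int = FP_RADIUS) -> float:
    """Shared on-bits over union of on-bits of the two fingerprints."""
    b1 = morgan_bits(smiles1, radius)
    b2 = morgan_bits(smiles2, radius)
    if not b1 and not b2:
        return 1.0
    union = len(b1 | b2)
    return len(b1 & b2) / union if union else 0.0
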
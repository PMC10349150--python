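"""Sequence models for precursor classification and cleavage-site tagging.

Both models share one encoder: amino acids are tokenized and embedded, two
1-D convolution branches run over the embedded sequence — one along
sequence positions, one along embedding channels — their outputs are
concatenated with the raw embeddings and fed to a single-layer
bidirectional LSTM.  The precursor classifier (bgc2orf) flattens the LSTM
outputs into a dense layer with a sigmoid probability (decision cutoff
0.5); the cleavage tagger (orf2core) instead applies dropout and a dense
projection to per-position emissions for a 5-label linear-chain CRF
(start / before / core / after / end), decoded by Viterbi.  Cleavage sites
are the before->core and core->after transitions; the top-k of each, ranked
by CRF transition marginals, combine into up to k^2 candidate cores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .crf import (N_LABELS, crf_nll, crf_viterbi, transition_marginals)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_ID = 0
UNK_ID = 21
#: token vocabulary: pad, 20 amino acids, X
VOCAB = {"<pad>": PAD_ID, **{aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)},
         "X": UNK_ID}
VOCAB_SIZE = 22


def encode_sequence(seq: str, pad_len: int = 200) -> np.ndarray:
    """Tokenize and pad/truncate to a fixed-length integer vector."""
    if len(seq) > pad_len:
        warnings.warn(f"sequence of length {len(seq)} truncated to {pad_len}",
                      stacklevel=2)
        seq = seq[:pad_len]
    ids = np.full(pad_len, PAD_ID, dtype=np.int64)
    for i, aa in enumerate(seq):
        tok = VOCAB.get(aa)
        if tok is None:
            raise ValueError(f"non-amino-acid character {aa!r} at position {i}")
        ids[i] = tok
    return ids


@dataclass
class Bgc2orfSpec:
    pad_len: int = 200
    embed_size: int = 100
    conv_filters: int = 64
    kernel_size: int = 5
    hidden_size: int = 64
    cutoff: float = 0.5
    lr: float = 1e-3
    lr_decay: float = 0.9
    lr_decay_every: int = 40
    max_epochs: int = 400
    patience: int = 25

    def validate(self):
        for name in ("pad_len", "embed_size", "conv_filters", "kernel_size",
                     "hidden_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Orf2coreSpec(Bgc2orfSpec):
    dropout: float = 0.2
    constrained: bool = True


@dataclass
class DataSplit:
    train: float = 0.81
    validation: float = 0.09
    test: float = 0.10
    rebalance: bool = True

    def __post_init__(self):
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")


def _init(rng, *shape, scale=None):
    scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
    return ad.Parameter(rng.normal(0.0, scale, size=shape))


class _Encoder:
    """Embedding + two conv branches + BiLSTM, shared by both models."""

    def __init__(self, spec: Bgc2orfSpec, rng: np.random.Generator):
        E, F, K, H, L = (spec.embed_size, spec.conv_filters, spec.kernel_size,
                         spec.hidden_size, spec.pad_len)
        self.spec = spec
        self.embed = _init(rng, VOCAB_SIZE, E, scale=0.1)
        # branch over sequence positions: (B, L, E) -> (B, L, F)
        self.conv_seq_k = _init(rng, K, E, F, scale=1.0 / np.sqrt(K * E))
        self.conv_seq_b = ad.Parameter(np.zeros(F))
        # branch over embedding channels: (B, E, L) -> (B, E, L) -> back
        self.conv_chan_k = _init(rng, K, L, L, scale=1.0 / np.sqrt(K * L))
        self.conv_chan_b = ad.Parameter(np.zeros(L))
        C = E + F + E  # embeddings + position branch + channel branch
        self.lstm = {}
        for d in ("fw", "bw"):
            self.lstm[d] = {
                "Wx": _init(rng, C, 4 * H, scale=1.0 / np.sqrt(C)),
                "Wh": _init(rng, H, 4 * H, scale=1.0 / np.sqrt(H)),
                "b": ad.Parameter(np.zeros(4 * H)),
            }
        self.H = H

    def params(self):
        ps = [self.embed, self.conv_seq_k, self.conv_seq_b,
              self.conv_chan_k, self.conv_chan_b]
        for d in ("fw", "bw"):
            ps += list(self.lstm[d].values())
        return ps

    def __call__(self, ids: np.ndarray) -> ad.Tensor:
        """ids (B, L) -> contextual features (B, L, 2H)."""
        B, L = ids.shape
        H = self.H
        x = ad.embedding(self.embed, ids)                       # (B, L, E)
        a = ad.relu(ad.conv1d_same(x, self.conv_seq_k, self.conv_seq_b))
        xt = ad.transpose(x, (0, 2, 1))                         # (B, E, L)
        bt = ad.relu(ad.conv1d_same(xt, self.conv_chan_k, self.conv_chan_b))
        b = ad.transpose(bt, (0, 2, 1))                         # (B, L, E)
        feats = ad.concat([x, a, b], axis=-1)
        outs = {}
        for d, order in (("fw", range(L)), ("bw", range(L - 1, -1, -1))):
            W = self.lstm[d]
            h = ad.Tensor(np.zeros((B, H)))
            c = ad.Tensor(np.zeros((B, H)))
            steps = [None] * L
            for t in order:
                gates = feats[:, t, :] @ W["Wx"] + h @ W["Wh"] + W["b"]
                i = ad.sigmoid(gates[:, 0:H])
                f = ad.sigmoid(gates[:, H:2 * H])
                g = ad.tanh(gates[:, 2 * H:3 * H])
                o = ad.sigmoid(gates[:, 3 * H:4 * H])
                c = f * c + i * g
                h = o * ad.tanh(c)
                steps[t] = h.reshape(B, 1, H)
            outs[d] = ad.concat(steps, axis=1)                  # (B, L, H)
        return ad.concat([outs["fw"], outs["bw"]], axis=-1)     # (B, L, 2H)


class PrecursorClassifier:
    """Binary RiPP-precursor ORF classifier (bgc2orf)."""

    def __init__(self, spec: Bgc2orfSpec | None = None, seed: int = 0):
        self.spec = spec or Bgc2orfSpec()
        self.spec.validate()
        self.rng = np.random.default_rng(seed)
        self.encoder = _Encoder(self.spec, self.rng)
        L, H = self.spec.pad_len, self.spec.hidden_size
        self.dense_w = _init(self.rng, L * 2 * H, 1)
        self.dense_b = ad.Parameter(np.zeros(1))

    def params(self):
        return self.encoder.params() + [self.dense_w, self.dense_b]

    def forward(self, ids: np.ndarray) -> ad.Tensor:
        B = ids.shape[0]
        feats = self.encoder(ids)
        flat = feats.reshape(B, -1)
        return ad.sigmoid(flat @ self.dense_w + self.dense_b)   # (B, 1)

    def loss(self, ids: np.ndarray, y: np.ndarray) -> ad.Tensor:
        p = self.forward(ids)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        eps = 1e-9
        ll = (ad.log(p + eps) * ad.Tensor(y)
              + ad.log(1.0 - p + eps) * ad.Tensor(1.0 - y))
        return -ll.mean()

    def predict_proba(self, seqs: list[str]) -> np.ndarray:
        ids = np.stack([encode_sequence(s, self.spec.pad_len) for s in seqs])
        return self.forward(ids).data.ravel()

    def score(self, seq: str) -> float:
        return float(self.predict_proba([seq])[0])

    def classify(self, p: float) -> bool:
        """Decision at the cutoff; exactly at the cutoff counts as positive."""
        return p >= self.spec.cutoff

    def predict(self, seqs: list[str]) -> np.ndarray:
        return self.predict_proba(seqs) >= self.spec.cutoff


# transitions that respect the start->before->core->after->end grammar
_ALLOWED = np.full((N_LABELS, N_LABELS), -1e4)
for _a, _b in [(0, 1), (1, 1), (1, 2), (2, 2), (2, 3), (3, 3), (3, 4), (4, 4),
               (0, 2), (2, 4)]:
    _ALLOWED[_a, _b] = 0.0


class CleavageTagger:
    """CRF cleavage-site tagger (orf2core)."""

    def __init__(self, spec: Orf2coreSpec | None = None, seed: int = 0):
        self.spec = spec or Orf2coreSpec()
        self.spec.validate()
        self.rng = np.random.default_rng(seed)
        self.encoder = _Encoder(self.spec, self.rng)
        H = self.spec.hidden_size
        self.emit_w = _init(self.rng, 2 * H, N_LABELS)
        self.emit_b = ad.Parameter(np.zeros(N_LABELS))
        self.transitions = ad.Parameter(np.zeros((N_LABELS, N_LABELS)))

    def params(self):
        return self.encoder.params() + [self.emit_w, self.emit_b, self.transitions]

    def emissions(self, ids: np.ndarray, train: bool = False) -> ad.Tensor:
        feats = self.encoder(ids)
        feats = ad.dropout(feats, self.spec.dropout, self.rng, train)
        return feats @ self.emit_w + self.emit_b                # (B, L, K)

    def _trans_matrix(self) -> np.ndarray:
        t = self.transitions.data
        return t + _ALLOWED if self.spec.constrained else t

    def loss(self, ids: np.ndarray, labels: np.ndarray,
             mask: np.ndarray) -> ad.Tensor:
        emis = self.emissions(ids, train=True)
        trans = self.transitions
        if self.spec.constrained:
            trans = trans + ad.Tensor(_ALLOWED)
        return crf_nll(emis, trans, labels, mask)

    def decode(self, seq: str) -> list[int]:
        ids = encode_sequence(seq, self.spec.pad_len)[None, :]
        emis = self.emissions(ids).data[0][: len(seq)]
        return crf_viterbi(emis, self._trans_matrix())

    def decode_cores(self, seq: str, k: int = 5) -> list[tuple[int, int, float]]:
        """Up to k^2 positioned cores (start, end, joint marginal).

        N-terminal sites are ranked by the marginal probability of a
        before->core transition, C-terminal sites by core->after; every
        (N, C) pair with N < C is returned, best-first.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        L = min(len(seq), self.spec.pad_len)
        ids = encode_sequence(seq, self.spec.pad_len)[None, :]
        emis = self.emissions(ids).data[0][:L]
        trans = self._trans_matrix()
        if L < 2:
            return []
        m_n = transition_marginals(emis, trans, 1, 2)   # before -> core at t
        m_c = transition_marginals(emis, trans, 2, 3)   # core -> after at t
        top_n = np.argsort(-m_n, kind="stable")[:k]
        top_c = np.argsort(-m_c, kind="stable")[:k]
        cores = []
        for tn in top_n:
            for tc in top_c:
                start, end = int(tn) + 1, int(tc) + 1
                if start < end:
                    cores.append((start, end, float(m_n[tn] * m_c[tc])))
        cores.sort(key=lambda c: (-c[2], c[0], c[1]))
        return cores[: k * k]


def labels_for_core(length: int, core_start: int, core_end: int,
                    pad_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Gold label sequence and mask for an ORF with core [core_start, core_end)."""
    if not 0 < core_start < core_end <= length:
        raise ValueError("core interval must be inside the ORF, off the ends")
    labels = np.full(pad_len, 0, dtype=np.int64)
    mask = np.zeros(pad_len)
    mask[:length] = 1.0
    labels[0] = 0                       # <start>
    labels[1:core_start] = 1            # <before>
    labels[core_start:core_end] = 2     # <core>
    labels[core_end:length - 1] = 3     # <after>
    if core_end < length:
        labels[length - 1] = 4          # <end>
    return labels, mask
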
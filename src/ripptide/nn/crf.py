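"""Linear-chain CRF: Viterbi decoding, forward-backward, and training loss.

Label semantics for cleavage tagging: 5 labels
{start:0, before:1, core:2, after:3, end:4}; an N-terminal cleavage site is
a before->core transition, a C-terminal one a core->after transition.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

LABELS = ("start", "before", "core", "after", "end")
N_LABELS = len(LABELS)
_EPS = 1e-9


def crf_viterbi(emissions: np.ndarray, transitions: np.ndarray) -> list[int]:
    """Highest-scoring label path; ties resolved to the lowest label index
    at the earliest differing position.

    emissions: (L, K); transitions: (K, K) additive log-potentials.
    """
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    L, K = emissions.shape
    # B[t, y] = best score of a path suffix starting at position t in label y
    B = np.empty((L, K))
    B[L - 1] = emissions[L - 1]
    for t in range(L - 2, -1, -1):
        B[t] = emissions[t] + (transitions + B[t + 1][None, :]).max(axis=1)
    path = [int(np.flatnonzero(B[0] >= B[0].max() - _EPS)[0])]
    for t in range(1, L):
        y_prev = path[-1]
        scores = transitions[y_prev] + B[t]
        target = B[t - 1][y_prev] - emissions[t - 1][y_prev]
        path.append(int(np.flatnonzero(scores >= target - _EPS)[0]))
    return path


def crf_forward_backward(emissions: np.ndarray, transitions: np.ndarray):
    """Log-space forward/backward messages and the log partition function."""
    from scipy.special import logsumexp
    emissions = np.asarray(emissions, dtype=float)
    L, K = emissions.shape
    alpha = np.empty((L, K))
    beta = np.empty((L, K))
    alpha[0] = emissions[0]
    for t in range(1, L):
        alpha[t] = emissions[t] + logsumexp(alpha[t - 1][:, None] + transitions,
                                            axis=0)
    beta[L - 1] = 0.0
    for t in range(L - 2, -1, -1):
        beta[t] = logsumexp(transitions + emissions[t + 1][None, :]
                            + beta[t + 1][None, :], axis=1)
    logZ = logsumexp(alpha[L - 1])
    return alpha, beta, logZ


def position_marginals(emissions, transitions) -> np.ndarray:
    """(L, K) posterior label probabilities; each row sums to 1."""
    alpha, beta, logZ = crf_forward_backward(emissions, transitions)
    return np.exp(alpha + beta - logZ)


def transition_marginals(emissions, transitions, y_from: int, y_to: int) -> np.ndarray:
    """P(y_t = y_from, y_{t+1} = y_to) for t = 0..L-2."""
    emissions = np.asarray(emissions, dtype=float)
    alpha, beta, logZ = crf_forward_backward(emissions, transitions)
    L = emissions.shape[0]
    if L < 2:
        return np.zeros(0)
    t = np.arange(L - 1)
    logp = (alpha[t, y_from] + transitions[y_from, y_to]
            + emissions[t + 1, y_to] + beta[t + 1, y_to] - logZ)
    return np.exp(logp)


def crf_nll(emissions: "ad.Tensor", transitions: "ad.Tensor",
            labels: np.ndarray, mask: np.ndarray) -> "ad.Tensor":
    """Mean negative log-likelihood of gold label sequences (autodiff).

    emissions: (B, L, K) Tensor; labels: (B, L) int; mask: (B, L) 0/1 with
    at least the first position set per sequence.
    """
    B, L, K = emissions.data.shape
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=float)
    bi = np.arange(B)
    # gold path score
    gold_emit = emissions[bi[:, None], np.arange(L)[None, :], labels] * ad.Tensor(mask)
    pair_mask = mask[:, 1:] * mask[:, :-1]
    gold_trans = transitions[labels[:, :-1], labels[:, 1:]] * ad.Tensor(pair_mask)
    gold = gold_emit.sum(axis=1) + gold_trans.sum(axis=1)
    # partition function by masked alpha recursion
    alpha = emissions[:, 0, :]
    trans = transitions.reshape(1, K, K)
    for t in range(1, L):
        prev = alpha.reshape(B, K, 1)
        new = ad.logsumexp(prev + trans, axis=1) + emissions[:, t, :]
        alpha = ad.where_mask(mask[:, t][:, None], new, alpha)
    logZ = ad.logsumexp(alpha, axis=1)
    return (logZ - gold).mean()
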
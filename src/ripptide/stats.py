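"""Poisson-Binomial PSM significance and target-decoy FDR.

The score of a molecule-spectrum match is the number of experimental peaks
on fully annotated root-to-fragment paths.  Under the null, each
theoretical fragment is annotated independently with its own probability
p_i (a Bernoulli trial); the p-value of a score n is the upper tail
P(X >= n) of the Poisson-Binomial sum, computed exactly by dynamic
programming.
"""

from __future__ import annotations

import warnings

import numpy as np


def poisson_binomial_tail(probs, n: int) -> float:
    """Exact P(X >= n) for X = sum of independent Bernoulli(p_i)."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("success probabilities must lie in [0, 1]")
    if n <= 0:
        return 1.0
    if n > probs.size:
        return 0.0
    # dp[k] = P(X = k) after processing a prefix of trials
    dp = np.zeros(probs.size + 1)
    dp[0] = 1.0
    for k, p in enumerate(probs):
        dp[1:k + 2] = dp[1:k + 2] * (1 - p) + dp[:k + 1] * p
        dp[0] *= (1 - p)
    return float(dp[n:].sum())


def uniform_null_probs(n_fragments: int, n_peaks: int, tol: float,
                       mass_window: float) -> np.ndarray:
    """Per-fragment annotation probability under a uniform-peak null."""
    p = min(1.0, n_peaks * 2.0 * tol / max(mass_window, 1e-9))
    return np.full(n_fragments, p)


def estimate_fdr(target_scores, decoy_scores, threshold: float) -> float:
    """Target-decoy FDR at a score threshold: #decoy >= t / #target >= t."""
    target_scores = np.asarray(list(target_scores), dtype=float)
    decoy_scores = np.asarray(list(decoy_scores), dtype=float)
    if target_scores.size == 0:
        warnings.warn("no target PSMs; FDR undefined, returning 1.0", stacklevel=2)
        return 1.0
    n_t = int((target_scores >= threshold).sum())
    n_d = int((decoy_scores >= threshold).sum())
    return n_d / max(1, n_t)


def fdr_curve(target_scores, decoy_scores, thresholds=None, monotone=False):
    """FDR at each threshold, descending by score.

    With ``monotone=True`` the raw ratios are replaced by q-values
    (q(t) = min over t' <= t of FDR(t')), which are non-increasing in the
    threshold.
    """
    if thresholds is None:
        thresholds = sorted(set(list(target_scores) + list(decoy_scores)),
                            reverse=True)
    curve = [(t, estimate_fdr(target_scores, decoy_scores, t))
             for t in thresholds]
    if monotone:
        out = []
        running = np.inf
        for t, v in sorted(curve, key=lambda tv: tv[0]):   # ascending t
            running = min(running, v)
            out.append((t, running))
        curve = sorted(out, key=lambda tv: -tv[0])
    return curve
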
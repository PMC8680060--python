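"""Linear-chain CRF: path scoring, forward log-partition, forward–backward
marginals, and Viterbi decoding.

Conventions
-----------
``emissions`` is an (L, K) array of per-token tag scores produced by the
encoder; ``transitions`` is a (K+2, K+2) array where rows index the source
tag and columns the destination, with two virtual states appended:
``START = K`` (row used for the transition into the first tag) and
``STOP = K+1`` (column used for the transition out of the last tag).

A path score is

    score(y) = t[START, y_1] + sum_i e[i, y_i] + sum_i t[y_{i-1}, y_i]
               + t[y_L, STOP]

and the log-partition ``logZ = log sum_y exp(score(y))`` is computed by the
forward recursion in log space (log-sum-exp), so it never overflows.

Impossible BMEWO-V transitions (e.g. O→M, B-t1→E-t2) can be masked out;
masked cells are held at a large negative constant rather than -inf so the
log-space recursions stay NaN-free even if every predecessor of a state is
masked.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .codec import OUTSIDE, PREFIXES, TagSchema

__all__ = [
    "MASKED_SCORE",
    "crf_score",
    "crf_log_partition",
    "crf_marginals",
    "viterbi_decode",
    "build_transition_mask",
    "apply_mask",
]

#: Score assigned to disallowed transitions (soft -inf).
MASKED_SCORE = -1.0e4


def _logsumexp(a: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def _check(emissions: np.ndarray, transitions: np.ndarray) -> tuple[int, int]:
    L, K = emissions.shape
    if transitions.shape != (K + 2, K + 2):
        raise ValueError(
            f"transitions must be ({K + 2},{K + 2}) for K={K}, got {transitions.shape}"
        )
    return L, K


def crf_score(
    emissions: np.ndarray, transitions: np.ndarray, tags: Sequence[int]
) -> float:
    """Unnormalized log-score of one tag path, boundary terms included."""
    L, K = _check(emissions, transitions)
    if len(tags) != L:
        raise ValueError(f"{len(tags)} tags for {L} tokens")
    start, stop = K, K + 1
    tags = list(tags)
    if any(not (0 <= t < K) for t in tags):
        raise IndexError(f"tag index out of range [0,{K})")
    score = transitions[start, tags[0]] + emissions[0, tags[0]]
    for i in range(1, L):
        score += transitions[tags[i - 1], tags[i]] + emissions[i, tags[i]]
    score += transitions[tags[-1], stop]
    return float(score)


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log of the sum over all K^L paths of exp(path score)."""
    L, K = _check(emissions, transitions)
    start, stop = K, K + 1
    alpha = transitions[start, :K] + emissions[0]
    for i in range(1, L):
        alpha = _logsumexp(alpha[:, None] + transitions[:K, :K], axis=0) + emissions[i]
    return float(_logsumexp(alpha + transitions[:K, stop]))


def crf_marginals(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward–backward.

    Returns ``(unary, pairwise, logZ)`` where ``unary[i, k]`` is
    P(y_i = k) and ``pairwise`` is a (K+2, K+2) matrix of expected
    transition counts (boundary transitions included) — exactly the
    gradient of logZ with respect to emissions and transitions.
    """
    L, K = _check(emissions, transitions)
    start, stop = K, K + 1
    t = transitions[:K, :K]

    alpha = np.empty((L, K))
    alpha[0] = transitions[start, :K] + emissions[0]
    for i in range(1, L):
        alpha[i] = _logsumexp(alpha[i - 1][:, None] + t, axis=0) + emissions[i]
    logZ = float(_logsumexp(alpha[-1] + transitions[:K, stop]))

    beta = np.empty((L, K))
    beta[-1] = transitions[:K, stop]
    for i in range(L - 2, -1, -1):
        beta[i] = _logsumexp(t + (emissions[i + 1] + beta[i + 1])[None, :], axis=1)

    unary = np.exp(alpha + beta - logZ)

    pairwise = np.zeros((K + 2, K + 2))
    pairwise[start, :K] = np.exp(
        transitions[start, :K] + emissions[0] + beta[0] - logZ
    )
    pairwise[:K, stop] = np.exp(alpha[-1] + transitions[:K, stop] - logZ)
    for i in range(1, L):
        pairwise[:K, :K] += np.exp(
            alpha[i - 1][:, None] + t + (emissions[i] + beta[i])[None, :] - logZ
        )
    return unary, pairwise, logZ


def viterbi_decode(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[list[int], float]:
    """Best-scoring tag path and its score.

    Ties are broken toward the lowest tag index at every backpointer
    (np.argmax returns the first maximum), so decoding is deterministic.
    """
    L, K = _check(emissions, transitions)
    start, stop = K, K + 1
    delta = transitions[start, :K] + emissions[0]
    backptr = np.empty((L, K), dtype=np.intp)
    for i in range(1, L):
        scores = delta[:, None] + transitions[:K, :K]
        backptr[i] = np.argmax(scores, axis=0)
        delta = scores[backptr[i], np.arange(K)] + emissions[i]
    final = delta + transitions[:K, stop]
    last = int(np.argmax(final))
    best_score = float(final[last])
    path = [last]
    for i in range(L - 1, 0, -1):
        path.append(int(backptr[i, path[-1]]))
    path.reverse()
    return path, best_score


# ---------------------------------------------------------------------------
# BMEWO-V transition constraints

def _allowed(prefix_a: str, type_a: Optional[str], prefix_b: str, type_b: Optional[str]) -> bool:
    # V is free on both sides: it may open, continue, or close a run, and
    # its type (the inner mention's) is independent of the outer run type.
    if prefix_a == "V" or prefix_b == "V":
        return True
    if prefix_a in (OUTSIDE, "E", "W"):  # closed context
        return prefix_b in (OUTSIDE, "B", "W")
    if prefix_a in ("B", "M"):  # open run of type_a
        return prefix_b in ("M", "E") and type_b == type_a
    raise AssertionError(prefix_a)


def build_transition_mask(schema: TagSchema) -> np.ndarray:
    """(K+2, K+2) boolean mask of structurally possible transitions."""
    tags = schema.tags
    K = len(tags)
    start, stop = K, K + 1

    def split(tag: str) -> tuple[str, Optional[str]]:
        return schema.split(tag)

    mask = np.zeros((K + 2, K + 2), dtype=bool)
    for a, tag_a in enumerate(tags):
        pa, ta = split(tag_a)
        for b, tag_b in enumerate(tags):
            pb, tb = split(tag_b)
            mask[a, b] = _allowed(pa, ta, pb, tb)
    for b, tag_b in enumerate(tags):  # START behaves like a closed context
        pb, tb = split(tag_b)
        mask[start, b] = pb in (OUTSIDE, "B", "W", "V")
    for a, tag_a in enumerate(tags):  # STOP reachable from closed contexts
        pa, ta = split(tag_a)
        mask[a, stop] = pa in (OUTSIDE, "E", "W", "V")
    return mask


def apply_mask(transitions: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace disallowed cells with :data:`MASKED_SCORE`."""
    return np.where(mask, transitions, MASKED_SCORE)
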
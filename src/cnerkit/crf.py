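"""Linear-chain CRF core: exact inference over emission/transition scores.

The conditional distribution over a label sequence y for an input x is

    P(y | x) = exp{ sum_t e[t, y_t] + sum_t T[y_{t-1}, y_t] } / Z(x)

where ``e`` collects the per-position state scores (weighted state feature
functions) and ``T`` the label-pair transition scores (weighted transition
feature functions).  There is no transition term at t=0 and no explicit
start/stop weights; label-sequence legality (e.g. that I-x follows B-x) is
learned from data rather than hard-coded.

All inference runs in log space, float64.  These routines are shared by the
feature-based CRF tagger and the BiLSTM-CRF output layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass
class SequenceScores:
    """Unnormalized log-potentials for one sentence.

    ``emissions`` is [n_positions x n_labels]; ``transitions`` is
    [n_labels x n_labels], row = previous label, column = current label.
    """

    emissions: np.ndarray
    transitions: np.ndarray

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=np.float64)
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        if self.emissions.ndim != 2 or self.transitions.ndim != 2:
            raise ValueError("emissions and transitions must be 2-D")
        L = self.emissions.shape[1]
        if self.transitions.shape != (L, L):
            raise ValueError(
                f"transitions shape {self.transitions.shape} inconsistent with "
                f"{L} labels"
            )

    @property
    def n_positions(self) -> int:
        return self.emissions.shape[0]

    @property
    def n_labels(self) -> int:
        return self.emissions.shape[1]


def sequence_log_score(scores: SequenceScores, labels: np.ndarray | list[int]) -> float:
    """Log-potential of one labeling: emission terms plus pairwise transition terms."""
    y = np.asarray(labels, dtype=np.intp)
    if y.shape[0] != scores.n_positions:
        raise ValueError(
            f"label sequence length {y.shape[0]} != {scores.n_positions} positions"
        )
    total = float(scores.emissions[np.arange(y.shape[0]), y].sum())
    if y.shape[0] > 1:
        total += float(scores.transitions[y[:-1], y[1:]].sum())
    return total


def forward_log_alphas(scores: SequenceScores) -> np.ndarray:
    """Forward recursion: alpha[t, j] = log-sum over prefixes ending in label j."""
    n, L = scores.emissions.shape
    alphas = np.empty((n, L))
    alphas[0] = scores.emissions[0]
    for t in range(1, n):
        # alpha[t, j] = e[t, j] + logsumexp_i(alpha[t-1, i] + T[i, j])
        alphas[t] = scores.emissions[t] + logsumexp(
            alphas[t - 1][:, None] + scores.transitions, axis=0
        )
    return alphas


def backward_log_betas(scores: SequenceScores) -> np.ndarray:
    """Backward recursion: beta[t, i] = log-sum over suffixes starting after label i."""
    n, L = scores.emissions.shape
    betas = np.zeros((n, L))
    for t in range(n - 2, -1, -1):
        betas[t] = logsumexp(
            scores.transitions + (scores.emissions[t + 1] + betas[t + 1])[None, :],
            axis=1,
        )
    return betas


def log_partition(scores: SequenceScores) -> float:
    """log Z(x): log-sum-exp of the sequence score over all label sequences."""
    if scores.n_positions < 1:
        raise ValueError("need at least one position")
    return float(logsumexp(forward_log_alphas(scores)[-1]))


def posterior_marginals(scores: SequenceScores) -> tuple[np.ndarray, np.ndarray, float]:
    """Node and pairwise posterior marginals via forward-backward.

    Returns ``(node, pair, log_z)`` where ``node[t, j] = P(y_t = j | x)`` and
    ``pair[i, j] = sum_t P(y_{t-1} = i, y_t = j | x)`` (summed over positions,
    which is the quantity the gradient needs).
    """
    alphas = forward_log_alphas(scores)
    betas = backward_log_betas(scores)
    log_z = float(logsumexp(alphas[-1]))
    node = np.exp(alphas + betas - log_z)
    n, L = scores.emissions.shape
    pair = np.zeros((L, L))
    for t in range(1, n):
        log_pair = (
            alphas[t - 1][:, None]
            + scores.transitions
            + (scores.emissions[t] + betas[t])[None, :]
            - log_z
        )
        pair += np.exp(log_pair)
    return node, pair, log_z


def viterbi_decode(scores: SequenceScores) -> tuple[list[int], float]:
    """Best label sequence and its log-potential.

    Ties are broken toward the lower label index at every backtrack step
    (``argmax`` returns the first maximum), so the all-zero score matrix
    decodes to all label 0.
    """
    if scores.n_positions < 1:
        raise ValueError("need at least one position")
    n, L = scores.emissions.shape
    delta = scores.emissions[0].copy()
    backptr = np.empty((n, L), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + scores.transitions  # [prev, cur]
        backptr[t] = np.argmax(cand, axis=0)
        delta = cand[backptr[t], np.arange(L)] + scores.emissions[t]
    best_last = int(np.argmax(delta))
    best_score = float(delta[best_last])
    path = [best_last]
    for t in range(n - 1, 0, -1):
        path.append(int(backptr[t, path[-1]]))
    path.reverse()
    return path, best_score
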
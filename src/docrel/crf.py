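"""Linear-chain conditional random field over the output tag space.

Standard parameterization with start/stop scores: a path ``y_1..y_n`` over a
lattice with per-position emission scores ``e_t[k]`` and a ``K x K``
transition matrix ``A`` has score

    start[y_1] + sum_t e_t[y_t] + sum_t A[y_{t-1}, y_t] + stop[y_n].

``log_partition`` is computed by the forward recursion in log space;
``viterbi`` decodes the best path with ties broken toward the lowest tag
index.  No hard transition constraints are imposed by default; an optional
``allowed`` boolean mask on transitions can forbid pairs for experiments.

Batched, masked variants (used for training) live alongside; masked
(padding) positions never affect the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG_INF = -1e30


@dataclass
class TagLattice:
    """Scores for one sequence: emissions [n, K], transitions [K, K]."""

    emissions: np.ndarray
    transitions: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    allowed: np.ndarray | None = None  # optional [K, K] boolean constraint

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        n, k = self.emissions.shape
        if n == 0:
            raise ValueError("empty sequence")
        if self.transitions.shape != (k, k) or self.start.shape != (k,) \
                or self.stop.shape != (k,):
            raise ValueError("inconsistent lattice shapes")
        if not (np.isfinite(self.emissions).all()
                and np.isfinite(self.transitions).all()):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return self.emissions.shape[0]

    @property
    def k(self) -> int:
        return self.emissions.shape[1]

    def effective_transitions(self) -> np.ndarray:
        if self.allowed is None:
            return self.transitions
        return np.where(self.allowed, self.transitions, NEG_INF)


@dataclass
class TagPath:
    tags: list[int]
    score: float


def path_score(lattice: TagLattice, tags: list[int] | np.ndarray) -> float:
    """Score of one tag path (start + emissions + transitions + stop)."""
    tags = list(tags)
    if len(tags) != lattice.n:
        raise ValueError("path length mismatch")
    trans = lattice.effective_transitions()
    s = lattice.start[tags[0]] + lattice.stop[tags[-1]]
    s += sum(lattice.emissions[t, k] for t, k in enumerate(tags))
    s += sum(trans[a, b] for a, b in zip(tags, tags[1:]))
    return float(s)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.squeeze(m, axis) + np.log(np.sum(np.exp(a - m), axis=axis))


def log_partition(lattice: TagLattice) -> float:
    """log sum over all K^n paths of exp(path score), log-sum-exp stable."""
    trans = lattice.effective_transitions()
    alpha = lattice.start + lattice.emissions[0]
    for t in range(1, lattice.n):
        alpha = _logsumexp(alpha[:, None] + trans, axis=0) + lattice.emissions[t]
    return float(_logsumexp(alpha + lattice.stop, axis=0))


def nll(lattice: TagLattice, gold: list[int] | np.ndarray) -> float:
    """Negative log-likelihood of the gold path: logZ - score(gold)."""
    return log_partition(lattice) - path_score(lattice, gold)


def viterbi(lattice: TagLattice) -> TagPath:
    """Best-scoring path; ties broken by the lowest tag index."""
    trans = lattice.effective_transitions()
    n, k = lattice.n, lattice.k
    score = lattice.start + lattice.emissions[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = score[:, None] + trans  # [from, to]
        back[t] = np.argmax(cand, axis=0)  # first max = lowest index
        score = cand[back[t], np.arange(k)] + lattice.emissions[t]
    final = score + lattice.stop
    last = int(np.argmax(final))
    tags = [last]
    for t in range(n - 1, 0, -1):
        last = int(back[t, last])
        tags.append(last)
    tags.reverse()
    return TagPath(tags=tags, score=float(np.max(final)))


# ---------------------------------------------------------------------------
# Batched, masked operations for training (time-major [T, B, K])
# ---------------------------------------------------------------------------

def crf_log_partition_batch(emissions: np.ndarray, mask: np.ndarray,
                            transitions: np.ndarray, start: np.ndarray,
                            stop: np.ndarray):
    """Masked batch forward recursion.

    ``mask`` is [T, B] with 1 at valid positions (position 0 always valid);
    returns ``(logZ [B], alphas)`` where ``alphas`` caches the per-step
    forward tables for the gradient pass.
    """
    T, B, K = emissions.shape
    alpha = start[None, :] + emissions[0]  # [B, K]
    alphas = [alpha]
    for t in range(1, T):
        new = _logsumexp(alpha[:, :, None] + transitions[None], axis=1) \
            + emissions[t]
        m = mask[t][:, None]
        alpha = m * new + (1.0 - m) * alpha
        alphas.append(alpha)
    logz = _logsumexp(alpha + stop[None], axis=1)
    return logz, alphas


def crf_gold_score_batch(emissions, mask, transitions, start, stop, gold):
    """Scores of the gold paths; gold is [T, B] int, padded arbitrarily."""
    T, B, K = emissions.shape
    lengths = mask.sum(axis=0).astype(int)
    bi = np.arange(B)
    score = start[gold[0]] + emissions[0, bi, gold[0]]
    for t in range(1, T):
        m = mask[t]
        score = score + m * (transitions[gold[t - 1], gold[t]]
                             + emissions[t, bi, gold[t]])
    score = score + stop[gold[lengths - 1, bi]]
    return score


def crf_nll_batch_with_grad(emissions, mask, transitions, start, stop, gold):
    """Mean NLL over the batch and its gradients.

    Gradients are (model-expected counts - gold counts) / B, obtained by
    back-propagating through the forward recursion.

    Returns ``(loss, d_emissions, d_transitions, d_start, d_stop)``.
    """
    T, B, K = emissions.shape
    lengths = mask.sum(axis=0).astype(int)
    bi = np.arange(B)
    logz, alphas = crf_log_partition_batch(emissions, mask, transitions,
                                           start, stop)
    gold_score = crf_gold_score_batch(emissions, mask, transitions, start,
                                      stop, gold)
    loss = float(np.mean(logz - gold_score))

    d_em = np.zeros_like(emissions)
    d_trans = np.zeros_like(transitions)
    d_start = np.zeros_like(start)
    d_stop = np.zeros_like(stop)
    scale = 1.0 / B

    # --- expected counts: backprop through logZ ---
    final = alphas[-1] + stop[None]
    p_final = np.exp(final - logz[:, None])  # softmax over tags, [B, K]
    d_stop += scale * p_final.sum(axis=0)
    d_alpha = p_final  # d logZ / d alpha_{T-1}
    for t in range(T - 1, 0, -1):
        m = mask[t][:, None]
        d_new = d_alpha * m
        d_alpha_carry = d_alpha * (1.0 - m)
        d_em[t] += scale * d_new
        prev = alphas[t - 1]
        z = prev[:, :, None] + transitions[None]  # [B, from, to]
        zmax = z.max(axis=1, keepdims=True)
        ez = np.exp(z - zmax)
        p = ez / ez.sum(axis=1, keepdims=True)  # softmax over 'from'
        d_trans += scale * np.einsum("bjk,bk->jk", p, d_new)
        d_alpha = d_alpha_carry + np.einsum("bjk,bk->bj", p, d_new)
    d_em[0] += scale * d_alpha
    d_start += scale * d_alpha.sum(axis=0)

    # --- subtract gold counts ---
    np.add.at(d_start, gold[0], -scale)
    d_em[0, bi, gold[0]] -= scale
    for t in range(1, T):
        mb = mask[t].astype(bool)
        np.add.at(d_trans, (gold[t - 1][mb], gold[t][mb]), -scale)
        d_em[t, bi[mb], gold[t][mb]] -= scale
    np.add.at(d_stop, gold[lengths - 1, bi], -scale)

    return loss, d_em, d_trans, d_start, d_stop


def viterbi_batch(emissions, mask, transitions, start, stop) -> list[list[int]]:
    """Masked batch Viterbi; returns one tag list per sequence."""
    T, B, K = emissions.shape
    lengths = mask.sum(axis=0).astype(int)
    score = start[None] + emissions[0]
    backs = np.zeros((T, B, K), dtype=int)
    scores_at = [score]
    for t in range(1, T):
        cand = score[:, :, None] + transitions[None]  # [B, from, to]
        back = np.argmax(cand, axis=1)
        new = np.take_along_axis(cand, back[:, None, :], axis=1)[:, 0, :] \
            + emissions[t]
        m = mask[t][:, None]
        score = m * new + (1.0 - m) * score
        backs[t] = back
        scores_at.append(score)
    paths = []
    for b in range(B):
        n = int(lengths[b])
        final = scores_at[n - 1][b] + stop
        last = int(np.argmax(final))
        tags = [last]
        for t in range(n - 1, 0, -1):
            last = int(backs[t, b, last])
            tags.append(last)
        tags.reverse()
        paths.append(tags)
    return paths
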
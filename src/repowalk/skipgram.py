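"""Skip-gram with negative sampling (SGNS) over walk corpora.

A word2vec-style trainer: for every (center, context) pair drawn from
a window around each token, the objective

    log sigma(u_ctx . v_center) + sum_k log sigma(-u_neg_k . v_center)

is maximised by sequential SGD.  The window is dynamic (the effective
half-width is drawn uniformly from 1..window per center occurrence
per epoch, as in word2vec), negatives are drawn from the unigram
distribution raised to 3/4, and the learning rate decays linearly
over all scheduled pairs.

The update loop is sequential — each pair sees the weights left by
the previous pair, exactly as in the reference word2vec
implementation — and is JIT-compiled with numba.  Training is
single-threaded and fully deterministic under a fixed seed, which is
what makes walk-embedding pipelines reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_sgns"]


def _window_pairs(
    corpus: list[np.ndarray], window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """All (center, context) pairs within the full window, both
    directions, with the |offset| and a global center-occurrence id for
    later dynamic-window subsampling."""
    centers, contexts, offsets, occs = [], [], [], []
    pos = 0
    for walk in corpus:
        n = len(walk)
        gp = np.arange(pos, pos + n, dtype=np.int64)
        for off in range(1, min(window, n - 1) + 1):
            a, b = walk[:-off], walk[off:]
            full = np.full(n - off, off, dtype=np.int64)
            centers.append(a)
            contexts.append(b)
            offsets.append(full)
            occs.append(gp[:-off])
            centers.append(b)
            contexts.append(a)
            offsets.append(full)
            occs.append(gp[off:])
        pos += n
    if not centers:
        return (
            np.empty(0, np.int64), np.empty(0, np.int64),
            np.empty(0, np.int64), np.empty(0, np.int64), pos,
        )
    return (
        np.concatenate(centers),
        np.concatenate(contexts),
        np.concatenate(offsets),
        np.concatenate(occs),
        pos,
    )


@njit(cache=False, fastmath=True)
def _sgd_epoch(w_in, w_out, centers, contexts, negs, alpha, min_alpha, done, total):
    """One sequential SGD pass over the epoch's pairs (word2vec
    semantics: every update sees the weights left by the previous
    one)."""
    n = centers.shape[0]
    k = negs.shape[1]
    d = w_in.shape[1]
    grad = np.empty(d, dtype=w_in.dtype)
    for i in range(n):
        lr = alpha * (1.0 - (done + i) / total)
        if lr < min_alpha:
            lr = min_alpha
        h = w_in[centers[i]]
        for dd in range(d):
            grad[dd] = 0.0
        for j in range(k + 1):
            if j == 0:
                t = contexts[i]
                label = 1.0
            else:
                t = negs[i, j - 1]
                label = 0.0
            v = w_out[t]
            s = 0.0
            for dd in range(d):
                s += h[dd] * v[dd]
            if s > 8.0:
                sg = 1.0
            elif s < -8.0:
                sg = 0.0
            else:
                sg = 1.0 / (1.0 + np.exp(-s))
            g = (label - sg) * lr
            for dd in range(d):
                grad[dd] += g * v[dd]
                v[dd] += g * h[dd]
        for dd in range(d):
            h[dd] += grad[dd]


def train_sgns(
    corpus: list[np.ndarray],
    vocab_size: int,
    dimensions: int,
    window: int,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    seed: int = 0,
) -> np.ndarray:
    """Train SGNS on integer-encoded walks; returns the input
    (center) embedding matrix of shape (vocab_size, dimensions)."""
    rng = np.random.default_rng(seed)
    c_all, o_all, off_all, occ_all, n_occ = _window_pairs(corpus, window)
    if len(c_all) == 0:
        raise ValueError("corpus contains no context pairs (all walks length 1)")

    tok = np.concatenate(corpus)
    counts = np.bincount(tok, minlength=vocab_size).astype(np.float64)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    w_in = ((rng.random((vocab_size, dimensions)) - 0.5) / dimensions).astype(
        np.float32
    )
    w_out = np.zeros((vocab_size, dimensions), dtype=np.float32)

    # pre-draw the dynamic windows so the linear LR schedule can span
    # the exact number of pairs that will be trained
    epoch_indices = []
    for _ in range(epochs):
        half = rng.integers(1, window + 1, size=n_occ)
        keep = np.flatnonzero(off_all <= half[occ_all])
        rng.shuffle(keep)
        epoch_indices.append(keep)
    total = float(sum(len(k) for k in epoch_indices))

    done = 0
    for keep in epoch_indices:
        centers = np.ascontiguousarray(c_all[keep])
        contexts = np.ascontiguousarray(o_all[keep])
        negs = np.searchsorted(
            noise_cdf, rng.random((len(keep), negative))
        ).astype(np.int64)
        _sgd_epoch(
            w_in, w_out, centers, contexts, negs,
            np.float64(alpha), np.float64(min_alpha), float(done), total,
        )
        done += len(keep)
    return w_in.astype(np.float64)
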
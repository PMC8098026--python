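"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive each quantity from first principles (string
rewriting, double loops, exhaustive enumeration) and share no code with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


# ------------------------------------------------------------- FCS reference
def oracle_pair_counts(seqs: list[list[str]]) -> dict:
    """Count adjacent pairs; occurrences of the same pair must not overlap,
    chosen greedily from the left (interval scheduling on start indices)."""
    counts: dict = defaultdict(int)
    for s in seqs:
        starts = defaultdict(list)
        for i in range(len(s) - 1):
            starts[(s[i], s[i + 1])].append(i)
        for pair, idxs in starts.items():
            last = -2
            for i in idxs:
                if i >= last + 2:
                    counts[pair] += 1
                    last = i
    return dict(counts)


def oracle_rewrite(seq: list[str], pair: tuple[str, str]) -> list[str]:
    out = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and (seq[i], seq[i + 1]) == pair:
            out.append(seq[i] + seq[i + 1])
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def oracle_mine(corpus: list[str], theta: int, max_vocab: int | None = None):
    """Reference miner: recount from scratch every round, merge the most
    frequent pair (ties: smallest concatenated string, then smallest pair),
    stop below theta or at the vocabulary cap."""
    seqs = [list(s) for s in corpus if s]
    alphabet = sorted({c for s in seqs for c in s})
    vocab = ["<pad>", "<unk>"] + alphabet
    merges, freqs = [], []
    while max_vocab is None or len(vocab) < max_vocab:
        counts = oracle_pair_counts(seqs)
        if not counts:
            break
        ranked = sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0][0] + kv[0][1], kv[0])
        )
        pair, freq = ranked[0]
        if freq < theta:
            break
        seqs = [oracle_rewrite(s, pair) for s in seqs]
        merges.append(pair)
        freqs.append(freq)
        token = pair[0] + pair[1]
        if token not in vocab:
            vocab.append(token)
    return vocab, merges, freqs


# --------------------------------------------------- interaction / conv / nn
def oracle_dot_map(Ed: np.ndarray, Ep: np.ndarray) -> np.ndarray:
    nd, np_ = Ed.shape[0], Ep.shape[0]
    out = np.zeros((nd, np_))
    for j in range(nd):
        for i in range(np_):
            out[j, i] = float(np.dot(Ed[j], Ep[i]))
    return out


def oracle_conv_valid(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Direct-summation 2-D convolution (cross-correlation), one input
    channel, stride 1, valid padding."""
    H, W = x.shape
    Cout, _, kh, kw = w.shape
    out = np.zeros((Cout, H - kh + 1, W - kw + 1))
    for c in range(Cout):
        for i in range(H - kh + 1):
            for j in range(W - kw + 1):
                acc = b[c]
                for a in range(kh):
                    for bb in range(kw):
                        acc += x[i + a, j + bb] * w[c, 0, a, bb]
                out[c, i, j] = acc
    return out


# ------------------------------------------------------------------ metrics
def oracle_roc_auc(scores, labels) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_f1(scores, labels, threshold) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
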
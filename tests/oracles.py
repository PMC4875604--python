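"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit python loops, O(n^2) pair
counting, direct sums of kernels) kept free of any code from the package's
own scanning/ROC/KDE paths.
"""

from __future__ import annotations

import numpy as np

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def window_score(weights, window: str) -> float:
    """Position-by-position sum; N contributes 0."""
    total = 0.0
    for i, b in enumerate(window):
        if b != "N":
            total += weights[BASE_INDEX[b]][i]
    return total


def scan_oracle(weights, max_score, seq: str, min_percent: float):
    """All forward windows at or above the percent threshold, skipping
    all-N windows; (position, score, percent) tuples in position order."""
    w = len(weights[0])
    out = []
    for j in range(len(seq) - w + 1):
        win = seq[j : j + w]
        if set(win) == {"N"}:
            continue
        s = window_score(weights, win)
        pct = 100.0 * s / max_score
        if pct >= min_percent:
            out.append((j, s, pct))
    return out


def best_hit_oracle(weights, seq: str):
    """Exhaustive two-strand enumeration; ties prefer + strand then the
    smaller forward-frame position.  Returns (position, strand, score) or
    None."""
    w = len(weights[0])
    candidates = []
    if len(seq) < w:
        return None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for j in range(len(s) - w + 1):
            win = s[j : j + w]
            if set(win) == {"N"}:
                continue
            pos = j if strand == "+" else len(seq) - w - j
            candidates.append((-window_score(weights, win), strand != "+", pos, strand))
    if not candidates:
        return None
    neg_score, _, pos, strand = min(candidates)
    return (pos, strand, -neg_score)


def auc_pair_counting(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs where the
    positive wins, ties counting one half."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def kde_density_oracle(points, h, x) -> float:
    """Direct sum of Gaussian kernels at one query point."""
    z = (x - np.asarray(points)) / h
    return float(np.mean(np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)) / h)


def random_pfm(rng: np.random.Generator, width: int):
    """A random valid probability matrix (4 x width, columns sum to 1)."""
    grid = rng.dirichlet(np.ones(4), size=width).T
    return grid


def random_dna(rng: np.random.Generator, length: int, n_fraction: float = 0.0) -> str:
    bases = "ACGT"
    seq = [bases[int(rng.integers(0, 4))] for _ in range(length)]
    if n_fraction:
        for i in range(length):
            if rng.random() < n_fraction:
                seq[i] = "N"
    return "".join(seq)
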
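"""Transcription-factor binding models and additive match scoring.

A TF binding model is a position frequency matrix (PFM): one column of base
probabilities per motif position, each column summing to 1.  For scanning, the
PFM is turned into a non-negative scoring matrix by multiplying every field by
a scaling factor (default 100), so that a window's match score is the sum of
the weights picked out by its bases and the theoretical maximum score is the
sum of the column maxima.  A hit is reported when the match score reaches a
given percentage of that maximum (default 20 %).  Scanning covers both strands
by also scanning the reverse complement and mapping hits back onto the forward
coordinate frame.

Scores are additive scaled frequencies, not background-corrected log-odds;
a log-odds mode is deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: index used for the ambiguous base N in encoded sequences
N_INDEX = 4
_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: recognised binding-model provenance labels
SOURCES = ("JASPAR", "HT-SELEX", "PBM", "SYNTHETIC")


class MotifError(ValueError):
    """Raised on invalid matrices, sequences or scan preconditions."""


def _as_matrix(probs) -> np.ndarray:
    m = np.asarray(probs, dtype=float)
    if m.ndim != 2 or m.shape[0] != 4:
        raise MotifError(f"expected a 4xW matrix in A,C,G,T row order, got shape {m.shape}")
    if m.shape[1] < 1:
        raise MotifError("matrix must have at least one column")
    return m


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base probabilities for one TF binding model.

    Rows are in A, C, G, T order; every column must sum to 1 (within 1e-6)
    and all entries must be non-negative.
    """

    tf_name: str
    probs: np.ndarray
    source: str = "SYNTHETIC"
    matrix_id: str = ""

    def __post_init__(self):
        m = _as_matrix(self.probs)
        m.setflags(write=False)
        object.__setattr__(self, "probs", m)
        if not self.matrix_id:
            object.__setattr__(self, "matrix_id", self.tf_name)
        if np.any(m < 0):
            raise MotifError(f"{self.tf_name}: negative probability entries")
        sums = m.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if bad.size:
            raise MotifError(
                f"{self.tf_name}: column {bad[0]} sums to {sums[bad[0]]:.6g}, expected 1"
            )

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))


@dataclass(frozen=True)
class ScoringMatrix:
    """Scaled matrix for additive match scoring.

    ``max_score`` is the theoretical maximum match score, obtained by summing
    the strongest weight of every column.
    """

    tf_name: str
    weights: np.ndarray
    matrix_id: str = ""

    def __post_init__(self):
        w = _as_matrix(self.weights)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        if not self.matrix_id:
            object.__setattr__(self, "matrix_id", self.tf_name)
        if np.any(w < 0):
            raise MotifError(f"{self.tf_name}: negative weights")
        if self.max_score <= 0:
            raise MotifError(f"{self.tf_name}: theoretical maximum score must be positive")

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        """Sum of per-column maxima — the best achievable match score."""
        return float(self.weights.max(axis=0).sum())


def to_scoring_matrix(pfm: PositionFrequencyMatrix, scale: float = 100.0) -> ScoringMatrix:
    """Scale a PFM into a scoring matrix (every field multiplied by ``scale``)."""
    if scale <= 0:
        raise MotifError(f"scale must be positive, got {scale}")
    return ScoringMatrix(
        tf_name=pfm.tf_name, weights=pfm.probs * scale, matrix_id=pfm.matrix_id
    )


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet A,C,G,T,N (uppercase)."""

    id: str
    seq: str

    def __post_init__(self):
        s = self.seq.upper()
        object.__setattr__(self, "seq", s)
        bad = set(s) - _ALPHABET
        if bad:
            raise MotifError(f"{self.id}: invalid characters {sorted(bad)} (alphabet ACGTN)")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifHit:
    """A scored window: 0-based start on the forward coordinate frame."""

    position: int
    strand: str
    score: float
    percent_score: float


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement (N maps to N)."""
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise MotifError(f"invalid characters {sorted(bad)} in sequence")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN to integer codes 0..4 (N = 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, N_INDEX, dtype=np.intp)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _padded_weights(m: ScoringMatrix) -> np.ndarray:
    # extra all-zero row so N contributes 0 at any position
    return np.vstack([m.weights, np.zeros((1, m.width))])


def score_window(m: ScoringMatrix, window: str) -> float:
    """Additive match score of a single window of length ``m.width``.

    N bases contribute 0 (no reward, no penalty).
    """
    if len(window) != m.width:
        raise MotifError(f"window length {len(window)} != matrix width {m.width}")
    codes = encode(window.upper())
    return float(_padded_weights(m)[codes, np.arange(m.width)].sum())


def _window_scores(m: ScoringMatrix, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window, plus a mask of windows that are entirely N."""
    codes = encode(seq)
    w = m.width
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = _padded_weights(m)[wins, np.arange(w)].sum(axis=1)
    all_n = (wins == N_INDEX).all(axis=1)
    return scores, all_n


def scan_sequence(
    m: ScoringMatrix, s: SequenceRecord | str, min_percent: float = 20.0
) -> list[MotifHit]:
    """Forward-strand scan: one hit per window whose percent score reaches
    ``min_percent``, ordered by position.  All-N windows are skipped.

    A sequence shorter than the matrix yields no hits (with a warning), since
    length-matched negatives may be shorter than wide matrices.
    """
    seq = s.seq if isinstance(s, SequenceRecord) else s.upper()
    name = s.id if isinstance(s, SequenceRecord) else "<str>"
    if len(seq) < m.width:
        logger.warning(
            "sequence %s (length %d) shorter than matrix %s (width %d); no hits",
            name, len(seq), m.matrix_id, m.width,
        )
        return []
    scores, all_n = _window_scores(m, seq)
    percent = 100.0 * scores / m.max_score
    keep = np.flatnonzero((percent >= min_percent) & ~all_n)
    return [
        MotifHit(position=int(i), strand="+", score=float(scores[i]),
                 percent_score=float(percent[i]))
        for i in keep
    ]


def best_hit(m: ScoringMatrix, s: SequenceRecord | str) -> MotifHit | None:
    """Best-scoring window over forward and reverse strands.

    The reverse strand is scanned as the forward scan of the reverse
    complement; its hit positions are mapped back onto the forward frame.
    Ties prefer the + strand, then the smaller forward position.  Returns
    ``None`` when no scorable window exists (short sequence or all-N).
    """
    seq = s.seq if isinstance(s, SequenceRecord) else s.upper()
    name = s.id if isinstance(s, SequenceRecord) else "<str>"
    if len(seq) < m.width:
        logger.warning(
            "sequence %s (length %d) shorter than matrix %s (width %d); no best hit",
            name, len(seq), m.matrix_id, m.width,
        )
        return None
    fwd, fwd_all_n = _window_scores(m, seq)
    rev, rev_all_n = _window_scores(m, reverse_complement(seq))
    n_win = len(fwd)
    # forward-frame start of the reverse-strand window scanned at offset j
    rev_positions = len(seq) - m.width - np.arange(n_win)

    best = None  # (score, strand_rank, position, strand)
    for scores, all_n, positions, strand, rank in (
        (fwd, fwd_all_n, np.arange(n_win), "+", 0),
        (rev, rev_all_n, rev_positions, "-", 1),
    ):
        valid = ~all_n
        if not valid.any():
            continue
        idx = np.flatnonzero(valid)
        # among equal scores keep the smallest forward position
        order = np.lexsort((positions[idx], -scores[idx]))
        j = idx[order[0]]
        cand = (-scores[j], rank, int(positions[j]), strand)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    neg_score, _, position, strand = best
    score = -neg_score
    return MotifHit(position=position, strand=strand, score=float(score),
                    percent_score=float(100.0 * score / m.max_score))


def best_score(m: ScoringMatrix, s: SequenceRecord | str) -> float | None:
    """Convenience: the dual-strand maximum match score, or None."""
    hit = best_hit(m, s)
    return None if hit is None else hit.score
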
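"""Positive/negative test-set construction and ROC/AUC evaluation.

The benchmarking protocol: ChIP-seq confirmed binding events (peaks, each
carrying an integer binding score) are the positive cases; length-matched
exonic sequences — DNA expected to be depleted of binding sites, with each
transcript's first exon excluded — are the negatives.  Every matrix scores
every sequence by its dual-strand best hit, and discrimination is measured by
the area under the ROC curve, which equals the probability that a random
positive outscores a random negative (ties counting one half).

A "high-confidence" positive set keeps only peaks reaching at least 80 % of
the TF's maximum binding score, and drops TFs with fewer than 100 such peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .motifs import ScoringMatrix, SequenceRecord, best_hit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakRecord:
    """A binding event: genomic interval (0-based half-open) plus strength."""

    chrom: str
    start: int
    end: int
    tf_name: str
    binding_score: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")
        if self.binding_score < 0:
            raise ValueError(f"negative binding score {self.binding_score}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LabeledScore:
    score: float
    label: str  # "positive" | "negative"
    pair_id: str


@dataclass(frozen=True)
class RocCurve:
    """Step ROC curve: points from (0,0) to (1,1), AUC by trapezoid
    (equal to the Mann–Whitney statistic under the half-tie convention)."""

    points: tuple  # ordered (fpr, tpr) pairs
    auc: float


@dataclass(frozen=True)
class BenchmarkSummary:
    per_matrix: pd.DataFrame       # tf_name, source, auc
    per_tf: pd.DataFrame           # source, tf_name, auc (matrices averaged per TF)
    per_source: pd.DataFrame       # source, n_matrices, n_tfs, mean_auc, frac_auc_ge_0.7


def high_confidence_filter(
    peaks: Sequence[PeakRecord],
    score_fraction: float = 0.8,
    min_instances: int = 100,
    max_scores: Mapping[str, float] | None = None,
) -> list[PeakRecord]:
    """Keep peaks reaching ``score_fraction`` of the TF's maximum binding
    score; drop TFs retaining fewer than ``min_instances`` peaks.

    The per-TF maximum defaults to the maximum observed in ``peaks`` (a
    reproducible surrogate for an externally published ceiling); pass
    ``max_scores`` to override per TF.
    """
    if not peaks:
        raise ValueError("empty peak list")
    if not 0 < score_fraction <= 1:
        raise ValueError(f"score_fraction must be in (0, 1], got {score_fraction}")
    observed_max: dict[str, float] = {}
    for p in peaks:
        observed_max[p.tf_name] = max(observed_max.get(p.tf_name, 0), p.binding_score)
    if max_scores:
        observed_max.update(max_scores)
    surviving: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        if p.binding_score >= score_fraction * observed_max[p.tf_name]:
            surviving.setdefault(p.tf_name, []).append(p)
    out: list[PeakRecord] = []
    for tf, kept in surviving.items():
        if len(kept) < min_instances:
            logger.info("dropping TF %s: %d high-confidence peaks < %d", tf, len(kept), min_instances)
            continue
        out.extend(kept)
    return out


def exclude_first_exons(
    transcripts: Mapping[str, Sequence[SequenceRecord]],
) -> list[SequenceRecord]:
    """Exon pool with each transcript's first exon omitted (first exons can
    harbour functional binding sites downstream of the TSS)."""
    pool: list[SequenceRecord] = []
    for tx, exons in transcripts.items():
        if len(exons) <= 1:
            logger.info("transcript %s has a single exon; contributes nothing", tx)
            continue
        pool.extend(exons[1:])
    return pool


def sample_matched_negatives(
    positives: Sequence[SequenceRecord],
    exon_pool: Sequence[SequenceRecord],
    seed: int,
) -> list[SequenceRecord]:
    """One length-matched negative per positive, drawn uniformly among pool
    sequences of equal or greater length and randomly trimmed to match.

    Sampling is without replacement while eligible pool members last, then
    with replacement (logged).  Fully reproducible from ``seed``.
    """
    if not exon_pool:
        raise ValueError("empty exon pool")
    rng = np.random.default_rng(seed)
    pool_lengths = np.array([len(e) for e in exon_pool])
    used: set[int] = set()
    negatives: list[SequenceRecord] = []
    for i, pos in enumerate(positives):
        want = len(pos)
        eligible = np.flatnonzero(pool_lengths >= want)
        if eligible.size == 0:
            raise ValueError(f"no pool sequence of length >= {want} for positive {pos.id}")
        unused = [j for j in eligible if j not in used]
        if unused:
            j = int(rng.choice(unused))
            used.add(j)
        else:
            j = int(rng.choice(eligible))
            logger.info("eligible pool exhausted at positive %d; sampling with replacement", i)
        exon = exon_pool[j]
        offset = int(rng.integers(0, len(exon) - want + 1))
        negatives.append(
            SequenceRecord(id=f"neg_{i}|{exon.id}:{offset}-{offset + want}",
                           seq=exon.seq[offset : offset + want])
        )
    return negatives


def score_test_set(
    m: ScoringMatrix,
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
) -> list[LabeledScore]:
    """Dual-strand best-hit score for every positive and its index-paired
    negative.  Sequences that cannot be scored (shorter than the matrix,
    all-N) are skipped pairwise and logged, so labels stay balanced."""
    if len(positives) != len(negatives):
        raise ValueError(f"{len(positives)} positives vs {len(negatives)} negatives; must pair by index")
    out: list[LabeledScore] = []
    n_failed = 0
    for i, (pos, neg) in enumerate(zip(positives, negatives)):
        hp, hn = best_hit(m, pos), best_hit(m, neg)
        if hp is None or hn is None:
            n_failed += 1
            continue
        pair = f"pair_{i}"
        out.append(LabeledScore(score=hp.score, label="positive", pair_id=pair))
        out.append(LabeledScore(score=hn.score, label="negative", pair_id=pair))
    if n_failed:
        logger.warning("matrix %s: %d pairs skipped (unscorable member)", m.matrix_id, n_failed)
    return out


def roc_auc(scores: Sequence[LabeledScore]) -> RocCurve:
    """ROC curve over all distinct score thresholds and its AUC.

    The AUC equals the probability that a uniformly drawn positive outscores
    a uniformly drawn negative, with ties counted half (Mann–Whitney
    identity); both classes must be present.
    """
    y = np.array([1 if s.label == "positive" else 0 for s in scores])
    x = np.array([s.score for s in scores], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs at least one positive and one negative score")
    fpr, tpr, _ = roc_curve(y, x, drop_intermediate=False)
    auc = float(roc_auc_score(y, x))
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return RocCurve(points=tuple(pts), auc=auc)


def summarize_sources(aucs: pd.DataFrame, auc_threshold: float = 0.7) -> BenchmarkSummary:
    """Per-source mean AUC and fraction of matrices reaching ``auc_threshold``,
    plus a per-TF table where multiple matrices for one TF are averaged.

    ``aucs`` needs columns ``tf_name``, ``source``, ``auc`` (one row per
    matrix)."""
    required = {"tf_name", "source", "auc"}
    if not required.issubset(aucs.columns):
        raise ValueError(f"AUC table needs columns {sorted(required)}")
    per_matrix = aucs.reset_index(drop=True).copy()
    per_tf = (
        per_matrix.groupby(["source", "tf_name"], as_index=False)["auc"].mean()
    )
    per_source = (
        per_matrix.groupby("source")
        .agg(
            n_matrices=("auc", "size"),
            n_tfs=("tf_name", "nunique"),
            mean_auc=("auc", "mean"),
        )
        .reset_index()
    )
    frac = (
        per_matrix.assign(hit=per_matrix["auc"] >= auc_threshold)
        .groupby("source")["hit"]
        .mean()
        .rename("frac_auc_ge_threshold")
        .reset_index()
    )
    per_source = per_source.merge(frac, on="source")
    return BenchmarkSummary(per_matrix=per_matrix, per_tf=per_tf, per_source=per_source)


def benchmark_matrices(
    matrices: Sequence,  # PositionFrequencyMatrix
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    scale: float = 100.0,
) -> pd.DataFrame:
    """Score a positive/negative sequence pair set with each PFM and return
    the per-matrix AUC table (tf_name, source, matrix_id, auc, n_pairs)."""
    from .motifs import to_scoring_matrix

    rows = []
    for pfm in matrices:
        m = to_scoring_matrix(pfm, scale=scale)
        labeled = score_test_set(m, positives, negatives)
        curve = roc_auc(labeled)
        rows.append(
            dict(tf_name=pfm.tf_name, source=pfm.source, matrix_id=pfm.matrix_id,
                 auc=curve.auc, n_pairs=len(labeled) // 2)
        )
    return pd.DataFrame(rows, columns=["tf_name", "source", "matrix_id", "auc", "n_pairs"])
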
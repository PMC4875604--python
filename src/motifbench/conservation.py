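"""Per-base conservation summaries over binding-site and control intervals.

Binding-site intervals are compared with length-matched random intervals by
two per-interval statistics — the maximum and the mean per-base score — whose
group averages (and dispersions) are then contrasted.  Tracks are per-base
score arrays (step 1) such as phyloP or phastCons; bases without data are
treated as missing, never as 0, and excluded from both statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalSummary:
    chrom: str
    start: int
    end: int
    max: float | None
    mean: float | None
    covered_bases: int


class ScoreTrack:
    """Per-chromosome arrays of per-base scores with a start offset.

    Values are stored densely from each chromosome's first covered base;
    gaps are NaN ("missing"), and queries outside the covered range are
    missing too.
    """

    def __init__(self, data: Mapping[str, tuple[int, np.ndarray]]):
        self._data = {
            chrom: (int(start), np.asarray(vals, dtype=float))
            for chrom, (start, vals) in data.items()
        }

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def coverage(self, chrom: str) -> tuple[int, int]:
        start, vals = self._data[chrom]
        return start, start + len(vals)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); NaN where no data exists."""
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        out = np.full(end - start, np.nan)
        if chrom not in self._data:
            return out
        t_start, vals = self._data[chrom]
        lo = max(start, t_start)
        hi = min(end, t_start + len(vals))
        if hi > lo:
            out[lo - start : hi - start] = vals[lo - t_start : hi - t_start]
        return out


def interval_summary(track: ScoreTrack, chrom: str, start: int, end: int) -> IntervalSummary:
    """Max and mean score over the covered bases of a half-open interval;
    a fully uncovered interval yields missing statistics."""
    vals = track.values(chrom, start, end)
    covered = int(np.sum(~np.isnan(vals)))
    if covered == 0:
        return IntervalSummary(chrom, start, end, None, None, 0)
    return IntervalSummary(
        chrom, start, end,
        max=float(np.nanmax(vals)), mean=float(np.nanmean(vals)),
        covered_bases=covered,
    )


def random_intervals(
    lengths: Sequence[int],
    chrom_sizes: Mapping[str, int],
    seed: int,
) -> list[tuple[str, int, int]]:
    """Length-matched random genomic intervals, uniform over all valid start
    positions across the allowed chromosomes (the control design restricts
    these to a small set, e.g. chromosomes 1 and 2)."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms])
    out = []
    for L in lengths:
        n_starts = sizes - L + 1
        n_starts = np.where(n_starts > 0, n_starts, 0)
        total = int(n_starts.sum())
        if total == 0:
            raise ValueError(f"length {L} exceeds every allowed chromosome")
        # uniform over the union of valid starts
        k = int(rng.integers(0, total))
        ci = int(np.searchsorted(np.cumsum(n_starts), k, side="right"))
        start = k - int(np.concatenate([[0], np.cumsum(n_starts)])[ci])
        out.append((chroms[ci], start, start + L))
    return out


@dataclass(frozen=True)
class GroupConservation:
    n: int
    mean_max: float
    sd_max: float
    mean_mean: float
    sd_mean: float


@dataclass(frozen=True)
class ConservationComparison:
    sites: GroupConservation
    controls: GroupConservation
    diff_mean_max: float       # sites - controls, average of per-interval maxima
    diff_mean_mean: float
    se_diff_max: float         # standard error of the difference of means
    se_diff_mean: float


def _group_stats(summaries: Sequence[IntervalSummary]) -> GroupConservation:
    maxima = np.array([s.max for s in summaries if s.covered_bases > 0], dtype=float)
    means = np.array([s.mean for s in summaries if s.covered_bases > 0], dtype=float)
    if maxima.size == 0:
        raise ValueError("group has no covered intervals")
    return GroupConservation(
        n=int(maxima.size),
        mean_max=float(maxima.mean()),
        sd_max=float(maxima.std(ddof=1)) if maxima.size > 1 else 0.0,
        mean_mean=float(means.mean()),
        sd_mean=float(means.std(ddof=1)) if means.size > 1 else 0.0,
    )


def group_comparison(
    site_summaries: Sequence[IntervalSummary],
    control_summaries: Sequence[IntervalSummary],
) -> ConservationComparison:
    """Average-of-max and average-of-mean per group, their difference
    (sites minus controls), and the standard error of that difference."""
    s = _group_stats(site_summaries)
    c = _group_stats(control_summaries)

    def se(sd_a, n_a, sd_b, n_b):
        return float(np.sqrt(sd_a**2 / n_a + sd_b**2 / n_b))

    return ConservationComparison(
        sites=s, controls=c,
        diff_mean_max=s.mean_max - c.mean_max,
        diff_mean_mean=s.mean_mean - c.mean_mean,
        se_diff_max=se(s.sd_max, s.n, c.sd_max, c.n),
        se_diff_mean=se(s.sd_mean, s.n, c.sd_mean, c.n),
    )


def summarize_intervals(
    track: ScoreTrack, intervals: Sequence[tuple[str, int, int]]
) -> list[IntervalSummary]:
    return [interval_summary(track, c, s, e) for c, s, e in intervals]
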
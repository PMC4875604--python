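"""Synthetic regulatory-genomics data with controllable signal strength.

Everything the other modules consume can be generated here offline: a
position frequency matrix of tunable information content, "peak" sequences
with one embedded motif instance each and ENCODE-like integer binding
scores, motif-depleted background sequences standing in for the exonic
negative pool, single-nucleotide variants that either destroy the embedded
motif or fall in its flanks, and per-base conservation tracks elevated over
the embedded motifs.

The background model is i.i.d. bases with configurable GC content (no Markov
structure) — sufficient for the contracts exercised here, but deliberately
simpler than real genomic sequence.  All randomness flows through a single
integer-seeded NumPy generator, so every output is reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .benchmark import PeakRecord
from .conservation import ScoreTrack
from .motifs import (
    BASES,
    PositionFrequencyMatrix,
    SequenceRecord,
    reverse_complement,
    to_scoring_matrix,
)
from .variants import VariantContext

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: per-column maximum probability at the two ends of the information scale
UNIFORM_MAX = 0.25
FULL_INFO_MAX = 0.97


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic data.

    ``information_level`` maps linearly to the per-column maximum
    probability: 0 gives uniform columns (0.25 each), 1 gives 0.97 with the
    remainder split over the other bases (never below ``min_prob``, so score
    quotients cannot hit 0/0).  Binding scores are integers in [0, 1000]
    rising monotonically with the embedded instance's percent score.
    """

    seed: int = 0
    tf_name: str = "TF1"
    motif_width: int = 10
    information_level: float = 1.0
    n_positives: int = 500
    n_negatives: int = 500
    peak_length_range: tuple[int, int] = (100, 300)
    gc_content: float = 0.41
    min_prob: float = 0.001
    binding_score_noise: float = 0.0
    n_destroying: int = 200
    n_flank: int = 200
    variant_flank: int = 20
    conservation_elevation: float = 0.5
    conservation_noise_sd: float = 0.1
    gap_length: int = 50
    chrom: str = "chrSim"
    background_chrom: str = "chrBg"

    def __post_init__(self):
        if not 0 <= self.information_level <= 1:
            raise ValueError("information_level must be in [0, 1]")
        if self.peak_length_range[0] < self.motif_width:
            raise ValueError("peak length must be at least the motif width")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    codes = rng.choice(4, size=length, p=_base_probs(gc))
    return "".join(BASES[c] for c in codes)


def make_pfm(config: GeneratorConfig, rng: np.random.Generator | None = None) -> PositionFrequencyMatrix:
    """A PFM whose per-column maximum probability follows the information
    level; the consensus base of each column is chosen at random.

    Realised column maxima are jittered within +/-0.02 of the target and the
    remaining mass is split unevenly (Dirichlet) over the other bases, as in
    real frequency matrices — so match scores are continuous rather than
    lattice-valued.  ``information_level`` 0 yields exactly uniform columns.
    """
    rng = config.rng() if rng is None else rng
    w = config.motif_width
    target = UNIFORM_MAX + config.information_level * (FULL_INFO_MAX - UNIFORM_MAX)
    probs = np.empty((4, w))
    for j in range(w):
        if config.information_level == 0:
            probs[:, j] = UNIFORM_MAX
            continue
        top = int(rng.integers(0, 4))
        p_max = float(np.clip(target + rng.uniform(-0.02, 0.02),
                              UNIFORM_MAX + 0.01, 1.0 - 3 * config.min_prob))
        # floor guaranteed exactly: min_prob plus a Dirichlet split of the rest
        spare = 1.0 - p_max - 3 * config.min_prob
        rest = config.min_prob + spare * rng.dirichlet(np.full(3, 2.0))
        col = np.empty(4)
        col[top] = p_max
        col[[i for i in range(4) if i != top]] = rest
        probs[:, j] = col
    return PositionFrequencyMatrix(
        tf_name=config.tf_name, probs=probs, source="SYNTHETIC",
        matrix_id=f"{config.tf_name}_synthetic",
    )


@dataclass(frozen=True)
class EmbeddedPeak:
    """One synthetic binding event: the sequence, its genomic record, and
    where/how the motif instance was embedded."""

    record: SequenceRecord
    peak: PeakRecord
    offset: int          # 0-based start of the embed within the sequence
    strand: str          # strand the instance was placed on
    instance: str        # the sampled instance in motif (forward) orientation


def _sample_instance(pfm: PositionFrequencyMatrix, rng: np.random.Generator) -> str:
    """Draw a motif instance from the sharpened (squared, renormalised)
    column distributions: confirmed in vivo sites are enriched for strong
    matches relative to the frequency model itself, and at full information
    (column maxima ~0.97) nearly every embedded instance is the consensus."""
    sharp = pfm.probs**2
    sharp = sharp / sharp.sum(axis=0, keepdims=True)
    return "".join(
        BASES[int(rng.choice(4, p=sharp[:, j]))] for j in range(pfm.width)
    )


def make_peak_set(
    pfm: PositionFrequencyMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[EmbeddedPeak]:
    """Peak sequences, one sampled motif instance each at a random offset on
    a random strand, with an integer binding score that rises monotonically
    with the instance's percent match score (plus optional integer noise)."""
    rng = config.rng() if rng is None else rng
    m = to_scoring_matrix(pfm)
    lo, hi = config.peak_length_range
    w = pfm.width
    out: list[EmbeddedPeak] = []
    cursor = config.gap_length
    for i in range(config.n_positives):
        length = int(rng.integers(lo, hi + 1))
        seq = list(random_background(length, config.gc_content, rng))
        instance = _sample_instance(pfm, rng)
        offset = int(rng.integers(0, length - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = instance if strand == "+" else reverse_complement(instance)
        seq[offset : offset + w] = placed
        seq = "".join(seq)
        percent = 100.0 * sum(m.weights["ACGT".index(b)][j] for j, b in enumerate(instance)) / m.max_score
        score = 10.0 * percent
        if config.binding_score_noise > 0:
            score += rng.normal(0, config.binding_score_noise)
        score = int(np.clip(round(score), 0, 1000))
        record = SequenceRecord(id=f"peak_{i:04d}", seq=seq)
        peak = PeakRecord(chrom=config.chrom, start=cursor, end=cursor + length,
                          tf_name=config.tf_name, binding_score=score)
        out.append(EmbeddedPeak(record=record, peak=peak, offset=offset,
                                strand=strand, instance=instance))
        cursor += length + config.gap_length
    return out


def make_negative_pool(
    config: GeneratorConfig,
    pfm: PositionFrequencyMatrix,
    rng: np.random.Generator | None = None,
    max_attempts: int = 1000,
    reject_percent: float = 80.0,
) -> list[SequenceRecord]:
    """Motif-depleted background sequences: rejection-sampled so no window on
    either strand reaches ``reject_percent`` of the matrix maximum.

    Lengths are drawn over the positive peak-length range, with a handful
    pinned at the maximum so every positive finds an eligible length-match.
    """
    from .motifs import best_hit

    rng = config.rng() if rng is None else rng
    m = to_scoring_matrix(pfm)
    lo, hi = config.peak_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_negatives)
    n_pinned = max(1, config.n_negatives // 20)
    lengths[:n_pinned] = hi
    out: list[SequenceRecord] = []
    for i, length in enumerate(lengths):
        for attempt in range(max_attempts):
            seq = random_background(int(length), config.gc_content, rng)
            hit = best_hit(m, seq)
            if hit is None or hit.percent_score < reject_percent:
                out.append(SequenceRecord(id=f"exon_{i:04d}", seq=seq))
                break
        else:
            raise RuntimeError(
                f"rejection cap ({max_attempts}) exceeded for negative {i}; "
                "a narrower or more informative motif rejects less background"
            )
    return out


@dataclass(frozen=True)
class VariantPlan:
    n_destroying: int
    n_flank: int
    flank: int = 20


@dataclass(frozen=True)
class SyntheticVariant:
    context: VariantContext
    truth: str            # "loss" for motif-destroying, "none" for flank
    peak_id: str


def make_variants(
    peaks: list[EmbeddedPeak],
    pfm: PositionFrequencyMatrix,
    plan: VariantPlan,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[SyntheticVariant]:
    """Single-nucleotide variants with known ground truth.

    Motif-destroying variants replace the consensus (highest-weight) base at
    the strongest column carried by the embedded instance with that column's
    lowest-weight base (truth: loss).  Flank variants sit at least one motif
    width away from the embed — so no scan window spans both — while keeping
    the embed fully inside the variant's flanked context window, so the best
    hit is provably the unchanged embed (truth: none).  The latter requires
    ``plan.flank >= 2 * width - 1``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    w = pfm.width
    # columns ordered by how much score a consensus->worst substitution costs
    col_order = np.argsort(-(pfm.probs.max(axis=0) - pfm.probs.min(axis=0)))
    out: list[SyntheticVariant] = []

    def context_for(ep: EmbeddedPeak, pos: int, alt: str) -> VariantContext:
        seq = ep.record.seq
        ref = seq[pos]
        lo = max(0, pos - plan.flank)
        hi = min(len(seq), pos + 1 + plan.flank)
        wt = seq[lo:hi]
        var = wt[: pos - lo] + alt + wt[pos - lo + 1:]
        gpos = (ep.peak.chrom, ep.peak.start + pos + 1, ref, alt)
        return VariantContext(wt_seq=wt, var_seq=var, genomic_position=gpos)

    def pick_peaks(n: int) -> list[EmbeddedPeak]:
        if not peaks:
            raise ValueError("no peaks supplied")
        idx = rng.choice(len(peaks), size=n, replace=n > len(peaks))
        return [peaks[int(i)] for i in idx]

    for ep in pick_peaks(plan.n_destroying) if plan.n_destroying else []:
        chosen = None
        for c in col_order:
            top = int(np.argmax(pfm.probs[:, c]))
            if ep.instance[c] == BASES[top]:
                chosen = int(c)
                break
        if chosen is None:  # instance carries no consensus base anywhere (very low info)
            chosen = int(col_order[0])
        worst = BASES[int(np.argmin(pfm.probs[:, chosen]))]
        if ep.strand == "+":
            pos = ep.offset + chosen
            alt = worst
        else:
            pos = ep.offset + (w - 1 - chosen)
            alt = _COMPLEMENT[worst]
        if ep.record.seq[pos] == alt:  # degenerate column: worst == carried base
            alt = _COMPLEMENT[alt] if _COMPLEMENT[alt] != ep.record.seq[pos] else "A"
        out.append(SyntheticVariant(context=context_for(ep, pos, alt),
                                    truth="loss", peak_id=ep.record.id))

    if plan.n_flank and plan.flank < 2 * w - 1:
        raise ValueError(
            f"flank variants need plan.flank >= 2*width-1 ({2 * w - 1}), got {plan.flank}"
        )
    for ep in pick_peaks(plan.n_flank) if plan.n_flank else []:
        length = len(ep.record.seq)
        o = ep.offset
        # distance to the nearest embed base in [w, flank-w+1]: no window can
        # span both, yet the whole embed stays inside the +/-flank context
        valid = [
            p
            for d in range(w, plan.flank - w + 2)
            for p in (o - d, o + w - 1 + d)
            if 0 <= p < length
        ]
        if not valid:
            raise ValueError(f"peak {ep.record.id} too short for a flank variant")
        pos = int(rng.choice(valid))
        ref = ep.record.seq[pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        out.append(SyntheticVariant(context=context_for(ep, pos, alt),
                                    truth="none", peak_id=ep.record.id))
    return out


def make_conservation_track(
    peaks: list[EmbeddedPeak],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> ScoreTrack:
    """Per-base tracks: Gaussian baseline noise everywhere, elevated by
    ``conservation_elevation`` over each embedded motif instance.  A second,
    baseline-only chromosome of comparable size hosts the random controls."""
    rng = config.rng() if rng is None else rng
    if not peaks:
        raise ValueError("no peaks supplied")
    sim_len = max(ep.peak.end for ep in peaks) + config.gap_length
    sim = rng.normal(0.0, config.conservation_noise_sd, size=sim_len)
    for ep in peaks:
        lo = ep.peak.start + ep.offset
        sim[lo : lo + len(ep.instance)] += config.conservation_elevation
    bg = rng.normal(0.0, config.conservation_noise_sd, size=sim_len)
    return ScoreTrack({config.chrom: (0, sim), config.background_chrom: (0, bg)})


def assemble_genome(
    peaks: list[EmbeddedPeak],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Concatenate the peak sequences (with background gaps) into the
    simulated chromosome the peak coordinates refer to, plus a background
    chromosome of the same length."""
    rng = config.rng() if rng is None else rng
    if not peaks:
        raise ValueError("no peaks supplied")
    total = max(ep.peak.end for ep in peaks) + config.gap_length
    chrom = list(random_background(total, config.gc_content, rng))
    for ep in peaks:
        chrom[ep.peak.start : ep.peak.end] = ep.record.seq
    sim = "".join(chrom)
    bg = random_background(total, config.gc_content, rng)
    return {config.chrom: sim, config.background_chrom: bg}


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything the pipeline consumes, generated from one config."""

    config: GeneratorConfig
    pfm: PositionFrequencyMatrix
    peaks: list[EmbeddedPeak]
    negatives: list[SequenceRecord]
    variants: list[SyntheticVariant]
    track: ScoreTrack
    genome: dict[str, str]

    @property
    def positive_records(self) -> list[SequenceRecord]:
        return [ep.record for ep in self.peaks]

    @property
    def peak_records(self) -> list[PeakRecord]:
        return [ep.peak for ep in self.peaks]


def simulate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """Generate one coherent dataset; a single seeded generator drives every
    step, so the result is a pure function of the config."""
    rng = config.rng()
    pfm = make_pfm(config, rng)
    peaks = make_peak_set(pfm, config, rng)
    negatives = make_negative_pool(config, pfm, rng)
    plan = VariantPlan(n_destroying=config.n_destroying, n_flank=config.n_flank,
                       flank=config.variant_flank)
    variants = make_variants(peaks, pfm, plan, rng)
    track = make_conservation_track(peaks, config, rng)
    genome = assemble_genome(peaks, config, rng)
    return SimulatedDataset(config=config, pfm=pfm, peaks=peaks, negatives=negatives,
                            variants=variants, track=track, genome=genome)
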
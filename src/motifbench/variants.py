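"""Variant effect on TF binding: score quotients, kernel-density naive Bayes,
and reliability-calibrated verdicts.

The feature is the quotient q of the maximum (dual-strand best-hit) match
scores of the wild-type and the variant sequence window: q > 1 points towards
loss of a binding site, q < 1 towards gain.  For each matrix, a two-class
Bayes classifier is trained on quotients of positive (confirmed binding)
versus negative (binding-depleted) sequence scores: the "binding lost" class
on positive/negative quotients, the "binding gained" class on their
reciprocals.  Because quotients are ratio-scaled and far from normal, each
class-conditional density is a Gaussian kernel density estimate on log(q)
with the Silverman/nrd0 rule-of-thumb bandwidth, so the two classes are
mirror images in log-space.

Posterior probabilities alone are often far from 1 for weak matrices, so each
prediction also carries an empirical positive/negative predictive value
(PPV/NPV) read from a calibration table binned on held-out data; only
matrices whose predictive value reaches a threshold (default 70 %) contribute
to the per-TF aggregate call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .benchmark import PeakRecord
from .motifs import (
    MotifError,
    PositionFrequencyMatrix,
    ScoringMatrix,
    best_hit,
    to_scoring_matrix,
)

logger = logging.getLogger(__name__)

BUNDLE_VERSION = 1

LOSS = "loss"
GAIN = "gain"


# ---------------------------------------------------------------------------
# variant contexts and score quotients


@dataclass(frozen=True)
class VariantContext:
    """Wild-type and variant sequence windows for one DNA alteration.

    For positional input the windows span a flank (default 20 bp) on each
    side of the variant.  ``genomic_position`` is ``(chrom, pos_1based, ref,
    alt)`` when known, enabling the known-binding-site lookup.
    """

    wt_seq: str
    var_seq: str
    genomic_position: tuple[str, int, str, str] | None = None

    def __post_init__(self):
        if self.wt_seq.upper() == self.var_seq.upper():
            raise ValueError("wild-type and variant sequences are identical (not a variant)")
        object.__setattr__(self, "wt_seq", self.wt_seq.upper())
        object.__setattr__(self, "var_seq", self.var_seq.upper())

    def swapped(self) -> "VariantContext":
        pos = None
        if self.genomic_position:
            chrom, p, ref, alt = self.genomic_position
            pos = (chrom, p, alt, ref)
        return VariantContext(self.var_seq, self.wt_seq, pos)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """0-based half-open fetch from a dict of strings or a pyfaidx Fasta."""
    contig = genome[chrom]
    if isinstance(contig, str):
        if end > len(contig):
            raise ValueError(f"interval {chrom}:{start}-{end} beyond contig end {len(contig)}")
        return contig[start:end].upper()
    piece = contig[start:end]
    seq = piece.seq if hasattr(piece, "seq") else str(piece)
    if len(seq) != end - start:
        raise ValueError(f"interval {chrom}:{start}-{end} beyond contig end")
    return seq.upper()


def build_context(
    genome, chrom: str, pos: int, ref: str, alt: str, flank: int = 20
) -> VariantContext:
    """Build wt/variant windows of ``flank`` bp either side of a variant.

    ``pos`` is 1-based; ``ref`` must match the genome there.  The flank is
    clamped (with a warning) at the contig start.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"{chrom}:{pos} ref == alt ({ref}); not a variant")
    start = pos - 1 - flank
    if start < 0:
        logger.warning("%s:%d flank %d clipped at contig start", chrom, pos, flank)
        start = 0
    end = pos - 1 + len(ref) + flank
    window = _fetch(genome, chrom, start, end)
    offset = pos - 1 - start
    found = window[offset : offset + len(ref)]
    if found != ref:
        raise ValueError(f"reference mismatch at {chrom}:{pos}: expected {ref}, found {found}")
    var = window[:offset] + alt + window[offset + len(ref):]
    return VariantContext(wt_seq=window, var_seq=var, genomic_position=(chrom, pos, ref, alt))


@dataclass(frozen=True)
class ScoreQuotient:
    """wt best score divided by variant best score (both floored)."""

    matrix_id: str
    q: float

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError(f"quotient must be positive, got {self.q}")


def score_quotient(
    m: ScoringMatrix, ctx: VariantContext, floor: float | None = None
) -> ScoreQuotient:
    """Quotient of the dual-strand maximum match scores of wt and variant.

    Scores below ``floor`` (default 1 % of the matrix maximum) are raised to
    it, so zero-probability columns can never produce a 0/0 quotient.  A
    window shorter than the matrix scores at the floor; both windows shorter
    is an error.
    """
    if floor is None:
        floor = 0.01 * m.max_score
    if len(ctx.wt_seq) < m.width and len(ctx.var_seq) < m.width:
        raise MotifError(
            f"both windows shorter than matrix {m.matrix_id} (width {m.width})"
        )
    wt = best_hit(m, ctx.wt_seq)
    var = best_hit(m, ctx.var_seq)
    wt_s = wt.score if wt is not None else 0.0
    var_s = var.score if var is not None else 0.0
    return ScoreQuotient(matrix_id=m.matrix_id, q=max(wt_s, floor) / max(var_s, floor))


def score_change_direction(
    wt_score: float, var_score: float, min_relative_change: float = 0.0
) -> str | None:
    """Direction implied by raw best-score change: loss when the variant
    score drops, gain when it rises; changes smaller than
    ``min_relative_change`` (relative to the wt score) are called None."""
    if wt_score == var_score:
        return None
    base = wt_score if wt_score > 0 else 1.0
    if abs(var_score - wt_score) / base <= min_relative_change:
        return None
    return LOSS if var_score < wt_score else GAIN


# ---------------------------------------------------------------------------
# training pairs and the kernel-density classifier


def make_training_pairs(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    cap: int = 1_000_000,
    seed: int = 0,
    floor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quotients of positive-versus-negative score pairs for both classes.

    The binding-lost class gets pos/neg quotients; the binding-gained class
    their elementwise reciprocals.  When the full cross-product exceeds
    ``cap``, a uniform seeded sample of ``cap`` pairs per class is drawn.
    Scores are floored before division.
    """
    pos = np.maximum(np.asarray(pos_scores, dtype=float), floor)
    neg = np.maximum(np.asarray(neg_scores, dtype=float), floor)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    total = pos.size * neg.size
    if total <= cap:
        lost = np.outer(pos, neg ** -1.0).ravel()
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, pos.size, size=cap)
        j = rng.integers(0, neg.size, size=cap)
        lost = pos[i] / neg[j]
        logger.info("pair cap engaged: sampled %d of %d possible pairs", cap, total)
    return lost, 1.0 / lost


def nrd0_bandwidth(x: np.ndarray, floor: float = 1e-3) -> float:
    """Silverman's rule-of-thumb bandwidth (R's bw.nrd0):
    0.9 * min(sd, IQR/1.34) * n^(-1/5), floored for degenerate samples."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    if h < floor:
        logger.warning("degenerate training sample: bandwidth floored at %g", floor)
        h = floor
    return h


@dataclass(frozen=True)
class KernelDensityClassModel:
    """Gaussian KDE over log-quotients for one class."""

    class_label: str  # "binding_lost" | "binding_gained"
    log_points: np.ndarray
    bandwidth: float
    prior: float = 0.5

    def __post_init__(self):
        pts = np.asarray(self.log_points, dtype=float)
        pts.setflags(write=False)
        object.__setattr__(self, "log_points", pts)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not 0 <= self.prior <= 1:
            raise ValueError("prior must be in [0, 1]")

    def log_density(self, x) -> np.ndarray:
        """Log KDE density at log-quotient value(s) ``x``.

        Exact sum over all kernels (no truncation or gridding), evaluated
        with the max-shift trick so far tails stay finite."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pts, h, n = self.log_points, self.bandwidth, self.log_points.size
        out = np.empty(x.shape)
        # chunk queries so the (chunk x n) kernel matrix stays small
        chunk = max(1, int(40_000_000 // max(n, 1)))
        const = np.log(n * h * np.sqrt(2 * np.pi))
        for lo in range(0, x.size, chunk):
            z = np.subtract.outer(x[lo : lo + chunk], pts)
            z /= h
            np.square(z, out=z)
            z *= -0.5
            m = z.max(axis=1)
            z -= m[:, None]
            np.exp(z, out=z)
            out[lo : lo + chunk] = m + np.log(z.sum(axis=1)) - const
        return out

    def density(self, q) -> np.ndarray:
        """KDE density at quotient(s) ``q``, in log-quotient space."""
        return np.exp(self.log_density(np.log(np.asarray(q, dtype=float))))


@dataclass(frozen=True)
class QuotientClassifier:
    """Two-class kernel-density naive Bayes over score quotients."""

    lost: KernelDensityClassModel
    gained: KernelDensityClassModel

    def posterior(self, q) -> tuple[np.ndarray, np.ndarray]:
        """(p_lost, p_gained) for quotient(s) ``q`` by Bayes' rule.

        When both class densities vanish numerically the priors are
        returned (with a warning)."""
        logq = np.log(np.atleast_1d(np.asarray(q, dtype=float)))
        ll = self.lost.log_density(logq) + np.log(self.lost.prior)
        lg = self.gained.log_density(logq) + np.log(self.gained.prior)
        both = np.stack([ll, lg])
        bad = ~np.isfinite(both).any(axis=0)
        if bad.any():
            logger.warning("both class densities vanish for %d quotients; using priors", bad.sum())
            both[:, bad] = np.log([[self.lost.prior], [self.gained.prior]])
        norm = logsumexp(both, axis=0)
        p = np.exp(both - norm)
        return p[0], p[1]

    def posterior_scalar(self, q: float) -> tuple[float, float]:
        pl, pg = self.posterior(q)
        return float(pl[0]), float(pg[0])


def fit_kde_classifier(
    lost_q: Sequence[float],
    gained_q: Sequence[float],
    priors: tuple[float, float] = (0.5, 0.5),
    bandwidth: float | None = None,
) -> QuotientClassifier:
    """Fit the two class KDEs on log-quotients.

    Each class needs at least 10 training quotients; bandwidths default to
    Silverman's rule per class and can be overridden jointly."""
    lost = np.log(np.asarray(lost_q, dtype=float))
    gained = np.log(np.asarray(gained_q, dtype=float))
    if lost.size < 10 or gained.size < 10:
        raise ValueError(
            f"need >= 10 training quotients per class, got {lost.size}/{gained.size}"
        )
    if abs(sum(priors) - 1.0) > 1e-9:
        raise ValueError("class priors must sum to 1")
    h_lost = bandwidth if bandwidth is not None else nrd0_bandwidth(lost)
    h_gained = bandwidth if bandwidth is not None else nrd0_bandwidth(gained)
    return QuotientClassifier(
        lost=KernelDensityClassModel("binding_lost", lost, h_lost, priors[0]),
        gained=KernelDensityClassModel("binding_gained", gained, h_gained, priors[1]),
    )


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationTable:
    """Empirical PPV/NPV per posterior-confidence bin on held-out pairs.

    Bins cover [0.5, 1.0]; an empty bin is undefined (NaN)."""

    bin_edges: np.ndarray         # length n_bins + 1, from 0.5 to 1.0
    ppv: np.ndarray               # per bin; NaN where no lost-calls fell
    npv: np.ndarray               # per bin; NaN where no gained-calls fell
    n_lost_calls: np.ndarray
    n_gained_calls: np.ndarray

    def _bin(self, confidence: float) -> int:
        i = int(np.searchsorted(self.bin_edges, confidence, side="right")) - 1
        return min(max(i, 0), len(self.bin_edges) - 2)

    def predictive_value(self, direction: str, confidence: float) -> float | None:
        """PPV (loss calls) or NPV (gain calls) of the bin holding
        ``confidence``; None when the bin is undefined."""
        table = self.ppv if direction == LOSS else self.npv
        v = table[self._bin(confidence)]
        return None if np.isnan(v) else float(v)


def calibrate(
    classifier: QuotientClassifier,
    lost_holdout: Sequence[float],
    gained_holdout: Sequence[float],
    n_bins: int = 10,
) -> CalibrationTable:
    """Bin held-out predictions by posterior confidence and record, per bin,
    the fraction of loss-calls that were truly lost (PPV) and of gain-calls
    that were truly gained (NPV)."""
    edges = np.linspace(0.5, 1.0, n_bins + 1)
    qs = np.concatenate([np.asarray(lost_holdout, float), np.asarray(gained_holdout, float)])
    truth_lost = np.concatenate(
        [np.ones(len(lost_holdout), dtype=bool), np.zeros(len(gained_holdout), dtype=bool)]
    )
    pl, pg = classifier.posterior(qs)
    called_lost = pl > pg
    confidence = np.maximum(pl, pg)
    bins = np.clip(np.searchsorted(edges, confidence, side="right") - 1, 0, n_bins - 1)
    ppv = np.full(n_bins, np.nan)
    npv = np.full(n_bins, np.nan)
    n_lost = np.zeros(n_bins, dtype=int)
    n_gained = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel_l = (bins == b) & called_lost
        sel_g = (bins == b) & ~called_lost
        n_lost[b], n_gained[b] = sel_l.sum(), sel_g.sum()
        if n_lost[b]:
            ppv[b] = truth_lost[sel_l].mean()
        if n_gained[b]:
            npv[b] = (~truth_lost[sel_g]).mean()
    return CalibrationTable(edges, ppv, npv, n_lost, n_gained)


# ---------------------------------------------------------------------------
# trained matrices, bundles, per-TF verdicts


@dataclass(frozen=True)
class TrainedMatrix:
    """Everything needed to judge one variant with one binding model."""

    pfm: PositionFrequencyMatrix
    classifier: QuotientClassifier
    calibration: CalibrationTable
    scale: float = 100.0
    floor_fraction: float = 0.01

    @property
    def matrix_id(self) -> str:
        return self.pfm.matrix_id

    @property
    def tf_name(self) -> str:
        return self.pfm.tf_name

    def scoring_matrix(self) -> ScoringMatrix:
        return to_scoring_matrix(self.pfm, scale=self.scale)


@dataclass(frozen=True)
class MatrixVerdict:
    matrix_id: str
    q: float
    direction: str | None          # "loss" | "gain" | None (tie)
    posterior: float               # confidence of the called direction
    predictive_value: float | None # PPV or NPV at that confidence
    grade: int                     # ordinal reliability 1 (weak) .. 5 (strong)


@dataclass(frozen=True)
class TfVerdict:
    tf_name: str
    per_matrix: tuple
    call: str                      # "loss" | "gain" | "uncertain" | "no_reliable_prediction"
    known_site_flag: bool


def reliability_grade(predictive_value: float | None) -> int:
    if predictive_value is None:
        return 1
    for grade, cut in ((5, 0.9), (4, 0.8), (3, 0.7), (2, 0.6)):
        if predictive_value >= cut:
            return grade
    return 1


def classify_variant(
    ctx: VariantContext,
    trained: Sequence[TrainedMatrix],
    peak_db: Sequence[PeakRecord] | None = None,
    min_predictive_value: float = 0.70,
) -> TfVerdict:
    """Per-TF verdict from every trained matrix of that TF.

    Each matrix contributes its posterior direction and the matching PPV/NPV;
    only matrices whose predictive value reaches ``min_predictive_value``
    enter the aggregate call, decided by majority direction (ties are
    "uncertain"; no qualifying matrix gives "no_reliable_prediction")."""
    if not trained:
        raise ValueError("no trained matrices supplied")
    tf_names = {t.tf_name for t in trained}
    if len(tf_names) != 1:
        raise ValueError(f"matrices span several TFs: {sorted(tf_names)}")
    tf_name = trained[0].tf_name

    records: list[MatrixVerdict] = []
    for t in trained:
        m = t.scoring_matrix()
        sq = score_quotient(m, ctx, floor=t.floor_fraction * m.max_score)
        pl, pg = t.classifier.posterior_scalar(sq.q)
        if abs(pl - pg) <= 1e-12:
            direction, conf = None, 0.5
        elif pl > pg:
            direction, conf = LOSS, pl
        else:
            direction, conf = GAIN, pg
        pv = t.calibration.predictive_value(direction, conf) if direction else None
        records.append(
            MatrixVerdict(matrix_id=t.matrix_id, q=sq.q, direction=direction,
                          posterior=conf, predictive_value=pv,
                          grade=reliability_grade(pv))
        )

    contributing = [
        r for r in records
        if r.direction is not None
        and r.predictive_value is not None
        and r.predictive_value >= min_predictive_value
    ]
    if not contributing:
        call = "no_reliable_prediction"
    else:
        n_loss = sum(r.direction == LOSS for r in contributing)
        n_gain = len(contributing) - n_loss
        call = LOSS if n_loss > n_gain else GAIN if n_gain > n_loss else "uncertain"

    known = False
    if peak_db is not None and ctx.genomic_position is not None:
        chrom, pos, _, _ = ctx.genomic_position
        p0 = pos - 1
        known = any(
            p.tf_name == tf_name and p.chrom == chrom and p.start <= p0 < p.end
            for p in peak_db
        )
    return TfVerdict(tf_name=tf_name, per_matrix=tuple(records), call=call,
                     known_site_flag=known)


def direction_agreement(
    predictions: Sequence[str | None], experimental: Sequence[str]
) -> float:
    """Fraction of pair-aligned direction calls (loss/gain) matching the
    experimentally observed direction, ignoring declined (None) predictions."""
    if len(predictions) != len(experimental):
        raise ValueError("prediction and experimental lists must pair by index")
    if not predictions:
        raise ValueError("empty input")
    kept = [(p, e) for p, e in zip(predictions, experimental) if p in (LOSS, GAIN)]
    if not kept:
        raise ValueError("every prediction was declined; agreement undefined")
    return sum(p == e for p, e in kept) / len(kept)


# ---------------------------------------------------------------------------
# training driver and JSON bundle


def train_matrix(
    pfm: PositionFrequencyMatrix,
    positives: Sequence,
    negatives: Sequence,
    cap: int = 1_000_000,
    seed: int = 0,
    scale: float = 100.0,
    floor_fraction: float = 0.01,
    holdout_fraction: float = 0.2,
    n_bins: int = 10,
    max_calibration_points: int = 20_000,
) -> TrainedMatrix:
    """Train one matrix end to end: best-hit scores of positive and negative
    sequences -> capped pair quotients -> held-out split -> KDE classifier +
    calibration table.  Set ``holdout_fraction=0`` for resubstitution
    calibration.

    The held-out set used for calibration is subsampled to
    ``max_calibration_points`` per class: binned PPV/NPV estimates gain
    nothing from more, while posterior evaluation is linear in both the
    training and the held-out size."""
    m = to_scoring_matrix(pfm, scale=scale)
    floor = floor_fraction * m.max_score
    pos_scores = [h.score for h in (best_hit(m, s) for s in positives) if h is not None]
    neg_scores = [h.score for h in (best_hit(m, s) for s in negatives) if h is not None]
    lost, gained = make_training_pairs(pos_scores, neg_scores, cap=cap, seed=seed, floor=floor)
    rng = np.random.default_rng(seed + 1)
    n = lost.size
    idx = rng.permutation(n)
    n_hold = int(round(holdout_fraction * n))
    hold, fit = idx[:n_hold], idx[n_hold:]
    if fit.size < 10:
        raise ValueError("too few pairs left for training after the held-out split")
    clf = fit_kde_classifier(lost[fit], gained[fit])
    cal_idx = hold if hold.size else fit
    if not hold.size:
        logger.info("matrix %s: resubstitution calibration", pfm.matrix_id)
    if cal_idx.size > max_calibration_points:
        cal_idx = rng.choice(cal_idx, size=max_calibration_points, replace=False)
    cal_lost, cal_gained = lost[cal_idx], gained[cal_idx]
    table = calibrate(clf, cal_lost, cal_gained, n_bins=n_bins)
    return TrainedMatrix(pfm=pfm, classifier=clf, calibration=table,
                         scale=scale, floor_fraction=floor_fraction)


@dataclass
class ClassifierBundle:
    """Versioned collection of trained matrices plus training metadata."""

    matrices: dict        # matrix_id -> TrainedMatrix
    flank: int = 20
    cap: int = 1_000_000
    seed: int = 0
    version: int = BUNDLE_VERSION

    def by_tf(self) -> dict[str, list[TrainedMatrix]]:
        groups: dict[str, list[TrainedMatrix]] = {}
        for t in self.matrices.values():
            groups.setdefault(t.tf_name, []).append(t)
        return groups

    def to_dict(self) -> dict:
        def kde(model: KernelDensityClassModel) -> dict:
            return {
                "class_label": model.class_label,
                "log_points": np.round(model.log_points, 9).tolist(),
                "bandwidth": model.bandwidth,
                "prior": model.prior,
            }

        out = {"version": self.version, "flank": self.flank, "cap": self.cap,
               "seed": self.seed, "matrices": {}}
        for mid, t in self.matrices.items():
            c = t.calibration
            out["matrices"][mid] = {
                "tf_name": t.tf_name,
                "source": t.pfm.source,
                "probs": np.round(t.pfm.probs, 9).tolist(),
                "scale": t.scale,
                "floor_fraction": t.floor_fraction,
                "lost": kde(t.classifier.lost),
                "gained": kde(t.classifier.gained),
                "calibration": {
                    "bin_edges": c.bin_edges.tolist(),
                    "ppv": [None if np.isnan(v) else v for v in c.ppv],
                    "npv": [None if np.isnan(v) else v for v in c.npv],
                    "n_lost_calls": c.n_lost_calls.tolist(),
                    "n_gained_calls": c.n_gained_calls.tolist(),
                },
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierBundle":
        if d.get("version") != BUNDLE_VERSION:
            raise ValueError(f"unsupported bundle version {d.get('version')}")

        def kde(sub: dict) -> KernelDensityClassModel:
            return KernelDensityClassModel(
                class_label=sub["class_label"],
                log_points=np.asarray(sub["log_points"], float),
                bandwidth=float(sub["bandwidth"]),
                prior=float(sub["prior"]),
            )

        matrices = {}
        for mid, sub in d["matrices"].items():
            probs = np.asarray(sub["probs"], float)
            # renormalise away JSON rounding so PFM invariants hold exactly
            probs = probs / probs.sum(axis=0, keepdims=True)
            pfm = PositionFrequencyMatrix(
                tf_name=sub["tf_name"], probs=probs, source=sub["source"], matrix_id=mid
            )
            cal = sub["calibration"]
            table = CalibrationTable(
                bin_edges=np.asarray(cal["bin_edges"], float),
                ppv=np.asarray([np.nan if v is None else v for v in cal["ppv"]], float),
                npv=np.asarray([np.nan if v is None else v for v in cal["npv"]], float),
                n_lost_calls=np.asarray(cal["n_lost_calls"], int),
                n_gained_calls=np.asarray(cal["n_gained_calls"], int),
            )
            matrices[mid] = TrainedMatrix(
                pfm=pfm,
                classifier=QuotientClassifier(lost=kde(sub["lost"]), gained=kde(sub["gained"])),
                calibration=table,
                scale=float(sub["scale"]),
                floor_fraction=float(sub["floor_fraction"]),
            )
        return cls(matrices=matrices, flank=int(d["flank"]), cap=int(d["cap"]),
                   seed=int(d["seed"]), version=int(d["version"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ClassifierBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_bundle(
    pfms: Sequence[PositionFrequencyMatrix],
    positives: Sequence,
    negatives: Sequence,
    cap: int = 1_000_000,
    seed: int = 0,
    flank: int = 20,
    **kwargs,
) -> ClassifierBundle:
    """Train a classifier for every matrix and collect them into a bundle."""
    matrices = {}
    for k, pfm in enumerate(pfms):
        matrices[pfm.matrix_id] = train_matrix(
            pfm, positives, negatives, cap=cap, seed=seed + k, **kwargs
        )
    return ClassifierBundle(matrices=matrices, flank=flank, cap=cap, seed=seed)
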
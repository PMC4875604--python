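"""File formats and coordinate plumbing.

JASPAR-style PFM text, FASTA, BED/narrowPeak peak tables, a minimal VCF 4.x
subset (CHROM/POS/REF/ALT, no samples), fixed-step wiggle and bedGraph score
tracks, and TSV/JSON reports.  BED intervals are 0-based half-open; VCF
positions are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .benchmark import PeakRecord
from .conservation import ScoreTrack
from .motifs import MotifError, PositionFrequencyMatrix, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised on malformed input files, with the offending line where known."""


# ---------------------------------------------------------------------------
# JASPAR-style PFM text


def parse_pfm_text(text: str, source: str = "SYNTHETIC") -> list[PositionFrequencyMatrix]:
    """Parse JASPAR-style PFM blocks.

    Each block: a ``>id [name]`` header, then four rows in A,C,G,T order,
    optionally of the form ``A [ 1 2 3 ]``.  Counts and probabilities are
    auto-detected: columns are always normalised by their sum, which is the
    identity for probability matrices.
    """
    matrices: list[PositionFrequencyMatrix] = []
    header: str | None = None
    rows: list[list[float]] = []
    row_line = 0

    def flush(line_no: int):
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"line {line_no}: matrix '{header}' has {len(rows)} rows, expected 4")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"line {line_no}: matrix '{header}' rows differ in column count {sorted(widths)}")
        grid = np.array(rows, dtype=float)
        sums = grid.sum(axis=0)
        if np.any(sums <= 0):
            raise FormatError(f"line {line_no}: matrix '{header}' has a zero-sum column")
        grid = grid / sums
        parts = header.split(None, 1)
        matrix_id = parts[0]
        name = parts[1] if len(parts) > 1 else parts[0]
        matrices.append(
            PositionFrequencyMatrix(tf_name=name, probs=grid, source=source, matrix_id=matrix_id)
        )
        header, rows = None, []

    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(i)
            header = line[1:].strip()
            continue
        if header is None:
            raise FormatError(f"line {i}: matrix row before any '>' header")
        body = line
        if body[0].upper() in "ACGT" and (len(body) == 1 or not body[1].isdigit()):
            body = body[1:]
        body = body.replace("[", " ").replace("]", " ")
        try:
            rows.append([float(tok) for tok in body.split()])
        except ValueError as exc:
            raise FormatError(f"line {i}: cannot parse matrix row: {raw!r}") from exc
        row_line = i
    flush(row_line + 1)
    return matrices


def parse_pfm_file(path, source: str = "SYNTHETIC") -> list[PositionFrequencyMatrix]:
    return parse_pfm_text(Path(path).read_text(), source=source)


def write_pfm_file(path, matrices: Sequence[PositionFrequencyMatrix]) -> None:
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f">{m.matrix_id} {m.tf_name}\n")
            for base, row in zip("ACGT", m.probs):
                fields = " ".join(f"{v:.10g}" for v in row)
                fh.write(f"{base} [ {fields} ]\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[SequenceRecord]) -> None:
    SeqIO.write(
        (BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path), "fasta",
    )


def read_transcript_exons(path) -> dict[str, list[SequenceRecord]]:
    """Per-transcript ordered exon records from FASTA.

    Record ids follow ``<transcript>|<exon_number>`` (for example
    ``ENST0001|1``); exons are grouped by transcript and ordered by the
    numeric suffix, ready for first-exon exclusion."""
    groups: dict[str, list[tuple[int, SequenceRecord]]] = {}
    for rec in read_fasta(path):
        if "|" not in rec.id:
            raise FormatError(f"exon record id {rec.id!r} lacks '<transcript>|<n>' form")
        tx, num = rec.id.rsplit("|", 1)
        try:
            order = int(num)
        except ValueError as exc:
            raise FormatError(f"exon record id {rec.id!r}: non-numeric exon number") from exc
        groups.setdefault(tx, []).append((order, rec))
    return {tx: [r for _, r in sorted(lst)] for tx, lst in groups.items()}


def extract_sequences(genome, intervals: Sequence[tuple]) -> list[SequenceRecord]:
    """Fetch BED-style intervals from a genome (dict of strings or pyfaidx
    Fasta).  Interval tuples are (chrom, start, end[, name[, strand]]); a
    '-' strand yields the reverse complement."""
    out = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        name = iv[3] if len(iv) > 3 and iv[3] else f"{chrom}:{start}-{end}"
        strand = iv[4] if len(iv) > 4 else "+"
        contig = genome[chrom]
        if isinstance(contig, str):
            if end > len(contig) or start < 0:
                raise FormatError(f"interval {chrom}:{start}-{end} outside contig (length {len(contig)})")
            seq = contig[start:end]
        else:
            piece = contig[start:end]
            seq = piece.seq if hasattr(piece, "seq") else str(piece)
            if len(seq) != end - start:
                raise FormatError(f"interval {chrom}:{start}-{end} outside contig")
        seq = seq.upper()
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(SequenceRecord(id=str(name), seq=seq))
    return out


# ---------------------------------------------------------------------------
# BED / narrowPeak peaks


def read_peaks(path, dialect: str = "bed5", tf_name: str | None = None) -> list[PeakRecord]:
    """Read peaks from BED5 (score in column 5) or narrowPeak (signal value
    in column 7).  The feature name column carries the TF name unless
    ``tf_name`` overrides it."""
    if dialect not in ("bed5", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    score_col = 4 if dialect == "bed5" else 6
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] <= score_col:
        raise FormatError(f"{path}: {dialect} needs at least {score_col + 1} columns")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PeakRecord(
                chrom=str(row[0]), start=int(row[1]), end=int(row[2]),
                tf_name=tf_name or str(row[3]),
                binding_score=int(round(float(row[score_col]))),
            )
        )
    return out


def write_peaks(path, peaks: Sequence[PeakRecord], dialect: str = "bed5") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "bed5":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_name}\t{p.binding_score}\n")
            else:  # narrowPeak: name, score, strand, signalValue, pValue, qValue, peak
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_name}\t{min(p.binding_score, 1000)}\t."
                    f"\t{p.binding_score}\t-1\t-1\t-1\n"
                )


def read_bed_intervals(path) -> list[tuple]:
    """Plain BED intervals as tuples (chrom, start, end[, name[, strand]])."""
    out = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path} line {i}: BED needs >= 3 columns")
            iv = [f[0], int(f[1]), int(f[2])]
            if len(f) > 3:
                iv.append(f[3])
            if len(f) > 5:
                iv.append(f[5])
            out.append(tuple(iv))
    return out


# ---------------------------------------------------------------------------
# minimal VCF 4.x


def read_vcf(path) -> list[tuple[str, int, str, str]]:
    """Minimal VCF reader: (CHROM, POS 1-based, REF, ALT) per record;
    multi-allelic ALT fields are split into one variant each."""
    out = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise FormatError(f"{path} line {i}: VCF data line needs >= 5 columns")
            chrom, pos, _, ref, alts = f[0], f[1], f[2], f[3].upper(), f[4]
            for alt in alts.split(","):
                out.append((chrom, int(pos), ref, alt.upper()))
    return out


def write_vcf(path, variants: Sequence[tuple[str, int, str, str]], build: str = "unknown") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={build}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in variants:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# wiggle (fixedStep, step 1) and bedGraph score tracks


def read_wiggle(path) -> ScoreTrack:
    """fixedStep step=1 wiggle; one block per chromosome (later blocks on
    the same chromosome must be contiguous with the first)."""
    data: dict[str, tuple[int, list[float]]] = {}
    chrom, expect = None, None
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                if step != 1:
                    raise FormatError(f"{path} line {i}: only step=1 supported, got {step}")
                if chrom in data:
                    prev_start, vals = data[chrom]
                    if start != prev_start + len(vals):
                        raise FormatError(
                            f"{path} line {i}: non-contiguous block for {chrom}"
                        )
                else:
                    data[chrom] = (start, [])
                continue
            if chrom is None:
                raise FormatError(f"{path} line {i}: value before any fixedStep header")
            data[chrom][1].append(float(line))
    return ScoreTrack({c: (s, np.array(v)) for c, (s, v) in data.items()})


def write_wiggle(path, track: ScoreTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            start, end = track.coverage(chrom)
            vals = track.values(chrom, start, end)
            fh.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
            for v in vals:
                fh.write(f"{v:.6g}\n")


def read_bedgraph(path) -> ScoreTrack:
    """bedGraph (0-based half-open intervals) expanded to per-base arrays;
    uncovered gaps inside the span become missing (NaN)."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split()
            if len(f) != 4:
                raise FormatError(f"{path} line {i}: bedGraph needs 4 columns")
            spans.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    data = {}
    for chrom, ivs in spans.items():
        lo = min(s for s, _, _ in ivs)
        hi = max(e for _, e, _ in ivs)
        arr = np.full(hi - lo, np.nan)
        for s, e, v in ivs:
            arr[s - lo : e - lo] = v
        data[chrom] = (lo, arr)
    return ScoreTrack(data)


# ---------------------------------------------------------------------------
# reports


def write_auc_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_roc_points(path, curve) -> None:
    pd.DataFrame(curve.points, columns=["fpr", "tpr"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
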
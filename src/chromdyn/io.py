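"""Readers and writers for the plain-text formats the pipeline touches.

BED3/BED6, BEDPE loop tables with named count columns, TSS tables, FASTA,
and a minimal PWM text format (one ">name" header, then L rows of four base
probabilities in A,C,G,T order). All coordinates are written and returned
0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalError, PeakSet

PathLike = Union[str, Path]

_SKIP_PREFIXES = ("track", "browser", "#")


class ParseError(ValueError):
    """Raised on malformed input, carrying the offending line number."""


def read_bed(path: PathLike, name: Optional[str] = None) -> PeakSet:
    """Read a BED3/BED6 file into a PeakSet (0-based half-open, as on disk).

    track/browser/comment lines are skipped. Malformed coordinates raise
    :class:`ParseError` naming the line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            iv_name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, iv_name, score)
                )
            except IntervalError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(name if name is not None else path.stem, intervals)


def write_bed(peaks: PeakSet, path: PathLike) -> int:
    """Write a PeakSet as BED; returns the number of records written.

    Emits BED3 when no interval carries name/score/strand, else BED6.
    """
    six = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in peaks
    )
    with open(path, "w") as fh:
        for iv in peaks:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return len(peaks)


# ---------------------------------------------------------------------------
# BEDPE loop tables
# ---------------------------------------------------------------------------

BEDPE_COORDS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def read_bedpe(path: PathLike) -> pd.DataFrame:
    """Read a BEDPE file with a header line naming the extra columns.

    The first six columns are anchor coordinates; any further columns
    (per-sample counts, fdr, ...) are preserved by name.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BEDPE_COORDS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing BEDPE columns {missing}")
    for col in ("start1", "end1", "start2", "end2"):
        if (df[col] < 0).any():
            raise ParseError(f"{path}: negative coordinate in {col}")
    if (df["end1"] <= df["start1"]).any() or (df["end2"] <= df["start2"]).any():
        raise ParseError(f"{path}: end <= start in anchor coordinates")
    return df


def write_bedpe(df: pd.DataFrame, path: PathLike) -> int:
    cols = BEDPE_COORDS + [c for c in df.columns if c not in BEDPE_COORDS]
    df[cols].to_csv(path, sep="\t", index=False)
    return len(df)


# ---------------------------------------------------------------------------
# TSS tables
# ---------------------------------------------------------------------------


def read_tss_table(path: PathLike) -> pd.DataFrame:
    """Read a gene TSS table: gene_id, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing TSS columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id values")
    return df


def write_tss_table(df: pd.DataFrame, path: PathLike) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_sequences(
    fasta: dict[str, str], peaks: PeakSet
) -> list[str]:
    """Pull the subsequence under each interval from an in-memory genome."""
    out = []
    for iv in peaks:
        if iv.chrom not in fasta:
            raise ParseError(f"chromosome {iv.chrom!r} absent from FASTA")
        out.append(fasta[iv.chrom][iv.start : iv.end])
    return out


# ---------------------------------------------------------------------------
# PWM text
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with optional background."""

    name: str
    probs: np.ndarray  # shape (L, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ParseError(f"PWM {self.name}: matrix must be L x 4")
        if self.probs.shape[0] < 4:
            raise ParseError(f"PWM {self.name}: motif length must be >= 4")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ParseError(
                f"PWM {self.name}: column probabilities must sum to 1 "
                f"(max deviation {np.abs(sums - 1).max():.2e})"
            )
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ParseError(f"PWM {self.name}: background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def max_score(self) -> float:
        """Maximum achievable log-odds score (consensus sequence score)."""
        lom = np.log2(np.maximum(self.probs, 1e-12) / self.background)
        return float(lom.max(axis=1).sum())


def read_pwms(path: PathLike) -> list[PWM]:
    """Read PWM text: '>name' headers, then L rows of 4 probabilities each."""
    pwms: list[PWM] = []
    name: Optional[str] = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if name is not None:
            if not rows:
                raise ParseError(f"{path}:{lineno}: motif {name!r} has no rows")
            pwms.append(PWM(name, np.array(rows)))
        name, rows = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].strip()
            else:
                vals = line.split()
                if len(vals) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 probabilities")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
        flush(lineno)
    return pwms


def write_pwms(pwms: list[PWM], path: PathLike) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.probs:
                fh.write(" ".join(format(v, ".6f") for v in row) + "\n")
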
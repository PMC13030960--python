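"""Genomic intervals: 1-based, fully-closed coordinates.

All printed promoter/ORF/cCRE coordinates in this package use the 1-based
fully-closed convention (length = end - start + 1), which is what genome
browsers display.  BED files on disk are 0-based half-open; the readers and
writers here convert exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based fully-closed chromosomal span.

    ``strand`` is ``+``, ``-`` or ``.`` (unknown).  ``assembly`` is a free
    label such as ``hg38`` or ``KIZ3``; ``name`` carries a feature id when
    one exists (e.g. a cCRE accession).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    assembly: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 1 <= start <= end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp under the closed convention; 0 on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def interval_length_kb(iv: GenomicInterval) -> float:
    """Interval length in kilobases, rounded half-up to one decimal.

    chr18:72,542,815-72,544,612 has 1,798 bases and prints as 1.8 kb.
    """
    kb = Decimal(iv.length) / Decimal(1000)
    return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class OverlapSummary:
    """Per-peak overlap of a target interval against a peak list."""

    target: GenomicInterval
    per_peak_bp: list[int] = field(default_factory=list)
    n_overlapping: int = 0
    total_bp: int = 0


def peak_overlap(target: GenomicInterval, peaks: Iterable[GenomicInterval]) -> OverlapSummary:
    """Overlap of ``target`` with each peak (closed-interval arithmetic).

    Adjacent-but-not-overlapping peaks contribute 0 bp.  Used to summarise
    how epigenomic peaks (cCRE, ATAC, DHS, H3K27Ac, H3K4Me3) line up with a
    candidate promoter.
    """
    summary = OverlapSummary(target=target)
    for peak in peaks:
        bp = target.overlap_bp(peak)
        summary.per_peak_bp.append(bp)
        if bp > 0:
            summary.n_overlapping += 1
            summary.total_bp += bp
    return summary


# --- BED I/O (0-based half-open on disk <-> 1-based closed in memory) ---


def read_bed(path: str | Path, assembly: str = "") -> list[GenomicInterval]:
    """Read a 3-6 column BED file into 1-based closed intervals."""
    out: list[GenomicInterval] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom, start0, end_ex = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else ""
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        out.append(
            GenomicInterval(
                chrom=chrom,
                start=start0 + 1,
                end=end_ex,
                strand=strand,
                assembly=assembly,
                name=name,
            )
        )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 6-column BED (exact inverse of :func:`read_bed`)."""
    lines = []
    for iv in intervals:
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start - 1),
                    str(iv.end),
                    iv.name or ".",
                    "0",
                    iv.strand if iv.strand in ("+", "-") else ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
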
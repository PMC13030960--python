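"""Progressive three-species promoter alignment and its summary statistics.

The aligner is a deterministic progressive scheme built on affine-gap
pairwise global alignment (Needleman-Wunsch via Bio.Align.PairwiseAligner):
the two most similar sequences are aligned first and the remaining sequence
is merged through the anchor row.  The statistics — pairwise percent
identity over both-non-gap columns, per-species coverage of a reference,
and a per-column identity track — are the quantities of interest; the
aligner only has to be reasonable and reproducible, and an externally
produced alignment (aligned FASTA) can be substituted for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

GAP = "-"


@dataclass
class AlignParams:
    """Affine-gap scoring parameters.

    The default gap-open penalty is deliberately stiff: at ~50% sequence
    identity a permissive open penalty lets the dynamic program pair
    random matches through compensating gaps, inflating the estimated
    identity by several percentage points.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


@dataclass
class PromoterAlignment:
    """A gapped multiple alignment plus per-species coordinate maps.

    ``col_of_pos[s][p-1]`` is the 0-based column of 1-based ungapped
    position ``p`` in species ``s``; ``pos_of_col[s][c]`` is the 1-based
    ungapped position at column ``c`` or 0 where that row has a gap.
    """

    species_ids: list[str]
    rows: list[str]
    col_of_pos: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    pos_of_col: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        if not self.col_of_pos:
            for sp, row in zip(self.species_ids, self.rows):
                cols = np.flatnonzero(np.frombuffer(row.encode(), dtype="S1") != b"-")
                self.col_of_pos[sp] = cols
                inv = np.zeros(len(row), dtype=np.int64)
                inv[cols] = np.arange(1, len(cols) + 1)
                self.pos_of_col[sp] = inv

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, species: str) -> str:
        return self.rows[self._index(species)]

    def ungapped(self, species: str) -> str:
        return self.row(species).replace(GAP, "")

    def _index(self, species: str) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in alignment {self.species_ids}")


def _pairwise(a: str, b: str, params: AlignParams) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _quick_identity(a: str, b: str, params: AlignParams) -> float:
    ra, rb = _pairwise(a, b, params)
    both = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)


def _merge_on_anchor(anchor_pair1: tuple[str, str], anchor_pair2: tuple[str, str]) -> tuple[str, str, str]:
    """Merge two pairwise alignments sharing an anchor first row.

    Returns (anchor, other1, other2) rows of equal length; insertions
    relative to the anchor are emitted first-alignment-first, which keeps
    the procedure deterministic.
    """
    a1, b1 = anchor_pair1
    a2, c2 = anchor_pair2
    i = j = 0
    out_a: list[str] = []
    out_b: list[str] = []
    out_c: list[str] = []
    while i < len(a1) or j < len(a2):
        ins1 = i < len(a1) and a1[i] == GAP
        ins2 = j < len(a2) and a2[j] == GAP
        if ins1:
            out_a.append(GAP)
            out_b.append(b1[i])
            out_c.append(GAP)
            i += 1
        elif ins2:
            out_a.append(GAP)
            out_b.append(GAP)
            out_c.append(c2[j])
            j += 1
        else:
            out_a.append(a1[i])
            out_b.append(b1[i])
            out_c.append(c2[j])
            i += 1
            j += 1
    return "".join(out_a), "".join(out_b), "".join(out_c)


def align_promoters(
    seqs: Sequence[str],
    species_ids: Sequence[str] | None = None,
    params: AlignParams | None = None,
) -> PromoterAlignment:
    """Progressively align 2-3 sequences with affine gap penalties.

    For three sequences the closest pair (by quick pairwise identity) is
    aligned first; the third is aligned to the more similar member of that
    pair and merged through it.
    """
    params = params or AlignParams()
    seqs = [s.upper() for s in seqs]
    if not 2 <= len(seqs) <= 3:
        raise ValueError("align_promoters takes 2 or 3 sequences")
    if any(not s for s in seqs):
        raise ValueError("empty sequence")
    if species_ids is None:
        species_ids = ["human", "treeshrew", "mouse"][: len(seqs)]
    species_ids = list(species_ids)

    if len(seqs) == 2:
        r0, r1 = _pairwise(seqs[0], seqs[1], params)
        return PromoterAlignment(species_ids=species_ids, rows=[r0, r1])

    idents = {
        (i, j): _quick_identity(seqs[i], seqs[j], params)
        for i, j in ((0, 1), (0, 2), (1, 2))
    }
    (i, j) = max(idents, key=lambda k: (idents[k], -k[0], -k[1]))
    k = ({0, 1, 2} - {i, j}).pop()
    # anchor = member of the closest pair more similar to the outgroup
    anchor, other = (i, j) if idents[tuple(sorted((i, k)))] >= idents[tuple(sorted((j, k)))] else (j, i)
    pair_ao = _pairwise(seqs[anchor], seqs[other], params)
    pair_ak = _pairwise(seqs[anchor], seqs[k], params)
    row_a, row_o, row_k = _merge_on_anchor(pair_ao, pair_ak)
    rows_by_index = {anchor: row_a, other: row_o, k: row_k}
    return PromoterAlignment(
        species_ids=species_ids, rows=[rows_by_index[n] for n in range(3)]
    )


def map_position(aln: PromoterAlignment, species: str, ungapped_pos: int) -> int:
    """1-based ungapped position -> 1-based alignment column."""
    cols = aln.col_of_pos[_require(aln, species)]
    if not 1 <= ungapped_pos <= len(cols):
        raise IndexError(
            f"position {ungapped_pos} out of range 1..{len(cols)} for {species}"
        )
    return int(cols[ungapped_pos - 1]) + 1


def map_column(aln: PromoterAlignment, species: str, column: int) -> int:
    """1-based alignment column -> 1-based ungapped position (inverse map)."""
    inv = aln.pos_of_col[_require(aln, species)]
    if not 1 <= column <= len(inv):
        raise IndexError(f"column {column} out of range 1..{len(inv)}")
    pos = int(inv[column - 1])
    if pos == 0:
        raise ValueError(f"no ungapped position: {species} has a gap at column {column}")
    return pos


def _require(aln: PromoterAlignment, species: str) -> str:
    if species not in aln.species_ids:
        raise KeyError(f"species {species!r} not in alignment {aln.species_ids}")
    return species


@dataclass
class IdentityTrack:
    """Per-column flags for each non-reference species vs the reference.

    Flags: ``match``, ``mismatch``, ``gap`` (species gapped), ``ref-gap``
    (reference gapped).  Columns where either base is N count as mismatch.
    """

    reference: str
    flags: dict[str, list[str]]


@dataclass
class AlignmentStatistics:
    pairwise_identity: dict[tuple[str, str], float]
    coverage: dict[str, float]
    track: IdentityTrack


def _column_match(x: str, y: str) -> bool:
    return x == y and x not in (GAP, "N")


def alignment_statistics(aln: PromoterAlignment, reference: str = "human") -> AlignmentStatistics:
    """Pairwise percent identity, per-species coverage, and identity track.

    identity(A, B) = 100 x matches / (columns where both are non-gap);
    coverage(S)   = 100 x (reference positions aligned to non-gap in S)
                    / (reference ungapped length).
    """
    _require(aln, reference)
    ids = aln.species_ids
    pid: dict[tuple[str, str], float] = {}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ra, rb = aln.rows[a], aln.rows[b]
            both = matches = 0
            for x, y in zip(ra, rb):
                if x != GAP and y != GAP:
                    both += 1
                    matches += _column_match(x, y)
            val = 100.0 * matches / both if both else 0.0
            pid[(ids[a], ids[b])] = val
            pid[(ids[b], ids[a])] = val

    ref_row = aln.row(reference)
    ref_len = len(ref_row) - ref_row.count(GAP)
    coverage: dict[str, float] = {}
    flags: dict[str, list[str]] = {}
    for sp in ids:
        row = aln.row(sp)
        if sp == reference:
            coverage[sp] = 100.0
            continue
        covered = sum(
            1 for x, y in zip(ref_row, row) if x != GAP and y != GAP
        )
        coverage[sp] = 100.0 * covered / ref_len if ref_len else 0.0
        col_flags = []
        for x, y in zip(ref_row, row):
            if x == GAP:
                col_flags.append("ref-gap")
            elif y == GAP:
                col_flags.append("gap")
            elif _column_match(x, y):
                col_flags.append("match")
            else:
                col_flags.append("mismatch")
        flags[sp] = col_flags

    return AlignmentStatistics(
        pairwise_identity=pid,
        coverage=coverage,
        track=IdentityTrack(reference=reference, flags=flags),
    )


# --- aligned-FASTA I/O ---


def read_alignment_fasta(path: str | Path, species_ids: Sequence[str] | None = None) -> PromoterAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need >= 2 aligned records")
    ids = list(species_ids) if species_ids else [r.id for r in records]
    return PromoterAlignment(species_ids=ids, rows=[str(r.seq).upper() for r in records])


def write_alignment_fasta(aln: PromoterAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp, row in zip(aln.species_ids, aln.rows):
            fh.write(f">{sp}\n{row}\n")
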
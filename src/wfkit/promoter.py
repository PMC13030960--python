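"""Promoter delineation from conserved blocks, ORFs and cCRE elements.

The boundary logic reproduced here: a cross-species conserved block anchors
the candidate promoter; any open reading frame inside the block that could
interfere with a downstream reporter is excised (with an explicit spacer
buffer), and the promoter may finally be truncated at the gene-proximal edge
of a candidate cis-regulatory element (cCRE) to fit AAV payload limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from wfkit.intervals import GenomicInterval

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame, reported in forward-strand 1-based coordinates.

    ``start``/``end`` always satisfy start <= end regardless of strand;
    ``frame`` is the 0-2 offset of the first codon on the reading strand.
    """

    start: int
    end: int
    strand: str
    frame: int
    length_nt: int

    def __post_init__(self) -> None:
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.end - self.start + 1 != self.length_nt:
            raise ValueError("ORF span inconsistent with length")


@dataclass(frozen=True)
class ConservedBlock:
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    percent_identity: float
    score: int

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start + 1


def _validate_seq(seq: str, *, allow_n: bool = True) -> str:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    alphabet = "ACGTN" if allow_n else "ACGT"
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(f"invalid character {ch!r} at position {i + 1}")
    return seq


def _orfs_one_strand(seq: str) -> list[tuple[int, int, int]]:
    """All (start0, end0_exclusive, frame) ATG->first-in-frame-stop ORFs.

    Codons containing N neither start nor stop an ORF and break any ORF
    that spans them.
    """
    n = len(seq)
    hits = []
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                open_starts.clear()
                continue
            if codon in STOP_CODONS:
                for s in open_starts:
                    hits.append((s, pos + 3, frame))
                open_starts.clear()
            elif codon == START_CODON:
                open_starts.append(pos)
    return hits


def find_orfs(seq: str, min_length_nt: int = 300, strands: Sequence[str] = ("+", "-")) -> list[OrfHit]:
    """Scan for ATG-initiated ORFs ending at the first in-frame stop codon.

    Every ATG opens a candidate, so nested ORFs sharing a stop are all
    reported.  Minus-strand hits are mapped back to forward-strand
    coordinates.  Results are sorted by (start, end, strand).
    """
    seq = _validate_seq(seq)
    if min_length_nt < 3 or min_length_nt % 3 != 0:
        raise ValueError("min_length_nt must be >= 3 and divisible by 3")
    n = len(seq)
    out: list[OrfHit] = []
    if "+" in strands:
        for s0, e0, frame in _orfs_one_strand(seq):
            if e0 - s0 >= min_length_nt:
                out.append(OrfHit(start=s0 + 1, end=e0, strand="+", frame=frame, length_nt=e0 - s0))
    if "-" in strands:
        rc = reverse_complement(seq)
        for s0, e0, frame in _orfs_one_strand(rc):
            if e0 - s0 >= min_length_nt:
                # position i (0-based) on rc maps to forward position n-1-i
                out.append(
                    OrfHit(start=n - e0 + 1, end=n - s0, strand="-", frame=frame, length_nt=e0 - s0)
                )
    out.sort(key=lambda h: (h.start, h.end, h.strand))
    return out


def find_conserved_blocks(
    query: str,
    subject: str,
    word_size: int = 11,
    min_block_len: int = 100,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 20,
) -> list[ConservedBlock]:
    """Seed-and-extend ungapped local alignment between two sequences.

    Exact ``word_size``-mers shared by query and subject seed ungapped
    extensions in both directions under an x-drop rule; blocks are then
    selected greedily by score so that kept blocks do not overlap on the
    query.  This is a deliberately simple conserved-block finder, not a
    BLASTn replica: it is meant to recover long, high-identity homologous
    blocks such as the one anchoring the promoter.
    """
    if word_size < 7:
        raise ValueError("word_size must be >= 7")
    query = _validate_seq(query)
    subject = _validate_seq(subject)
    if len(query) < word_size or len(subject) < word_size:
        return []

    index: dict[str, list[int]] = {}
    for j in range(len(subject) - word_size + 1):
        word = subject[j : j + word_size]
        if "N" not in word:
            index.setdefault(word, []).append(j)

    # per-diagonal high-water mark: skip seeds already inside an extension
    covered: dict[int, int] = {}
    raw: list[ConservedBlock] = []
    for i in range(len(query) - word_size + 1):
        word = query[i : i + word_size]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            diag = i - j
            if covered.get(diag, -1) >= i:
                continue
            qs, qe, ss, se, score, ident = _extend_ungapped(
                query, subject, i, j, word_size, match, mismatch, xdrop
            )
            covered[diag] = qe  # 0-based inclusive end on query
            length = qe - qs + 1
            if length >= min_block_len:
                raw.append(
                    ConservedBlock(
                        query_start=qs + 1,
                        query_end=qe + 1,
                        subject_start=ss + 1,
                        subject_end=se + 1,
                        percent_identity=100.0 * ident / length,
                        score=score,
                    )
                )

    raw.sort(key=lambda b: (-b.score, b.query_start))
    kept: list[ConservedBlock] = []
    for blk in raw:
        if all(
            blk.query_end < k.query_start or blk.query_start > k.query_end for k in kept
        ):
            kept.append(blk)
    kept.sort(key=lambda b: b.query_start)
    return kept


def _extend_ungapped(q, s, i, j, w, match, mismatch, xdrop):
    score = w * match
    ident = w
    best = score
    # right extension
    qe, se = i + w - 1, j + w - 1
    best_qe, best_se, best_ident_r = qe, se, 0
    cur, idr = score, 0
    x, y = qe + 1, se + 1
    while x < len(q) and y < len(s):
        cur += match if q[x] == s[y] else mismatch
        idr += 1 if q[x] == s[y] else 0
        if cur > best:
            best, best_qe, best_se, best_ident_r = cur, x, y, idr
        if best - cur > xdrop:
            break
        x += 1
        y += 1
    score = best
    # left extension
    qs, ss = i, j
    best_qs, best_ss, best_ident_l = qs, ss, 0
    cur, idl = score, 0
    x, y = i - 1, j - 1
    while x >= 0 and y >= 0:
        cur += match if q[x] == s[y] else mismatch
        idl += 1 if q[x] == s[y] else 0
        if cur > best:
            best, best_qs, best_ss, best_ident_l = cur, x, y, idl
        if best - cur > xdrop:
            break
        x -= 1
        y -= 1
    ident += best_ident_r + best_ident_l
    return best_qs, best_qe, best_ss, best_se, best, ident


def delineate_promoter(
    block: GenomicInterval,
    orfs: Iterable[GenomicInterval],
    gene_strand: str,
    buffer_bp: int = 0,
) -> GenomicInterval:
    """Excise interfering ORFs from a conserved block and keep the promoter.

    Each ORF interval overlapping the block is removed, together with
    ``buffer_bp`` spacer bases on both of its flanks; the largest remaining
    sub-interval is the promoter (ties broken toward the gene's 5' side).
    With the printed block/ORF coordinates and the observed 175 bp spacer
    this reproduces the published huC2Pro boundaries.
    """
    if gene_strand not in ("+", "-"):
        raise ValueError("gene_strand must be '+' or '-'")
    if buffer_bp < 0:
        raise ValueError("buffer_bp must be >= 0")

    segments = [(block.start, block.end)]
    for orf in orfs:
        if orf.chrom != block.chrom or block.overlap_bp(orf) == 0:
            continue
        cut_lo = orf.start - buffer_bp
        cut_hi = orf.end + buffer_bp
        nxt: list[tuple[int, int]] = []
        for lo, hi in segments:
            if cut_hi < lo or cut_lo > hi:
                nxt.append((lo, hi))
                continue
            if lo < cut_lo:
                nxt.append((lo, cut_lo - 1))
            if hi > cut_hi:
                nxt.append((cut_hi + 1, hi))
        segments = nxt

    if not segments:
        raise ValueError("no promoter remains: ORF(s) cover the whole block")

    def five_prime_key(seg: tuple[int, int]) -> int:
        lo, hi = seg
        # prefer the segment nearer the gene's 5' end on ties
        return -hi if gene_strand == "-" else lo

    segments.sort(key=lambda seg: (-(seg[1] - seg[0]), five_prime_key(seg)))
    lo, hi = segments[0]
    return GenomicInterval(
        chrom=block.chrom, start=lo, end=hi, strand=gene_strand, assembly=block.assembly
    )


def truncate_promoter(
    promoter: GenomicInterval, ccre: GenomicInterval, gene_strand: str
) -> GenomicInterval:
    """Truncate a promoter at the 3' boundary (in gene orientation) of a cCRE.

    Keeps the promoter from its 5' end through the cCRE edge nearer the gene
    body; the cCRE must overlap the promoter.  Applied to huC2Pro with the
    EH38E1925959 element this yields the 1.2 kb truncated promoter.
    """
    if gene_strand not in ("+", "-"):
        raise ValueError("gene_strand must be '+' or '-'")
    if promoter.overlap_bp(ccre) == 0:
        raise ValueError("cCRE does not overlap the promoter")
    if gene_strand == "-":
        # promoter 5' end = genomic high; cCRE 3' boundary = its genomic start
        start = max(ccre.start, promoter.start)
        end = promoter.end
    else:
        start = promoter.start
        end = min(ccre.end, promoter.end)
    return GenomicInterval(
        chrom=promoter.chrom, start=start, end=end, strand=gene_strand,
        assembly=promoter.assembly,
    )
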
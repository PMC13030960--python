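"""PWM scanning of the human promoter and cross-species conservation calls.

Each JASPAR position frequency matrix is converted to a log-odds PWM
(pseudocount distributed by background) and slid over both strands of the
human promoter; hits above a relative-score threshold are mapped through
the three-species alignment, the orthologous characters are extracted, and
a character-wise similarity against the human site decides whether the
site is human-specific or shared with tree shrew, mouse, or both.  The
70% similarity threshold is the default classification boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from wfkit.alignment import GAP, PromoterAlignment, map_position
from wfkit.promoter import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_TAU = 0.70
DEFAULT_MIN_REL_SCORE = 0.85
CLASSES = ("human_specific", "shared_ts", "shared_ms", "shared_both")


@dataclass
class PositionFrequencyMatrix:
    """A 4 x L count matrix (rows A, C, G, T) with scanning parameters."""

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.ndim != 2:
            raise ValueError(f"{self.tf_name}: matrix must be 4 x L")
        if np.any(self.matrix < 0):
            raise ValueError(f"{self.tf_name}: counts must be non-negative")
        if np.any(self.matrix.sum(axis=0) <= 0):
            raise ValueError(f"{self.tf_name}: every column needs positive total count")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix with background-distributed pseudocount."""
        counts = self.matrix + self.pseudocount * self.background[:, None]
        probs = counts / counts.sum(axis=0, keepdims=True)
        return np.log2(probs / self.background[:, None])

    def reverse_complement(self) -> "PositionFrequencyMatrix":
        return PositionFrequencyMatrix(
            tf_name=self.tf_name,
            matrix=self.matrix[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background.copy(),
        )


@dataclass(frozen=True)
class TFBSHit:
    """A motif occurrence on the ungapped human promoter (1-based closed)."""

    tf_name: str
    start: int
    end: int
    strand: str
    rel_score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0.0 <= self.rel_score <= 1.0 + 1e-9:
            raise ValueError("rel_score must lie in [0, 1]")


@dataclass(frozen=True)
class ConservationCall:
    hit: TFBSHit
    similarity_ts: float
    similarity_ms: float
    conservation_class: str

    def __post_init__(self) -> None:
        if self.conservation_class not in CLASSES:
            raise ValueError(f"unknown class {self.conservation_class!r}")


def read_jaspar(source: str | Path | io.TextIOBase) -> list[PositionFrequencyMatrix]:
    """Read JASPAR-format text matrices (``>MA0002.2 RUNX1`` + 4 bracketed rows).

    Parsing is delegated to Bio.motifs; row order is normalised to A, C, G, T
    and malformed records raise with the offending record named.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        try:
            parsed = bio_motifs.parse(handle, "jaspar")
            records = list(parsed)
        except Exception as exc:  # malformed rows surface from Bio.motifs
            raise ValueError(f"malformed JASPAR input: {exc}") from exc
    finally:
        if close:
            handle.close()
    out = []
    for rec in records:
        name = f"{rec.matrix_id} {rec.name}".strip() if rec.matrix_id else rec.name
        counts = np.array([rec.counts[b] for b in BASES], dtype=float)
        try:
            out.append(PositionFrequencyMatrix(tf_name=name, matrix=counts))
        except ValueError as exc:
            raise ValueError(f"record {name!r}: {exc}") from exc
    return out


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT characters become -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Relative scores for every window; windows with non-ACGT get NaN."""
    L = lod.shape[1]
    n_win = codes.size - L + 1
    lo = lod.min(axis=0).sum()
    hi = lod.max(axis=0).sum()
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        col_codes = codes[j : j + n_win]
        bad = col_codes < 0
        valid &= ~bad
        safe = np.where(bad, 0, col_codes)
        scores += lod[safe, j]
    rel = (scores - lo) / (hi - lo) if hi > lo else np.ones(n_win)
    rel = np.where(valid, rel, np.nan)
    return rel


def scan_pwm(
    seq: str,
    pfm: PositionFrequencyMatrix,
    min_rel_score: float = DEFAULT_MIN_REL_SCORE,
) -> list[TFBSHit]:
    """Scan both strands of ``seq`` with a PFM's log-odds matrix.

    rel_score = (score - min_possible) / (max_possible - min_possible), so
    the best possible k-mer scores exactly 1.  Minus-strand hits are scored
    against the reverse-complement matrix and reported in forward
    coordinates.  Windows containing non-ACGT characters are skipped.
    """
    L = pfm.length
    if len(seq) < L:
        return []
    codes = _encode(seq)
    hits: list[TFBSHit] = []
    for strand, lod in (("+", pfm.log_odds()), ("-", pfm.reverse_complement().log_odds())):
        rel = _window_scores(codes, lod)
        for i in np.flatnonzero(rel >= min_rel_score - 1e-12):
            hits.append(
                TFBSHit(
                    tf_name=pfm.tf_name,
                    start=int(i) + 1,
                    end=int(i) + L,
                    strand=strand,
                    rel_score=float(min(rel[i], 1.0)),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand, h.tf_name))
    return hits


def map_and_score(
    hit: TFBSHit,
    aln: PromoterAlignment,
    other: str,
    human: str = "human",
) -> float:
    """Character-wise similarity of the orthologous site in ``other``.

    The hit span on the ungapped human promoter is mapped to alignment
    columns; the other species' characters at those columns are compared
    against the human characters (case-insensitive, gaps and N mismatch).
    Minus-strand sites are reverse-complemented on both sides first, which
    preserves the match count but mirrors the published procedure.
    """
    human_row = aln.row(human)
    other_row = aln.row(other)
    cols = [map_position(aln, human, p) for p in range(hit.start, hit.end + 1)]
    h_chars = "".join(human_row[c - 1] for c in cols)
    o_chars = "".join(other_row[c - 1] for c in cols)
    assert GAP not in h_chars, "human row cannot be gapped at its own positions"
    if hit.strand == "-":
        h_chars = reverse_complement(h_chars.replace(GAP, "N"))
        o_chars = reverse_complement(o_chars.replace(GAP, "N"))
    matches = sum(
        1
        for x, y in zip(h_chars.upper(), o_chars.upper())
        if x == y and x in BASES
    )
    return matches / (hit.end - hit.start + 1)


def classify_conservation(
    similarity_ts: float, similarity_ms: float, tau: float = DEFAULT_TAU
) -> str:
    """Conservation class from the two similarities; >= tau counts as shared."""
    for s in (similarity_ts, similarity_ms):
        if not 0.0 <= s <= 1.0:
            raise ValueError("similarities must lie in [0, 1]")
    ts = similarity_ts >= tau
    ms = similarity_ms >= tau
    if ts and ms:
        return "shared_both"
    if ts:
        return "shared_ts"
    if ms:
        return "shared_ms"
    return "human_specific"


def call_conservation(
    hits: Iterable[TFBSHit],
    aln: PromoterAlignment,
    tau: float = DEFAULT_TAU,
    human: str = "human",
    treeshrew: str = "treeshrew",
    mouse: str = "mouse",
) -> list[ConservationCall]:
    """Map, score and classify every hit against both non-human species."""
    calls = []
    for hit in hits:
        s_ts = map_and_score(hit, aln, treeshrew, human=human)
        s_ms = map_and_score(hit, aln, mouse, human=human)
        calls.append(
            ConservationCall(
                hit=hit,
                similarity_ts=s_ts,
                similarity_ms=s_ms,
                conservation_class=classify_conservation(s_ts, s_ms, tau),
            )
        )
    return calls


@dataclass
class ConservationSummary:
    counts: dict[str, int]
    percents: dict[str, float]
    positions: pd.DataFrame  # columns: aligned_column, conservation_class


def summarize_conservation(
    calls: Sequence[ConservationCall], aln: PromoterAlignment | None = None,
    human: str = "human",
) -> ConservationSummary:
    """Class counts/percentages over all human hits plus a positional table."""
    counts = {c: 0 for c in CLASSES}
    rows = []
    for call in calls:
        counts[call.conservation_class] += 1
        col = (
            map_position(aln, human, call.hit.start) if aln is not None else call.hit.start
        )
        rows.append(
            {
                "tf_name": call.hit.tf_name,
                "aligned_column": col,
                "conservation_class": call.conservation_class,
            }
        )
    total = sum(counts.values())
    percents = {
        c: (100.0 * n / total if total else 0.0) for c, n in counts.items()
    }
    positions = pd.DataFrame(rows, columns=["tf_name", "aligned_column", "conservation_class"])
    return ConservationSummary(counts=counts, percents=percents, positions=positions)


def calls_to_frame(calls: Sequence[ConservationCall]) -> pd.DataFrame:
    """Flatten calls for CSV export (tf, span, strand, scores, class)."""
    return pd.DataFrame(
        [
            {
                "tf_name": c.hit.tf_name,
                "start": c.hit.start,
                "end": c.hit.end,
                "strand": c.hit.strand,
                "rel_score": c.hit.rel_score,
                "sim_ts": c.similarity_ts,
                "sim_ms": c.similarity_ms,
                "conservation_class": c.conservation_class,
            }
            for c in calls
        ],
        columns=[
            "tf_name", "start", "end", "strand",
            "rel_score", "sim_ts", "sim_ms", "conservation_class",
        ],
    )
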
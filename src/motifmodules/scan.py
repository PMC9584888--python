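"""PWM scanning of sequences on both strands with La/Ld acceptance thresholds.

A window of matrix length is scored at every position of the forward strand;
the antisense strand is scored at the same forward-strand windows with the
reverse-complemented matrix.  A window is accepted as a hit when its score La
satisfies both thresholds:

    La >= la_min      (lower score threshold)
    Ld = Lm - La <= ld_max   (upper threshold on the deficit from the maximum)

Hits carry 1-based inclusive forward-strand coordinates and the forward-strand
oligo regardless of strand; sense hits are labelled ``N``, antisense ``R``.
Antisense matches apply only to DNA, so RNA mode restricts reporting to the
sense strand.  Windows containing the masked base N are unscorable and
silently skipped.  Overlapping hits are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrices import BASES, ScoringMatrix
from .sequences import SequenceRecord

__all__ = ["ScanParams", "MotifHit", "make_hit", "score_window",
           "scan_sequence", "scan_all", "encode_residues"]

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES + "N"):
    _ENCODE[ord(_b)] = _i

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

STRAND_SENSE = "N"
STRAND_ANTISENSE = "R"


@dataclass(frozen=True)
class ScanParams:
    """Acceptance thresholds for the scan.

    ``la_min`` is the minimum log2-odds score of a match (typical working
    values are 6-9) and ``ld_max`` the maximum allowed deficit Lm - La
    (typical 7-9).  ``rna_mode`` suppresses antisense (R) hits, which are
    meaningful for DNA only.
    """

    la_min: float
    ld_max: float
    rna_mode: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.la_min):
            raise ValueError("la_min must be finite")
        if not (self.ld_max >= 0):
            raise ValueError("ld_max must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    """One accepted match of a matrix on a sequence.

    ``start``/``stop`` are 1-based inclusive forward-strand coordinates;
    ``oligo`` is the forward-strand subsequence spanning them (not
    reverse-complemented for antisense hits).  ``ld`` is stored as exactly
    ``lm - la``.
    """

    sequence_name: str
    matrix_id: str
    matrix_name: str
    strand: str  # N = sense, R = antisense
    start: int
    stop: int
    la: float
    lm: float
    ld: float
    oligo: str

    def __post_init__(self) -> None:
        if self.strand not in (STRAND_SENSE, STRAND_ANTISENSE):
            raise ValueError(f"strand must be 'N' or 'R', got {self.strand!r}")
        if self.stop - self.start + 1 != len(self.oligo):
            raise ValueError("oligo length does not match coordinates")
        if self.ld != self.lm - self.la:
            raise ValueError("ld must equal lm - la exactly")


def make_hit(sequence_name: str, matrix: ScoringMatrix, strand: str,
             start: int, la: float, oligo: str) -> MotifHit:
    """Build a hit from a matrix match, deriving stop and Ld."""
    return MotifHit(
        sequence_name=sequence_name,
        matrix_id=matrix.matrix_id,
        matrix_name=matrix.name,
        strand=strand,
        start=start,
        stop=start + matrix.length - 1,
        la=float(la),
        lm=float(matrix.lm),
        ld=float(matrix.lm) - float(la),
        oligo=oligo,
    )


def encode_residues(residues: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as integers 0..4 (N = 4)."""
    enc = _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if np.any(enc < 0):
        raise ValueError("residues must be normalized to A/C/G/T/N")
    return enc


def _padded_weights(matrix: ScoringMatrix) -> np.ndarray:
    # column 4 scores the masked base N as NaN -> window unscorable
    return np.concatenate(
        [matrix.weights, np.full((matrix.length, 1), np.nan)], axis=1
    )


def score_window(matrix: ScoringMatrix, window: str) -> float | None:
    """Score one window of exactly matrix length; ``None`` if unscorable.

    The score is the sum over positions of the weight of the base observed
    there.  A window containing N has no defined score.
    """
    if len(window) != matrix.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {matrix.length}"
        )
    enc = encode_residues(window.upper())
    score = float(_padded_weights(matrix)[np.arange(matrix.length), enc].sum())
    return None if np.isnan(score) else score


def _window_scores(enc: np.ndarray, matrix: ScoringMatrix) -> np.ndarray:
    L = matrix.length
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    return _padded_weights(matrix)[np.arange(L), windows].sum(axis=1)


def scan_sequence(seq: SequenceRecord, matrix: ScoringMatrix,
                  params: ScanParams) -> list[MotifHit]:
    """All accepted hits of one matrix on one sequence, both strands.

    Returns hits sorted by (start, strand, matrix_id).  A matrix longer than
    the sequence yields an empty result.
    """
    L, n = matrix.length, seq.length
    if L > n:
        return []
    hits: list[MotifHit] = []

    # The antisense strand is scored by sliding the sense matrix over the
    # reverse-complemented sequence (equivalent to a reverse-complemented
    # matrix on the forward strand, but with the identical summation order,
    # so a perfect antisense match scores exactly Lm).
    strand_sequences = [(STRAND_SENSE, seq.residues)]
    if not params.rna_mode:
        rc = seq.residues.translate(_RC_TABLE)[::-1]
        strand_sequences.append((STRAND_ANTISENSE, rc))

    for strand, residues in strand_sequences:
        scores = _window_scores(encode_residues(residues), matrix)
        with np.errstate(invalid="ignore"):
            accept = (scores >= params.la_min) & ((matrix.lm - scores) <= params.ld_max)
        for pos in np.flatnonzero(accept):
            # map an antisense window back to forward-strand coordinates
            fwd0 = int(pos) if strand == STRAND_SENSE else n - L - int(pos)
            hits.append(make_hit(seq.name, matrix, strand, fwd0 + 1,
                                 scores[pos], seq.residues[fwd0:fwd0 + L]))
    hits.sort(key=lambda h: (h.start, h.strand, h.matrix_id))
    return hits


def scan_all(seqs: Sequence[SequenceRecord], matrices: Iterable[ScoringMatrix],
             params: ScanParams) -> dict[str, list[MotifHit]]:
    """Scan every matrix over every sequence.

    Returns hits grouped by sequence name (every input sequence gets an entry,
    possibly empty), each group sorted by (start, strand, matrix_id).
    """
    result: dict[str, list[MotifHit]] = {}
    matrices = list(matrices)
    for seq in seqs:
        hits: list[MotifHit] = []
        for matrix in matrices:
            hits.extend(scan_sequence(seq, matrix, params))
        hits.sort(key=lambda h: (h.start, h.strand, h.matrix_id))
        result[seq.name] = hits
    return result
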
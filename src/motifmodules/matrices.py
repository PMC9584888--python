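"""Motif count matrices, log-odds scoring matrices and the JASPAR text dialect.

A transcription-factor binding profile enters the package as a position
frequency matrix (PFM): one row of A/C/G/T counts per motif position, read
from JASPAR raw-PFM text or built from a set of equal-length consensus
sequences.  Against a background base distribution the PFM is converted into
a position weight matrix (PWM) of per-position log2-odds weights

    w[i][b] = log2( ((n[i][b] + p * bg[b]) / (N[i] + p)) / bg[b] )

where ``n[i][b]`` is the count of base ``b`` at position ``i``, ``N[i]`` the
column sum at that position, ``bg`` the background frequencies and ``p`` an
additive pseudocount distributed in proportion to the background.  With the
default uniform background a perfectly conserved position contributes
log2(1/0.25) = 2 to the score, so the maximum attainable score ``Lm`` (the
score of the consensus oligo) is bounded by twice the motif length.

Column sums are taken per position: JASPAR distributes matrices whose columns
do not all sum to the same depth, and those are accepted as-is.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as _bio_motifs

__all__ = [
    "BASES",
    "IUPAC_NUCLEOTIDES",
    "MatrixError",
    "JasparParseError",
    "BackgroundModel",
    "MotifCountMatrix",
    "ScoringMatrix",
    "parse_jaspar",
    "write_jaspar",
    "build_pfm_from_sequences",
    "pfm_to_pwm",
    "reverse_complement_matrix",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide one-letter codes mapped to the unambiguous bases they
#: denote.  U is the RNA alias of T.
IUPAC_NUCLEOTIDES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MatrixError(ValueError):
    """Invalid motif matrix or matrix construction input."""


class JasparParseError(MatrixError):
    """Malformed JASPAR raw-PFM text; the message names the offending record."""


@dataclass(frozen=True)
class BackgroundModel:
    """Background base distribution plus additive pseudocount.

    Parameters
    ----------
    freq:
        Frequencies of A, C, G, T; must be strictly positive and sum to 1.
        Default is the uniform 0.25 each.
    pseudocount:
        Non-negative total pseudocount added per matrix column, distributed
        across the bases in proportion to ``freq``.  The default of 1.0 keeps
        every weight finite for sparse count matrices while perturbing
        deep-count matrices negligibly; 0 is allowed and yields -inf weights
        for unobserved bases.
    """

    freq: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (4,):
            raise MatrixError("background must give exactly four base frequencies")
        if not np.all(f > 0):
            raise MatrixError("background frequencies must be strictly positive")
        if abs(float(f.sum()) - 1.0) > 1e-12:
            raise MatrixError(f"background frequencies must sum to 1, got {f.sum()!r}")
        if not (self.pseudocount >= 0):
            raise MatrixError("pseudocount must be non-negative")
        object.__setattr__(self, "freq", tuple(float(x) for x in f))

    @property
    def freq_array(self) -> np.ndarray:
        return np.asarray(self.freq, dtype=float)


@dataclass(frozen=True)
class MotifCountMatrix:
    """Per-position A/C/G/T counts for one motif (the PFM).

    ``counts`` has shape (L, 4) in base order A, C, G, T.  Counts may be
    fractional (consensus sets with degenerate IUPAC codes contribute 1/k per
    denoted base) and column sums may differ between positions.
    """

    matrix_id: str
    name: str
    counts: np.ndarray
    source: str = "user_counts"  # jaspar_file | user_consensus | user_counts

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
            raise MatrixError(
                f"matrix {self.matrix_id!r}: counts must have shape (L>=1, 4), got {c.shape}"
            )
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise MatrixError(f"matrix {self.matrix_id!r}: counts must be finite and non-negative")
        if np.any(c.sum(axis=1) == 0):
            raise MatrixError(f"matrix {self.matrix_id!r}: a position has all-zero counts")
        if self.source not in ("jaspar_file", "user_consensus", "user_counts"):
            raise MatrixError(f"matrix {self.matrix_id!r}: unknown source {self.source!r}")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)

    @property
    def length(self) -> int:
        return int(self.counts.shape[0])

    @property
    def consensus(self) -> str:
        """Most-frequent base per position (ties broken in A<C<G<T order)."""
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))


@dataclass(frozen=True)
class ScoringMatrix:
    """Per-position log2-odds weights (the PWM) with maximum score Lm.

    ``lm`` is the sum over positions of the per-position maximum weight, i.e.
    the score of the consensus oligo; it is stored but always recomputable
    from ``weights``.
    """

    matrix_id: str
    name: str
    weights: np.ndarray
    lm: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise MatrixError(
                f"matrix {self.matrix_id!r}: weights must have shape (L>=1, 4), got {w.shape}"
            )
        if np.any(np.isnan(w)):
            raise MatrixError(f"matrix {self.matrix_id!r}: weights must not be NaN")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        recomputed = float(w.max(axis=1).sum())
        if not math.isclose(self.lm, recomputed, rel_tol=0.0, abs_tol=1e-9):
            raise MatrixError(
                f"matrix {self.matrix_id!r}: stored Lm {self.lm} != recomputed {recomputed}"
            )

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])

    @property
    def consensus(self) -> str:
        """A maximum-scoring oligo (ties broken in A<C<G<T order)."""
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=1))


# ---------------------------------------------------------------------------
# JASPAR raw-PFM text


_HEADER_RE = re.compile(r"^>\s*(\S+)\s*(.*)$")


def _split_jaspar_records(text: str) -> list[tuple[str, str]]:
    """Split JASPAR text into (record_id, record_text) blocks."""
    blocks: list[tuple[str, list[str]]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            m = _HEADER_RE.match(line)
            rec_id = m.group(1) if m and m.group(1) else "<unnamed>"
            blocks.append((rec_id, [line]))
        else:
            if not blocks:
                raise JasparParseError("count row appears before any '>' header line")
            blocks[-1][1].append(line)
    return [(rid, "\n".join(lines) + "\n") for rid, lines in blocks]


def parse_jaspar(text: str) -> list[MotifCountMatrix]:
    """Parse JASPAR raw-PFM text into count matrices, in file order.

    Each record is a ``>ID NAME`` header followed by four labelled count rows
    (``A [ ... ]`` etc.).  Malformed records (missing base row, unequal row
    lengths, negative or non-numeric counts) raise :class:`JasparParseError`
    naming the record.
    """
    records = _split_jaspar_records(text)
    if not records:
        raise JasparParseError("no JASPAR records found in input")
    out: list[MotifCountMatrix] = []
    for rec_id, block in records:
        try:
            parsed = _bio_motifs.parse(io.StringIO(block), "jaspar")
        except Exception as exc:
            raise JasparParseError(f"record {rec_id!r}: {exc}") from exc
        if len(parsed) != 1:
            raise JasparParseError(
                f"record {rec_id!r}: expected a header and four labelled count rows"
            )
        motif = parsed[0]
        if motif.length == 0:
            raise JasparParseError(f"record {rec_id!r}: empty count rows")
        counts = np.column_stack([np.asarray(motif.counts[b], dtype=float) for b in BASES]).reshape(-1, 4)
        try:
            out.append(
                MotifCountMatrix(
                    matrix_id=motif.matrix_id or rec_id,
                    name=motif.name or "",
                    counts=counts,
                    source="jaspar_file",
                )
            )
        except MatrixError as exc:
            raise JasparParseError(f"record {rec_id!r}: {exc}") from exc
    return out


def _fmt_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_jaspar(matrices: Iterable[MotifCountMatrix]) -> str:
    """Render count matrices in the JASPAR raw-PFM dialect.

    Counts are written at full precision (integers without a decimal point)
    so that parse -> write -> parse is the identity.
    """
    chunks = []
    for m in matrices:
        header = f">{m.matrix_id}\t{m.name}".rstrip()
        rows = [
            f"{base} [ {' '.join(_fmt_count(x) for x in m.counts[:, i])} ]"
            for i, base in enumerate(BASES)
        ]
        chunks.append("\n".join([header, *rows]))
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# Construction and transforms


def build_pfm_from_sequences(
    seqs: Sequence[str], matrix_id: str, name: str = ""
) -> MotifCountMatrix:
    """Build a count matrix from equal-length IUPAC nucleotide strings.

    Each sequence contributes 1 per position: an unambiguous base gets the
    full unit, a degenerate IUPAC code (R, Y, N, ...) splits it as 1/k over
    the k bases it denotes.  U is treated as T.
    """
    if len(seqs) == 0:
        raise MatrixError("cannot build a matrix from an empty sequence list")
    length = len(seqs[0])
    if length == 0:
        raise MatrixError("consensus sequences must be non-empty")
    counts = np.zeros((length, 4), dtype=float)
    for si, seq in enumerate(seqs):
        if len(seq) != length:
            raise MatrixError(
                f"consensus sequences must all have the same length: "
                f"sequence {si + 1} has length {len(seq)}, expected {length}"
            )
        for i, ch in enumerate(seq.upper()):
            bases = IUPAC_NUCLEOTIDES.get(ch)
            if bases is None:
                raise MatrixError(
                    f"sequence {si + 1}: {ch!r} at position {i + 1} is not an IUPAC nucleotide code"
                )
            share = 1.0 / len(bases)
            for b in bases:
                counts[i, _BASE_INDEX[b]] += share
    return MotifCountMatrix(matrix_id=matrix_id, name=name or matrix_id, counts=counts,
                            source="user_consensus")


def pfm_to_pwm(pfm: MotifCountMatrix, bg: BackgroundModel | None = None) -> ScoringMatrix:
    """Convert counts to log2-odds weights and compute the maximum score Lm.

    With zero pseudocount an unobserved base gets weight -inf; such weights
    propagate through scanning as windows that can never pass a finite score
    threshold.
    """
    bg = bg or BackgroundModel()
    freq = bg.freq_array
    col_sums = pfm.counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        prob = (pfm.counts + bg.pseudocount * freq) / (col_sums + bg.pseudocount)
        weights = np.log2(prob / freq)
    lm = float(weights.max(axis=1).sum())
    return ScoringMatrix(matrix_id=pfm.matrix_id, name=pfm.name, weights=weights, lm=lm)


def reverse_complement_matrix(m: ScoringMatrix) -> ScoringMatrix:
    """Scoring matrix for the reverse-complement motif.

    Positions are reversed and bases complement-permuted; in A,C,G,T order the
    complement permutation is the reversal T,G,C,A, so both axes flip.  Lm is
    unchanged.
    """
    return ScoringMatrix(
        matrix_id=m.matrix_id,
        name=m.name,
        weights=m.weights[::-1, ::-1].copy(),
        lm=m.lm,
    )
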
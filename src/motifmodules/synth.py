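"""Synthetic promoter-set fixtures with implanted motifs and motif pairs.

The generator emulates the package's intended inputs: a handful of promoter
(or mRNA) sequences of a few hundred to a few thousand bases, drawn i.i.d.
from a background base distribution, into which exact consensus occurrences
of chosen matrices are implanted at known positions and strands — singly, or
as pairs at a fixed offset to plant a conserved module.  Ground truth (every
implant and every planted pair) is returned alongside the sequences, so scans
and module searches can be checked against known coordinates.

Being i.i.d., the background has none of the compositional structure of real
promoters (CpG islands, repeats, phylogenetic relatedness between the input
sequences); what it provides is a realistic false-positive floor for the
score thresholds and exact ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .matrices import BASES, MotifCountMatrix
from .sequences import SequenceRecord

__all__ = ["FixtureError", "Implant", "ModuleImplant", "FixtureSpec",
           "ImplantTruth", "ModuleTruth", "Fixture", "generate_fixture",
           "random_count_matrix"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FixtureError(ValueError):
    """Invalid fixture specification (e.g. overlapping implants)."""


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Implant:
    """One consensus occurrence to write into one sequence.

    ``position`` is the 1-based start on the forward strand; for strand R the
    reverse complement of the matrix consensus is written there.
    """

    matrix: MotifCountMatrix
    strand: str  # N | R
    position: int
    seq_index: int

    def __post_init__(self) -> None:
        if self.strand not in ("N", "R"):
            raise FixtureError("implant strand must be 'N' or 'R'")
        if self.position < 1:
            raise FixtureError("implant position must be >= 1 (1-based)")
        if self.seq_index < 0:
            raise FixtureError("implant seq_index must be >= 0")


@dataclass(frozen=True)
class ModuleImplant:
    """A motif pair planted at a fixed start-to-start offset in several sequences.

    The first member's start in each sequence is either given in ``anchors``
    (parallel to ``seq_indices``) or drawn uniformly from the valid range; the
    second member starts ``offset`` bases downstream (negative = upstream).
    Both members go on the sense strand.
    """

    matrix_a: MotifCountMatrix
    matrix_b: MotifCountMatrix
    offset: int
    seq_indices: tuple[int, ...]
    anchors: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.anchors is not None and len(self.anchors) != len(self.seq_indices):
            raise FixtureError("anchors must be parallel to seq_indices")
        if self.offset == 0:
            raise FixtureError("module implant offset must be non-zero")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic sequence set."""

    n_sequences: int = 3
    sequence_length: int = 1000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    implants: tuple[Implant, ...] = ()
    module_implants: tuple[ModuleImplant, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.sequence_length < 1:
            raise FixtureError("need at least one sequence of length >= 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.all(bg > 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise FixtureError("background must be four positive frequencies summing to 1")


@dataclass(frozen=True)
class ImplantTruth:
    """Ground-truth record of one written implant."""

    sequence_name: str
    matrix_id: str
    strand: str
    start: int
    stop: int
    oligo: str  # forward-strand oligo actually written


@dataclass(frozen=True)
class ModuleTruth:
    """Ground-truth record of one planted pair occurrence."""

    sequence_name: str
    matrix_id_a: str
    matrix_id_b: str
    start_a: int
    start_b: int
    offset: int


@dataclass(frozen=True)
class Fixture:
    """Generated sequences plus the implant/module ground truth."""

    spec: FixtureSpec
    records: tuple[SequenceRecord, ...]
    implant_truth: tuple[ImplantTruth, ...]
    module_truth: tuple[ModuleTruth, ...]

    @property
    def fasta(self) -> str:
        return "".join(f">{r.name}\n{r.residues}\n" for r in self.records)


def _place(seq: list[str], occupied: list[tuple[int, int]], start: int,
           oligo: str, seq_name: str) -> tuple[int, int]:
    """Write ``oligo`` at 1-based ``start``; error on out-of-bounds or overlap."""
    stop = start + len(oligo) - 1
    if stop > len(seq):
        raise FixtureError(
            f"{seq_name}: implant at {start}..{stop} extends past sequence end ({len(seq)})"
        )
    for a, b in occupied:
        if start <= b and a <= stop:
            raise FixtureError(
                f"{seq_name}: implant at {start}..{stop} overlaps implant at {a}..{b}"
            )
    seq[start - 1:stop] = list(oligo)
    occupied.append((start, stop))
    return start, stop


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the sequence set described by ``spec`` (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=float)
    base_arr = np.frombuffer("".join(BASES).encode(), dtype="S1")

    seqs: list[list[str]] = [
        [b.decode() for b in rng.choice(base_arr, size=spec.sequence_length, p=bg)]
        for _ in range(spec.n_sequences)
    ]
    names = [f"synthetic_seq_{i + 1}" for i in range(spec.n_sequences)]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(spec.n_sequences)]

    implant_truth: list[ImplantTruth] = []
    for imp in spec.implants:
        if imp.seq_index >= spec.n_sequences:
            raise FixtureError(f"implant seq_index {imp.seq_index} out of range")
        consensus = imp.matrix.consensus
        oligo = consensus if imp.strand == "N" else _revcomp(consensus)
        start, stop = _place(seqs[imp.seq_index], occupied[imp.seq_index],
                             imp.position, oligo, names[imp.seq_index])
        implant_truth.append(ImplantTruth(names[imp.seq_index], imp.matrix.matrix_id,
                                          imp.strand, start, stop, oligo))

    module_truth: list[ModuleTruth] = []
    for mod in spec.module_implants:
        cons_a, cons_b = mod.matrix_a.consensus, mod.matrix_b.consensus
        for k, si in enumerate(mod.seq_indices):
            if si >= spec.n_sequences:
                raise FixtureError(f"module implant seq_index {si} out of range")
            lo = 1 + max(0, -mod.offset)
            hi = spec.sequence_length - max(len(cons_a) - 1,
                                            mod.offset + len(cons_b) - 1)
            if hi < lo:
                raise FixtureError(
                    f"{names[si]}: no room for pair at offset {mod.offset}"
                )
            if mod.anchors is not None:
                start_a = mod.anchors[k]
                if not (lo <= start_a <= hi):
                    raise FixtureError(
                        f"{names[si]}: anchor {start_a} leaves the pair outside 1..{spec.sequence_length}"
                    )
            else:
                # draw an anchor clear of earlier implants (bounded retries)
                for _ in range(200):
                    cand = int(rng.integers(lo, hi + 1))
                    iv_a = (cand, cand + len(cons_a) - 1)
                    iv_b = (cand + mod.offset, cand + mod.offset + len(cons_b) - 1)
                    clash = any(a <= iv[1] and iv[0] <= b
                                for a, b in occupied[si] for iv in (iv_a, iv_b))
                    clash = clash or (iv_a[0] <= iv_b[1] and iv_b[0] <= iv_a[1])
                    if not clash:
                        start_a = cand
                        break
                else:
                    raise FixtureError(
                        f"{names[si]}: could not place pair at offset {mod.offset} without overlap"
                    )
            start_b = start_a + mod.offset
            _place(seqs[si], occupied[si], start_a, cons_a, names[si])
            _place(seqs[si], occupied[si], start_b, cons_b, names[si])
            implant_truth.append(ImplantTruth(names[si], mod.matrix_a.matrix_id, "N",
                                              start_a, start_a + len(cons_a) - 1, cons_a))
            implant_truth.append(ImplantTruth(names[si], mod.matrix_b.matrix_id, "N",
                                              start_b, start_b + len(cons_b) - 1, cons_b))
            module_truth.append(ModuleTruth(names[si], mod.matrix_a.matrix_id,
                                            mod.matrix_b.matrix_id, start_a, start_b,
                                            mod.offset))

    records = tuple(
        SequenceRecord(name=n, residues="".join(s), alphabet="dna")
        for n, s in zip(names, seqs)
    )
    return Fixture(spec=spec, records=records,
                   implant_truth=tuple(implant_truth),
                   module_truth=tuple(module_truth))


def random_count_matrix(rng: np.random.Generator, length: int,
                        matrix_id: str = "RAND", name: str = "",
                        depth: int = 20, conservation: float = 0.85) -> MotifCountMatrix:
    """Random information-rich count matrix for tests and demos.

    Each position gets ``depth`` observations; the position's consensus base
    (drawn uniformly) receives a fraction ``conservation`` of them in
    expectation, the rest spread over the other bases.
    """
    if not (0.25 < conservation <= 1.0):
        raise ValueError("conservation must be in (0.25, 1]")
    consensus = rng.integers(0, 4, size=length)
    probs = np.full((length, 4), (1.0 - conservation) / 3.0)
    probs[np.arange(length), consensus] = conservation
    counts = np.vstack([rng.multinomial(depth, p) for p in probs]).astype(float)
    counts[np.arange(length), consensus] += 1  # consensus never all-zero
    return MotifCountMatrix(matrix_id=matrix_id, name=name or matrix_id,
                            counts=counts, source="user_counts")
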
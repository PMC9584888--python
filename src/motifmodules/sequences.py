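"""Nucleotide FASTA input with validation and RNA normalization.

Sequences are validated to contain nucleotide characters only (IUPAC codes,
case-insensitive).  Internally everything is held in a DNA alphabet: uracils
are converted to thymine (recording that the record arrived as RNA), and
ambiguity codes other than N are masked to N — the scanner treats N-containing
windows as unscorable rather than inventing scores for them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .matrices import IUPAC_NUCLEOTIDES

__all__ = ["FastaError", "SequenceRecord", "read_fasta", "read_fasta_file"]

_VALID = set(IUPAC_NUCLEOTIDES)  # includes U and N
_KEEP = set("ACGTN")


class FastaError(ValueError):
    """Invalid FASTA input; the message names the record and bad character."""


@dataclass(frozen=True)
class SequenceRecord:
    """One validated nucleotide sequence.

    ``residues`` is the normalized A/C/G/T/N string; ``alphabet`` records
    whether the input contained uracil (``"rna"``) or not (``"dna"``).
    """

    name: str
    residues: str
    alphabet: str = "dna"  # dna | rna

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"record {self.name!r}: empty sequence")
        bad = set(self.residues) - _KEEP
        if bad:
            raise FastaError(f"record {self.name!r}: non-normalized character {sorted(bad)[0]!r}")
        if self.alphabet not in ("dna", "rna"):
            raise FastaError(f"record {self.name!r}: alphabet must be 'dna' or 'rna'")

    @property
    def length(self) -> int:
        return len(self.residues)


def _normalize(name: str, raw: str) -> SequenceRecord:
    seq = raw.upper()
    has_u = False
    out = []
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise FastaError(
                f"record {name!r}: invalid nucleotide character {ch!r} at position {i + 1}"
            )
        if ch == "U":
            has_u = True
            out.append("T")
        elif ch in _KEEP:
            out.append(ch)
        else:  # degenerate IUPAC code: mask
            out.append("N")
    return SequenceRecord(name=name, residues="".join(out),
                          alphabet="rna" if has_u else "dna")


def read_fasta(text: str) -> list[SequenceRecord]:
    """Parse multi-FASTA text into validated, normalized records.

    Record order is preserved; duplicate header names get an ordinal suffix
    (``name_2``, ``name_3``, ...) so that downstream tables keyed on the name
    stay unambiguous.  Raises :class:`FastaError` on empty input or any
    non-nucleotide character, naming the record and the first bad character.
    """
    entries = [(rec.description or rec.id, str(rec.seq))
               for rec in SeqIO.parse(io.StringIO(text), "fasta")]
    if not entries:
        raise FastaError("no FASTA records found in input")
    seen: dict[str, int] = {}
    records = []
    for name, raw in entries:
        seen[name] = seen.get(name, 0) + 1
        unique = name if seen[name] == 1 else f"{name}_{seen[name]}"
        records.append(_normalize(unique, raw))
    return records


def read_fasta_file(path: str | Path) -> list[SequenceRecord]:
    """Read and validate a multi-FASTA file (CRLF and line wrapping tolerated)."""
    return read_fasta(Path(path).read_text())
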
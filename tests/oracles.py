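"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive plain-Python: per-window score sums
over dict lookups and exhaustive pair enumeration, with no shared code path
with the package's vectorized scanner or module search.
"""

from __future__ import annotations

import math
from itertools import combinations

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def weights_as_dicts(weights) -> list[dict[str, float]]:
    """(L, 4) array -> list of per-position {base: weight} dicts."""
    return [{b: float(row[i]) for i, b in enumerate(BASES)} for row in weights]


def rc_weight_dicts(wd: list[dict[str, float]]) -> list[dict[str, float]]:
    return [{b: pos[_COMP[b]] for b in BASES} for pos in reversed(wd)]


def naive_window_score(wd: list[dict[str, float]], window: str) -> float | None:
    """Sum of per-position weights; None when the window contains N."""
    if "N" in window:
        return None
    return sum(pos[c] for pos, c in zip(wd, window))


def naive_scan(residues: str, weights, lm: float, la_min: float, ld_max: float,
               rna_mode: bool = False) -> set[tuple[str, int, float]]:
    """All accepted (strand, 1-based start, score) triples, brute force."""
    wd = weights_as_dicts(weights)
    strands = [("N", wd)] + ([] if rna_mode else [("R", rc_weight_dicts(wd))])
    L = len(wd)
    out: set[tuple[str, int, float]] = set()
    for strand, w in strands:
        for pos in range(len(residues) - L + 1):
            score = naive_window_score(w, residues[pos:pos + L])
            if score is None:
                continue
            if score >= la_min and (lm - score) <= ld_max:
                out.add((strand, pos + 1, round(score, 9)))
    return out


def exhaustive_modules(starts_by_seq_by_identity: dict[str, dict[str, list[int]]],
                       window_bp: int, min_shared: int) -> set[tuple[str, str]]:
    """Brute-force conserved-pair enumeration.

    ``starts_by_seq_by_identity``: identity -> sequence name -> hit starts.
    Returns the set of (member_a, member_b) pairs (a < b) supported within
    the window by at least ``min_shared`` sequences.
    """
    idents = sorted(starts_by_seq_by_identity)
    out: set[tuple[str, str]] = set()
    for a, b in combinations(idents, 2):
        supporting = 0
        seqs = set(starts_by_seq_by_identity[a]) & set(starts_by_seq_by_identity[b])
        for seq in seqs:
            found = any(
                abs(sb - sa) <= window_bp
                for sa in starts_by_seq_by_identity[a][seq]
                for sb in starts_by_seq_by_identity[b][seq]
            )
            if found:
                supporting += 1
        if supporting >= min_shared:
            out.add((a, b))
    return out
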
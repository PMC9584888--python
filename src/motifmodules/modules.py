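"""Cross-sequence conservation filtering and conserved-module detection.

A motif identity (a matrix, or a matrix x strand combination when strand
orientation is taken into account) is *conserved* when it has at least one
accepted hit in at least ``n_required`` of the input sequences; all hits of
non-conserved identities are discarded before the module search.

A *module* is an unordered pair of two distinct conserved motif identities
occurring within a fixed positional window of each other (default +/- 200 bp,
measured start-to-start on forward-strand coordinates).  The pair is reported
when at least ``min_shared`` (default 2) input sequences each contain such a
co-occurrence; every witnessing hit pair and its signed offset is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement
from typing import Mapping

from .scan import MotifHit

__all__ = ["ConservationParams", "ModuleParams", "ModuleWitness", "Module",
           "hit_identity", "filter_conserved", "find_modules"]


@dataclass(frozen=True)
class ConservationParams:
    """Conservation filter settings.

    ``n_required`` is the minimum number of input sequences a motif must hit
    to be kept.  ``strand_specific`` counts conservation per (matrix, strand)
    rather than per matrix; it defaults to on because strand orientation is
    part of a binding site's identity in this filtering step.
    """

    n_required: int
    strand_specific: bool = True

    def __post_init__(self) -> None:
        if self.n_required < 1:
            raise ValueError("n_required must be >= 1")


@dataclass(frozen=True)
class ModuleParams:
    """Module search settings: window in bp, minimum sharing, self-pair flag."""

    window_bp: int = 200
    min_shared: int = 2
    allow_self_pairs: bool = False

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_shared < 2:
            raise ValueError("min_shared must be >= 2")


@dataclass(frozen=True)
class ModuleWitness:
    """One co-occurrence of a module's members in one sequence.

    ``offset`` is the signed start-to-start distance start(b) - start(a) on
    forward-strand coordinates; |offset| never exceeds the window.
    """

    hit_a: MotifHit
    hit_b: MotifHit
    offset: int


@dataclass(frozen=True)
class Module:
    """An unordered pair of conserved motifs with its supporting evidence.

    ``member_a`` <= ``member_b`` lexicographically; ``support`` maps each
    supporting sequence name to its witnessing hit pairs.
    """

    member_a: str
    member_b: str
    support: Mapping[str, tuple[ModuleWitness, ...]]

    @property
    def n_shared(self) -> int:
        return len(self.support)


def hit_identity(hit: MotifHit, strand_specific: bool) -> str:
    """Motif identity key used for conservation counting and module members."""
    return f"{hit.matrix_id}/{hit.strand}" if strand_specific else hit.matrix_id


def filter_conserved(
    hits_by_seq: Mapping[str, list[MotifHit]], params: ConservationParams
) -> tuple[set[str], dict[str, list[MotifHit]]]:
    """Drop every hit whose motif identity is not conserved widely enough.

    ``hits_by_seq`` must have one entry per input sequence (empty lists
    included) so the sequence universe is known.  Returns the conserved
    identity set and the retained hits, grouped as given, hits unchanged.
    """
    n_seqs = len(hits_by_seq)
    if n_seqs < 1:
        raise ValueError("hits from at least one sequence are required")
    if params.n_required > n_seqs:
        raise ValueError(
            f"n_required={params.n_required} exceeds the number of input sequences ({n_seqs})"
        )
    seqs_per_identity: dict[str, set[str]] = {}
    for seq_name, hits in hits_by_seq.items():
        for hit in hits:
            seqs_per_identity.setdefault(hit_identity(hit, params.strand_specific),
                                         set()).add(seq_name)
    conserved = {ident for ident, seqs in seqs_per_identity.items()
                 if len(seqs) >= params.n_required}
    retained = {
        seq_name: [h for h in hits
                   if hit_identity(h, params.strand_specific) in conserved]
        for seq_name, hits in hits_by_seq.items()
    }
    return conserved, retained


def find_modules(
    hits_by_seq: Mapping[str, list[MotifHit]],
    params: ModuleParams,
    strand_specific: bool = True,
) -> list[Module]:
    """Enumerate conserved modules among already conservation-filtered hits.

    Every unordered pair of distinct motif identities is tested; a sequence
    supports a pair when some hit of one member and some hit of the other lie
    within ``window_bp`` of each other (start-to-start).  Pairs supported by
    at least ``min_shared`` sequences are returned, sorted by member names.
    ``strand_specific`` must match the setting used for conservation
    filtering so that member identities line up.
    """
    # identity -> per-sequence hit lists
    by_identity: dict[str, dict[str, list[MotifHit]]] = {}
    for seq_name, hits in hits_by_seq.items():
        for hit in hits:
            ident = hit_identity(hit, strand_specific)
            by_identity.setdefault(ident, {}).setdefault(seq_name, []).append(hit)

    identities = sorted(by_identity)
    pair_iter = (combinations_with_replacement(identities, 2) if params.allow_self_pairs
                 else combinations(identities, 2))

    modules: list[Module] = []
    for ident_a, ident_b in pair_iter:
        support: dict[str, tuple[ModuleWitness, ...]] = {}
        seqs_a, seqs_b = by_identity[ident_a], by_identity[ident_b]
        for seq_name in sorted(set(seqs_a) & set(seqs_b)):
            witnesses = []
            for ha in seqs_a[seq_name]:
                for hb in seqs_b[seq_name]:
                    if ident_a == ident_b and hb.start <= ha.start:
                        continue  # self-pair: count each unordered hit pair once
                    offset = hb.start - ha.start
                    if abs(offset) <= params.window_bp:
                        witnesses.append(ModuleWitness(ha, hb, offset))
            if witnesses:
                support[seq_name] = tuple(witnesses)
        if len(support) >= params.min_shared:
            modules.append(Module(member_a=ident_a, member_b=ident_b, support=support))
    modules.sort(key=lambda m: (m.member_a, m.member_b))
    return modules
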
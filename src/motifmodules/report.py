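"""Tabular reporting, BED export, summary counts and the end-to-end pipeline.

The hit table reproduces the tool's spreadsheet schema: one row per accepted
match with the sequence, matrix length, strand (N sense / R antisense),
1-based inclusive coordinates, the scores La and Lm, their difference
Ld = Lm - La, and the forward-strand oligo.  Scores are printed with six
decimal places; TSV and XLSX exports carry identical rows.

The summary reports both occurrence- and matrix-level tallies — "motifs" is
the total number of accepted hits, "tfbs" the number of distinct matrices
with at least one hit — because either reading of a scan's yield is useful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matrices import ScoringMatrix
from .modules import (ConservationParams, Module, ModuleParams,
                      filter_conserved, find_modules)
from .scan import MotifHit, ScanParams, scan_all
from .sequences import SequenceRecord

__all__ = ["HIT_COLUMNS", "MODULE_COLUMNS", "ReportBundle", "hits_to_table",
           "modules_to_table", "export_bed", "summarize", "run_pipeline",
           "write_outputs"]

HIT_COLUMNS = [
    "Sequence Name",
    "Sequence Length",
    "Matrix Length",
    "Hit Sense",
    "Hit Start",
    "Hit Stop",
    "Hit Score (La)",
    "Hit Max log likelihood ratio score (Lm)",
    "Difference (Ld)",
    "Hit Oligo",
]

MODULE_COLUMNS = [
    "Member A",
    "Member B",
    "Shared Sequences",
    "Sequence Name",
    "A Start",
    "A Stop",
    "B Start",
    "B Stop",
    "Offset",
]

_SCORE_FMT = "{:.6f}".format


def hits_to_table(hits_by_seq: Mapping[str, Sequence[MotifHit]],
                  seq_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Hit table with the spreadsheet schema; scores as 6-decimal strings."""
    rows = []
    for seq_name, hits in hits_by_seq.items():
        for h in hits:
            rows.append({
                "Sequence Name": h.sequence_name,
                "Sequence Length": seq_lengths[seq_name],
                "Matrix Length": h.stop - h.start + 1,
                "Hit Sense": h.strand,
                "Hit Start": h.start,
                "Hit Stop": h.stop,
                "Hit Score (La)": _SCORE_FMT(h.la),
                "Hit Max log likelihood ratio score (Lm)": _SCORE_FMT(h.lm),
                "Difference (Ld)": _SCORE_FMT(h.ld),
                "Hit Oligo": h.oligo,
            })
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def modules_to_table(modules: Sequence[Module]) -> pd.DataFrame:
    """Module table: one row per witnessing hit pair."""
    rows = []
    for m in modules:
        for seq_name in sorted(m.support):
            for w in m.support[seq_name]:
                rows.append({
                    "Member A": m.member_a,
                    "Member B": m.member_b,
                    "Shared Sequences": m.n_shared,
                    "Sequence Name": seq_name,
                    "A Start": w.hit_a.start,
                    "A Stop": w.hit_a.stop,
                    "B Start": w.hit_b.start,
                    "B Stop": w.hit_b.stop,
                    "Offset": w.offset,
                })
    return pd.DataFrame(rows, columns=MODULE_COLUMNS)


def export_bed(hits: Iterable[MotifHit]) -> str:
    """BED6 text: 0-based half-open intervals, score = La, strand +/-."""
    lines = []
    for h in hits:
        strand = "+" if h.strand == "N" else "-"
        lines.append("\t".join([
            h.sequence_name, str(h.start - 1), str(h.stop),
            f"{h.matrix_id}|{h.matrix_name}", f"{h.la:.3f}", strand,
        ]))
    return "\n".join(lines) + ("\n" if lines else "")


def summarize(hits_by_seq: Mapping[str, Sequence[MotifHit]],
              conserved: set[str], modules: Sequence[Module]) -> dict:
    all_hits = [h for hits in hits_by_seq.values() for h in hits]
    return {
        "sequences": len(hits_by_seq),
        "motifs": len(all_hits),                                  # hit occurrences
        "tfbs": len({h.matrix_id for h in all_hits}),             # distinct matrices
        "conserved_motifs": len(conserved),
        "modules": len(modules),
    }


@dataclass(frozen=True)
class ReportBundle:
    """Everything one pipeline run produced."""

    hits_by_seq: dict[str, list[MotifHit]]
    conserved: set[str]
    retained_by_seq: dict[str, list[MotifHit]]
    modules: list[Module]
    hit_table: pd.DataFrame
    module_table: pd.DataFrame
    summary: dict


def run_pipeline(seqs: Sequence[SequenceRecord],
                 matrices: Sequence[ScoringMatrix],
                 scan_params: ScanParams,
                 conservation_params: ConservationParams | None = None,
                 module_params: ModuleParams | None = None) -> ReportBundle:
    """Scan, conservation-filter and module-search; assemble all tables.

    With ``conservation_params`` omitted, every hit is retained (equivalent to
    ``n_required=1``) and the module search still runs over all hits when
    ``module_params`` is given; with ``module_params`` omitted no module
    search is performed.
    """
    hits_by_seq = scan_all(seqs, matrices, scan_params)
    strand_specific = True
    if conservation_params is not None:
        strand_specific = conservation_params.strand_specific
        conserved, retained = filter_conserved(hits_by_seq, conservation_params)
    else:
        conserved = {f"{h.matrix_id}/{h.strand}"
                     for hits in hits_by_seq.values() for h in hits}
        retained = {k: list(v) for k, v in hits_by_seq.items()}
    modules = (find_modules(retained, module_params, strand_specific=strand_specific)
               if module_params is not None else [])
    seq_lengths = {s.name: s.length for s in seqs}
    return ReportBundle(
        hits_by_seq=hits_by_seq,
        conserved=conserved,
        retained_by_seq=retained,
        modules=modules,
        hit_table=hits_to_table(hits_by_seq, seq_lengths),
        module_table=modules_to_table(modules),
        summary=summarize(hits_by_seq, conserved, modules),
    )


def write_outputs(bundle: ReportBundle, out_prefix: str | Path,
                  bed: bool = False) -> dict[str, Path]:
    """Write TSV, XLSX, JSON summary (and optionally BED) under a prefix.

    Returns the paths written.  Repeated runs on identical inputs produce
    byte-identical TSV/BED/JSON.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["hits_tsv"] = prefix.with_name(prefix.name + "_hits.tsv")
    bundle.hit_table.to_csv(paths["hits_tsv"], sep="\t", index=False)
    paths["modules_tsv"] = prefix.with_name(prefix.name + "_modules.tsv")
    bundle.module_table.to_csv(paths["modules_tsv"], sep="\t", index=False)

    paths["xlsx"] = prefix.with_name(prefix.name + ".xlsx")
    with pd.ExcelWriter(paths["xlsx"], engine="openpyxl") as xw:
        bundle.hit_table.to_excel(xw, sheet_name="hits", index=False)
        bundle.module_table.to_excel(xw, sheet_name="modules", index=False)

    paths["summary_json"] = prefix.with_name(prefix.name + "_summary.json")
    paths["summary_json"].write_text(json.dumps(bundle.summary, indent=2,
                                                sort_keys=True) + "\n")

    if bed:
        paths["bed"] = prefix.with_name(prefix.name + "_hits.bed")
        all_hits = [h for hits in bundle.hits_by_seq.values() for h in hits]
        paths["bed"].write_text(export_bed(all_hits))
    return paths
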
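# motifmodules

Motif scanning and conserved-module detection in nucleic-acid sequences.

`motifmodules` answers a common question in regulatory genomics: given a set
of related sequences — promoters of a gene family, enhancer candidates,
mRNAs, lncRNAs — which transcription-factor binding sites (TFBSs) or other
short motifs occur in them, which of those are *conserved* across the set,
and which *pairs* of conserved motifs co-occur closely enough to form a
candidate cis-regulatory module?  Single-sequence motif prediction
overpredicts heavily; demanding conservation across related sequences, and
co-occurrence of motif pairs, are the classic ways to cut the false-positive
load.

## The model

Motifs are described by position frequency matrices (PFMs): per-position
A/C/G/T counts, read from JASPAR raw-PFM text or built in-tool from
equal-length consensus sequences (IUPAC degenerate codes contribute
fractionally).  A PFM with counts *n<sub>ib</sub>* is converted against a
background distribution *bg* with additive pseudocount *p* into a position
weight matrix (PWM) of log-odds weights

```
w[i][b] = log2( ((n[i][b] + p·bg[b]) / (N[i] + p)) / bg[b] )
```

where *N<sub>i</sub>* is the column sum at position *i*.  With the default
uniform background each position can contribute at most
log₂(1/0.25) = 2 to a score.

Every window of matrix length on both strands is scored with
*La* = Σᵢ w[i][baseᵢ]; the matrix maximum *Lm* (the consensus score) defines
the deficit *Ld* = *Lm* − *La*.  A window is a hit when

```
La ≥ la_min     and     Ld = Lm − La ≤ ld_max
```

so `la_min` is the lower score threshold and `ld_max` caps how far below the
consensus a match may fall.  Hits are reported in 1-based inclusive
forward-strand coordinates, sense strand `N`, antisense `R`; antisense
matches apply only to DNA, so RNA mode (uracils are converted internally to
thymine) reports the sense strand only.

Downstream, a motif is **conserved** when it hits at least *N* of the input
sequences (strand orientation counts by default), and a **module** is an
unordered pair of distinct conserved motifs whose hits lie within ±200 bp of
each other (start-to-start) in at least two input sequences.

## Worked example

Generate a synthetic three-promoter set with a planted poly(A)-signal
consensus in each sequence, then scan it with the built-in poly(A) hexamer
matrix, keep motifs conserved in all 3 sequences, and search for modules:

```
$ motifmodules fixture --n-sequences 3 --length 1000 --seed 11 --out promoters.fasta
wrote promoters.fasta and promoters.truth.tsv

$ motifmodules scan promoters.fasta --polya --la 7 --ld 3 \
      --conserved-in 3 --find-modules --bed --out-prefix demo
sequences: 3
motifs (hit occurrences): 15
TFBSs (distinct matrices hit): 1
conserved motifs: 1
modules: 0
```

15 windows pass La ≥ 7 and Ld ≤ 3; they all belong to the one poly(A) matrix
(1 distinct TFBS), which is conserved in all three sequences; with a single
matrix there is no motif *pair*, so no modules.  The hit table
(`demo_hits.tsv`, mirrored sheet-for-sheet in `demo.xlsx`) starts:

```
Sequence Name    Sequence Length  Matrix Length  Hit Sense  Hit Start  Hit Stop  Hit Score (La)  Hit Max log likelihood ratio score (Lm)  Difference (Ld)  Hit Oligo
synthetic_seq_1  1000             6              N          37         42        7.119652        9.842118                                 2.722466         GATAAA
synthetic_seq_1  1000             6              N          69         74        7.967649        9.842118                                 1.874469         TATAAA
```

Each row is one accepted window: `GATAAA` at 37–42 scores La = 7.119652
against the matrix maximum Lm = 9.842118, a deficit Ld = 2.722466 — a
single-base variant of the canonical `AATAAA`, which itself appears at the
implanted coordinate (334–339) with Ld = 0.000000.  `demo_hits.bed` holds the
same hits as BED6 (0-based half-open, score = La, strand +/−), and
`demo_summary.json` the summary counts.  Both the occurrence count ("motifs")
and the distinct-matrix count ("TFBSs") are always printed, since either can
be the quantity of interest.

The same pipeline is available as a library:

```python
from motifmodules import (read_fasta_file, parse_jaspar, pfm_to_pwm,
                          ScanParams, ConservationParams, ModuleParams,
                          run_pipeline)

seqs = read_fasta_file("promoters.fasta")
pwms = [pfm_to_pwm(p) for p in parse_jaspar(open("matrices.jaspar").read())]
bundle = run_pipeline(seqs, pwms, ScanParams(la_min=6, ld_max=8),
                      ConservationParams(n_required=3), ModuleParams())
print(bundle.summary)          # {'sequences': ..., 'motifs': ..., 'modules': ...}
bundle.hit_table               # pandas DataFrame, spreadsheet schema
```

## File formats

* **Input**: multi-FASTA (DNA or RNA; validated, U→T, ambiguity codes → N);
  JASPAR raw-PFM text (`>ID NAME` header + four bracketed count rows, also
  written back in the same dialect); consensus-set text files (one sequence
  per line, optional `#ID NAME` first line).
* **Output**: TSV hit table (UTF-8, header exactly as above), XLSX workbook
  with `hits` and `modules` sheets containing the identical rows, BED6, and a
  JSON summary.  Scores print with six decimals; repeated runs are
  byte-identical.

## Scope

The package is the computational core only: no web front-end, interactive
figure rendering or database service, and no TRANSFAC matrix ingestion.
Scores are not calibrated to p-values, and the background model is
zeroth-order (no dinucleotide composition).
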
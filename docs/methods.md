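# Methods

## Scoring model

A motif of length *L* is a position frequency matrix (PFM) of per-position
A/C/G/T counts.  Counts need not be normalized: JASPAR distributes matrices
whose column sums differ between positions, so the conversion to weights uses
each column's own sum *N<sub>i</sub>* rather than a single matrix-wide depth.
Fractional counts are legal — a consensus set containing IUPAC degenerate
codes contributes 1/k to each of the k denoted bases, preserving one unit of
evidence per sequence per position.

The position weight matrix (PWM) is

    w[i][b] = log2( ((n[i][b] + p·bg[b]) / (N[i] + p)) / bg[b] )

with background frequencies `bg` (default uniform 0.25) and additive
pseudocount `p` (default 1.0, distributed in proportion to the background).
The log base is 2 and anchors the score scale: with a uniform background a
perfectly conserved position contributes exactly log₂(1/0.25) = 2, and no
weight can exceed log₂(1/min bg).  The matrix maximum

    Lm = Σᵢ maxᵦ w[i][b]

is the score of the consensus oligo.  A window scores
La = Σᵢ w[i][base at i]; the acceptance test is La ≥ `la_min` together with
Ld = Lm − La ≤ `ld_max`, so `la_min` is an absolute floor and `ld_max` a cap
on the deficit relative to the best this matrix can do.  Typical working
values are La 6–9 and Ld 7–9; raising La or lowering Ld strictly shrinks the
hit set (monotonicity is part of the test suite).

### Pseudocount choice

The default p = 1.0 keeps all weights finite for sparse count matrices while
shifting deep-count JASPAR matrices by a negligible amount.  p = 0 is
supported: unobserved bases then get weight −∞, which propagates correctly —
a window containing such a base can never pass a finite `la_min`, so
zero-pseudocount matrices behave as exact-ish consensus matchers.  Scan
results at fixed thresholds do depend on p; published hit counts obtained
with an unknown pseudocount convention are therefore not reproducible
bit-for-bit, only in magnitude.

## Strand handling and coordinates

Both strands are scanned over the forward-strand window grid.  The antisense
strand is implemented by sliding the *sense* matrix over the
reverse-complemented sequence and mapping window positions back to
forward-strand coordinates.  This is mathematically identical to scanning a
reverse-complemented matrix on the forward strand (in A,C,G,T order the
complement permutation is the base-axis reversal, so the reverse-complement
matrix is `weights[::-1, ::-1]`), but it keeps the floating-point summation
order identical on both strands: a perfect antisense match scores *exactly*
Lm, and its Ld is exactly 0.0, not 0 up to an ulp.

Hits carry 1-based inclusive coordinates (stop − start + 1 = L) and the
forward-strand oligo on both strands; BED export converts to 0-based
half-open.  Sense hits are labelled `N`, antisense `R`.  RNA input (detected
by the presence of U, which is converted to T on read) is scanned in RNA mode
on the sense strand only, since an antisense match has no meaning on a
single-stranded molecule.

Windows containing N are unscorable and skipped silently: N arises from
masked or ambiguous input positions (ambiguity codes other than N are
normalized to N on read, rather than rejected, because public promoter
records do contain them), and fabricating a score for an unknown base would
bias both tails.  Overlapping hits are all retained.

## Conservation filter

A motif identity — (matrix, strand) by default — is conserved when it has at
least one hit in at least `n_required` distinct input sequences; hits of
non-conserved identities are dropped, retained hits are passed through
unchanged.  Strand-specific counting is the default because the strand
orientation of a binding site is part of its identity in this filtering step;
`strand_specific=False` pools both strands per matrix for use cases (e.g.
palindromic or orientation-independent elements) where that is too strict.
`n_required` must not exceed the number of input sequences; that is a
parameter error, not an empty result.

## Module search

All unordered pairs of distinct conserved identities are enumerated.  A
sequence supports a pair when some hit of one member and some hit of the
other lie within `window_bp` (default 200) of each other, measured
start-to-start on forward-strand coordinates — the simplest convention
consistent with a "± window" rule; witnesses record the signed offset
start(B) − start(A).  A pair becomes a module when at least `min_shared`
(default 2) sequences support it.  Two deliberate non-constraints: offsets
need not be similar across the supporting sequences (the sharing rule is
about co-occurrence, not geometry; an offset-consistency constraint is a
possible extension), and self-pairs (A,A) are excluded by default behind an
`allow_self_pairs` flag, since a module is read as two *distinct* binding
sites.  Modules of more than two members are out of scope.

The enumeration is exhaustive, O(Σ pairs × hits²) in the worst case, which is
ample at the intended scale (a handful of sequences, hundreds of retained
hits); the test suite checks it against an independent brute-force oracle.

## Synthetic fixtures

`generate_fixture` emulates the package's input: `n_sequences` i.i.d.
background sequences (default 3 × 1000 bp, uniform base composition — the
scale of a typical promoter-set comparison) into which motif consensus
strings are implanted at known positions/strands, singly or as pairs at a
fixed offset.  Implants that would overlap raise an error rather than
silently corrupting the ground truth; randomly anchored pair implants retry
placement a bounded number of times.  Generation is a pure function of the
spec including its seed.

What the fixtures do show: exact recovery of implants at their coordinates
with Ld = 0, module recovery against the enumeration oracle, and a
false-positive floor matching the analytic i.i.d. rate (for a 10-mer
consensus over 1 kb of uniform background, ≈ 2·991·4⁻¹⁰ exact matches per
sequence, verified by Monte Carlo over 200 seeds).  What they do not show:
behaviour on real promoters, which have CpG islands, repeats and phylogenetic
correlation between input sequences; conservation counts on real gene
families will differ from the i.i.d. baseline, and thresholds should be
chosen per study.

## Numerical and formatting choices

* Scores print with six decimal places in all tables; TSV and XLSX carry the
  same formatted strings so the two exports are row-identical and
  diff-stable.  BED scores round to three decimals.
* Consensus extraction from a PFM/PWM breaks ties in A < C < G < T order.
* Hit ordering is (start, strand, matrix id); module ordering is by member
  names; both make repeated runs byte-identical.
* The JASPAR writer emits counts at full precision (integers without a
  decimal point) so parse → write → parse is the identity including
  fractional counts.
* The scan pipeline itself has no randomness; only fixture generation takes
  a seed, which is why the CLI exposes `--seed` on `fixture` and not on
  `scan`.

## Test and acceptance problem sizes

The acceptance-style checks run at desk scale, chosen to exercise the
documented invariants well inside a minute or two on one core: scanner ≡
brute-force oracle on 50 random instances (sequences up to 2 kb, up to 20
matrices each), implant and module recovery over 20 seeded fixtures each,
threshold monotonicity over 50 random parameter pairs, strand symmetry over
10 instances, and format round-trips over 20 matrices.  The acceptance
script measures its counts on 3 × 1000 bp promoter sets with 6 matrices and
its recovery rates over 10 fixtures (≈130 implants).

## Known limitations

* Zeroth-order background only; no dinucleotide or positional composition
  model, and no p-value calibration of La — thresholds are on the log-odds
  scale directly.
* Position independence is assumed (plain PWM); variable-length or
  interdependent motifs (e.g. HMM-based flexible models) are not supported.
* Conservation is presence/absence per sequence; no weighting by hit count,
  score, or phylogenetic distance.
* In-silico matches indicate in-vitro binding potential at best; nothing
  here models chromatin state or factor abundance.
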
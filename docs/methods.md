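# Methods

`ribotail` implements two analyses that together characterise a
translation phenotype driven by defective quality control of the
signal-recognition-particle RNA (7SL): a ribosome-profiling arm that
quantifies translation efficiency and positional ribosome density on
transcripts, and a cRACE arm that reconstructs exact RNA 3' ends and
models non-templated uridylation. A synthetic-data module generates
both read types with exact ground truth so every stage has
parameter-recovery tests without external sequencing data.

## Ribosome-profiling arm

### RPF filtering and A-site inference

A ribosome-protected fragment (RPF) is kept when it is uniquely mapped,
28–31 nt long, and its inferred A site lies inside the CDS in the zero
reading frame. The A site is taken at a fixed offset of +15 nt from the
fragment's 5' end for all retained lengths; with a fixed offset, frame
filtering at the A site is equivalent to filtering on the 5'-end frame.
Rejections are counted per rule (first failing rule wins) so library
quality is auditable from `filter_report.json`. Filtering is idempotent
by construction.

Coordinates are 0-based half-open transcript coordinates throughout;
SAM input (transcript-space) is converted at the boundary and reduced
to forward-strand primary records, with uniqueness taken from the NH
tag when present.

### Codon occupancy

For each A-site event, the raw positional count at its codon is divided
by the *basal occupancy* of that position — the mean of the raw counts
at the +1, +2 and +3 codons downstream within the same gene. Per-codon
occupancy is the mean of these per-event ratios grouped by A-site codon
identity. This self-normalisation has the defining property that a
library with positionally uniform coverage yields occupancy exactly 1.0
for every codon; values above 1 indicate dwell-time excess at that
codon relative to its local downstream context. Events with fewer than
three downstream CDS codons, or whose basal window is empty, are
excluded from normalisation and counted separately; they still
contribute to raw counts. Note that with sparse counts the ratio
estimator is biased upward (occupied positions condition on count ≥ 1,
and 1/basal is convex), so absolute occupancies from shallow libraries
should be compared between conditions, not interpreted singly.

### Metagene profiles

Each CDS is rescaled to 50 bins (codon index `i` of an `n`-codon CDS
maps to bin `floor(50·i/n)`), the binned counts are divided by the
gene's total RPF count, and profiles are averaged across genes with
equal weight — so highly expressed genes do not dominate the shape.
Genes below `min_rpf = 32` reads are dropped; genes shorter than 50
codons are kept but flagged (their bins receive zero or multiple
codons). Each per-gene profile sums to one, hence so does the mean.

### Translation efficiency

TE is RPF abundance on the CDS divided by mRNA abundance. Counts are
converted to CPM over *testable* genes (mRNA count ≥ 10 in every mRNA
library, RPF count ≥ 10 in at least one RPF library); TE per replicate
is `(rpf_cpm + 0.5) / (mrna_cpm + 0.5)` pairing RPF and mRNA libraries
by replicate, and per-condition TE is the geometric mean over
replicates. The pseudocount (0.5) and count floor (10) stabilise ratios
at low counts; CPM rather than raw counts makes replicates of different
depth comparable. Differential translation uses the 2-fold rule:
`|log2(te_KO / te_CTRL)| ≥ 1`, inclusive at the boundary; genes that
are not testable are reported as such rather than silently dropped.

### Enrichment and codon usage

Enrichment of signal-peptide / transmembrane annotations among
up/down-called genes uses a two-sided Fisher's exact test
(point-probability convention) on a 2×2 table over the testable
background only — genes that could not be called carry no information
about the calls. Codon-usage comparison between gene sets uses CDS
sense-codon frequencies (stop codons excluded), a per-codon
two-proportion z test, and Benjamini–Hochberg correction across the 61
sense codons. CDS composition, not A-site occupancy, is the primary
codon statistic; occupancy tables are available for the latter.

## cRACE arm

### Junction location and tail calling

Circularisation RACE reads have the layout
`[3' segment][non-templated tail][5' anchor]`. The 5' anchor (the
reference's first `five_prime_anchor_len` nt, exact match) must occur
exactly once in the read; ambiguity or absence fails the read with a
reason code — the caller discards, never guesses. The 3' terminus is
placed by the longest prefix of the pre-anchor segment matching
contiguously and uniquely in the mature sequence (minimum 12 nt).

Tail partitioning is *templated-first (greedy maximal)*: from the
matched terminus, read nucleotides that continue the template — mature
sequence first, then the downstream genomic extension once the
canonical end is crossed — are consumed as templated; only the
remainder is tail. This is forced by the biology: a Pol III terminator
leaves four templated U's downstream of the canonical end, and those
must never be counted as a tail. Consequently a read ending in exactly
four U's past the canonical end is a genomic extension (offset +4,
empty tail), and a fifth U becomes a 1-nt tail. A read is *uridylated*
when its non-templated tail contains ≥ 5 consecutive U. The greedy rule
makes uridylation calls conservative: tails that happen to continue the
template are shortened, occasionally below the 5-U threshold. A
companion field applies the ≥5-U rule to the raw post-terminus segment
(templated U's included) so the two conventions can be compared
explicitly; they are never merged.

### Logistic model

The probability of uridylation is modelled as
`P(U-tail) = logistic(β0 + β1·x)` with `x` the truncation depth in nt
(`x = −end_offset`; genomic extension enters as negative truncation, a
single signed axis; a switch restricts the fit to non-extended reads).
The fit is Newton–Raphson on the log-likelihood (gradient tolerance
1e-8, max 50 iterations, step halving on overshoot), standard errors
from the observed information. Complete and quasi-complete separation
are detected up front from the outcome-conditional ranges of `x` and
flagged, with coefficients reported as unbounded instead of iterating
to overflow. The fitter is validated against an iteratively refined
grid search of the likelihood surface and against an independent
library implementation.

## Synthetic data: what it emulates, and what it does not

The ribosome-profiling generator draws per-gene read counts
multinomially with weight (mRNA abundance × TE), so library depth is
fixed and gene counts are realistically coupled. Defaults define the
stated world of the tests: 2000 genes of 80–400 codons; mRNA abundance
log-normal with σ = 1 (typical bulk expression spread); TE multipliers
(KO/CTRL) log-normal with σ = 0.15 (modest biological TE variation)
except 20 planted genes at ratio 0.4; signal-peptide flags on 25% of
genes and transmembrane on 10% (roughly the mammalian secretome /
membrane proteome fraction); read lengths 28–31 at (0.2, 0.3, 0.3,
0.2); 95% unique mappers; frame fidelity 0.9 — off-frame reads are
injected deliberately so the zero-frame filter has work to do. The
5'-CDS stall of signal-peptide genes in the knockout is a positional
density multiplier (default 5× over the first 25 codons), renormalised
within the gene, so gene totals reflect TE only and metagene shape is
decoupled from TE calling: the expected fraction of a stalled L-codon
gene's reads in the first k codons has the closed form
`s·k / (s·k + (L − k))`, which the tests check.

The cRACE generator samples a 3' terminus (canonical 15%, genomic
extension +1..+4 with 10%, otherwise geometric truncation with p = 0.08
capped at 150 nt — the real truncation spectrum is not known, so the
distribution is config-exposed, not asserted as biological truth), then
uridylates with the logistic model (defaults β0 = −3, β1 = 0.25/nt) and
appends a 5 + Poisson(2) U tail, or with 10% probability a
sub-threshold 1–4 U tail on non-uridylated reads. Reads are error-free
by default; a uniform substitution rate can stress junction detection.
Truth tables store the greedy-canonical form of each read's end offset
and tail (computed by an in-simulator normalisation independent of the
caller), so exact per-read comparison is well defined even when a
sampled tail continues the template.

What a green test does *not* establish: no ligation or PCR bias, no
position-dependent sequencing error, no rRNA/tRNA contamination (the
real pipeline removes those upstream), no isoform ambiguity (one
transcript per gene), and no per-length A-site offset variation.
Because generated tails can continue the template, the *called*
uridylation data are slightly attenuated relative to the generative
logistic parameters; the parameter-recovery benchmark therefore draws
(x, y) directly from the generative model, while pipeline exactness is
covered by the per-read truth comparison.

## Numerical choices and degenerate inputs

- Fisher's two-sided p via the point-probability criterion; zero
  margins return p = 1 with a degeneracy flag; the sample odds ratio is
  `ad/bc` with 0/0 → NaN and x/0 → inf, flagged rather than raised.
- TE of non-testable genes is NaN, never 0 or dropped rows; calls
  propagate `not_testable`.
- Metagene bin mapping uses floor on integer codon indices — no
  fractional interpolation, so profiles are exactly unit-sum.
- Logistic separation detection precedes iteration; shuffling input
  order cannot change the fit (closed-form objective).
- All writers emit fixed float precision (`%.6g`) and deterministic
  column order; run manifests contain no timestamps, so a fixed seed
  reproduces every output byte-for-byte.

## Known limitations

- One fixed A-site offset for all read lengths; libraries whose offset
  varies by length need upstream correction.
- The occupancy estimator's small-sample upward bias (see above).
- Junction detection is exact-match; highly degraded reads fail with a
  reason code instead of being rescued by approximate matching (a
  ≤1-mismatch knob exists for the anchor but gapped alignment does not).
- The codon-usage statistic treats codons as independent within a set
  (two-proportion test); within-gene correlation is ignored.
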
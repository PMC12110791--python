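# Methods

`cnvpop` re-creates, at desk scale, the downstream half of a
population-resequencing CNV study: per-sample CNV calls from several
callers are filtered and merged into consensus calls, pooled across the
cohort into CNV regions (CNVRs), genotyped from windowed read depth, and
scanned for between-population divergence with the Vst statistic.  The
upstream half — read QC, alignment, and the CNV callers themselves — is
out of scope: the pipeline starts from caller *output* files.

## Coordinate and data conventions

All intervals are 0-based half-open (BED-like).  GFF3 input and output is
converted at the I/O boundary.  Chromosome names are matched exactly — no
`chr`-prefix normalisation — because silent renaming corrupts overlap
counts.  Callers are abstracted to three roles: `RD` (single-sample
read-depth), `PAIRED` (discordant/split-read-pair) and `POPRD`
(population-aware read-depth).  Only deletions and duplications are
modelled; inversions and translocations are rejected at parse time.

## Call filtering

A call is retained when its p-value is below 0.001, its fraction of
zero-mapping-quality reads (q0) is below 0.5, and it spans strictly more
than 1 kb.  All three comparisons are strict: a call of exactly 1000 bp is
removed.  Quality fields the caller does not report pass vacuously, so
pair-based callers are filtered on length alone.  The filter is pure and
idempotent.

## Consensus merging

The SURVIVOR-style merge is re-implemented as a graph construction: calls
from *different* callers in the same sample are linked when they share a
type and reciprocally overlap at ≥ 50% (overlap divided by each call's own
length).  Connected components supported by ≥ 2 distinct callers — and by
the anchor caller `POPRD` by default, mirroring a design in which the
population-aware caller defines the base set — emit one consensus call at
the per-coordinate medians (floored for even component sizes, a
deterministic tie-break).  Consensus quality is conservative: minimum
p-value, maximum q0, mean of reported CN estimates.  All knobs
(`min_callers`, overlap fraction, type requirement, anchor) are exposed;
`anchor=None` gives the plain union-of-two-callers reading.

## CNVR construction and the landscape summary

Across the cohort, any two calls sharing ≥ 1 bp merge transitively into
one region spanning the union; *touching* half-open intervals share no
base and stay separate.  No reciprocal-overlap requirement applies at this
stage — that constraint already acted within samples.  Regions are
classified gain (duplications only), loss (deletions only) or both, then
class-specific caps apply: loss and mixed regions longer than 50 kb and
gain regions longer than 500 kb are *discarded*, not truncated, because
truncation would invent breakpoints (regions exactly at the cap are kept:
"did not exceed").  The summary reports type counts, total and mean length
(floored to integer bp, with the exact ratio also stored), the covered
genome fraction relative to the supplied layout, and a half-open size
histogram [0,2), [2,5), [5,10), [10,∞) kb.

## Read-depth genotyping

Copy number per CNVR per sample is `CN = 2·r/m`, with `m` the sample's
mean windowed depth over all windows and `r` the overlap-weighted mean
depth of the windows intersecting the region (partial windows contribute
by overlap fraction).  The estimator is scale-invariant in sequencing
depth — exactly so in real arithmetic, bitwise for power-of-two rescalings
— and produces a dense matrix; regions without depth coverage are imputed
at the diploid value 2 and flagged in a mask.  Keeping *all* windows in
`m` keeps the estimator simple at the cost of a small upward bias in the
baseline when variant loci are included: at the default simulated locus
load (~2% of the genome, gains dominating) the bias is ≲ 1–2% of CN and is
far below the Poisson noise floor.  No GC correction is applied (the
synthetic tracks are GC-free); a per-chromosome correction callback is
accepted for real data.

## Annotation and enrichment

Context uses a fixed precedence over the whole region span: exonic ≻
intronic ≻ upstream ≻ downstream ≻ intergenic, with upstream/downstream
defined strand-aware within a 1 kb flank.  Gene *assignment* is
independent of the label and strand-ignorant: every gene whose span ± 1 kb
intersects the region is associated with it.  QTL intersection first
removes catalogue entries spanning ≥ 5 Mb (the interval is read as the
confidence interval; wide intervals carry little positional information),
then reports every ≥ 1 bp (CNVR, QTL) pair with distinct-count summaries.
Enrichment is an explicit upper-tail hypergeometric test per term over a
user-supplied term→gene map, Benjamini–Hochberg adjusted across tested
terms; raw and adjusted values are both reported so either convention
(raw p < 0.01 for GO-style lists, raw p < 0.05 for pathway-style lists, or
FDR) can be thresholded downstream.

## Vst divergence

For one population pair, per region,

    Vst = (Vt − Vs) / Vt,   Vs = (n1·V1 + n2·V2) / (n1 + n2),

with all variances divisor-n (population variance, the classical
convention for this statistic; the divisor is configurable for sensitivity
checks).  `Vt = 0` (copy-number invariant region) yields Vst = 0 rather
than NaN so the ranking stays total; negative values are retained in
records and means.  Outliers are called either as the descending top 5%
(ceil(0.05·N), deterministic cnvr_id tie-break) or as records strictly
above a percentile of the distribution (default 98th), computed with
linear interpolation between order statistics — percentile definitions
differ across ecosystems, so one is pinned.  Outlier genes are the
deduplicated union of each outlier region's nearby-gene set.

## Synthetic cohort

The generator emulates the downstream products of a 27-sample,
three-population cattle resequencing cohort.  Defaults (the study
conditions): populations NY:7, PN:10, XN:10; genome 3 × 10 Mb; 60 shared
and 12 divergent loci; log-uniform locus lengths 2–20 kb; carrier
frequencies uniform in [0.3, 0.8]; breakpoint jitter N(0, 50 bp) rounded;
per-caller false-negative rate 5% and false-positive (decoy) rate 2%;
depth 30 reads per 1 kb window, Poisson-distributed per window (depth is a
count; no overdispersion is modelled).

Design choices worth knowing:

* **Integer truth.**  Deletion carriers have CN 1 (80%) or 0; duplication
  carriers CN 3–6.  Integer truth makes genotyper bias directly
  measurable.
* **Window-aligned loci ≥ 2 windows.**  Read-depth callers resolve
  breakpoints at bin resolution anyway; alignment makes the noiseless
  limit exactly recoverable, and the 2 kb floor keeps truth above the
  strict >1 kb filter even after jitter.
* **Divergent loci.**  Each cycles a target pair: the first population is
  fixed diploid, the second fixed at the shifted CN (so the target pair's
  expected Vst is exactly 1), and the third population is a 50/50 mixture,
  giving the non-target pairs intermediate divergence and each locus a
  unique "correct" pair.  Expected Vst is computed exactly from the
  assigned copy numbers with self-contained arithmetic — the analysis
  module is tested against it, not with it.
* **Decoy false positives** are placed clear of true loci and drawn
  independently per caller, so the ≥ 2-caller consensus removes them; they
  exercise the merge logic rather than surviving into CNVRs.
* One integer-seeded NumPy generator drives every draw in fixed order, so
  a seed fixes the cohort byte-for-byte across platforms.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: GC and mappability bias, overdispersed or
correlated depth noise, caller-specific breakpoint biases beyond symmetric
jitter, mixed gain/loss loci (synthetic cohorts therefore contain no
"both"-class CNVRs — that classification path is covered by
constructed-call tests), linkage between loci, and relatedness within
populations.

## Problem sizes and numerics

The shipped configurations — 27 samples, 72 loci, 30 Mb genome, 30,000
depth windows per sample — run the full pipeline in a few seconds and give
the acceptance suite comfortable statistical margins: genotyping MAE ~0.10
copies for loci ≥ 5 windows (bound: 0.25), and 12/12 planted divergent
loci in the correct pair's top-5% outlier set (bound: ≥ 10/12).  Vst
agreement with a brute-force two-pass variance oracle is required to
1e-12; the noiseless-cohort Vst match to the truth table to 1e-9.
Degenerate inputs have pinned behaviour: empty CNVR sets summarize to a
flagged all-zero record, all-zero depth tracks raise, empty Vst record
lists raise, terms with no query overlap are skipped.

## Known limitations

The genotyper's global-mean baseline includes variant windows (see above);
a baseline-masking variant would remove the bias at the cost of coupling
genotyping to the CNVR set.  Vst significance is rank-based only — no
permutation test is provided (a hook point exists at the record level).
BED export of CNVRs is lossy by format; the TSV table is the
full-fidelity interchange.  VCF structural-variant ingestion is a future
adapter; call tables are the supported input.
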
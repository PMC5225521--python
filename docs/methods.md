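# Methods

This note documents the statistical models, the defaults and the design
choices behind chromreg, and what the synthetic-data generators do and do
not emulate.

## Expression: normalization and DEG calling

Size factors are the median-of-ratios estimator: for sample j,
`s_j = median_i k_ij / g_i` with `g_i` the across-sample geometric mean
of gene i, restricted to genes with strictly positive counts everywhere
(genes with any zero are excluded from the median and reported). The
estimator assumes most genes are unchanged between samples; a global
shift (e.g. every gene truly 2-fold up) is absorbed into the size factor
by construction. Scaling one library by c rescales the normalized matrix
only by the global constant c^(1/m), because the geometric-mean
reference moves with it — cross-sample structure is invariant.

DEG calling is by joint threshold, not a statistical test: a gene is
called iff `|log2((t+p)/(v+p))| ≥ log2_min` and `|t−v| ≥ diff_min` on
normalized values, defaults 0.75 and 50. Choices made where the
procedure was open:

* **Pseudocount** p = 1 normalized read enters the ratio only, so zero
  counts stay finite while the absolute-difference criterion remains on
  the unmodified values. Consequence: a fold sitting exactly at the
  ratio threshold is nudged infinitesimally below it whenever t > v, so
  exact-boundary behaviour is only observable with p = 0 (how the test
  suite exercises the inclusive comparisons).
* **The difference criterion applies to normalized counts** (ratios are
  computed after normalization; mixing raw counts into the difference
  would compare incompatible scales).
* Both comparisons are inclusive (≥).

`length_normalize` divides a normalized expression value by the gene's
composite (union) exon length, yielding the density used when relating
expression to promoter openness.

## Chromatin: DHS processing and ΔDHS

Peaks are 0-based half-open; GTF is converted on read and written
1-based inclusive. Filtering retains a peak iff it has ≥ 20 reads in the
sample **and** in the undigested input control (boundary inclusive) and
shares no base with a blacklist interval. Merging is the transitive
closure over gaps ≤ 100 bp with read counts summed; it is idempotent.
Feature annotation assigns each peak the first matching class in the
fixed priority promoter > 5'UTR > 3'UTR > exon > intron > intergenic,
with the promoter defined as 2000 bp strand-aware upstream of each
transcript TSS. With multi-transcript genes a peak inside one
transcript's intron frequently overlaps another transcript's exon and is
labelled exon — the priority is a reporting convention, not a biological
claim.

The change score on the unified m-peak set is

    ΔDHS_i = sqrt(n_i^T / (Σ n^T / m)) − sqrt(n_i^V / (Σ n^V / m)),

i.e. each count is scaled by its condition's mean reads-per-DHS before
the square root. This symmetric form is adopted deliberately: it makes
the score antisymmetric under condition swap (verified to machine
precision over random peak sets), and it gives the per-condition terms
unit mean square (`Σ n_i/(Σ/m) = m`). A condition with zero total reads
contributes a zero term with a warning. Selection keeps Δ ≥ 0.20;
closing sites (Δ ≤ −0.20) are available behind the `direction` argument
since downward selection is a symmetric question.

TSS openness is the expression-weighted coverage of ±1000 bp windows
around each transcript TSS. "Coverage" is the number of reads
overlapping the window (each read counted once), chosen over mean depth
for integer stability. Weights are transcript expression shares of the
gene total; fallbacks, in order: a gene unexpressed in the scored
condition borrows the other condition's weights; unexpressed in both
uses the maximum single-window coverage. The open/closed call puts a
gene in the closed class iff its coverage is ≤ the first-quintile order
statistic (index ⌈0.2 n⌉ of the sorted coverages); the inclusive
boundary means a gene exactly at the cut is closed, and fully tied
coverages degenerate to all-closed with a warning. Fewer than 5 genes:
everything open, warned.

## Motifs: PWM construction, exact calibration, scanning

PWMs come from weighted position count matrices with constant column sum
W > 1: `S = ln((x + a q) / ((W + a) q))`, pseudocount `a = ln W`.
Background frequencies are estimated from the forward strands of the
scanned sequence set (ambiguous bases excluded; uniform fallback for an
empty set).

Threshold calibration computes the exact distribution of the window
score over i.i.d. background w-mers by dynamic programming after
discretizing scores to multiples of 1e-4 natural-log units; the
threshold is the smallest achievable score with upper tail ≤ p (default
0.001), +inf with a warning when no word qualifies. Scanning uses the
same integer grid, so threshold and scan decisions cannot disagree by
rounding; the reported hit score is the exact float log-odds sum. The DP
tail is tested against brute-force enumeration of all 4^w words for
every bundled matrix (agreement ≤ 1e-8, in practice machine epsilon).
Both strands are scanned, reverse-strand hits reported in forward
coordinates; windows containing an ambiguous base produce no hit;
overlapping hits are all kept, since downstream counts are site counts.

The bundled matrices under `data/motifs/` are synthetic constructions
for testing and calibration (the `synthetic_` prefix marks this); they
are not curated database motifs.

## Enrichment and co-localization

Foreground = promoter-associated regions of upregulated genes;
background = those of all other genes. A region touching promoters of
both an upregulated and another gene goes to the foreground, keeping the
sets disjoint. Expected sites = background hits / background scanned
length × foreground scanned length; the ratio is observed/expected.
"Scanned length" is the summed length of the scanned regions
themselves. Report tables round half-up to two decimals with full
precision retained. Candidate selection keeps motifs with ratio > 1 in
one line and < 1 in the other whose TF is expressed (≥ `min_reads`) in
the enriched line, ranked by the enriched ratio, top 15.

Co-localization: a TF hit is co-localized with a SMAD-binding element
(CAGACA, GTCT, CAGC, CGCC, GGCGCC, GCCGnCGC; both strands, exact IUPAC
match) iff the minimal gap between the intervals is ≤ 200 bp (overlap =
0). The binomial null probability is the fraction of valid scan offsets
in the scanned regions whose window would be co-localized by position
alone — the test therefore asks for spatial association beyond what SBE
density already implies. One-sided upper test; undefined (NA) with zero
hits. Short GC-rich elements are dense in GC-balanced sequence, so null
probabilities near 1 (and uninformative tests) are expected for the
4-mers; the longer elements carry the signal.

## Survival screening

Median split with ties assigned to the low group (deterministic and
order-independent); patients with missing expression are dropped with a
logged count. The log-rank statistic is computed from the risk tables
(`(Σ(O−E))²/ΣV`, hypergeometric variance per distinct event time, χ²(1)
two-sided p), which also yields the worse-prognosis direction from the
sign of O−E in the high group. The implementation is verified
digit-identical to lifelines and to R `survival::survdiff` on shared
data. BH adjustment delegates to statsmodels behind the `bh_adjust`
surface.

A calibration caveat established while validating: with all-event
cohorts of 100 patients the χ²(1) reference is measurably liberal for
this statistic (empirical level ≈ 0.06 at nominal 0.05 over 10⁴
simulations — an asymptotics artifact, identical in lifelines/R, not an
implementation defect). Null-calibration studies in the test suite and
acceptance script therefore use 200-patient cohorts, where the measured
long-run level is 0.050.

## Synthetic data: what it emulates, what it does not

All generators derive independent named substreams from one global seed
(`default_rng([seed, stream_id])`), so adding a generator never perturbs
the draws of another, and identical seeds give byte-identical outputs.

* **Annotation**: non-overlapping 2–6 kb genes on one chromosome, 2–4
  exons per transcript, CDS spans yielding UTRs, strand-aware 2000 bp
  promoters guaranteed inside the chromosome. No overlapping genes,
  nested genes, or alternative promoters at realistic density.
* **Counts**: log-normal gene baselines scaled to the target depth,
  per-sample library-size factors in [0.7, 1.3], negative-binomial
  sampling with **var = (1 + φ)·mean** (constant Fano factor; φ = 0 is
  Poisson). This parameterization models read-sampling overdispersion
  for a single library pair; it is deliberately not the quadratic
  var = μ + φμ² law used for biological replicate variability, which
  would make single-sample threshold DE calling meaningless at high
  counts (log2-ratio noise ≈ 0.46 at φ = 0.05 regardless of depth). With
  one library per condition and no replicates there is no biological
  variance component to estimate, matching the thresholding design.
* **DHS peaks**: placement in promoter/intron/intergenic compartments
  (defaults 0.20/0.45/0.35, intron-heavy like basal open-chromatin
  distributions; configurable), log-normal intensities, Poisson counts,
  planted openness folds in the treated condition, flat Poisson input
  control. No fragment-size, mappability, or peak-shape modeling.
* **Promoters**: i.i.d. bases at the stated GC content with consensus
  strings inserted at recorded non-overlapping offsets, Poisson counts
  per promoter at separate foreground/background rates. No dinucleotide
  structure, CpG islands, or repeats — enrichment nulls on this
  background are cleaner than on real promoters.
* **Survival**: exponential event times with a group hazard ratio tied
  to above/below-median expression; censoring is an independent
  exponential time with rate `base_hazard · c/(1−c)` for target censored
  fraction c (non-informative by construction; an earlier
  censor-at-fraction-of-event-time scheme was rejected because its
  informative censoring visibly inflated the log-rank null). No
  covariates, no proportional-hazards violations.

Passing tests on these generators demonstrate that the pipeline recovers
planted structure under its own model assumptions; they do not
demonstrate robustness to real-data pathologies (batch effects,
GC-dependent coverage, peak-calling artifacts, non-proportional
hazards).

## Problem sizes and defaults

The pipeline defaults simulate 100 genes, 300 peaks, 10 planted DEGs at
log2 fold 2, dispersion 0.05, depth 10⁶, 20 differential DHSs at 4-fold
openness, and 100-patient cohorts at hazard ratio 2 with 20% censoring.
Calibration studies use 20 simulation seeds (DEG recovery), 200
resamples (enrichment null), 1000 random peak sets (ΔDHS antisymmetry)
and 500 cohorts of 200 patients (log-rank null). These sizes make every
example and check complete in seconds while keeping Monte-Carlo
intervals tight enough to be meaningful.

## Known limitations

* The DEG criterion has no error control; it reproduces a thresholding
  design faithfully rather than improving on it.
* The enrichment test yields ratios, not p-values; formal inference on
  ratios would need a count model over regions.
* The co-localization null accounts for SBE positional density but not
  for sequence composition shared between the TF motif and the SBE;
  GC-rich motifs co-located with GC-rich elements will look associated
  on real sequence for compositional reasons.
* The quintile open/closed boundary is a visualization convention; the
  inclusive tie rule makes fully degenerate coverage vectors all-closed.
* `score_threshold` discretization (1e-4 log units) bounds threshold
  error at w·5e-5; matrices with near-tied scores at the cut may include
  or exclude words within that band.
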
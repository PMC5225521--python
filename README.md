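# chromreg

Integrated RNA-seq + DNase-seq analysis of condition-specific
transcriptional response, built around the question: *when a signaling
ligand (e.g. BMP4) triggers divergent phenotypes in different cell lines,
which transcription factors acting on already-open promoter chromatin
drive the difference?* The package implements the complete downstream
analysis as a tested, reusable library — from raw count tables and DHS
peak sets to candidate transcription factors — together with a
synthetic-data module that generates every input with planted ground
truth, so each stage's recovery behaviour is verifiable.

It is aimed at computational biologists who have per-gene read counts,
DNase-seq peak sets with read counts, promoter sequences and position
count matrices, and want the full chain of threshold-based differential
expression, differential chromatin scoring, exact-p-value motif scanning,
background-normalized binding-site enrichment and survival screening
without re-deriving each step.

## The statistics at the core

**Differential expression.** Counts are normalized with median-of-ratios
size factors, `s_j = median_i k_ij / (∏_j k_ij)^{1/m}` over genes with no
zero count. A gene is differentially expressed iff
`|log2((t+1)/(v+1))| ≥ 0.75` **and** `|t − v| ≥ 50` on normalized values.

**Differential DNase hypersensitivity.** On the unified peak set of m
DHSs, each site's change score compares its read share to the mean
reads-per-DHS of its condition:

```
ΔDHS_i = sqrt( n_i^treated / (Σ_k n_k^treated / m) )
       − sqrt( n_i^vehicle / (Σ_k n_k^vehicle / m) )
```

Sites with `ΔDHS ≥ 0.20` are selected as treatment-opened chromatin.

**Motif scanning.** A weighted position count matrix (WPCM) with column
total W becomes a log-odds PWM via
`S_{b,i} = ln((x_{b,i} + a·q_b) / ((W + a)·q_b))` with pseudocount
`a = ln W` and background frequencies `q`. A window scores
`M_j = Σ_i S_{b(i+j),i}`; the match threshold is calibrated **exactly**:
the distribution of `M` over i.i.d. background words is computed by
dynamic programming on a 1e-4 log-unit score grid, and the threshold is
the smallest score with upper tail ≤ 0.001.

**Enrichment.** For each motif, the expected foreground site count is the
background hit density times the scanned foreground length; the
enrichment ratio is observed/expected. Candidate TFs are enriched in one
cell line, depleted in the other, and expressed where enriched.
Co-localization of TF hits with SMAD-binding elements within 200 bp is
tested with a one-sided binomial test whose null probability is the
positional fraction of co-localizable scan offsets.

**Survival.** Patients are split at the median expression per gene, the
groups compared with the unweighted log-rank test
(`χ² = (Σ(O−E))²/ΣV`, hypergeometric variance per event time), and
p-values Benjamini-Hochberg adjusted.

## Worked example

```sh
python examples/01_differential_expression.py
```

```
size factors: {'vehicle': 0.806, 'treated': 1.2408}
called 10 DEGs; planted 10
gene_id  log2_ratio       diff direction
  g0001       1.995  39748.627        up
  ...
recovered 10/10 planted genes, 0 false positives
```

Ten genes were planted with a log2 fold of 2 among 100; after
normalization all ten exceed both thresholds (log2 ratios ≈ 2, normalized
differences far above 50) and no unplanted gene is called. The other
examples walk through ΔDHS scoring (`02`), exact threshold calibration
and scanning (`03`, threshold 4.2703 at p ≤ 0.001 recovering 48/48
planted sites), enrichment and co-localization (`04`, foreground ratio
1.79 for a 6-fold planted rate difference), survival screening (`05`) and
the end-to-end pipeline (`06`).

A thin CLI wraps the pipeline: `chromreg --seed 1 --outdir out run-all`
followed by `chromreg --outdir out report`.

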
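"""Call differentially expressed genes on simulated counts.

Generates a 100-gene annotation, draws negative-binomial read counts with
10 genes planted at log2 fold 2, normalizes both libraries with
median-of-ratios size factors, and applies the dual threshold
(|log2 ratio| >= 0.75 and normalized count difference >= 50).
"""

from chromreg import (
    call_degs,
    compute_size_factors,
    generate_annotation,
    generate_counts,
    normalize,
)

genes = generate_annotation(n_genes=100, transcripts_per_gene=1, chrom_length=4_000_000, seed=1)
vehicle, treated, truth = generate_counts(
    genes, n_de=10, log2_fold=2.0, dispersion=0.05, depth=1e6, seed=1
)

counts = vehicle.join(treated)
factors = compute_size_factors(counts)
norm = normalize(counts, factors)
degs = call_degs(norm["vehicle"], norm["treated"])

print(f"size factors: {factors.factors.round(4).to_dict()}")
print(f"called {len(degs)} DEGs; planted {len(truth.de_genes)}")
print(degs.head(10).round(3).to_string(index=False))
recovered = set(degs.gene_id) & set(truth.de_genes)
print(f"recovered {len(recovered)}/{len(truth.de_genes)} planted genes, "
      f"{len(set(degs.gene_id) - set(truth.de_genes))} false positives")
# Each row is one gene passing both thresholds: log2_ratio is the
# pseudocounted normalized expression ratio, diff the normalized read
# difference, direction the sign of the response.
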
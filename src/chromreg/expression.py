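"""Count normalization and threshold-based differential expression.

Normalization is the DESeq2-style median-of-ratios: each sample's size
factor is the median, over genes with strictly positive counts in every
sample, of the ratio of that gene's count to its across-sample geometric
mean. Differential expression is called by a dual threshold on the
normalized per-condition values: |log2 ratio| >= 0.75 AND absolute
normalized count difference >= 50 (both configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios size factors.

    factors: positive value per sample (indexed like the count columns).
    excluded_genes: genes with a zero count in some sample, excluded from
    the median.
    """

    factors: pd.Series
    excluded_genes: list[str]


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("count matrix has duplicate gene or sample labels")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix has negative entries")


def compute_size_factors(counts: pd.DataFrame) -> SizeFactors:
    """Median-of-ratios size factors (genes x samples count matrix).

    Raises ValueError when no gene has strictly positive counts in all
    samples (the geometric-mean reference is then undefined).
    """
    _validate_counts(counts)
    arr = counts.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene with strictly positive counts in all samples; "
            "median-of-ratios size factors are undefined"
        )
    logs = np.log(arr[eligible])
    log_geomeans = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomeans[:, None], axis=0))
    return SizeFactors(
        factors=pd.Series(factors, index=counts.columns, name="size_factor"),
        excluded_genes=list(counts.index[~eligible]),
    )


def normalize(counts: pd.DataFrame, factors: SizeFactors) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    _validate_counts(counts)
    if set(factors.factors.index) != set(counts.columns):
        raise ValueError("size factors do not match the count matrix samples")
    return counts.div(factors.factors, axis=1)


def call_degs(
    norm_vehicle: pd.Series,
    norm_treated: pd.Series,
    log2_min: float = 0.75,
    diff_min: float = 50.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Call DEGs by the dual threshold on normalized per-gene values.

    A gene is differentially expressed iff
    |log2((treated + pseudocount) / (vehicle + pseudocount))| >= log2_min
    and |treated - vehicle| >= diff_min. The pseudocount enters the ratio
    only, keeping the count-difference criterion on the raw normalized
    values. Returns a frame (gene_id, log2_ratio, diff, direction) for the
    called genes; both comparisons are inclusive.
    """
    if not norm_vehicle.index.equals(norm_treated.index):
        norm_treated = norm_treated.reindex(norm_vehicle.index)
        if norm_treated.isna().any():
            raise ValueError("vehicle and treated values are not aligned on genes")
    v = norm_vehicle.to_numpy(dtype=float)
    t = norm_treated.to_numpy(dtype=float)
    if (v < 0).any() or (t < 0).any():
        raise ValueError("normalized expression values must be non-negative")
    log2_ratio = np.log2((t + pseudocount) / (v + pseudocount))
    diff = t - v
    called = (np.abs(log2_ratio) >= log2_min) & (np.abs(diff) >= diff_min)
    out = pd.DataFrame(
        {
            "gene_id": norm_vehicle.index[called],
            "log2_ratio": log2_ratio[called],
            "diff": diff[called],
        }
    )
    out["direction"] = np.where(out["log2_ratio"] > 0, "up", "down")
    return out.reset_index(drop=True)


def length_normalize(expression: float, total_exon_length: int) -> float:
    """Expression density: normalized expression per bp of composite exon."""
    if total_exon_length <= 0:
        raise ValueError("total exon length must be positive")
    return expression / total_exon_length
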
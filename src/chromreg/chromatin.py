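"""DNase hypersensitive site (DHS) processing.

Peak sets are pandas frames with 0-based half-open chrom/start/end columns
plus arbitrary count columns. The module covers read-count/blacklist
filtering, gap-bounded merging, genomic feature annotation, the
differential hypersensitivity score ΔDHS on a unified peak set,
expression-weighted TSS openness, open/closed classification by the first
quintile, and asymmetric peak-set overlap.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end"]

FEATURE_PRIORITY = ["promoter", "utr5", "utr3", "exon", "intron", "intergenic"]


def _check_peaks(peaks: pd.DataFrame) -> None:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak frame lacks columns {missing}")
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peaks must satisfy start < end")


def _ensure_sorted(peaks: pd.DataFrame) -> pd.DataFrame:
    sorted_ok = all(
        grp["start"].is_monotonic_increasing for _, grp in peaks.groupby("chrom")
    ) and peaks["chrom"].is_monotonic_increasing
    if not sorted_ok:
        log.info("peak set not coordinate-sorted; sorting")
        peaks = peaks.sort_values(["chrom", "start", "end"], kind="mergesort")
    return peaks.reset_index(drop=True)


def _trees(regions: pd.DataFrame | Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if isinstance(regions, pd.DataFrame):
        it = regions[PEAK_COLUMNS].itertuples(index=False)
    else:
        it = regions
    # carry a running index as payload so duplicate intervals (e.g. stacked
    # reads) keep their multiplicity under the tree's set semantics
    for k, (chrom, start, end) in enumerate(it):
        trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end), k)
    return trees


def filter_dhs(
    peaks: pd.DataFrame,
    min_reads: int = 20,
    blacklist: pd.DataFrame | None = None,
    reads_col: str = "reads",
    input_col: str = "input_reads",
) -> pd.DataFrame:
    """Drop peaks under-covered in sample or input, or touching a blacklist.

    A peak is retained iff sample reads >= min_reads AND input-control
    reads >= min_reads AND it shares no base with any blacklist interval.
    """
    _check_peaks(peaks)
    peaks = _ensure_sorted(peaks)
    keep = (peaks[reads_col] >= min_reads) & (peaks[input_col] >= min_reads)
    if blacklist is not None and len(blacklist):
        trees = _trees(blacklist)
        hits = np.array(
            [
                bool(trees.get(c) and trees[c].overlap(s, e))
                for c, s, e in peaks[PEAK_COLUMNS].itertuples(index=False)
            ]
        )
        keep &= ~hits
    return peaks.loc[keep].reset_index(drop=True)


def merge_adjacent(
    peaks: pd.DataFrame,
    max_gap: int = 100,
    count_cols: Sequence[str] | None = None,
    source_col: str | None = None,
) -> pd.DataFrame:
    """Merge chains of peaks whose successive gaps are <= max_gap.

    Transitive closure per chromosome: the merged interval spans the chain;
    count columns are summed. When `source_col` is given, the merged peak
    carries the sorted comma-joined union of the contributing labels (used
    for shared/unique accounting between conditions). Idempotent for any
    already-merged set.
    """
    _check_peaks(peaks)
    peaks = _ensure_sorted(peaks)
    if count_cols is None:
        count_cols = [
            c
            for c in peaks.columns
            if c not in PEAK_COLUMNS + [source_col] and pd.api.types.is_numeric_dtype(peaks[c])
        ]
    rows = []
    for chrom, grp in peaks.groupby("chrom", sort=True):
        cur = None
        for row in grp.itertuples(index=False):
            d = row._asdict()
            if cur is None or d["start"] - cur["end"] > max_gap:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": d["start"], "end": d["end"]}
                for c in count_cols:
                    cur[c] = d[c]
                if source_col:
                    cur[source_col] = set(str(d[source_col]).split(","))
            else:
                cur["end"] = max(cur["end"], d["end"])
                for c in count_cols:
                    cur[c] += d[c]
                if source_col:
                    cur[source_col] |= set(str(d[source_col]).split(","))
            # keep scanning
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows)
    if source_col and len(out):
        out[source_col] = out[source_col].map(lambda s: ",".join(sorted(s)))
    return out.reset_index(drop=True)


def _feature_trees(genes: Sequence[GeneModel], promoter_length: int) -> dict[str, dict[str, IntervalTree]]:
    feats: dict[str, list[tuple[str, int, int]]] = {f: [] for f in FEATURE_PRIORITY[:-1]}
    for g in genes:
        a, b = g.promoter(promoter_length)
        if a < b:
            feats["promoter"].append((g.chrom, a, b))
        for t in g.transcripts:
            for iv in t.utr5(g.strand):
                feats["utr5"].append((g.chrom, *iv))
            for iv in t.utr3(g.strand):
                feats["utr3"].append((g.chrom, *iv))
            for iv in t.exons:
                feats["exon"].append((g.chrom, *iv))
            for iv in t.introns():
                feats["intron"].append((g.chrom, *iv))
    return {name: _trees(ivs) for name, ivs in feats.items()}


def annotate_dhs(
    peaks: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoter_length: int = 2000,
) -> pd.DataFrame:
    """Label each peak with one genomic feature by fixed priority.

    Priority: promoter > 5'UTR > 3'UTR > exon > intron > intergenic; the
    first class with >= 1 bp overlap wins. Peaks on chromosomes absent from
    the annotation fall through to intergenic (warned once).
    """
    _check_peaks(peaks)
    trees = _feature_trees(genes, promoter_length)
    known_chroms = {g.chrom for g in genes}
    labels = []
    warned = False
    for chrom, start, end in peaks[PEAK_COLUMNS].itertuples(index=False):
        if chrom not in known_chroms and not warned:
            log.warning("peaks on chromosome %r absent from annotation -> intergenic", chrom)
            warned = True
        label = "intergenic"
        for feat in FEATURE_PRIORITY[:-1]:
            tr = trees[feat].get(chrom)
            if tr is not None and tr.overlap(start, end):
                label = feat
                break
        labels.append(label)
    out = peaks.copy()
    out["feature"] = labels
    return out


def feature_distribution(annotated: pd.DataFrame) -> pd.Series:
    """Fraction of peaks per feature class (the Fig-3 style table)."""
    return (
        annotated["feature"].value_counts(normalize=True).reindex(FEATURE_PRIORITY).fillna(0.0)
    )


def delta_dhs(
    peaks: pd.DataFrame,
    treated_col: str = "reads_treated",
    vehicle_col: str = "reads_vehicle",
) -> pd.DataFrame:
    """Differential hypersensitivity score on the unified peak set.

    For peak i among m peaks,
        ΔDHS_i = sqrt(n_i^treated / (Σ n^treated / m))
               - sqrt(n_i^vehicle / (Σ n^vehicle / m)),
    i.e. each count is scaled by the mean reads-per-DHS of its condition
    before the square root, making the score antisymmetric under condition
    swap. A condition with zero total contributes 0 (warned).
    """
    if len(peaks) == 0:
        raise ValueError("delta_dhs requires at least one peak (m >= 1)")
    m = len(peaks)
    out = peaks.copy()
    terms = {}
    for col in (treated_col, vehicle_col):
        n = peaks[col].to_numpy(dtype=float)
        if (n < 0).any():
            raise ValueError(f"negative read counts in {col}")
        total = n.sum()
        if total == 0:
            log.warning("delta_dhs: zero total reads in %s; its term is 0", col)
            terms[col] = np.zeros(m)
        else:
            terms[col] = np.sqrt(n / (total / m))
    out["delta"] = terms[treated_col] - terms[vehicle_col]
    out["m"] = m
    out["total_treated"] = peaks[treated_col].sum()
    out["total_vehicle"] = peaks[vehicle_col].sum()
    return out


def select_differential(
    scores: pd.DataFrame, threshold: float = 0.20, direction: str = "opening"
) -> pd.DataFrame:
    """Select peaks by ΔDHS: opening (Δ >= t), closing (Δ <= -t), or both."""
    d = scores["delta"]
    if direction == "opening":
        keep = d >= threshold
    elif direction == "closing":
        keep = d <= -threshold
    elif direction == "both":
        keep = d.abs() >= threshold
    else:
        raise ValueError("direction must be opening, closing, or both")
    return scores.loc[keep].reset_index(drop=True)


def window_coverage(
    reads: pd.DataFrame, windows: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Reads overlapping each (chrom, start, end) window (each read once)."""
    trees = _trees(reads)
    out = np.zeros(len(windows), dtype=float)
    for k, (chrom, start, end) in enumerate(windows):
        tr = trees.get(chrom)
        if tr is not None:
            out[k] = len(tr.overlap(start, end))
    return out


def tss_openness(
    genes: Sequence[GeneModel],
    reads: pd.DataFrame,
    tx_expression: Mapping[str, float],
    tx_expression_other: Mapping[str, float] | None = None,
    extension: int = 1000,
) -> pd.DataFrame:
    """Expression-weighted DNase coverage of gene TSSs.

    Every transcript TSS is extended +-`extension` bp and its window
    coverage computed as the number of overlapping reads. Per gene the
    coverages are combined with weights proportional to each transcript's
    expression share of the gene total. Fallbacks: a gene unexpressed in
    this condition uses the other condition's weights; unexpressed in both
    uses the maximum window coverage. Returns (gene_id, weighted_coverage,
    fallback) with fallback in {none, other_condition, max_coverage}.
    """
    rows = []
    for g in genes:
        tss_map = g.transcript_tss_positions()
        if not tss_map:
            raise ValueError(f"{g.gene_id}: gene with no transcript")
        tids = list(tss_map)
        windows = [
            (g.chrom, max(0, tss_map[t] - extension), tss_map[t] + extension + 1)
            for t in tids
        ]
        cov = window_coverage(reads, windows)
        expr = np.array([float(tx_expression.get(t, 0.0)) for t in tids])
        fallback = "none"
        if expr.sum() <= 0 and tx_expression_other is not None:
            expr = np.array([float(tx_expression_other.get(t, 0.0)) for t in tids])
            fallback = "other_condition"
        if expr.sum() <= 0:
            rows.append((g.gene_id, float(cov.max()), "max_coverage"))
            continue
        weights = expr / expr.sum()
        rows.append((g.gene_id, float((weights * cov).sum()), fallback))
    return pd.DataFrame(rows, columns=["gene_id", "weighted_coverage", "fallback"])


def classify_tss(coverages: pd.Series, min_genes: int = 5) -> pd.Series:
    """Open/closed TSS call: closed iff coverage is in the first quintile.

    The quintile boundary is the order statistic at index ceil(0.2 n) of
    the sorted coverages, with an inclusive (<=) comparison so a gene
    exactly at the cut is closed. Fewer than `min_genes` genes: everything
    open (warned).
    """
    n = len(coverages)
    if n < min_genes:
        log.warning("classify_tss: only %d genes; classifying all open", n)
        return pd.Series("open", index=coverages.index, name="tss_state")
    order = np.sort(coverages.to_numpy(dtype=float))
    boundary = order[math.ceil(0.2 * n) - 1]
    if boundary == order[-1]:
        log.warning("classify_tss: degenerate coverages, quintile boundary equals maximum")
    return pd.Series(
        np.where(coverages.to_numpy(dtype=float) <= boundary, "closed", "open"),
        index=coverages.index,
        name="tss_state",
    )


def peak_overlap_fraction(set_a: pd.DataFrame, set_b: pd.DataFrame) -> float:
    """Fraction of A peaks with >= 1 bp overlap in B (asymmetric)."""
    _check_peaks(set_a)
    if len(set_a) == 0:
        raise ValueError("peak_overlap_fraction: set A is empty, fraction undefined")
    trees = _trees(set_b) if len(set_b) else {}
    hits = sum(
        1
        for c, s, e in set_a[PEAK_COLUMNS].itertuples(index=False)
        if trees.get(c) is not None and trees[c].overlap(s, e)
    )
    return hits / len(set_a)
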
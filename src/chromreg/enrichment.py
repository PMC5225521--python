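"""Background-normalized TFBS enrichment and SMAD-element co-localization.

The foreground is the set of promoter-associated open-chromatin regions of
upregulated genes; the background is the corresponding regions of every
other gene. The expected number of sites for a motif is the background hit
density (hits per scanned bp) times the scanned foreground length, and the
enrichment ratio is observed / expected. Co-localization of TF hits with
SMAD-binding elements (SBEs) within a distance window is tested with a
one-sided binomial test whose null probability is the fraction of valid
scan offsets that would be co-localized by position alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: The six SMAD-binding consensus elements used for co-localization.
SBE_PATTERNS = ["CAGACA", "GTCT", "CAGC", "CGCC", "GGCGCC", "GCCGNCGC"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def partition_promoter_dhs(
    promoter_dhs: pd.DataFrame, upregulated: set[str], genes_col: str = "genes"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split promoter-associated regions into foreground and background.

    `promoter_dhs` must carry a column of associated gene ids (iterable or
    comma-joined string per region). A region touching promoters of both an
    upregulated and another gene goes to the foreground, keeping the two
    sets disjoint.
    """
    def gene_set(v) -> set[str]:
        if isinstance(v, str):
            return set(v.split(","))
        return set(v)

    in_fg = promoter_dhs[genes_col].map(lambda v: bool(gene_set(v) & upregulated))
    fg = promoter_dhs.loc[in_fg].reset_index(drop=True)
    bg = promoter_dhs.loc[~in_fg].reset_index(drop=True)
    return fg, bg


def build_background(
    promoter_dhs: pd.DataFrame, upregulated: set[str], genes_col: str = "genes"
) -> pd.DataFrame:
    """Background regions: promoter DHSs of genes outside the upregulated set."""
    _, bg = partition_promoter_dhs(promoter_dhs, upregulated, genes_col)
    if len(bg) == 0:
        raise ValueError("background region set is empty; enrichment is undefined")
    return bg


def expected_sites(
    background_hits: float, background_length: float, foreground_length: float
) -> float:
    """Background hit density scaled to the foreground's scanned length."""
    if background_length <= 0:
        raise ValueError("background length must be positive")
    return background_hits / background_length * foreground_length


def enrichment_ratio(observed: float, expected: float) -> float:
    """Observed over expected site count; expected must be positive."""
    if expected <= 0:
        raise ValueError("expected site count must be positive for a ratio")
    return observed / expected


@dataclass
class EnrichmentResult:
    motif_id: str
    observed_sites: int
    background_sites: int
    foreground_length: int
    background_length: int
    expected_sites: float
    ratio: float | None


def enrich_motifs(
    fg_hits: pd.DataFrame,
    bg_hits: pd.DataFrame,
    foreground_length: int,
    background_length: int,
) -> pd.DataFrame:
    """Per-motif enrichment table from foreground/background hit frames.

    Hit frames follow the scan() layout (must carry motif_id). Motifs with
    zero background hits get expected 0 and an undefined (NaN) ratio.
    """
    motifs = sorted(set(fg_hits["motif_id"]) | set(bg_hits["motif_id"]))
    rows = []
    for m in motifs:
        obs = int((fg_hits["motif_id"] == m).sum())
        bg = int((bg_hits["motif_id"] == m).sum())
        exp = expected_sites(bg, background_length, foreground_length)
        ratio = enrichment_ratio(obs, exp) if exp > 0 else np.nan
        rows.append((m, obs, bg, exp, ratio))
    out = pd.DataFrame(
        rows, columns=["motif_id", "observed_sites", "background_sites", "expected_sites", "ratio"]
    )
    out["ratio_2dp"] = out["ratio"].map(
        lambda r: round_half_up(r, 2) if np.isfinite(r) else np.nan
    )
    return out


def select_candidates(
    enrich_a: pd.DataFrame,
    enrich_b: pd.DataFrame,
    tf_expression: pd.DataFrame,
    min_reads: float,
    top_k: int = 15,
) -> dict[str, pd.DataFrame]:
    """Cell-line-specific candidate TFs: enriched in one line, depleted in the other.

    enrich_a / enrich_b: enrich_motifs() tables for the two lines over the
    same motif universe. tf_expression: motif_id-indexed frame with columns
    'a' and 'b' (read counts of the TF in each line). A motif is a
    candidate for line a iff ratio_a > 1, ratio_b < 1 and expression in a
    >= min_reads (symmetrically for b); candidates are ranked by the
    enriched line's ratio, top_k kept.
    """
    a = enrich_a.set_index("motif_id")["ratio"]
    b = enrich_b.set_index("motif_id")["ratio"]
    if set(a.index) != set(b.index):
        raise ValueError("the two enrichment tables must cover the same motifs")
    out = {}
    for line, own, other in (("a", a, b), ("b", b, a)):
        expr = tf_expression[line].reindex(own.index)
        keep = (own > 1) & (other.reindex(own.index) < 1) & (expr >= min_reads)
        ranked = (
            own[keep]
            .sort_values(ascending=False)
            .head(top_k)
            .rename("ratio")
            .reset_index()
        )
        ranked["expression_reads"] = expr.reindex(ranked["motif_id"]).to_numpy()
        out[line] = ranked
    return out


@dataclass
class ColocalizationResult:
    motif_id: str
    sbe_pattern: str
    window: int
    colocalized: int
    total_hits: int
    null_probability: float
    p_value: float | None


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between half-open intervals; 0 when they touch or overlap."""
    return max(b_start - a_end, a_start - b_end, 0)


def colocalization_test(
    tf_hits: pd.DataFrame,
    sbe_occurrences: pd.DataFrame,
    region_lengths: dict[str, int],
    motif_width: int,
    window: int = 200,
) -> ColocalizationResult:
    """Binomial test of TF-hit / SBE co-localization within `window` bp.

    A TF hit is co-localized iff the minimal gap between its interval and
    any SBE occurrence in the same region is <= window (overlap = gap 0).
    The null probability is the fraction of all valid scan offsets across
    the regions whose window interval would be co-localized, so the test
    asks whether observed hits sit near SBEs more often than position
    alone predicts. One-sided (upper) binomial p; NA with zero hits.
    """
    pattern = sbe_occurrences["pattern"].iloc[0] if len(sbe_occurrences) else ""
    motif_id = tf_hits["motif_id"].iloc[0] if "motif_id" in tf_hits and len(tf_hits) else ""

    sbe_by_region: dict[str, list[tuple[int, int]]] = {}
    for r in sbe_occurrences.itertuples(index=False):
        sbe_by_region.setdefault(r.sequence_id, []).append((int(r.start), int(r.end)))

    # Null probability from positional coverage of SBE +- window.
    total_offsets = 0
    coloc_offsets = 0
    for region, length in region_lengths.items():
        n_off = length - motif_width + 1
        if n_off <= 0:
            continue
        total_offsets += n_off
        mask = np.zeros(n_off, dtype=bool)
        for s1, s2 in sbe_by_region.get(region, []):
            lo = max(0, s1 - window - motif_width)
            hi = min(n_off - 1, s2 + window)
            if hi >= lo:
                mask[lo : hi + 1] = True
        coloc_offsets += int(mask.sum())
    if total_offsets == 0:
        raise ValueError("no valid scan offsets in the provided regions")
    p0 = coloc_offsets / total_offsets

    n = len(tf_hits)
    k = 0
    for h in tf_hits.itertuples(index=False):
        gaps = [
            _interval_gap(int(h.start), int(h.end), s1, s2)
            for s1, s2 in sbe_by_region.get(h.sequence_id, [])
        ]
        if gaps and min(gaps) <= window:
            k += 1
    if n == 0:
        log.warning("colocalization_test: zero TF hits; test undefined")
        p_value = None
    else:
        p_value = float(stats.binom.sf(k - 1, n, p0))
    return ColocalizationResult(motif_id, pattern, window, k, n, p0, p_value)
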
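"""Synthetic inputs with planted ground truth.

Generates the full input suite the analysis consumes — gene annotation,
negative-binomial count matrices with planted fold changes, DHS peak sets
with planted condition-specific openness, promoter sequences with planted
motif occurrences, and exponential survival tables with a group hazard
ratio — each deterministic for a fixed seed and each returning a
SyntheticTruth record for recovery testing.

One global seed expands into independent named substreams (one per
generator), so adding a generator does not perturb the draws of the
others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, Transcript

_STREAMS = {
    "annotation": 1,
    "counts": 2,
    "dhs": 3,
    "promoters": 4,
    "survival": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed (stable across generator additions)."""
    return np.random.default_rng([int(seed) % 2**31, _STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Planted ground truth: what the downstream analysis should recover."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene_id -> log2 fold
    diff_dhs: dict[str, float] = field(default_factory=dict)  # peak_id -> openness fold
    motif_positions: list[tuple[str, int, str]] = field(default_factory=list)
    foreground_promoters: list[str] = field(default_factory=list)
    survival_hazard_ratio: float | None = None
    size_factors: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def generate_annotation(
    n_genes: int,
    transcripts_per_gene: int = 2,
    chrom_length: int = 1_000_000,
    seed: int = 0,
    chrom: str = "chrS",
    promoter_length: int = 2000,
    max_retries: int = 200,
) -> list[GeneModel]:
    """Place non-overlapping genes with multi-exon transcripts on one chromosome.

    Every gene keeps a strand-aware promoter (`promoter_length` bp upstream
    of its 5'-most TSS) inside the chromosome. Gene bodies are 2-6 kb with
    2-4 exons per transcript and a CDS span on the middle exons. Raises
    when bounded retries cannot place a gene (chromosome too small).
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = _rng(seed, "annotation")
    genes: list[GeneModel] = []
    occupied: list[tuple[int, int]] = []  # gene body + promoter footprints
    for gi in range(n_genes):
        placed = False
        for _ in range(max_retries):
            body_len = int(rng.integers(2000, 6001))
            strand = "+" if rng.random() < 0.5 else "-"
            lo = promoter_length + 1
            hi = chrom_length - body_len - promoter_length - 1
            if hi <= lo:
                break
            start = int(rng.integers(lo, hi))
            foot = (start - promoter_length - 1, start + body_len + promoter_length + 1)
            if any(a < foot[1] and foot[0] < b for a, b in occupied):
                continue
            transcripts = []
            for ti in range(transcripts_per_gene):
                n_exons = int(rng.integers(2, 5))
                # cut the body into 2*n_exons-1 alternating exon/intron blocks
                cuts = np.sort(rng.choice(np.arange(1, body_len), 2 * n_exons - 2, replace=False))
                bounds = np.concatenate(([0], cuts, [body_len])) + start
                exons = [
                    (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)
                ]
                # transcripts after the first may start later (alternative TSS)
                # but the first transcript anchors the gene 5' end
                cds = (exons[0][1] - max(1, (exons[0][1] - exons[0][0]) // 2), exons[-1][0] + max(1, (exons[-1][1] - exons[-1][0]) // 2))
                if cds[0] >= cds[1]:
                    cds = None
                transcripts.append(Transcript(f"g{gi:04d}.t{ti}", exons, cds))
            genes.append(GeneModel(f"g{gi:04d}", chrom, strand, transcripts))
            occupied.append(foot)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place gene {gi} after {max_retries} retries; "
                "chrom_length too small for n_genes"
            )
    genes.sort(key=lambda g: g.start)
    return genes


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray | float, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = (1 + dispersion) * mean.

    A constant Fano-factor overdispersion of the read-sampling noise
    (r = mean/dispersion, p = 1/(1+dispersion)); dispersion 0 is Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = np.maximum(mean / dispersion, 1e-12)
    p = 1.0 / (1.0 + dispersion)
    return rng.negative_binomial(r, p)


def generate_counts(
    annotation: list[GeneModel],
    n_de: int,
    log2_fold: float,
    dispersion: float,
    depth: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Negative-binomial gene counts with planted fold changes.

    Gene baselines are log-normal and scaled so expected vehicle depth is
    `depth`. Exactly n_de genes carry the planted log2 fold in the treated
    condition. Each sample gets a recorded library-size factor. Counts are
    drawn NB with var = (1 + dispersion) * mean (dispersion 0 = Poisson),
    i.e. a constant Fano-factor overdispersion of the read-sampling noise.
    """
    n_genes = len(annotation)
    if not 0 <= n_de <= n_genes:
        raise ValueError("need 0 <= n_de <= n_genes")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_de > 0 and log2_fold == 0:
        raise ValueError("planted fold of magnitude 0 is not a fold change")
    rng = _rng(seed, "counts")
    gene_ids = [g.gene_id for g in annotation]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= depth / base.sum()
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    fold = np.ones(n_genes)
    fold[de_idx] = 2.0**log2_fold
    sf = {"vehicle": float(rng.uniform(0.7, 1.3)), "treated": float(rng.uniform(0.7, 1.3))}

    vehicle = pd.DataFrame(
        {"vehicle": nb_counts(rng, base * sf["vehicle"], dispersion)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    treated = pd.DataFrame(
        {"treated": nb_counts(rng, base * fold * sf["treated"], dispersion)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SyntheticTruth(
        de_genes={gene_ids[i]: float(log2_fold) for i in sorted(de_idx)},
        size_factors=sf,
    )
    return vehicle, treated, truth


def generate_dhs(
    annotation: list[GeneModel],
    n_peaks: int,
    n_diff: int,
    openness_fold: float,
    seed: int = 0,
    chrom_length: int = 1_000_000,
    compartments: dict[str, float] | None = None,
    promoter_length: int = 2000,
    mean_intensity: float = 80.0,
    input_intensity: float = 60.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """DHS peaks with Poisson read counts and planted differential openness.

    Peaks are placed in promoter / intronic / intergenic compartments
    (intron-heavy by default, echoing basal open-chromatin distributions)
    with log-normal per-peak intensities. Planted differential peaks have
    their treated intensity multiplied by openness_fold. Input-control
    counts are Poisson around a flat intensity in both conditions.
    """
    if n_diff > n_peaks:
        raise ValueError("n_diff must be <= n_peaks")
    if openness_fold <= 0:
        raise ValueError("openness_fold must be positive")
    rng = _rng(seed, "dhs")
    compartments = compartments or {"promoter": 0.20, "intron": 0.45, "intergenic": 0.35}
    names = list(compartments)
    probs = np.array([compartments[k] for k in names], dtype=float)
    probs /= probs.sum()

    promoters = [g.promoter(promoter_length) for g in annotation]
    introns = [
        iv for g in annotation for t in g.transcripts for iv in t.introns()
    ]
    chrom = annotation[0].chrom if annotation else "chrS"

    rows = []
    for pi in range(n_peaks):
        width = int(rng.integers(150, 501))
        comp = names[int(rng.choice(len(names), p=probs))]
        pool = {"promoter": promoters, "intron": introns}.get(comp, [])
        pool = [iv for iv in pool if iv[1] - iv[0] > width]
        if comp != "intergenic" and pool:
            a, b = pool[int(rng.integers(len(pool)))]
            start = int(rng.integers(a, b - width))
        else:
            start = int(rng.integers(0, max(1, chrom_length - width)))
        rows.append((f"dhs{pi:05d}", chrom, start, start + width))
    peaks = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])

    intensity = rng.lognormal(mean=np.log(mean_intensity), sigma=0.5, size=n_peaks)
    diff_idx = rng.choice(n_peaks, size=n_diff, replace=False)
    fold = np.ones(n_peaks)
    fold[diff_idx] = openness_fold
    peaks["reads_vehicle"] = rng.poisson(intensity)
    peaks["reads_treated"] = rng.poisson(intensity * fold)
    peaks["input_reads_vehicle"] = rng.poisson(input_intensity, size=n_peaks)
    peaks["input_reads_treated"] = rng.poisson(input_intensity, size=n_peaks)
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    truth = SyntheticTruth(
        diff_dhs={peaks_row: float(openness_fold) for peaks_row in
                  [f"dhs{pi:05d}" for pi in sorted(diff_idx)]}
    )
    return peaks, truth


def generate_promoters(
    annotation: list[GeneModel],
    motif_consensus: str,
    planted_rate_fg: float,
    planted_rate_bg: float,
    gc: float = 0.5,
    seed: int = 0,
    promoter_length: int = 2000,
    fraction_foreground: float = 0.3,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Promoter sequences with motif consensus strings planted at known offsets.

    Background bases are i.i.d. with the stated GC content. Promoters are
    labelled foreground (a `fraction_foreground` subset) or background, and
    consensus copies are inserted Poisson(rate) per promoter at recorded,
    non-overlapping offsets. Keyed by gene id.
    """
    if planted_rate_fg < 0 or planted_rate_bg < 0:
        raise ValueError("planted rates must be >= 0")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if len(motif_consensus) > promoter_length:
        raise ValueError("motif longer than the promoter sequence")
    rng = _rng(seed, "promoters")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    w = len(motif_consensus)

    n_fg = int(round(fraction_foreground * len(annotation)))
    fg_idx = set(rng.choice(len(annotation), size=n_fg, replace=False).tolist())

    sequences: dict[str, str] = {}
    truth = SyntheticTruth()
    for k, g in enumerate(annotation):
        seq = rng.choice(bases, size=promoter_length, p=probs)
        rate = planted_rate_fg if k in fg_idx else planted_rate_bg
        n_insert = int(rng.poisson(rate))
        used: list[tuple[int, int]] = []
        for _ in range(n_insert):
            for _try in range(50):
                off = int(rng.integers(0, promoter_length - w + 1))
                if all(off + w <= a or off >= b for a, b in used):
                    seq[off : off + w] = list(motif_consensus.upper())
                    used.append((off, off + w))
                    truth.motif_positions.append((g.gene_id, off, motif_consensus))
                    break
        sequences[g.gene_id] = "".join(seq)
        if k in fg_idx:
            truth.foreground_promoters.append(g.gene_id)
    return sequences, truth


def reads_from_peaks(
    peaks: pd.DataFrame,
    count_col: str,
    seed: int = 0,
    read_length: int = 50,
) -> pd.DataFrame:
    """Expand per-peak read counts into uniformly placed read intervals.

    Used to exercise window-coverage computations without read-level
    simulation: each peak emits `count_col` reads of fixed length starting
    uniformly within the peak.
    """
    rng = _rng(seed, "dhs")
    rows = []
    for p in peaks.itertuples(index=False):
        n = int(getattr(p, count_col))
        if n <= 0:
            continue
        starts = rng.integers(p.start, max(p.start + 1, p.end - read_length), size=n)
        for s in starts:
            rows.append((p.chrom, int(s), int(s) + read_length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_survival(
    n_patients: int,
    hazard_ratio: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    base_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential survival tied to above/below-median expression.

    Expression is standard normal per patient; patients above the median
    form the high group, whose event hazard is base_hazard * hazard_ratio
    (low group: base_hazard). Censoring is non-informative: an independent
    exponential censoring time with rate base_hazard * censor_rate /
    (1 - censor_rate), giving an expected censored fraction of about
    `censor_rate` in the low group. Returns a frame
    (patient_id, time, event, expression).
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = _rng(seed, "survival")
    expr = rng.normal(size=n_patients)
    high = expr > np.median(expr)
    rate = np.where(high, base_hazard * hazard_ratio, base_hazard)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_hazard = base_hazard * censor_rate / (1.0 - censor_rate)
        t_censor = rng.exponential(1.0 / censor_hazard, size=n_patients)
    else:
        t_censor = np.full(n_patients, np.inf)
    censored = t_censor < t_event
    time = np.minimum(t_event, t_censor)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(n_patients)],
            "time": time,
            "event": (~censored).astype(int),
            "expression": expr,
        }
    )
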
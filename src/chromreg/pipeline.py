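"""End-to-end orchestration of the synthetic analysis pipeline.

Runs simulate -> normalize/DEG -> DHS filter/merge/annotate/ΔDHS -> TSS
openness -> motif scan -> enrichment/co-localization -> survival, writing
self-describing TSV outputs per stage plus a run log. Identical config and
seed give byte-identical outputs; the config hash is recorded in every
output header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, enrichment, expression, io, motif, survival as surv, synthetic
from .annotation import write_gtf

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the analysis defaults.

    Thresholds mirror the analysis constants: |log2 ratio| >= 0.75 and
    normalized count difference >= 50 for DEGs; >= 20 reads in sample and
    input for DHS retention; 100 bp merge gap; +-1000 bp TSS windows;
    2000 bp proximal promoters; ΔDHS >= 0.20 selection; PWM match p-value
    0.001; 200 bp co-localization window.
    """

    # analysis thresholds
    log2_min: float = 0.75
    diff_min: float = 50.0
    min_reads: int = 20
    merge_gap: int = 100
    tss_extension: int = 1000
    promoter_length: int = 2000
    delta_threshold: float = 0.20
    motif_p: float = 0.001
    coloc_window: int = 200
    # simulation conditions
    n_genes: int = 100
    transcripts_per_gene: int = 2
    chrom_length: int = 2_000_000
    n_de: int = 10
    log2_fold: float = 2.0
    dispersion: float = 0.05
    depth: float = 1_000_000.0
    n_peaks: int = 300
    n_diff_dhs: int = 20
    openness_fold: float = 4.0
    planted_rate_fg: float = 2.0
    planted_rate_bg: float = 0.5
    gc: float = 0.5
    n_patients: int = 100
    hazard_ratio: float = 2.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "log2_min", "diff_min", "min_reads", "merge_gap", "tss_extension",
            "promoter_length", "delta_threshold", "motif_p", "coloc_window",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _bundled_pwm_wpcm() -> motif.WPCM:
    """The synthetic TF matrix the pipeline plants and scans for."""
    paths = [p for p in motif.bundled_motif_paths() if "tf1" in p.name]
    return motif.read_wpcm(paths[0])


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns a summary dict of record counts.

    Stage failures raise StageError naming the stage; outputs written by
    earlier stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config {config.config_hash()} seed {config.seed}"
    summary: dict = {"config_hash": config.config_hash()}
    stage = "simulate"
    try:
        genes = synthetic.generate_annotation(
            config.n_genes, config.transcripts_per_gene, config.chrom_length,
            seed=config.seed, promoter_length=config.promoter_length,
        )
        write_gtf(genes, outdir / "annotation.gtf")
        vehicle, treated, truth_counts = synthetic.generate_counts(
            genes, config.n_de, config.log2_fold, config.dispersion, config.depth,
            seed=config.seed,
        )
        counts = vehicle.join(treated)
        io.write_counts(counts, outdir / "counts.tsv")
        wpcm = _bundled_pwm_wpcm()
        peaks, truth_dhs = synthetic.generate_dhs(
            genes, config.n_peaks, config.n_diff_dhs, config.openness_fold,
            seed=config.seed, chrom_length=config.chrom_length,
            promoter_length=config.promoter_length,
        )
        io.write_peaks_bed(peaks, outdir / "peaks.bed")
        promoters, truth_prom = synthetic.generate_promoters(
            genes, wpcm.consensus(), config.planted_rate_fg, config.planted_rate_bg,
            config.gc, seed=config.seed, promoter_length=config.promoter_length,
        )
        io.write_fasta(promoters, outdir / "promoters.fa")
        truth = synthetic.SyntheticTruth(
            de_genes=truth_counts.de_genes,
            diff_dhs=truth_dhs.diff_dhs,
            motif_positions=truth_prom.motif_positions,
            foreground_promoters=truth_prom.foreground_promoters,
            survival_hazard_ratio=config.hazard_ratio,
            size_factors=truth_counts.size_factors,
        )
        truth.to_json(outdir / "truth.json")
        summary["n_genes"] = len(genes)
        summary["n_peaks"] = len(peaks)

        stage = "normalize"
        factors = expression.compute_size_factors(counts)
        norm = expression.normalize(counts, factors)
        io.write_counts(norm.round(4), outdir / "normalized.tsv")

        stage = "deg"
        degs = expression.call_degs(
            norm["vehicle"], norm["treated"],
            log2_min=config.log2_min, diff_min=config.diff_min,
        )
        io.write_table(degs, outdir / "degs.tsv", tag)
        summary["n_degs"] = len(degs)

        stage = "dhs-filter"
        filt_v = chromatin.filter_dhs(
            peaks, config.min_reads, reads_col="reads_vehicle",
            input_col="input_reads_vehicle",
        )
        filt_t = chromatin.filter_dhs(
            peaks, config.min_reads, reads_col="reads_treated",
            input_col="input_reads_treated",
        )
        kept = peaks[
            peaks["peak_id"].isin(set(filt_v["peak_id"]) | set(filt_t["peak_id"]))
        ].copy()
        src = []
        vset, tset = set(filt_v["peak_id"]), set(filt_t["peak_id"])
        for pid in kept["peak_id"]:
            src.append(",".join(
                lbl for lbl, s in (("vehicle", vset), ("treated", tset)) if pid in s
            ))
        kept["source"] = src
        summary["n_dhs_vehicle"] = len(filt_v)
        summary["n_dhs_treated"] = len(filt_t)

        stage = "dhs-merge"
        merged = chromatin.merge_adjacent(
            kept, config.merge_gap,
            count_cols=["reads_vehicle", "reads_treated"], source_col="source",
        )
        io.write_peaks_bed(merged, outdir / "merged_peaks.bed")
        summary["n_dhs_merged"] = len(merged)

        stage = "dhs-annotate"
        annotated = chromatin.annotate_dhs(merged, genes, config.promoter_length)
        dist = chromatin.feature_distribution(annotated)
        io.write_table(
            dist.rename("fraction").reset_index().rename(columns={"index": "feature"}),
            outdir / "feature_distribution.tsv", tag,
        )

        stage = "dhs-delta"
        scored = chromatin.delta_dhs(annotated)
        io.write_table(scored.round(6), outdir / "delta_dhs.tsv", tag)
        selected = chromatin.select_differential(scored, config.delta_threshold)
        summary["n_delta_selected"] = len(selected)

        stage = "tss-openness"
        reads_v = synthetic.reads_from_peaks(peaks, "reads_vehicle", seed=config.seed)
        tx_expr = {}
        for cond in ("vehicle", "treated"):
            tx_expr[cond] = {
                t.transcript_id: float(norm.loc[g.gene_id, cond]) / len(g.transcripts)
                for g in genes for t in g.transcripts
            }
        openness = chromatin.tss_openness(
            genes, reads_v, tx_expr["vehicle"], tx_expr["treated"],
            extension=config.tss_extension,
        )
        openness["tss_state"] = chromatin.classify_tss(
            openness.set_index("gene_id")["weighted_coverage"]
        ).to_numpy()
        io.write_table(openness.round(4), outdir / "tss_openness.tsv", tag)

        stage = "motif-scan"
        background = motif.estimate_background(promoters)
        pwm = motif.build_pwm(wpcm, background)
        threshold = motif.score_threshold(pwm, p=config.motif_p)
        hits = motif.scan(promoters, pwm, threshold)
        io.write_table(hits.round(4), outdir / "motif_hits.tsv", tag)
        summary["n_motif_hits"] = len(hits)

        stage = "enrich"
        up = set(degs.loc[degs["direction"] == "up", "gene_id"])
        fg_genes = up & set(promoters)
        bg_genes = set(promoters) - fg_genes
        if fg_genes and bg_genes:
            fg_hits = hits[hits["sequence_id"].isin(fg_genes)]
            bg_hits = hits[hits["sequence_id"].isin(bg_genes)]
            enr = enrichment.enrich_motifs(
                fg_hits, bg_hits,
                foreground_length=config.promoter_length * len(fg_genes),
                background_length=config.promoter_length * len(bg_genes),
            )
        else:
            log.warning("enrich: empty foreground or background; writing empty table")
            enr = pd.DataFrame(
                columns=["motif_id", "observed_sites", "background_sites",
                         "expected_sites", "ratio", "ratio_2dp"]
            )
        io.write_table(enr, outdir / "enrichment.tsv", tag)

        stage = "coloc"
        fg_seqs = {g: promoters[g] for g in sorted(fg_genes)}
        coloc_rows = []
        if fg_seqs and len(hits):
            region_lengths = {g: len(s) for g, s in fg_seqs.items()}
            tf_fg = hits[hits["sequence_id"].isin(fg_seqs)]
            for pattern in enrichment.SBE_PATTERNS:
                occ = motif.find_consensus(fg_seqs, [pattern])
                if len(tf_fg) == 0:
                    continue
                res = enrichment.colocalization_test(
                    tf_fg, occ if len(occ) else occ.assign(pattern=pattern),
                    region_lengths, pwm.width, config.coloc_window,
                )
                coloc_rows.append(
                    (pwm.motif_id, pattern, res.colocalized, res.total_hits,
                     res.null_probability, res.p_value)
                )
        coloc = pd.DataFrame(
            coloc_rows,
            columns=["motif_id", "sbe_pattern", "colocalized", "total_hits",
                     "null_probability", "p_value"],
        )
        io.write_table(coloc, outdir / "colocalization.tsv", tag)

        stage = "survival"
        surv_rows = []
        screened = list(degs["gene_id"][:10])
        for k, gene_id in enumerate(screened):
            hr = config.hazard_ratio if gene_id in truth.de_genes else 1.0
            table = synthetic.generate_survival(
                config.n_patients, hr, config.censor_rate,
                seed=config.seed * 1009 + k,
            )
            groups = surv.median_split(table.set_index("patient_id")["expression"])
            records = table.set_index("patient_id")[["time", "event"]].copy()
            records["group"] = groups
            res = surv.logrank_test(records)
            surv_rows.append((gene_id, res.chi_square, res.p_value, res.worse_group))
        surv_df = pd.DataFrame(
            surv_rows, columns=["gene_id", "chi_square", "p", "worse_group"]
        )
        if len(surv_df):
            surv_df["p_adjusted"] = surv.bh_adjust(surv_df["p"].to_numpy())
        else:
            surv_df["p_adjusted"] = []
        io.write_table(surv_df.round(6), outdir / "survival_screen.tsv", tag)
        summary["n_survival_screened"] = len(surv_df)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(stage, exc) from exc

    (outdir / "run_log.txt").write_text(
        "\n".join([tag] + [f"{k}\t{v}" for k, v in summary.items()]) + "\n"
    )
    return summary


def make_report(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables from stage outputs; absent stages are skipped.

    Sections: DEG summary with per-DEG TSS state, shared/unique fractions
    of the merged DHS set between conditions, the feature distribution,
    and the top enrichment rows.
    """
    outdir = Path(outdir)
    report: dict[str, pd.DataFrame] = {}

    degs_p, tss_p = outdir / "degs.tsv", outdir / "tss_openness.tsv"
    if degs_p.exists():
        degs = io.read_table(degs_p)
        if tss_p.exists() and len(degs):
            tss = io.read_table(tss_p)[["gene_id", "tss_state"]]
            degs = degs.merge(tss, on="gene_id", how="left")
        report["deg_summary"] = degs

    merged_p = outdir / "merged_peaks.bed"
    if merged_p.exists():
        merged = io.read_peaks_bed(merged_p)
        report["dhs_sharing"] = shared_unique_fractions(merged)

    dist_p = outdir / "feature_distribution.tsv"
    if dist_p.exists():
        report["feature_distribution"] = io.read_table(dist_p)

    enr_p = outdir / "enrichment.tsv"
    if enr_p.exists():
        enr = io.read_table(enr_p)
        report["top_enrichment"] = (
            enr.sort_values("ratio", ascending=False).head(15).reset_index(drop=True)
            if len(enr) else enr
        )

    for name, df in report.items():
        io.write_table(df, outdir / f"report_{name}.tsv")
    return report


def shared_unique_fractions(merged: pd.DataFrame, source_col: str = "source") -> pd.DataFrame:
    """Shared vs condition-unique fractions of the merged unified peak set.

    A merged peak is shared iff it contains contributing peaks from both
    conditions (the post-merge accounting).
    """
    if len(merged) == 0:
        return pd.DataFrame(columns=["category", "count", "fraction"])
    sources = merged[source_col].map(lambda s: frozenset(str(s).split(",")))
    n = len(merged)
    shared = int(sources.map(lambda s: {"vehicle", "treated"} <= s).sum())
    only_v = int(sources.map(lambda s: s == frozenset({"vehicle"})).sum())
    only_t = int(sources.map(lambda s: s == frozenset({"treated"})).sum())
    return pd.DataFrame(
        {
            "category": ["shared", "vehicle_unique", "treated_unique"],
            "count": [shared, only_v, only_t],
            "fraction": [shared / n, only_v / n, only_t / n],
        }
    )
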
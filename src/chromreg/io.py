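"""Plain-text readers and writers for the pipeline's interchange formats.

Everything is TSV/BED/FASTA/GTF/JSON — diffable and re-readable by each
downstream stage without the orchestrator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """TSV with an optional leading '#' comment line (config hash etc.)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


PEAK_BED_COLUMNS = ["chrom", "start", "end", "peak_id"]


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """BED-like: chrom/start/end/name then every remaining column."""
    cols = [c for c in PEAK_BED_COLUMNS if c in peaks.columns]
    extra = [c for c in peaks.columns if c not in cols]
    peaks[cols + extra].to_csv(path, sep="\t", index=False)


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
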
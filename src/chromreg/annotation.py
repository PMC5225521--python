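"""Gene models, promoters and TSS geometry.

Coordinates are 0-based half-open internally. GTF is written (and read)
1-based inclusive, the format's native convention. A gene is a "composite"
of its transcripts: exon structure is kept per transcript, while the
gene-level TSS is the 5'-most transcript start respecting strand.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

Interval = tuple[int, int]


@dataclass
class Transcript:
    """One transcript: sorted, non-overlapping exons plus an optional CDS span.

    The CDS span, when present, is used to derive 5'/3' UTR intervals for
    feature annotation; it must lie within the exon hull.
    """

    transcript_id: str
    exons: list[Interval]
    cds: Interval | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if not 0 <= a < b:
                raise ValueError(f"{self.transcript_id}: bad exon ({a}, {b})")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds is not None:
            c0, c1 = self.cds
            if not (self.start <= c0 < c1 <= self.end):
                raise ValueError(f"{self.transcript_id}: CDS outside exon hull")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def tss(self, strand: str) -> int:
        """5'-most genomic base of the transcript (strand-aware)."""
        return self.start if strand == "+" else self.end - 1

    def total_exon_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def introns(self) -> list[Interval]:
        return [
            (b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]) if a1 > b0
        ]

    def utr5(self, strand: str) -> list[Interval]:
        """Exonic intervals 5' of the CDS; empty when no CDS is annotated."""
        if self.cds is None:
            return []
        c0, c1 = self.cds
        out = []
        for a, b in self.exons:
            if strand == "+":
                lo, hi = a, min(b, c0)
            else:
                lo, hi = max(a, c1), b
            if lo < hi:
                out.append((lo, hi))
        return out

    def utr3(self, strand: str) -> list[Interval]:
        if self.cds is None:
            return []
        c0, c1 = self.cds
        out = []
        for a, b in self.exons:
            if strand == "+":
                lo, hi = max(a, c1), b
            else:
                lo, hi = a, min(b, c0)
            if lo < hi:
                out.append((lo, hi))
        return out


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene without transcripts")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        """Gene-level TSS: the 5'-most transcript TSS respecting strand."""
        positions = [t.tss(self.strand) for t in self.transcripts]
        return min(positions) if self.strand == "+" else max(positions)

    def transcript_tss_positions(self) -> dict[str, int]:
        return {t.transcript_id: t.tss(self.strand) for t in self.transcripts}

    def promoter(self, length: int = 2000) -> Interval:
        """Proximal promoter: `length` bp immediately upstream of the gene TSS.

        Half-open; clipped at 0 on the + strand.
        """
        if self.strand == "+":
            return (max(0, self.tss - length), self.tss)
        return (self.tss + 1, self.tss + 1 + length)

    def total_exon_length(self) -> int:
        """Composite exon length: union of exonic bases over all transcripts."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        total, cur_a, cur_b = 0, None, None
        for a, b in ivs:
            if cur_b is None or a > cur_b:
                if cur_b is not None:
                    total += cur_b - cur_a
                cur_a, cur_b = a, b
            else:
                cur_b = max(cur_b, b)
        if cur_b is not None:
            total += cur_b - cur_a
        return total


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "chromreg") -> None:
    """Write gene/transcript/exon/CDS features as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for a, b in t.exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )
                if t.cds is not None:
                    a, b = t.cds
                    fh.write(
                        f"{g.chrom}\t{source}\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GTF into GeneModel objects (via gffutils, in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        for tf in db.children(gf, featuretype="transcript"):
            exons = [
                (ef.start - 1, ef.end) for ef in db.children(tf, featuretype="exon")
            ]
            cds_feats = list(db.children(tf, featuretype="CDS"))
            cds = None
            if cds_feats:
                cds = (min(c.start for c in cds_feats) - 1, max(c.end for c in cds_feats))
            transcripts.append(
                Transcript(tf.attributes["transcript_id"][0], exons, cds)
            )
        genes.append(
            GeneModel(gf.attributes["gene_id"][0], gf.seqid, gf.strand, transcripts)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
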
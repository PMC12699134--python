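"""File-format helpers: FASTA, GTF, BED and the pipeline's TSV tables.

Conventions
-----------
* In memory the genome is a ``dict[str, bytearray]`` of uppercase sequence
  (mutable so the simulator can plant motif instances in place).
* BED is 0-based half-open; GTF on disk is 1-based inclusive and converted
  on read/write.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gtf",
    "write_gtf",
]


@dataclass
class GeneModel:
    """Gene annotation as two tables.

    ``genes``: gene_id, chrom, start, end, strand, tss, tts, cds_start,
    cds_end (all coordinates 0-based half-open; tss/tts are single genomic
    positions of the transcription start/termination base).
    ``exons``: gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.genes):
            self.genes = self.genes.reset_index(drop=True)

    @property
    def tss_table(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "tss", "strand"]]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, bytearray]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    genome = {name: bytearray(str(fa[name][:]).encode()) for name in fa.keys()}
    fa.close()
    return genome


def write_fasta(genome: dict[str, bytearray], path, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            s = bytes(seq).decode()
            for i in range(0, len(s), line_width):
                fh.write(s[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = _BED6[: df.shape[1]] + list(df.columns[6:])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = [c for c in _BED6 if c in df.columns]
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = "."
        cols = ["chrom", "start", "end", "name"]
    if "score" not in out.columns and ("strand" in out.columns or extra_cols):
        out["score"] = 0
    if extra_cols:
        cols = ["chrom", "start", "end", "name", "score"]
        if "strand" not in out.columns:
            out["strand"] = "."
        cols += ["strand"] + list(extra_cols)
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gtf(model: GeneModel, path, source: str = "starrmap") -> None:
    """Emit gene/transcript/exon/CDS records, 1-based inclusive."""
    rows = []

    def rec(chrom, feature, start0, end0, strand, gene_id):
        attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
        rows.append(
            f"{chrom}\t{source}\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"
        )

    for g in model.genes.itertuples():
        rec(g.chrom, "gene", g.start, g.end, g.strand, g.gene_id)
        rec(g.chrom, "transcript", g.start, g.end, g.strand, g.gene_id)
        sub = model.exons[model.exons["gene_id"] == g.gene_id]
        for e in sub.itertuples():
            rec(e.chrom, "exon", e.start, e.end, g.strand, g.gene_id)
        if g.cds_start < g.cds_end:
            for e in sub.itertuples():
                cs, ce = max(e.start, g.cds_start), min(e.end, g.cds_end)
                if cs < ce:
                    rec(e.chrom, "CDS", cs, ce, g.strand, g.gene_id)
    Path(path).write_text("\n".join(rows) + "\n")


def read_gtf(path) -> GeneModel:
    """Parse a GTF into a :class:`GeneModel` (via gffutils, in-memory DB)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes, exons = [], []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes["gene_id"][0]
        start0, end0 = g.start - 1, g.end
        strand = g.strand
        tss = start0 if strand == "+" else end0 - 1
        tts = end0 - 1 if strand == "+" else start0
        cds = [
            (c.start - 1, c.end)
            for c in db.children(g, featuretype="CDS", order_by="start")
        ]
        cds_start = min(c[0] for c in cds) if cds else start0
        cds_end = max(c[1] for c in cds) if cds else start0
        genes.append(
            dict(
                gene_id=gene_id,
                chrom=g.seqid,
                start=start0,
                end=end0,
                strand=strand,
                tss=tss,
                tts=tts,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        for e in db.children(g, featuretype="exon", order_by="start"):
            exons.append(
                dict(gene_id=gene_id, chrom=e.seqid, start=e.start - 1, end=e.end)
            )
    return GeneModel(pd.DataFrame(genes), pd.DataFrame(exons))
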
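"""Chromatin-context and genomic-position annotation of enhancer peaks.

Boolean chromatin flags use whole-peak overlap (>= 1 bp, with an optional
flank for histone marks deposited around rather than on the element);
single-label genomic-feature assignment uses the peak summit so that every
peak maps to exactly one feature, with the precedence

    promoter_tss > tts > utr5 > utr3 > exon > intron > intergenic.

The promoter window defaults to -1 kb..+100 bp around the TSS and the TTS
window to -100 bp..+1 kb, both strand-oriented (the conventional peak
annotation defaults); all windows are configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel

__all__ = [
    "annotate_accessibility",
    "annotate_histone",
    "annotate_genomic_feature",
    "classify_tissue",
    "expression_by_group",
    "FEATURE_PRECEDENCE",
]

FEATURE_PRECEDENCE = (
    "promoter_tss", "tts", "utr5", "utr3", "exon", "intron", "intergenic"
)


def _flag_overlap(peaks: pd.DataFrame, track: pd.DataFrame, flank_bp: int = 0) -> np.ndarray:
    """True where a peak overlaps the flank-extended track.

    The flank is inclusive at its boundary: a peak that exactly touches the
    extended interval end-to-start still counts.
    """
    out = np.zeros(len(peaks), dtype=bool)
    if track is None or not len(track):
        return out
    peaks = peaks.reset_index(drop=True)
    for chrom, sub in peaks.groupby("chrom"):
        tr = track[track["chrom"] == chrom]
        if not len(tr):
            continue
        ts = np.sort(tr["start"].to_numpy(np.int64) - flank_bp)
        te = np.sort(tr["end"].to_numpy(np.int64) + flank_bp)
        qs = sub["start"].to_numpy(np.int64)
        qe = sub["end"].to_numpy(np.int64)
        if flank_bp == 0:
            # strict >= 1 bp overlap; book-ended intervals do not touch
            hit = (np.searchsorted(ts, qe, side="left")
                   - np.searchsorted(te, qs, side="right")) > 0
        else:
            # inclusive flank boundary: exactly touching the extended
            # interval still counts
            hit = (np.searchsorted(ts, qe, side="right")
                   - np.searchsorted(te, qs, side="left")) > 0
        out[sub.index.to_numpy()] = hit
    return out


def annotate_accessibility(peaks: pd.DataFrame, atac_peaks: pd.DataFrame) -> np.ndarray:
    """Accessible iff the peak overlaps an ATAC-seq peak by >= 1 bp."""
    return _flag_overlap(peaks, atac_peaks, flank_bp=0)


def annotate_histone(peaks: pd.DataFrame, chip_peaks: pd.DataFrame, flank_bp: int = 0) -> np.ndarray:
    """Histone flag: overlap with the ChIP peak extended by ``flank_bp``.

    Use ``flank_bp=0`` for H3K27ac (direct overlap) and 3000 for H3K4me1
    (peak within a +/-3 kb flanking region).
    """
    return _flag_overlap(peaks, chip_peaks, flank_bp=flank_bp)


def annotate_genomic_feature(
    peaks: pd.DataFrame,
    gene_model: GeneModel,
    promoter_window: tuple[int, int] = (-1_000, 100),
    tts_window: tuple[int, int] = (-100, 1_000),
) -> pd.DataFrame:
    """Feature class, nearest gene and signed TSS distance per peak summit.

    ``tss_distance_bp`` is strand-oriented: positive means downstream of the
    nearest TSS in the gene's direction of transcription. An empty gene
    model yields intergenic peaks with null gene fields.
    """
    genes = gene_model.genes
    n = len(peaks)
    features = np.full(n, "intergenic", dtype=object)
    nearest = np.full(n, None, dtype=object)
    tss_dist = np.full(n, np.nan)
    if genes is None or not len(genes):
        return pd.DataFrame(dict(
            genomic_feature=features, nearest_gene_id=nearest, tss_distance_bp=tss_dist))

    exons = gene_model.exons
    peaks = peaks.reset_index(drop=True)
    summits = peaks["summit"] if "summit" in peaks.columns else (
        (peaks["start"] + peaks["end"]) // 2
    )
    genes_by_chrom = {c: sub.reset_index(drop=True) for c, sub in genes.groupby("chrom")}
    exons_by_gene = {g: sub for g, sub in exons.groupby("gene_id")} if len(exons) else {}

    for i, (chrom, summit) in enumerate(zip(peaks["chrom"], summits)):
        sub = genes_by_chrom.get(chrom)
        if sub is None:
            continue
        tss = sub["tss"].to_numpy(np.int64)
        d_abs = np.abs(tss - summit)
        j = int(np.argmin(d_abs))
        g = sub.iloc[j]
        nearest[i] = g["gene_id"]
        tss_dist[i] = (summit - g["tss"]) if g["strand"] == "+" else (g["tss"] - summit)

        # candidate genes whose windows could contain the summit
        window = 2_000
        cand = sub[(sub["start"] - window <= summit) & (summit < sub["end"] + window)]
        best = "intergenic"
        for cg in cand.itertuples():
            f = _feature_for_gene(summit, cg, exons_by_gene.get(cg.gene_id),
                                  promoter_window, tts_window)
            if FEATURE_PRECEDENCE.index(f) < FEATURE_PRECEDENCE.index(best):
                best = f
        features[i] = best
    return pd.DataFrame(dict(
        genomic_feature=features, nearest_gene_id=nearest, tss_distance_bp=tss_dist))


def _feature_for_gene(summit, gene, gene_exons, promoter_window, tts_window) -> str:
    strand = gene.strand
    d_tss = (summit - gene.tss) if strand == "+" else (gene.tss - summit)
    if promoter_window[0] <= d_tss <= promoter_window[1]:
        return "promoter_tss"
    d_tts = (summit - gene.tts) if strand == "+" else (gene.tts - summit)
    if tts_window[0] <= d_tts <= tts_window[1]:
        return "tts"
    if not (gene.start <= summit < gene.end):
        return "intergenic"
    in_exon = False
    if gene_exons is not None:
        in_exon = bool(
            ((gene_exons["start"] <= summit) & (summit < gene_exons["end"])).any()
        )
    if in_exon:
        cds_lo, cds_hi = gene.cds_start, gene.cds_end
        if cds_lo < cds_hi:
            if summit < cds_lo:
                return "utr5" if strand == "+" else "utr3"
            if summit >= cds_hi:
                return "utr3" if strand == "+" else "utr5"
        return "exon"
    return "intron"


_TISSUE_MAP = {
    "low tissue specificity": "ubiquitous",
    "tissue enhanced": "tissue_specific",
    "tissue enriched": "tissue_specific",
    "group enriched": "tissue_specific",
}


def _norm_category(value: str) -> str:
    # unify unicode hyphens and separators used in tissue-atlas exports
    return (
        str(value).strip().lower()
        .replace("‐", " ").replace("‑", " ").replace("-", " ")
        .replace("_", " ")
    )


def classify_tissue(gene_ids, lookup: pd.DataFrame,
                    id_col: str = "gene_id",
                    category_col: str = "rna_tissue_specificity") -> pd.Series:
    """Map tissue-specificity categories to ubiquitous / tissue_specific.

    "Low tissue specificity" genes are ubiquitous; "tissue enhanced",
    "tissue enriched" and "group enriched" are tissue-specific. Genes absent
    from the table are "unknown"; an unrecognised category raises an error
    naming it.
    """
    lut = {}
    for rec in lookup.itertuples(index=False):
        raw = getattr(rec, category_col)
        key = _norm_category(raw)
        if key not in _TISSUE_MAP:
            raise ValueError(f"unrecognized tissue-specificity category: {raw!r}")
        lut[getattr(rec, id_col)] = _TISSUE_MAP[key]
    return pd.Series([lut.get(g, "unknown") for g in gene_ids], index=None, name="tissue_class")


def expression_by_group(
    expression: pd.Series, groups: pd.Series, log_transform: bool = True
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Group summaries, one-way ANOVA p, and Bonferroni pairwise p-values.

    ``expression`` is TPM indexed like ``groups``. Returns (summary table,
    anova_p, pairwise table). Requires >= 2 groups with >= 2 members each.
    """
    x = expression.astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    df = pd.DataFrame(dict(value=x, group=groups))
    sizes = df.groupby("group").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    summary = df.groupby("group")["value"].agg(
        n="size", median="median",
        q1=lambda v: float(np.percentile(v, 25)),
        q3=lambda v: float(np.percentile(v, 75)),
        mean="mean",
    ).reset_index()
    arrays = [sub["value"].to_numpy() for _, sub in df.groupby("group")]
    anova_p = float(stats.f_oneway(*arrays).pvalue)
    names = list(sizes.index)
    pairs = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = df[df["group"] == names[i]]["value"]
            b = df[df["group"] == names[j]]["value"]
            p = float(stats.ttest_ind(a, b).pvalue)
            pairs.append(dict(group_a=names[i], group_b=names[j],
                              p_value=p, p_bonferroni=min(1.0, p * n_pairs)))
    return summary, anova_p, pd.DataFrame(pairs)
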
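"""Chromatin flags, genomic-feature assignment, tissue classes, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starrmap import annotate
from starrmap.io import GeneModel


def peaks_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["summit"] = (df["start"] + df["end"]) // 2
    return df


def track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestChromatinFlags:
    def test_one_bp_overlap_is_accessible(self):
        got = annotate.annotate_accessibility(
            peaks_df([("1", 1000, 1500)]), track([("1", 1499, 2000)]))
        assert got.tolist() == [True]

    def test_bookended_interval_is_not_overlap(self):
        got = annotate.annotate_accessibility(
            peaks_df([("1", 1000, 1500)]), track([("1", 1500, 2000)]))
        assert got.tolist() == [False]

    def test_empty_track_masks_everything(self):
        got = annotate.annotate_accessibility(
            peaks_df([("1", 0, 500), ("2", 0, 500)]), track([]))
        assert not got.any()

    def test_flank_boundary_inclusive(self):
        chip = track([("1", 10_000, 10_400)])
        # peak ending exactly 3 kb before the chip peak start: positive
        at_edge = peaks_df([("1", 6_500, 7_000)])
        assert annotate.annotate_histone(at_edge, chip, flank_bp=3000).tolist() == [True]
        # one bp further away: negative
        beyond = peaks_df([("1", 6_499, 6_999)])
        assert annotate.annotate_histone(beyond, chip, flank_bp=3000).tolist() == [False]

    def test_zero_flank_is_direct_overlap(self):
        chip = track([("1", 10_000, 10_400)])
        assert annotate.annotate_histone(
            peaks_df([("1", 9_000, 10_000)]), chip, flank_bp=0).tolist() == [False]
        assert annotate.annotate_histone(
            peaks_df([("1", 9_000, 10_001)]), chip, flank_bp=0).tolist() == [True]


def small_gene_model():
    genes = pd.DataFrame([
        dict(gene_id="gP", chrom="1", start=10_000, end=16_000, strand="+",
             tss=10_000, tts=15_999, cds_start=10_300, cds_end=15_700),
        dict(gene_id="gM", chrom="1", start=40_000, end=46_000, strand="-",
             tss=45_999, tts=40_000, cds_start=40_300, cds_end=45_700),
    ])
    exons = pd.DataFrame([
        dict(gene_id="gP", chrom="1", start=10_000, end=11_000),
        dict(gene_id="gP", chrom="1", start=14_000, end=16_000),
        dict(gene_id="gM", chrom="1", start=40_000, end=41_000),
        dict(gene_id="gM", chrom="1", start=44_000, end=46_000),
    ])
    return GeneModel(genes, exons)


class TestGenomicFeature:
    def test_summit_near_plus_tss_is_promoter_with_positive_distance(self):
        out = annotate.annotate_genomic_feature(
            peaks_df([("1", 10_000, 10_100)]), small_gene_model())
        assert out["genomic_feature"][0] == "promoter_tss"
        assert out["nearest_gene_id"][0] == "gP"
        assert out["tss_distance_bp"][0] == 50

    def test_downstream_of_promoter_window_is_utr5_with_signed_distance(self):
        # summit 200 bp into the first exon, upstream of the CDS start
        out = annotate.annotate_genomic_feature(
            peaks_df([("1", 10_100, 10_300)]), small_gene_model())
        assert out["genomic_feature"][0] == "utr5"
        assert out["tss_distance_bp"][0] == 200

    def test_minus_strand_distance_flips_orientation(self):
        # summit 50 bp genomically left of a minus-strand TSS = downstream
        out = annotate.annotate_genomic_feature(
            peaks_df([("1", 45_899, 46_000)]), small_gene_model())
        assert out["tss_distance_bp"][0] == 50
        assert out["genomic_feature"][0] == "promoter_tss"

    def test_gene_desert_is_intergenic(self):
        out = annotate.annotate_genomic_feature(
            peaks_df([("1", 25_000, 25_400)]), small_gene_model())
        assert out["genomic_feature"][0] == "intergenic"
        assert out["nearest_gene_id"][0] in ("gP", "gM")

    def test_intron_and_exon_assignment(self):
        out = annotate.annotate_genomic_feature(
            peaks_df([("1", 12_400, 12_600), ("1", 14_400, 14_600)]), small_gene_model())
        assert out["genomic_feature"].tolist() == ["intron", "exon"]

    def test_utr_assignment_follows_strand(self):
        # exonic, past the CDS end of the plus-strand gene -> 3' UTR
        out = annotate.annotate_genomic_feature(
            peaks_df([("1", 15_750, 15_950)]), small_gene_model())
        assert out["genomic_feature"][0] == "utr3"

    def test_record_order_does_not_change_assignments(self):
        model = small_gene_model()
        shuffled = GeneModel(model.genes.iloc[::-1], model.exons.iloc[::-1])
        pk = peaks_df([("1", 10_100, 10_300), ("1", 25_000, 25_400),
                       ("1", 12_400, 12_600)])
        a = annotate.annotate_genomic_feature(pk, model)
        b = annotate.annotate_genomic_feature(pk, shuffled)
        assert a["genomic_feature"].tolist() == b["genomic_feature"].tolist()
        assert a["nearest_gene_id"].tolist() == b["nearest_gene_id"].tolist()

    def test_empty_gene_model_yields_null_fields(self):
        out = annotate.annotate_genomic_feature(
            peaks_df([("1", 100, 300)]), GeneModel(pd.DataFrame(), pd.DataFrame()))
        assert out["genomic_feature"][0] == "intergenic"
        assert out["nearest_gene_id"][0] is None

    def test_every_summit_gets_exactly_one_feature(self, small_study):
        truth = small_study.truth.copy()
        truth["summit"] = (truth["start"] + truth["end"]) // 2
        out = annotate.annotate_genomic_feature(truth, small_study.gene_model)
        assert out["genomic_feature"].isin(annotate.FEATURE_PRECEDENCE).all()


class TestTissueClassification:
    LOOKUP = pd.DataFrame(dict(
        gene_id=["g1", "g2", "g3", "g4"],
        rna_tissue_specificity=["Low tissue specificity", "Tissue enhanced",
                                "Group enriched", "Tissue enriched"]))

    def test_category_mapping(self):
        got = annotate.classify_tissue(["g1", "g2", "g3", "g4"], self.LOOKUP)
        assert got.tolist() == ["ubiquitous", "tissue_specific",
                                "tissue_specific", "tissue_specific"]

    def test_absent_gene_is_unknown(self):
        assert annotate.classify_tissue(["nope"], self.LOOKUP).tolist() == ["unknown"]

    def test_unrecognized_category_raises_naming_it(self):
        bad = pd.DataFrame(dict(gene_id=["g"], rna_tissue_specificity=["mystery class"]))
        with pytest.raises(ValueError, match="mystery class"):
            annotate.classify_tissue(["g"], bad)

    def test_unicode_hyphens_normalized(self):
        lut = pd.DataFrame(dict(gene_id=["g"], rna_tissue_specificity=["Tissue‐enhanced"]))
        assert annotate.classify_tissue(["g"], lut).tolist() == ["tissue_specific"]


class TestExpressionByGroup:
    def test_identical_groups_give_null_p(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 1, 100)
        expr = pd.Series(np.concatenate([vals, vals]))
        groups = pd.Series(["a"] * 100 + ["b"] * 100)
        _, p, _ = annotate.expression_by_group(expr, groups)
        assert p > 0.5

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        expr = pd.Series(np.concatenate([
            2.0 ** rng.normal(0, 1, 50), 2.0 ** rng.normal(0, 1, 50),
            2.0 ** rng.normal(5, 1, 50)]))
        groups = pd.Series(["a"] * 50 + ["b"] * 50 + ["c"] * 50)
        summary, p, pairwise = annotate.expression_by_group(expr, groups)
        assert p < 1e-10
        assert len(pairwise) == 3
        assert pairwise["p_bonferroni"].max() <= 1.0

    def test_synth_accessible_genes_expressed_higher(self, default_study):
        truth = default_study.truth
        expr = default_study.expression.set_index("gene_id")["tpm"]
        rows = truth.drop_duplicates("nearest_gene_id")
        groups = pd.Series(np.where(rows["accessible"], "accessible", "masked"),
                           index=rows["nearest_gene_id"])
        summary, p, _ = annotate.expression_by_group(
            expr.loc[groups.index].reset_index(drop=True),
            groups.reset_index(drop=True))
        med = summary.set_index("group")["median"]
        assert med["accessible"] > med["masked"]

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            annotate.expression_by_group(pd.Series([1.0, 2.0]), pd.Series(["a", "b"]))


def test_accessible_fraction_round_trip(default_study, default_peaks):
    """Accessibility of called peaks reproduces the configured fraction."""
    acc = annotate.annotate_accessibility(default_peaks, default_study.chromatin["atac"])
    assert acc.mean() == pytest.approx(default_study.config.accessible_fraction, abs=0.05)
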
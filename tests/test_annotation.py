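import numpy as np
import pandas as pd
import pytest

import capclust as cc
from capclust.annotation import Transcript, TranscriptModels


def tc(chrom, peak, strand="+", width=10):
    start = peak - width // 2
    return cc.TagCluster(chrom, start, start + width, strand, peak, 5.0, 2.0)


def bc(chrom, maxpos, half=200):
    return cc.BidirectionalCluster(chrom, maxpos - half, maxpos + half, maxpos, 0.99, 3.0)


@pytest.fixture
def models():
    """Two-isoform coding gene on +, a minus-strand gene, and a lone
    non-coding transcript.

    geneA (+, chr1): txA1 exons [1000,1200)+[2000,2500), CDS [1100,2200);
                     txA2 exons [1500,2500) -> txA1's promoter region is
                     inside txA2's upstream/proximal zone and txA2's TSS
                     (1500) falls in txA1's intron.
    geneB (-, chr1): txB exon [8000,9000), TSS at 8999.
    geneC (+, chr2): txC single exon [1000,1600), non-coding.
    """
    return TranscriptModels(
        [
            Transcript("txA1", "geneA", "chr1", "+", [(1000, 1200), (2000, 2500)], [(1100, 1200), (2000, 2200)]),
            Transcript("txA2", "geneA", "chr1", "+", [(1500, 2500)], [(2000, 2200)]),
            Transcript("txB", "geneB", "chr1", "-", [(8000, 9000)]),
            Transcript("txC", "geneC", "chr2", "+", [(1000, 1600)]),
        ]
    )


class TestLoadModels:
    def test_minimal_gtf_round_trip(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        models = cc.load_models(gtf)
        t = models.transcripts["t1"]
        assert t.exons == [(1000, 1200)]  # 1-based inclusive -> 0-based half-open
        assert t.tss == 1000

    def test_minus_strand_tss_at_maximal_coordinate(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\texon\t301\t400\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        t = cc.load_models(gtf).transcripts["t1"]
        assert t.tss == 399
        assert t.introns == [(200, 300)]

    def test_write_then_load_preserves_structure(self, tmp_path, models):
        path = tmp_path / "out.gtf"
        models.write_gtf(path)
        reloaded = cc.load_models(path)
        assert set(reloaded.transcripts) == set(models.transcripts)
        assert reloaded.transcripts["txA1"].cds == models.transcripts["txA1"].cds

    def test_missing_ids_rejected(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("chr1\tsrc\texon\t1\t100\t.\t+\t.\tfoo bar\n")
        with pytest.raises(Exception):
            cc.load_models(gtf)


class TestHierarchy:
    def test_promoter_wins_over_other_isoforms_context(self, models):
        # txA1's TSS (1000) is inside txA2's proximal zone; promoter outranks
        clusters = [tc("chr1", 1000)]
        assert cc.annotate_clusters(clusters, models) == ["promoter"]
        assert clusters[0].category == "promoter"

    def test_upstream_500bp_is_proximal(self, models):
        assert cc.annotate_clusters([tc("chr2", 500)], models) == ["proximal"]

    def test_antisense_for_opposite_strand_overlap_only(self, models):
        assert cc.annotate_clusters([tc("chr1", 8500, strand="+")], models) == ["antisense"]

    def test_categories_detail(self, models):
        cases = {
            2100: "CDS",        # inside both isoforms' CDS [2000,2200)
            1050: "promoter",   # within 100 bp of txA1 TSS
            1300: "proximal",   # 200 bp upstream of txA2 TSS, inside txA1 intron
            1700: "fiveUTR",    # txA2 exon upstream of its CDS, txA1 intron
            2300: "threeUTR",   # exonic past the CDS end 2200
        }
        got = cc.annotate_clusters([tc("chr1", p) for p in cases], models)
        assert got == list(cases.values())

    def test_minus_strand_exon(self, models):
        assert cc.annotate_clusters([tc("chr1", 8500, strand="-")], models) == ["exon"]

    def test_intergenic_when_nothing_overlaps(self, models):
        assert cc.annotate_clusters([tc("chr1", 50_000)], models) == ["intergenic"]

    def test_unstranded_bc_matches_either_strand_never_antisense(self, models):
        assert cc.annotate_clusters([bc("chr1", 8500, half=10)], models) == ["exon"]

    def test_every_cluster_gets_exactly_one_category(self, models):
        rng = np.random.default_rng(2)
        clusters = [tc("chr1", int(p), s) for p, s in zip(rng.integers(100, 99_000, 50), rng.choice(["+", "-"], 50))]
        cats = cc.annotate_clusters(clusters, models)
        assert len(cats) == 50
        assert all(c in cc.CategoryConfig().categories for c in cats)

    def test_permuted_priority_changes_only_multimatch_clusters(self, models):
        rng = np.random.default_rng(3)
        clusters = [tc("chr1", int(p)) for p in rng.integers(100, 99_000, 80)]
        default = cc.annotate_clusters(clusters, models)
        permuted_order = list(reversed(cc.CategoryConfig().categories))
        permuted = cc.annotate_clusters(clusters, models, cc.CategoryConfig(categories=permuted_order))
        for a, b in zip(default, permuted):
            if a == b:
                continue
            # a change means the peak matched at least two categories
            assert a != "intergenic" and b != "intergenic"


class TestEnhancerSelection:
    def test_intronic_bc_kept(self, models):
        kept = cc.select_enhancer_candidates([bc("chr1", 1750, half=50)], models)
        # inside txA1's intron but overlapping txA2's exon span -> dropped;
        # use geneB-free intergenic locus on chr2 far from genes instead
        assert kept == []

    def test_truly_intronic_bc(self):
        models = TranscriptModels(
            [Transcript("t1", "g1", "chr1", "+", [(1000, 1200), (9000, 9500)])]
        )
        kept = cc.select_enhancer_candidates([bc("chr1", 5000)], models)
        assert [b.category for b in kept] == ["intron"]

    def test_exon_overlap_dropped_by_span(self):
        models = TranscriptModels(
            [Transcript("t1", "g1", "chr1", "+", [(1000, 1200), (9000, 9500)])]
        )
        # maxpos in the intron but the +-200 span touches the second exon
        assert cc.select_enhancer_candidates([bc("chr1", 8900)], models) == []

    def test_bc_near_tss_dropped(self):
        models = TranscriptModels([Transcript("t1", "g1", "chr1", "+", [(50_000, 60_000)])])
        # 500 bp upstream of the annotated TSS -> inside the 1 kbp zone
        assert cc.select_enhancer_candidates([bc("chr1", 49_500)], models) == []
        # 5 kbp upstream is clear
        kept = cc.select_enhancer_candidates([bc("chr1", 45_000)], models)
        assert [b.category for b in kept] == ["intergenic"]


class TestGeneAssignment:
    def test_single_gene_body_same_strand(self, models):
        assignment = cc.assign_genes([tc("chr1", 2100)], models)
        assert list(assignment.mapping.values()) == ["geneA"]

    def test_intergenic_peak_unassigned(self, models):
        assignment = cc.assign_genes([tc("chr1", 50_000)], models)
        assert list(assignment.mapping.values()) == [None]

    def test_opposite_strand_not_assigned(self, models):
        assignment = cc.assign_genes([tc("chr1", 2100, strand="-")], models)
        assert list(assignment.mapping.values()) == [None]

    def test_nested_genes_resolved_by_nearest_tss(self):
        models = TranscriptModels(
            [
                Transcript("tOuter", "outer", "chr1", "+", [(1000, 20_000)]),
                Transcript("tInner", "inner", "chr1", "+", [(9000, 11_000)]),
            ]
        )
        assignment = cc.assign_genes([tc("chr1", 9100)], models)
        assert list(assignment.mapping.values()) == ["inner"]

    def test_exact_tie_left_unassigned(self):
        models = TranscriptModels(
            [
                Transcript("t1", "g1", "chr1", "+", [(1000, 5000)]),
                Transcript("t2", "g2", "chr1", "+", [(3000, 7000)]),
            ]
        )
        # peak at 2000: 1000 bp from both TSSs (1000 and 3000)
        assignment = cc.assign_genes([tc("chr1", 2000)], models)
        assert list(assignment.mapping.values()) == [None]


def matrix_for(clusters, data):
    counts = pd.DataFrame(data, index=[c.uid for c in clusters])
    features = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.strand) for c in clusters],
        columns=["chrom", "start", "end", "strand"],
        index=counts.index,
    )
    return cc.ExpressionMatrix(features, counts)


class TestGeneMatrixAndComposition:
    @pytest.fixture
    def setup(self):
        models = TranscriptModels(
            [
                Transcript("t1", "g1", "chr1", "+", [(1000, 5000)]),
                Transcript("t2", "g2", "chr1", "+", [(20_000, 30_000)]),
            ]
        )
        clusters = [tc("chr1", 1100), tc("chr1", 3000), tc("chr1", 21_000), tc("chr1", 50_000)]
        assignment = cc.assign_genes(clusters, models)
        matrix = matrix_for(
            clusters,
            {"s0": [10, 5, 7, 2], "s1": [20, 1, 0, 3], "s2": [0, 0, 4, 1]},
        )
        return clusters, assignment, matrix

    def test_gene_matrix_sums_assigned_tcs(self, setup):
        clusters, assignment, matrix = setup
        gmat = cc.gene_matrix(matrix, assignment)
        assert gmat.counts.loc["g1"].tolist() == [15, 21, 0]
        assert gmat.counts.loc["g2"].tolist() == [7, 0, 4]

    def test_count_conservation_over_assigned(self, setup):
        clusters, assignment, matrix = setup
        gmat = cc.gene_matrix(matrix, assignment)
        assigned_ids = list(assignment.assigned())
        assert gmat.counts.values.sum() == matrix.counts.loc[assigned_ids].values.sum()

    def test_composition_fractions_sum_to_one_per_gene(self, setup):
        _, assignment, matrix = setup
        frac = assignment.composition(matrix)
        g1_ids = [cid for cid, g in assignment.assigned().items() if g == "g1"]
        sums = frac.loc[g1_ids].sum(axis=0)
        assert sums["s0"] == pytest.approx(1.0) and sums["s1"] == pytest.approx(1.0)
        assert np.isnan(frac.loc[g1_ids, "s2"]).all()  # zero gene total

    def test_minor_tc_removed_major_kept(self, setup):
        clusters, assignment, matrix = setup
        kept = cc.composition_filter(matrix, assignment, min_fraction=0.1, min_samples=0)
        # TC at 3000 contributes 5/15 and 1/21 and 0 -> passes in 1 sample (> 0)
        assert clusters[0].uid in kept and clusters[1].uid in kept
        kept_strict = cc.composition_filter(matrix, assignment, min_fraction=0.5, min_samples=1)
        assert clusters[1].uid not in kept_strict

    def test_unassigned_tc_kept_unconditionally(self, setup):
        clusters, assignment, matrix = setup
        kept = cc.composition_filter(matrix, assignment, min_fraction=0.99, min_samples=2)
        assert clusters[3].uid in kept

    def test_single_tc_gene_always_kept(self, setup):
        clusters, assignment, matrix = setup
        kept = cc.composition_filter(matrix, assignment, min_fraction=0.1, min_samples=1)
        assert clusters[2].uid in kept  # sole TC of g2, fraction 1.0 where expressed


class TestMultiTcSummary:
    def test_fraction_of_multi_tc_genes(self):
        mapping = {"a": "g1", "b": "g1", "c": "g2", "d": "g3", "e": "g3", "f": "g3", "g": None}
        assignment = cc.GeneAssignment(mapping)
        table, summary = cc.multi_tc_summary(assignment, kept_ids={"a", "c", "d"})
        assert summary["multi_tc_fraction"] == pytest.approx(2 / 3)
        assert summary["multi_tc_fraction_filtered"] == 0.0
        assert table.loc["g3", "n_tcs"] == 3 and table.loc["g3", "n_kept"] == 1

    def test_all_single_tc(self):
        assignment = cc.GeneAssignment({"a": "g1", "b": "g2"})
        _, summary = cc.multi_tc_summary(assignment, kept_ids={"a", "b"})
        assert summary["multi_tc_fraction"] == 0.0

    def test_filter_never_raises_multi_fraction(self):
        rng = np.random.default_rng(1)
        mapping = {f"tc{i}": f"g{rng.integers(0, 10)}" for i in range(40)}
        assignment = cc.GeneAssignment(mapping)
        all_ids = set(mapping)
        some = set(list(mapping)[:20])
        _, full = cc.multi_tc_summary(assignment, all_ids)
        _, filt = cc.multi_tc_summary(assignment, some)
        assert filt["multi_tc_fraction_filtered"] <= full["multi_tc_fraction_filtered"]
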
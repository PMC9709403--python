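import numpy as np
import pandas as pd
import pytest

from polyatac.annotation import (
    CATEGORIES,
    AnnotationConfig,
    accessibility_related_genes,
    annotate_peaks,
    category_proportions,
    classify_summit,
    join_expression,
)
from polyatac.io_formats import GeneModel, Peak


@pytest.fixture
def config():
    return AnnotationConfig()  # 4 kb upstream, 1.5 kb downstream


def _gene_plus(tss=10_000, length=5_000):
    return GeneModel("gA", "chr1", tss, tss + length, "+")


class TestClassifySummit:
    def test_promoter_inclusive_upstream_boundary(self, config):
        gene = _gene_plus()
        a = classify_summit(10_000 - 4_000, "chr1", [gene], config)
        assert a.category == "promoter"
        assert a.distance_to_tss == -4_000

    def test_one_bp_beyond_is_intergenic_upstream(self, config):
        gene = _gene_plus()
        a = classify_summit(5_999, "chr1", [gene], config)
        assert a.category == "intergenic_upstream"

    def test_minus_strand_upstream_is_rightward(self, config):
        # - strand gene spanning [8000, 10001): TSS = 10000
        gene = GeneModel("gB", "chr1", 8_000, 10_001, "-")
        a = classify_summit(11_500, "chr1", [gene], config)
        assert a.category == "promoter"
        assert a.distance_to_tss == -1_500

    def test_genebody_after_promoter_limb(self, config):
        gene = _gene_plus()
        a = classify_summit(10_000 + 1_501, "chr1", [gene], config)
        assert a.category == "genebody"

    def test_downstream_of_tes(self, config):
        gene = _gene_plus()
        a = classify_summit(15_000, "chr1", [gene], config)  # end is 15000; TES 14999
        assert a.category == "intergenic_downstream"

    def test_unassigned_without_genes(self, config):
        a = classify_summit(100, "chrZ", [_gene_plus()], config)
        assert a.category == "unassigned"
        assert a.gene_id is None

    def test_nearest_gene_tie_lexicographic(self, config):
        g1 = GeneModel("g2", "chr1", 10_000, 12_000, "+")
        g2 = GeneModel("g1", "chr1", 30_000, 32_000, "+")
        a = classify_summit(20_000, "chr1", [g1, g2], config)
        assert a.gene_id == "g1"  # |20000-10000| == |20000-30000|; tie -> smaller id

    def test_boundary_sweep_plus_strand(self, config):
        """Exhaustive sweep: category changes exactly at TSS-u, TSS+d+1, TES+1."""
        tss, length = 10_000, 3_000
        gene = GeneModel("gS", "chr1", tss, tss + length, "+")
        u, d = config.promoter_upstream, config.promoter_downstream
        tes = gene.tes
        changes = []
        prev = None
        for pos in range(tss - u - 2, tes + 3):
            cat = classify_summit(pos, "chr1", [gene], config).category
            if cat != prev:
                changes.append((pos, cat))
                prev = cat
        assert changes == [
            (tss - u - 2, "intergenic_upstream"),
            (tss - u, "promoter"),
            (tss + d + 1, "genebody"),
            (tes + 1, "intergenic_downstream"),
        ]

    def test_boundary_sweep_minus_strand_mirror(self, config):
        """Strand symmetry: mirroring the genome flips positions, not categories."""
        genome = 100_000
        tss_plus, length = 10_000, 3_000
        plus = GeneModel("gS", "chr1", tss_plus, tss_plus + length, "+")
        # mirror: position p -> genome - 1 - p
        minus = GeneModel(
            "gS", "chr1", genome - (tss_plus + length), genome - tss_plus, "-"
        )
        u = config.promoter_upstream
        for pos in range(tss_plus - u - 2, plus.tes + 3):
            cat_plus = classify_summit(pos, "chr1", [plus], config).category
            cat_minus = classify_summit(genome - 1 - pos, "chr1", [minus], config).category
            assert cat_plus == cat_minus, pos


class TestAccessibilityGenes:
    def _peak(self, summit_pos, name="p"):
        return Peak("chr1", summit_pos - 50, summit_pos + 50, name=name, summit=50)

    def test_one_peak_labels_gene(self, config):
        gene = _gene_plus()
        counts = accessibility_related_genes([self._peak(9_000)], [gene], config)
        assert counts == {"gA": 1}

    def test_zero_peaks(self, config):
        assert accessibility_related_genes([], [_gene_plus()], config) == {}

    def test_three_peaks_counted(self, config):
        gene = _gene_plus()
        peaks = [self._peak(p, name=f"p{p}") for p in (7_000, 9_000, 11_000)]
        counts = accessibility_related_genes(peaks, [gene], config)
        assert counts == {"gA": 3}

    def test_peak_outside_window_ignored(self, config):
        gene = _gene_plus()
        counts = accessibility_related_genes([self._peak(50_000)], [gene], config)
        assert counts == {}


class TestCategoryProportions:
    def _annot(self, category):
        from polyatac.annotation import PeakAnnotation

        return PeakAnnotation("p", "chr1", 0, "g", 0, category)

    def test_all_promoter(self):
        props = category_proportions([self._annot("promoter")] * 4)
        assert props["promoter"] == 1.0
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mixed(self):
        annots = (
            [self._annot("promoter")] * 2
            + [self._annot("genebody")]
            + [self._annot("intergenic_upstream")]
        )
        props = category_proportions(annots)
        assert props == {
            "promoter": 0.5,
            "genebody": 0.25,
            "intergenic_upstream": 0.25,
            "intergenic_downstream": 0.0,
        }

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            category_proportions([])

    def test_unassigned_excluded_with_warning(self):
        annots = [self._annot("promoter"), self._annot("unassigned")]
        with pytest.warns(UserWarning, match="unassigned"):
            props = category_proportions(annots)
        assert props["promoter"] == 1.0


class TestJoinExpression:
    def test_disjoint_ids_warn(self):
        expr = pd.DataFrame({"gene_id": ["gX"], "expression": [1.0]})
        with pytest.warns(UserWarning, match="50%"):
            joined, groups = join_expression({"gA": 2}, expr)
        assert joined["n_promoter_peaks"].tolist() == [0]

    def test_all_zero_single_group(self):
        expr = pd.DataFrame({"gene_id": ["g1", "g2"], "expression": [1.0, 2.0]})
        joined, groups = join_expression({}, expr)
        assert groups["peak_group"].tolist() == ["0"]

    def test_expression_tracks_peak_count(self):
        rng = np.random.default_rng(0)
        n = 400
        counts = rng.integers(0, 5, size=n)
        expr_values = counts * 10.0 + rng.normal(0, 0.5, n)
        genes = [f"g{i}" for i in range(n)]
        expr = pd.DataFrame({"gene_id": genes, "expression": expr_values})
        peak_counts = {g: int(c) for g, c in zip(genes, counts) if c > 0}
        joined, groups = join_expression(peak_counts, expr)
        medians = groups.set_index("peak_group")["median"]
        assert (
            medians["0"] < medians["1"] < medians["2"] < medians[">=3"]
        )


class TestAnnotatePeaks:
    def test_batch_matches_single(self, config):
        genes = [
            GeneModel("g1", "chr1", 10_000, 15_000, "+"),
            GeneModel("g2", "chr1", 40_000, 43_000, "-"),
        ]
        peaks = [
            Peak("chr1", 8_900, 9_100, name="a", summit=100),
            Peak("chr1", 44_400, 44_600, name="b", summit=100),
        ]
        annots = annotate_peaks(peaks, genes, config)
        assert [a.category for a in annots] == ["promoter", "promoter"]
        assert [a.gene_id for a in annots] == ["g1", "g2"]
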
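import numpy as np
import pytest

from polyatac.io_formats import ChromSizes, GeneModel, TagRecord
from polyatac.signal_tracks import (
    MetageneConfig,
    PileupConfig,
    binned_correlation,
    metagene_matrix,
    pileup,
    tss_enrichment,
)

from conftest import make_tags
from oracles import brute_force_pileup


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 20_000})


class TestPileup:
    def test_plus_tag_window(self, sizes):
        # cut at 1000, shift -75, extsize 150 -> unit coverage on [925, 1075)
        tags = [TagRecord("chr1", 1000, 1050, "+", 60)]
        cov = pileup(tags, PileupConfig(spmr=False), sizes)["chr1"]
        assert cov[924] == 0 and cov[925] == 1 and cov[1074] == 1 and cov[1075] == 0
        assert cov.sum() == 150

    def test_spmr_single_tag(self, sizes):
        tags = [TagRecord("chr1", 1000, 1050, "+", 60)]
        cov = pileup(tags, PileupConfig(spmr=True), sizes)["chr1"]
        assert cov[1000] == pytest.approx(1e6)

    def test_additivity(self, sizes):
        tags = [TagRecord("chr1", 1000, 1050, "+", 60)] * 2
        cov = pileup(tags, PileupConfig(spmr=False), sizes)["chr1"]
        assert cov[1000] == 2

    def test_minus_strand_mirrors_plus(self, sizes):
        # a +/- pair cutting at the same site covers symmetric windows
        conf = PileupConfig(spmr=False)
        plus = pileup([TagRecord("chr1", 1000, 1050, "+", 60)], conf, sizes)["chr1"]
        minus = pileup([TagRecord("chr1", 951, 1001, "-", 60)], conf, sizes)["chr1"]
        # - strand cut at 1000: window [926, 1076) vs + window [925, 1075)
        assert minus.sum() == 150
        assert abs(int(np.flatnonzero(minus).mean()) - int(np.flatnonzero(plus).mean())) <= 1

    def test_mass_conservation_no_clipping(self, sizes):
        rng = np.random.default_rng(1)
        tags = make_tags("chr1", rng.integers(500, 19_000, size=300))
        cov = pileup(tags, PileupConfig(spmr=False), sizes)["chr1"]
        assert cov.sum() == 300 * 150

    def test_spmr_mass(self, sizes):
        rng = np.random.default_rng(2)
        tags = make_tags("chr1", rng.integers(500, 19_000, size=400))
        cov = pileup(tags, PileupConfig(spmr=True), sizes)["chr1"]
        # total mass = extsize * 1e6 under SPMR, independent of library size
        assert cov.sum() == pytest.approx(150 * 1e6)

    def test_clipping_warns(self, sizes):
        tags = [TagRecord("chr1", 10, 60, "+", 60)]
        with pytest.warns(UserWarning, match="clipped"):
            cov = pileup(tags, PileupConfig(spmr=False), sizes)["chr1"]
        assert cov.sum() < 150

    def test_matches_brute_force(self, sizes):
        rng = np.random.default_rng(7)
        plus = make_tags("chr1", rng.integers(300, 19_000, size=100), strand="+")
        minus = make_tags("chr1", rng.integers(300, 19_000, size=100), strand="-")
        tags = plus + minus
        fast = pileup(tags, PileupConfig(spmr=False), sizes)["chr1"]
        slow = brute_force_pileup(tags, -75, 150, sizes)["chr1"]
        np.testing.assert_array_equal(fast.astype(np.int64), slow)


class TestBinnedCorrelation:
    def _uniform_track(self, sizes, seed, scale=1.0):
        rng = np.random.default_rng(seed)
        return {"chr1": rng.poisson(5, size=sizes["chr1"]).astype(float) * scale}

    def test_self_correlation(self, sizes):
        t = self._uniform_track(sizes, 0)
        corr = binned_correlation([t, t], bin_bp=100)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_scale_invariance(self, sizes):
        t = self._uniform_track(sizes, 0)
        t2 = {"chr1": 2.0 * t["chr1"]}
        corr = binned_correlation([t, t2], bin_bp=100)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_independent_tracks_near_zero(self):
        # two independent Poisson(5) bin vectors, 10,000 bins
        sizes = ChromSizes({"chr1": 100_000})
        rng = np.random.default_rng(123)
        a = {"chr1": np.repeat(rng.poisson(5, 10_000), 10).astype(float)}
        b = {"chr1": np.repeat(rng.poisson(5, 10_000), 10).astype(float)}
        corr = binned_correlation([a, b], bin_bp=10)
        assert abs(corr[0, 1]) < 0.05

    def test_zero_variance_is_nan(self, sizes):
        flat = {"chr1": np.ones(sizes["chr1"])}
        noisy = self._uniform_track(sizes, 1)
        corr = binned_correlation([flat, noisy], bin_bp=100)
        assert np.isnan(corr[0, 1])
        assert corr[0, 0] == 1.0

    def test_symmetric_psd(self, sizes):
        tracks = [self._uniform_track(sizes, s) for s in range(4)]
        corr = binned_correlation(tracks, bin_bp=100)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        eigvals = np.linalg.eigvalsh(corr)
        assert eigvals.min() > -1e-9

    def test_requires_two_tracks(self, sizes):
        with pytest.raises(ValueError):
            binned_correlation([self._uniform_track(sizes, 0)])


class TestMetagene:
    def _sizes(self):
        return ChromSizes({"chr1": 40_000})

    def test_uniform_track_uniform_matrix(self):
        sizes = self._sizes()
        track = {"chr1": np.full(sizes["chr1"], 3.5)}
        genes = [GeneModel("g1", "chr1", 10_000, 20_000, "+")]
        matrix, means, ids = metagene_matrix(track, genes)
        assert ids == ["g1"]
        np.testing.assert_allclose(matrix, 3.5)
        np.testing.assert_allclose(means, 3.5)

    def test_tss_signal_lands_at_upstream_boundary_column(self):
        sizes = self._sizes()
        track = {"chr1": np.zeros(sizes["chr1"])}
        track["chr1"][10_000:10_010] = 1.0  # exactly the first body bin of a + gene
        genes = [GeneModel("g1", "chr1", 10_000, 20_000, "+")]
        conf = MetageneConfig()
        matrix, _, _ = metagene_matrix(track, genes, conf)
        col = int(np.argmax(matrix[0]))
        assert col == conf.upstream // conf.bin_size

    def test_minus_strand_reversal(self):
        sizes = self._sizes()
        track = {"chr1": np.zeros(sizes["chr1"])}
        track["chr1"][19_990:20_000] = 1.0  # TSS-side bin of a - gene
        genes = [GeneModel("g1", "chr1", 10_000, 20_000, "-")]
        conf = MetageneConfig()
        matrix, _, _ = metagene_matrix(track, genes, conf)
        col = int(np.argmax(matrix[0]))
        assert col == conf.upstream // conf.bin_size

    def test_skip_zeros_drops_empty_rows(self):
        sizes = self._sizes()
        track = {"chr1": np.zeros(sizes["chr1"])}
        track["chr1"][10_000:11_000] = 1.0
        genes = [
            GeneModel("g1", "chr1", 10_000, 20_000, "+"),
            GeneModel("g2", "chr1", 30_000, 35_000, "+"),
        ]
        matrix, _, ids = metagene_matrix(track, genes, MetageneConfig(skip_zeros=True))
        assert ids == ["g1"]

    def test_requires_genes(self):
        with pytest.raises(ValueError):
            metagene_matrix({"chr1": np.zeros(100)}, [])


class TestTssEnrichment:
    def _setup(self, signal=None):
        sizes = ChromSizes({"chr1": 30_000})
        track = {"chr1": np.ones(sizes["chr1"])}
        if signal is not None:
            track["chr1"] = signal
        genes = [GeneModel("g1", "chr1", 15_000, 20_000, "+")]
        return track, genes

    def test_uniform_track_scores_exactly_one(self):
        track, genes = self._setup()
        assert tss_enrichment(track, genes) == 1.0

    def test_doubled_tss_signal_scores_two(self):
        sig = np.ones(30_000)
        sig[15_000 - 50 : 15_000 + 51] = 2.0
        track, genes = self._setup(sig)
        assert tss_enrichment(track, genes) == pytest.approx(2.0, abs=0.01)

    def test_minus_strand_symmetry(self):
        sig = np.ones(30_000)
        sig[19_999 - 50 : 19_999 + 51] = 2.0
        track = {"chr1": sig}
        genes = [GeneModel("g1", "chr1", 15_000, 20_000, "-")]
        assert tss_enrichment(track, genes) == pytest.approx(2.0, abs=0.01)

    def test_empty_gene_list_errors(self):
        track, _ = self._setup()
        with pytest.raises(ValueError):
            tss_enrichment(track, [])

    def test_zero_flank_returns_nan(self):
        sig = np.zeros(30_000)
        sig[15_000] = 5.0
        track, genes = self._setup(sig)
        with pytest.warns(UserWarning, match="flank"):
            assert np.isnan(tss_enrichment(track, genes))
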
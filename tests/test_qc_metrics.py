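import numpy as np
import pytest

from polyatac.io_formats import ChromSizes, FragmentRecord, Peak
from polyatac.qc_metrics import (
    SpotConfig,
    fragment_length_profile,
    frip,
    merge_intervals,
    spot,
)
from polyatac.simulate import SimConfig, simulate_library

from conftest import make_tags


class TestFrip:
    def test_arithmetic(self):
        tags = make_tags("chr1", [50, 150, 250, 350, 1_000, 2_000, 3_000, 4_000, 5_000, 6_000])
        peaks = [Peak("chr1", 0, 400, summit=10)]  # first 4 cut sites inside
        assert frip(tags, peaks) == pytest.approx(0.4)

    def test_whole_genome_peak(self):
        tags = make_tags("chr1", [50, 150, 250])
        peaks = [Peak("chr1", 0, 10_000, summit=1)]
        assert frip(tags, peaks) == 1.0

    def test_empty_peak_set(self):
        tags = make_tags("chr1", [50])
        assert frip(tags, []) == 0.0

    def test_no_tags_is_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(frip([], [Peak("chr1", 0, 100, summit=0)]))

    def test_invariant_under_peak_permutation(self):
        rng = np.random.default_rng(0)
        tags = make_tags("chr1", rng.integers(0, 10_000, size=500))
        peaks = [Peak("chr1", s, s + 200, summit=0) for s in (1_000, 4_000, 7_000)]
        shuffled = [peaks[2], peaks[0], peaks[1]]
        assert frip(tags, peaks) == frip(tags, shuffled)

    def test_invariant_under_peak_splitting(self):
        rng = np.random.default_rng(1)
        tags = make_tags("chr1", rng.integers(0, 10_000, size=500))
        whole = [Peak("chr1", 2_000, 3_000, summit=0)]
        split = [Peak("chr1", 2_000, 2_500, summit=0), Peak("chr1", 2_500, 3_000, summit=0)]
        assert frip(tags, whole) == frip(tags, split)

    def test_fragment_overlap_mode(self):
        # tag [90,140) overlaps peak [100,200) but its + cut site (90) is outside
        tags = make_tags("chr1", [90])
        peaks = [Peak("chr1", 100, 200, summit=0)]
        assert frip(tags, peaks) == 0.0
        assert frip(tags, peaks, count_fragments=True) == 1.0


class TestMergeIntervals:
    def test_merge(self):
        assert merge_intervals([(0, 10), (5, 20), (30, 40), (40, 50)]) == [(0, 20), (30, 50)]


class TestSpot:
    def test_all_tags_one_window(self):
        sizes = ChromSizes({"chr1": 100_000})
        tags = make_tags("chr1", [5_000 + i for i in range(100)])
        assert spot(tags, sizes) == 1.0

    def test_uniform_tags_near_zero(self):
        sizes = ChromSizes({"chr1": 500_000})
        rng = np.random.default_rng(42)
        tags = make_tags("chr1", sorted(int(p) for p in rng.integers(0, 500_000, size=20_000)))
        s = spot(tags, sizes)
        # false-positive windows at z >= 2 carry a small fraction of tags
        assert s < 0.15

    def test_no_tags_nan(self, toy_sizes):
        with pytest.warns(UserWarning):
            assert np.isnan(spot([], toy_sizes))

    def test_tracks_in_peak_fraction(self):
        # SPOT approximates FRiP measured against the true signal regions;
        # cut sites of in-peak fragments fall within peak +/- length/2, so
        # the truth regions are padded by half the (fixed) fragment length
        config = SimConfig(
            seed=33,
            chromosomes=(("chr1A", 500_000),),
            n_genes=30,
            n_distal_peaks=10,
            n_fragments=40_000,
            in_peak_fraction=0.5,
            contamination_rate=0.0,
            length_components=((75.0, 10.0, 1.0),),
        )
        truth = simulate_library(config)
        padded = [
            Peak(p.chrom, max(0, p.start - 60), p.end + 60, summit=0)
            for p in truth.truth_peaks
        ]
        truth_frip = frip(truth.tags, padded)
        s = spot(truth.tags, truth.chrom_sizes)
        assert s == pytest.approx(truth_frip, abs=0.05)

    def test_monotone_in_signal_fraction(self):
        values = []
        for alpha in (0.1, 0.3, 0.6):
            config = SimConfig(
                seed=34,
                chromosomes=(("chr1A", 400_000),),
                n_genes=20,
                n_distal_peaks=5,
                n_fragments=20_000,
                in_peak_fraction=alpha,
                contamination_rate=0.0,
            )
            truth = simulate_library(config)
            values.append(spot(truth.tags, truth.chrom_sizes))
        assert values[0] < values[1] < values[2]
        assert all(0 <= v <= 1 for v in values)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SpotConfig(hotspot_window=1_000, background_window=500)


class TestFragmentLengthProfile:
    def test_all_nfr(self):
        frags = [FragmentRecord("chr1", 0, 75) for _ in range(500)]
        profile = fragment_length_profile(frags)
        assert profile.nfr_fraction == 1.0
        assert profile.periodicity == pytest.approx(0.0, abs=0.05)

    def test_bimodal_mixture_recovery(self):
        rng = np.random.default_rng(8)
        n = 20_000
        comp = rng.random(n) < 0.5
        lengths = np.where(
            comp, rng.normal(75, 10, n), rng.normal(265, 15, n)
        )
        lengths = np.clip(np.round(lengths), 20, 1_000).astype(int)
        frags = [FragmentRecord("chr1", 0, int(l)) for l in lengths]
        profile = fragment_length_profile(frags)
        assert len(profile.modes) >= 2
        assert abs(profile.modes[0] - 75) < 20
        assert abs(profile.modes[1] - 265) < 20
        lo, hi = profile.mode_fractions
        assert lo == pytest.approx(0.5, abs=0.03)
        assert hi == pytest.approx(0.5, abs=0.03)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fragment_length_profile([])

    def test_low_confidence_flag(self):
        frags = [FragmentRecord("chr1", 0, 100 + i) for i in range(50)]
        assert fragment_length_profile(frags).low_confidence

    def test_histogram_sums_to_n(self):
        rng = np.random.default_rng(9)
        frags = [FragmentRecord("chr1", 0, int(l)) for l in rng.integers(20, 900, size=1_000)]
        profile = fragment_length_profile(frags)
        assert profile.histogram.sum() == 1_000

    def test_periodic_library_scores_high(self):
        # strongly nucleosome-banded library: peaks every ~190 bp
        rng = np.random.default_rng(10)
        n = 30_000
        comp = rng.choice(3, size=n, p=[0.4, 0.4, 0.2])
        means = np.array([80, 270, 460])[comp]
        lengths = np.clip(np.round(rng.normal(means, 12)), 20, 1_000).astype(int)
        frags = [FragmentRecord("chr1", 0, int(l)) for l in lengths]
        banded = fragment_length_profile(frags).periodicity
        flat = fragment_length_profile(
            [FragmentRecord("chr1", 0, int(l)) for l in rng.integers(20, 900, size=n)]
        ).periodicity
        assert banded > flat
        assert banded > 0.3
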
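"""Signal-to-noise scores (FRiP, SPOT) and fragment-length diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import ChromSizes, Peak

__all__ = [
    "SpotConfig",
    "FragmentLengthProfile",
    "merge_intervals",
    "frip",
    "spot",
    "fragment_length_profile",
]


@dataclass(frozen=True)
class SpotConfig:
    hotspot_window: int = 250
    background_window: int = 50_000
    z_threshold: float = 2.0

    def __post_init__(self):
        if self.background_window <= self.hotspot_window:
            raise ValueError("background window must exceed hotspot window")


def merge_intervals(intervals):
    """Merge overlapping or abutting (start, end) intervals; returns sorted list."""
    ivs = sorted(intervals)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _cut_sites_by_chrom(tags) -> dict[str, np.ndarray]:
    sites: dict[str, list[int]] = {}
    for t in tags:
        sites.setdefault(t.chrom, []).append(t.cut_site)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in sites.items()}


def frip(tags, peaks, count_fragments: bool = False) -> float:
    """Fraction of tags whose cut site falls inside a peak (NaN if no tags).

    Overlapping peaks are merged first, so abutting/overlapping peak sets
    give identical scores.  ``count_fragments`` switches to counting tags
    whose full interval overlaps a peak.
    """
    tags = list(tags)
    if not tags:
        warnings.warn("frip: no tags; returning NaN", stacklevel=2)
        return float("nan")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged = {c: merge_intervals(v) for c, v in by_chrom.items()}
    starts = {c: np.array([s for s, _ in ivs]) for c, ivs in merged.items()}
    ends = {c: np.array([e for _, e in ivs]) for c, ivs in merged.items()}
    inside = 0
    for t in tags:
        if t.chrom not in merged:
            continue
        if count_fragments:
            lo, hi = t.start, t.end
            i = np.searchsorted(ends[t.chrom], lo, side="right")
            hit = i < starts[t.chrom].size and starts[t.chrom][i] < hi
        else:
            pos = t.cut_site
            i = np.searchsorted(starts[t.chrom], pos, side="right") - 1
            hit = i >= 0 and pos < ends[t.chrom][i]
        if hit:
            inside += 1
    return inside / len(tags)


def spot(tags, chrom_sizes: ChromSizes, config: SpotConfig = SpotConfig()) -> float:
    """Signal Portion Of Tags under a binomial local-background model.

    The genome is tiled into ``hotspot_window`` bins.  For each bin the
    expected tag count is (local tags) * w/W from the surrounding
    ``background_window``; bins with binomial z-score >= ``z_threshold`` are
    hotspots.  SPOT = tags in hotspot bins / total tags.
    """
    tags = list(tags)
    if not tags:
        warnings.warn("spot: no tags; returning NaN", stacklevel=2)
        return float("nan")
    sites = _cut_sites_by_chrom(tags)
    w = config.hotspot_window
    in_hotspot = 0
    for chrom in chrom_sizes:
        if chrom not in sites:
            continue
        pos = sites[chrom]
        length = chrom_sizes[chrom]
        nbins = (length + w - 1) // w
        obs = np.bincount(pos // w, minlength=nbins).astype(np.float64)
        csum = np.concatenate(([0.0], np.cumsum(obs)))
        half_bins = config.background_window // (2 * w)
        bins = np.arange(nbins)
        lo = np.maximum(0, bins - half_bins)
        hi = np.minimum(nbins, bins + half_bins + 1)
        local = csum[hi] - csum[lo]
        frac = 1.0 / (hi - lo)  # w / actual background span
        exp = local * frac
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (obs - exp) / np.sqrt(exp * (1.0 - frac))
        hot = (z >= config.z_threshold) & (exp > 0)
        if hot.any():
            in_hotspot += int(obs[hot].sum())
    return in_hotspot / len(tags)


@dataclass
class FragmentLengthProfile:
    """Fragment-length histogram with nucleosome-band diagnostics.

    ``histogram[i]`` counts fragments of length i+1 (1..max_length).
    ``periodicity`` is the normalised amplitude of the ~190 bp component of
    the detrended histogram's autocorrelation, in [0, 1].  ``modes`` are the
    detected local maxima of the smoothed histogram; ``mode_fractions`` the
    share of fragments on either side of the first inter-mode valley.
    """

    histogram: np.ndarray
    n_fragments: int
    nfr_fraction: float
    mono_fraction: float
    periodicity: float
    modes: list[int]
    mode_fractions: tuple[float, float] | None
    low_confidence: bool


def fragment_length_profile(
    fragments,
    max_length: int = 1000,
    nfr_max: int = 100,
    mono_range: tuple[int, int] = (180, 247),
    period: int = 190,
) -> FragmentLengthProfile:
    """Histogram + periodicity + nucleosome-band fractions for a fragment list.

    NFR fragments are shorter than ``nfr_max``; mono-nucleosome fragments lie
    in ``mono_range`` (inclusive).  Fewer than 100 fragments flags the
    periodicity as low-confidence.
    """
    lengths = np.asarray([f.length for f in fragments], dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("fragment_length_profile requires >= 1 fragment")
    clipped = np.clip(lengths, 1, max_length)
    hist = np.bincount(clipped, minlength=max_length + 1)[1:].astype(np.float64)
    n = lengths.size
    nfr = float(np.sum(lengths < nfr_max) / n)
    mono = float(np.sum((lengths >= mono_range[0]) & (lengths <= mono_range[1])) / n)

    # periodicity: detrend with a broad moving average, autocorrelate,
    # report the ~period-lag peak relative to lag 0
    kernel = np.ones(101) / 101.0
    trend = np.convolve(hist, kernel, mode="same")
    resid = hist - trend
    var0 = float(np.dot(resid, resid))
    if var0 > 0:
        lags = np.arange(max(1, period - 40), min(hist.size - 1, period + 40))
        ac = np.array([np.dot(resid[:-lag], resid[lag:]) for lag in lags]) / var0
        periodicity = float(np.clip(ac.max(), 0.0, 1.0))
    else:
        periodicity = 0.0

    smooth = np.convolve(hist, np.ones(21) / 21.0, mode="same")
    modes = _local_maxima(smooth, min_prominence=0.05 * smooth.max())
    mode_fractions = None
    if len(modes) >= 2:
        lo, hi = modes[0], modes[1]
        valley = lo + int(np.argmin(smooth[lo:hi]))
        below = float(np.sum(clipped <= valley + 1) / n)
        mode_fractions = (below, 1.0 - below)
    return FragmentLengthProfile(
        histogram=hist,
        n_fragments=n,
        nfr_fraction=nfr,
        mono_fraction=mono,
        periodicity=periodicity,
        modes=[m + 1 for m in modes],  # index -> length
        mode_fractions=mode_fractions,
        low_confidence=n < 100,
    )


def _local_maxima(values: np.ndarray, min_prominence: float) -> list[int]:
    from scipy.signal import find_peaks

    idx, _ = find_peaks(values, prominence=min_prominence)
    return [int(i) for i in idx]
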
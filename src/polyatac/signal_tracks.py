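"""Cut-site pileup tracks, binned correlation and metagene matrices.

The pileup uses shift/extsize semantics: each cut site is moved by ``shift``
in the read's 5'->3' direction and extended ``extsize`` bp downstream, so
the defaults (-75/150) centre a 150 bp window on the Tn5 cut.  SPMR
normalisation divides by (library size / 1e6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import ChromSizes, GeneModel

__all__ = [
    "PileupConfig",
    "MetageneConfig",
    "pileup",
    "binned_correlation",
    "metagene_matrix",
    "tss_enrichment",
]


@dataclass(frozen=True)
class PileupConfig:
    shift: int = -75
    extsize: int = 150
    spmr: bool = True

    def __post_init__(self):
        if self.extsize <= 0:
            raise ValueError("extsize must be > 0")


@dataclass(frozen=True)
class MetageneConfig:
    upstream: int = 3000
    downstream: int = 3000
    body: int = 5000
    bin_size: int = 10
    skip_zeros: bool = False

    def __post_init__(self):
        for name in ("upstream", "downstream", "body", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def tag_windows(tags, config: PileupConfig):
    """Yield the extension window [wstart, wend) for each tag (unclipped).

    + strand: window starts at cut + shift.  - strand: mirrored, the window
    ends just past cut - shift so the two strands cover symmetric intervals
    around the cut site.
    """
    shift, extsize = config.shift, config.extsize
    for tag in tags:
        cut = tag.cut_site
        if tag.strand == "+":
            wstart = cut + shift
        else:
            wstart = cut - shift - extsize + 1
        yield tag.chrom, wstart, wstart + extsize


def pileup(tags, config: PileupConfig, chrom_sizes: ChromSizes) -> dict[str, np.ndarray]:
    """Per-base coverage track; dict chrom -> float64 array of length len(chrom).

    Windows are clipped at chromosome ends.  With SPMR the signal is divided
    by n_tags/1e6.
    """
    tags = list(tags)
    deltas = {name: np.zeros(length + 1) for name, length in chrom_sizes.items()}
    clipped = 0
    for chrom, wstart, wend in tag_windows(tags, config):
        if chrom not in deltas:
            continue
        length = chrom_sizes[chrom]
        s, e = max(0, wstart), min(length, wend)
        if s != wstart or e != wend:
            clipped += 1
        if s >= e:
            continue
        deltas[chrom][s] += 1.0
        deltas[chrom][e] -= 1.0
    if clipped:
        warnings.warn(f"pileup: clipped {clipped} window(s) at chromosome ends", stacklevel=2)
    scale = 1e6 / len(tags) if (config.spmr and tags) else 1.0
    return {name: np.cumsum(d[:-1]) * scale for name, d in deltas.items()}


def binned_means(track: dict[str, np.ndarray], bin_bp: int) -> np.ndarray:
    """Concatenated per-bin mean signal over all chromosomes (last bin may be short)."""
    out = []
    for values in track.values():
        n = values.size
        nbins = (n + bin_bp - 1) // bin_bp
        sums = np.add.reduceat(values, np.arange(0, n, bin_bp))
        widths = np.minimum(np.arange(1, nbins + 1) * bin_bp, n) - np.arange(0, n, bin_bp)
        out.append(sums / widths)
    return np.concatenate(out) if out else np.array([])


def binned_correlation(tracks, bin_bp: int = 10_000) -> np.ndarray:
    """Pairwise Pearson correlation of binned mean signal.

    ``tracks`` is a sequence of per-base track dicts over the same genome.
    Zero-variance tracks yield NaN rows/columns (diagonal stays 1).
    """
    tracks = list(tracks)
    if len(tracks) < 2:
        raise ValueError("binned_correlation requires >= 2 tracks")
    binned = np.vstack([binned_means(t, bin_bp) for t in tracks])
    n = len(tracks)
    corr = np.full((n, n), np.nan)
    sd = binned.std(axis=1)
    np.fill_diagonal(corr, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = np.corrcoef(binned[i], binned[j])[0, 1]
            corr[i, j] = corr[j, i] = r
    return corr


def _gene_oriented_signal(track, gene: GeneModel, abs_start: int, abs_end: int) -> np.ndarray:
    """Signal over [abs_start, abs_end) with out-of-chromosome flanks zero-padded."""
    values = track[gene.chrom]
    length = values.size
    out = np.zeros(abs_end - abs_start)
    s, e = max(0, abs_start), min(length, abs_end)
    if s < e:
        out[s - abs_start : e - abs_start] = values[s:e]
    return out


def metagene_matrix(
    track: dict[str, np.ndarray],
    genes,
    config: MetageneConfig = MetageneConfig(),
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Scaled-regions matrix: upstream + rescaled body + downstream, one row
    per gene, all rows oriented upstream -> downstream.

    Returns (matrix, column_means, row_gene_ids).  With ``skip_zeros``,
    all-zero rows are dropped.  Gene bodies shorter than one bin are built by
    interpolation (flagged via a warning).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("metagene_matrix requires >= 1 gene")
    bs = config.bin_size
    n_up = config.upstream // bs
    n_down = config.downstream // bs
    n_body = config.body // bs
    rows = []
    ids = []
    short_genes = 0
    for gene in genes:
        if gene.chrom not in track:
            continue
        if gene.strand == "+":
            up = _gene_oriented_signal(track, gene, gene.start - config.upstream, gene.start)
            body = _gene_oriented_signal(track, gene, gene.start, gene.end)
            down = _gene_oriented_signal(track, gene, gene.end, gene.end + config.downstream)
        else:
            up = _gene_oriented_signal(track, gene, gene.end, gene.end + config.upstream)[::-1]
            body = _gene_oriented_signal(track, gene, gene.start, gene.end)[::-1]
            down = _gene_oriented_signal(track, gene, gene.start - config.downstream, gene.start)[
                ::-1
            ]
        up_binned = up[up.size - n_up * bs :].reshape(n_up, bs).mean(axis=1)
        down_binned = down[: n_down * bs].reshape(n_down, bs).mean(axis=1)
        if body.size < bs:
            short_genes += 1
        # rescale body to n_body bins by sampling at evenly spaced positions
        positions = (np.arange(n_body) + 0.5) * body.size / n_body
        body_binned = np.interp(positions, np.arange(body.size) + 0.5, body)
        rows.append(np.concatenate([up_binned, body_binned, down_binned]))
        ids.append(gene.gene_id)
    if short_genes:
        warnings.warn(f"metagene_matrix: {short_genes} gene(s) shorter than one bin", stacklevel=2)
    matrix = np.vstack(rows)
    if config.skip_zeros:
        keep = matrix.any(axis=1)
        matrix = matrix[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    return matrix, matrix.mean(axis=0) if matrix.size else np.array([]), ids


def tss_enrichment(
    track: dict[str, np.ndarray],
    genes,
    window: int = 1000,
    flank: int = 100,
    smooth: int = 11,
) -> float:
    """Flank-normalised TSS enrichment score.

    Signal is aggregated over TSS +/- ``window`` (strand-oriented), averaged
    across genes, normalised by the mean of the outer ``flank`` bp on each
    side, smoothed with a centred moving average, and the score is the
    profile maximum.  A uniform track scores exactly 1.0.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("tss_enrichment requires >= 1 gene")
    width = 2 * window + 1
    profile = np.zeros(width)
    n_used = 0
    for gene in genes:
        if gene.chrom not in track:
            continue
        tss = gene.tss
        sig = _gene_oriented_signal(track, gene, tss - window, tss + window + 1)
        if gene.strand == "-":
            sig = sig[::-1]
        profile += sig
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene lies on a chromosome present in the track")
    profile /= n_used
    flank_mean = np.concatenate([profile[:flank], profile[-flank:]]).mean()
    if flank_mean == 0:
        warnings.warn("tss_enrichment: zero flank signal; score undefined", stacklevel=2)
        return float("nan")
    norm = profile / flank_mean
    if smooth > 1:
        # convolve with unit weights, divide once: exact for constant input
        norm = np.convolve(norm, np.ones(smooth), mode="same") / smooth
        # edge bins of 'same' convolution are damped; exclude them from the max
        half = smooth // 2
        norm = norm[half : width - half]
    return float(norm.max())
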
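"""Synthetic fixture generator with known ground truth.

Produces a small genome, gene models, truth peaks, and Tn5 fragment
libraries with nucleosome-periodic fragment lengths, promoter-enriched cut
density, organelle contamination and PCR duplicates — everything the rest
of the toolkit assumes, with no external data.  All randomness flows from a
single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ChromSizes,
    FragmentRecord,
    GeneModel,
    Peak,
    TagRecord,
    open_text,
    write_bedpe_fragments,
    write_chrom_sizes,
    write_gff3_genes,
    write_tagalign,
)

__all__ = ["SimConfig", "TruthRecord", "simulate_library", "simulate_idr_scores", "fragments_to_tags"]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    # replicate libraries share a truth: fix truth_seed and vary seed
    truth_seed: int | None = None
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1A", 2_000_000),
        ("chr2A", 2_000_000),
        ("chrMt", 100_000),
    )
    n_genes: int = 180
    gene_length_range: tuple[int, int] = (1_500, 5_000)
    min_gene_spacing: int = 12_000
    n_distal_peaks: int = 20
    peak_width: int = 300
    in_peak_fraction: float = 0.4   # alpha
    n_fragments: int = 200_000
    # fragment-length mixture: (mean, sd, weight) per component, truncated to [20, 1000]
    length_components: tuple[tuple[float, float, float], ...] = (
        (75.0, 15.0, 0.55),
        (265.0, 20.0, 0.35),
        (460.0, 25.0, 0.10),
    )
    duplicate_rate: float = 0.0
    contamination_rate: float = 0.05
    read_length: int = 50
    expression_gamma: float = 1.5
    expression_noise_sd: float = 0.5

    def __post_init__(self):
        for name in ("in_peak_fraction", "duplicate_rate", "contamination_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(w for _, _, w in self.length_components) - 1.0) > 1e-9:
            raise ValueError("fragment-length mixture weights must sum to 1")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")


@dataclass
class TruthRecord:
    config: SimConfig
    chrom_sizes: ChromSizes
    genes: list[GeneModel]
    truth_peaks: list[Peak]
    fragments: list[FragmentRecord]
    tags: list[TagRecord]
    expression: pd.DataFrame
    n_duplicates: int
    n_organelle: int


def _place_genes(rng, chrom_sizes: ChromSizes, config: SimConfig) -> list[GeneModel]:
    nuclear = chrom_sizes.nuclear_names
    genes = []
    per_chrom = np.array_split(np.arange(config.n_genes), len(nuclear))
    margin = 10_000
    for chrom, idx in zip(nuclear, per_chrom):
        length = chrom_sizes[chrom]
        k = len(idx)
        if k == 0:
            continue
        usable = length - 2 * margin
        slots = np.linspace(margin, margin + usable, k + 1)
        for i, gi in enumerate(idx):
            glen = int(rng.integers(*config.gene_length_range))
            lo = int(slots[i])
            hi = int(slots[i + 1]) - glen - config.min_gene_spacing // 2
            start = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + glen,
                    strand=strand,
                )
            )
    return genes


def _place_truth_peaks(rng, chrom_sizes, genes, config: SimConfig) -> list[Peak]:
    peaks = []
    w = config.peak_width
    # one peak inside each gene promoter window (kept within the chromosome)
    for i, g in enumerate(genes):
        if g.strand == "+":
            lo, hi = g.tss - 3_000, g.tss + 1_000 - w
        else:
            lo, hi = g.tss - 1_000, g.tss + 3_000 - w
        lo = max(0, lo)
        hi = min(chrom_sizes[g.chrom] - w, max(lo + 1, hi))
        start = int(rng.integers(lo, hi))
        peaks.append(
            Peak(chrom=g.chrom, start=start, end=start + w, name=f"truth_prom_{i + 1}")
        )
    # distal peaks, away from genes
    nuclear = chrom_sizes.nuclear_names
    gene_spans = {c: [(g.start - 6_000, g.end + 6_000) for g in genes if g.chrom == c] for c in nuclear}
    placed = 0
    attempts = 0
    while placed < config.n_distal_peaks and attempts < 10_000:
        attempts += 1
        chrom = nuclear[int(rng.integers(len(nuclear)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - w))
        if any(s < start + w and start < e for s, e in gene_spans[chrom]):
            continue
        if any(p.chrom == chrom and p.start < start + w and start < p.end for p in peaks):
            continue
        placed += 1
        peaks.append(Peak(chrom=chrom, start=start, end=start + w, name=f"truth_distal_{placed}"))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def _sample_lengths(rng, n: int, config: SimConfig) -> np.ndarray:
    comps = config.length_components
    choice = rng.choice(len(comps), size=n, p=[w for _, _, w in comps])
    means = np.array([m for m, _, _ in comps])[choice]
    sds = np.array([s for _, s, _ in comps])[choice]
    lengths = rng.normal(means, sds)
    # truncate by resampling out-of-range draws
    bad = (lengths < 20) | (lengths > 1000)
    while bad.any():
        lengths[bad] = rng.normal(means[bad], sds[bad])
        bad = (lengths < 20) | (lengths > 1000)
    return np.round(lengths).astype(np.int64)


def fragments_to_tags(fragments, read_length: int = 50, mapq: int = 60) -> list[TagRecord]:
    """Emit one tag per fragment end (the paired-end read representation)."""
    tags = []
    for f in fragments:
        rl = min(read_length, f.length)
        tags.append(TagRecord(f.chrom, f.start, f.start + rl, "+", mapq))
        tags.append(TagRecord(f.chrom, f.end - rl, f.end, "-", mapq))
    return tags


def simulate_library(config: SimConfig = SimConfig(), outdir=None) -> TruthRecord:
    """Generate one synthetic library (and optionally write the fixture files).

    Cut-site placement: a fraction ``in_peak_fraction`` of non-organelle
    fragments are centred uniformly inside truth peaks, the rest uniformly on
    nuclear chromosomes; ``contamination_rate`` of fragments land uniformly
    on organelle chromosomes; duplicates are injected by resampling existing
    fragments.  Deterministic given ``config.seed`` (byte-identical files).
    """
    truth_seed = config.truth_seed if config.truth_seed is not None else config.seed
    rng_truth = np.random.default_rng(truth_seed)
    rng = np.random.default_rng(config.seed)
    chrom_sizes = ChromSizes(config.chromosomes)
    genes = _place_genes(rng_truth, chrom_sizes, config)
    truth_peaks = _place_truth_peaks(rng_truth, chrom_sizes, genes, config)

    n_total = config.n_fragments
    n_unique = int(round(n_total * (1.0 - config.duplicate_rate)))
    n_unique = max(1, n_unique)
    lengths = _sample_lengths(rng, n_unique, config)
    organelle = rng.random(n_unique) < config.contamination_rate
    in_peak = (~organelle) & (rng.random(n_unique) < config.in_peak_fraction)

    organelle_names = list(chrom_sizes.organelle_names)
    nuclear_names = chrom_sizes.nuclear_names
    nuclear_lens = np.array([chrom_sizes[c] for c in nuclear_names], dtype=np.float64)
    nuclear_probs = nuclear_lens / nuclear_lens.sum()

    fragments: list[FragmentRecord] = []
    for i in range(n_unique):
        length = int(lengths[i])
        if organelle[i] and organelle_names:
            chrom = organelle_names[int(rng.integers(len(organelle_names)))]
            climit = chrom_sizes[chrom]
            center = rng.uniform(length / 2, climit - length / 2)
        elif in_peak[i]:
            pk = truth_peaks[int(rng.integers(len(truth_peaks)))]
            chrom = pk.chrom
            climit = chrom_sizes[chrom]
            center = rng.uniform(pk.start, pk.end)
        else:
            ci = int(rng.choice(len(nuclear_names), p=nuclear_probs))
            chrom = nuclear_names[ci]
            climit = chrom_sizes[chrom]
            center = rng.uniform(length / 2, climit - length / 2)
        start = int(round(center - length / 2))
        start = max(0, min(start, climit - length))
        fragments.append(FragmentRecord(chrom, start, start + length))

    n_dup = n_total - n_unique
    if n_dup > 0:
        dup_idx = rng.integers(0, n_unique, size=n_dup)
        fragments.extend(fragments[int(j)] for j in dup_idx)

    tags = fragments_to_tags(fragments, config.read_length)

    # expression: log-scale linear in promoter-peak presence
    has_promoter_peak = np.ones(len(genes), dtype=bool)  # by construction, one each
    log_tpm = (
        config.expression_gamma * has_promoter_peak
        + rng_truth.normal(0.0, config.expression_noise_sd, size=len(genes))
    )
    expression = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "expression": np.exp(log_tpm)}
    )

    truth = TruthRecord(
        config=config,
        chrom_sizes=chrom_sizes,
        genes=genes,
        truth_peaks=truth_peaks,
        fragments=fragments,
        tags=tags,
        expression=expression,
        n_duplicates=n_dup,
        n_organelle=int(organelle.sum()),
    )
    if outdir is not None:
        _write_fixture(truth, Path(outdir))
    return truth


def _write_fixture(truth: TruthRecord, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(truth.chrom_sizes, outdir / "chrom.sizes")
    write_gff3_genes(truth.genes, outdir / "genes.gff3")
    with open_text(outdir / "truth_peaks.bed", "wt") as fh:
        for p in truth.truth_peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\n")
    write_bedpe_fragments(truth.fragments, outdir / "fragments.bedpe.gz")
    write_tagalign(truth.tags, outdir / "tags.tagAlign.gz")
    truth.expression.to_csv(outdir / "expr.tsv", sep="\t", index=False, float_format="%.6g")


def simulate_idr_scores(
    pi: float, rho: float, mu: float, sigma: float, n: int, seed: int = 0
) -> np.ndarray:
    """Draw n score pairs from the two-component copula mixture that
    :func:`polyatac.reproducibility.fit_idr` assumes.

    Reproducible pairs (probability ``pi``) come from a bivariate normal with
    common mean/sd and correlation ``rho``; the rest are independent standard
    normal.  Returns an (n, 2) array.
    """
    if not (0 <= pi <= 1) or not (0 <= rho < 1):
        raise ValueError("require pi in [0,1] and rho in [0,1)")
    rng = np.random.default_rng(seed)
    reproducible = rng.random(n) < pi
    z = rng.standard_normal((n, 2))
    out = np.empty((n, 2))
    # correlated component via Cholesky
    z2 = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    out[:, 0] = np.where(reproducible, mu + sigma * z[:, 0], z[:, 0])
    out[:, 1] = np.where(reproducible, mu + sigma * z2, z[:, 1])
    return out
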
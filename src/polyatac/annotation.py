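"""Peak-location classification and accessibility-related gene labeling.

Peaks are assigned to their nearest gene by summit-to-TSS distance and
classified, in precedence order, as promoter (TSS - 4 kb to TSS + 1.5 kb in
gene orientation, closed-inclusive at both ends), genebody, intergenic
upstream (beyond the promoter limb) or intergenic downstream (past the TES).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Peak

__all__ = [
    "AnnotationConfig",
    "PeakAnnotation",
    "CATEGORIES",
    "classify_summit",
    "annotate_peaks",
    "accessibility_related_genes",
    "category_proportions",
    "join_expression",
]

CATEGORIES = ("promoter", "genebody", "intergenic_upstream", "intergenic_downstream")


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_upstream: int = 4000
    promoter_downstream: int = 1500

    def __post_init__(self):
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValueError("promoter window extents must be >= 0")


@dataclass(frozen=True)
class PeakAnnotation:
    peak_name: str
    chrom: str
    summit_pos: int
    gene_id: str | None
    distance_to_tss: int | None  # signed; negative = upstream in gene orientation
    category: str  # one of CATEGORIES or "unassigned"


class _GeneIndex:
    """Per-chromosome sorted TSS arrays for nearest-gene lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._tss: dict[str, np.ndarray] = {}
        self._genes: dict[str, list[GeneModel]] = {}
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._genes[chrom] = gs
            self._tss[chrom] = np.array([g.tss for g in gs], dtype=np.int64)

    def nearest(self, chrom: str, pos: int) -> GeneModel | None:
        """Gene with minimal |pos - TSS|; ties -> lexicographically smaller id."""
        if chrom not in self._tss:
            return None
        tss = self._tss[chrom]
        genes = self._genes[chrom]
        i = int(np.searchsorted(tss, pos))
        best = None
        best_key = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(genes):
                key = (abs(pos - int(tss[j])), genes[j].gene_id)
                if best_key is None or key < best_key:
                    best_key = key
                    best = genes[j]
        return best


def _signed_tss_distance(summit: int, gene: GeneModel) -> int:
    """Distance summit -> TSS in gene orientation (negative = upstream)."""
    if gene.strand == "+":
        return summit - gene.tss
    return gene.tss - summit


def _classify(summit: int, gene: GeneModel, config: AnnotationConfig) -> str:
    d = _signed_tss_distance(summit, gene)
    if -config.promoter_upstream <= d <= config.promoter_downstream:
        return "promoter"
    if gene.start <= summit < gene.end:
        return "genebody"
    if d < -config.promoter_upstream:
        return "intergenic_upstream"
    return "intergenic_downstream"


def classify_summit(
    summit: int,
    chrom: str,
    genes,
    config: AnnotationConfig = AnnotationConfig(),
    peak_name: str = ".",
) -> PeakAnnotation:
    """Classify one summit position against the nearest gene on its chromosome."""
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    gene = index.nearest(chrom, summit)
    if gene is None:
        return PeakAnnotation(peak_name, chrom, summit, None, None, "unassigned")
    return PeakAnnotation(
        peak_name=peak_name,
        chrom=chrom,
        summit_pos=summit,
        gene_id=gene.gene_id,
        distance_to_tss=_signed_tss_distance(summit, gene),
        category=_classify(summit, gene, config),
    )


def annotate_peaks(
    peaks, genes, config: AnnotationConfig = AnnotationConfig()
) -> list[PeakAnnotation]:
    index = _GeneIndex(genes)
    return [
        classify_summit(p.summit_pos, p.chrom, index, config, peak_name=p.name)
        for p in peaks
    ]


def accessibility_related_genes(
    peaks, genes, config: AnnotationConfig = AnnotationConfig()
) -> dict[str, int]:
    """Per-gene count of peak summits inside the gene's promoter window.

    A gene is "chromatin accessibility-related" when its count is >= 1; the
    returned dict contains only such genes.
    """
    summits_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for p in peaks:
        tmp.setdefault(p.chrom, []).append(p.summit_pos)
    for chrom, v in tmp.items():
        summits_by_chrom[chrom] = np.sort(np.asarray(v, dtype=np.int64))
    counts: dict[str, int] = {}
    for g in genes:
        if g.chrom not in summits_by_chrom:
            continue
        if g.strand == "+":
            lo, hi = g.tss - config.promoter_upstream, g.tss + config.promoter_downstream
        else:
            lo, hi = g.tss - config.promoter_downstream, g.tss + config.promoter_upstream
        s = summits_by_chrom[g.chrom]
        n = int(np.searchsorted(s, hi, side="right") - np.searchsorted(s, lo, side="left"))
        if n > 0:
            counts[g.gene_id] = n
    return counts


def category_proportions(annotations) -> dict[str, float]:
    """Multinomial proportions over the four categories (unassigned excluded)."""
    annotations = list(annotations)
    if not annotations:
        raise ValueError("category_proportions requires >= 1 annotation")
    assigned = [a for a in annotations if a.category != "unassigned"]
    n_unassigned = len(annotations) - len(assigned)
    if n_unassigned:
        warnings.warn(f"{n_unassigned} unassigned annotation(s) excluded", stacklevel=2)
    if not assigned:
        raise ValueError("all annotations are unassigned")
    out = {c: 0.0 for c in CATEGORIES}
    for a in assigned:
        out[a.category] += 1.0
    return {c: v / len(assigned) for c, v in out.items()}


def join_expression(gene_peak_counts: dict[str, int], expression: pd.DataFrame) -> tuple[
    pd.DataFrame, pd.DataFrame
]:
    """Join per-gene promoter-peak counts with an expression table.

    ``expression`` needs columns ``gene_id`` and ``expression``.  Genes in
    the expression table absent from ``gene_peak_counts`` get count 0.
    Returns (per-gene join, group summary) where groups are peak-count bins
    {0, 1, 2, >=3} with median and IQR of expression.
    """
    expr = expression[["gene_id", "expression"]].copy()
    expr["n_promoter_peaks"] = expr["gene_id"].map(gene_peak_counts).fillna(0).astype(int)
    matched = expr["gene_id"].isin(gene_peak_counts)
    if gene_peak_counts and matched.sum() < 0.5 * len(gene_peak_counts):
        warnings.warn(
            "join_expression: < 50% of peak-bearing genes found in expression table",
            stacklevel=2,
        )
    bins = np.minimum(expr["n_promoter_peaks"], 3)
    labels = {0: "0", 1: "1", 2: "2", 3: ">=3"}
    expr["peak_group"] = bins.map(labels)
    groups = (
        expr.groupby("peak_group")["expression"]
        .agg(
            n="size",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reindex([labels[i] for i in range(4)])
        .dropna(how="all")
        .reset_index()
    )
    return expr, groups
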
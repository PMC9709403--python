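"""Post-alignment tag filtering, duplicate removal and library complexity.

Filtering keeps tags with MAPQ >= ``mapq_min`` (default 5: the strict
"< 5 dropped" rule) on known chromosomes.  Duplicates are identified by the
strand-specific 5' cut coordinate, matching Tn5 cut-site logic; library
complexity (NRF/PBC1/PBC2) is computed on the pre-dedup multiset.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .io_formats import ChromSizes, TagRecord

__all__ = [
    "FilterConfig",
    "FilterStats",
    "ComplexityMetrics",
    "filter_tags",
    "deduplicate",
    "organelle_fraction",
]


@dataclass(frozen=True)
class FilterConfig:
    mapq_min: int = 5
    drop_unpaired: bool = False
    organelle_names: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")


@dataclass
class FilterStats:
    total: int = 0
    kept: int = 0
    dropped_mapq: int = 0
    dropped_unknown_chrom: int = 0

    @property
    def dropped(self) -> int:
        return self.total - self.kept


def filter_tags(
    tags,
    config: FilterConfig = FilterConfig(),
    chrom_sizes: ChromSizes | None = None,
) -> tuple[list[TagRecord], FilterStats]:
    """Keep tags with ``mapq >= mapq_min`` on chromosomes known to ``chrom_sizes``."""
    stats = FilterStats()
    kept: list[TagRecord] = []
    for tag in tags:
        stats.total += 1
        if chrom_sizes is not None and tag.chrom not in chrom_sizes:
            stats.dropped_unknown_chrom += 1
            continue
        if tag.mapq < config.mapq_min:
            stats.dropped_mapq += 1
            continue
        kept.append(tag)
        stats.kept += 1
    return kept, stats


@dataclass(frozen=True)
class ComplexityMetrics:
    """ENCODE library-complexity metrics on the pre-dedup tag multiset.

    NRF = distinct/total, PBC1 = one-read/distinct, PBC2 = one-read/two-read
    (infinity when no position has exactly two reads).
    """

    total_tags: int
    distinct_positions: int
    one_read_positions: int
    two_read_positions: int

    @property
    def nrf(self) -> float:
        return self.distinct_positions / self.total_tags if self.total_tags else float("nan")

    @property
    def pbc1(self) -> float:
        return (
            self.one_read_positions / self.distinct_positions
            if self.distinct_positions
            else float("nan")
        )

    @property
    def pbc2(self) -> float:
        if self.two_read_positions == 0:
            return math.inf
        return self.one_read_positions / self.two_read_positions


def _dup_key(tag: TagRecord, full_interval: bool):
    if full_interval:
        return (tag.chrom, tag.strand, tag.start, tag.end)
    return (tag.chrom, tag.strand, tag.cut_site)


def deduplicate(
    tags, full_interval_key: bool = False
) -> tuple[list[TagRecord], ComplexityMetrics]:
    """Remove PCR duplicates and compute complexity metrics.

    The duplicate key is ``(chrom, strand, 5' cut)`` by default;
    ``full_interval_key`` switches to the complete interval (fragment input).
    One representative per key is kept, the first in sorted
    (chrom, start, end, strand) order.
    """
    counts = Counter(_dup_key(t, full_interval_key) for t in tags)
    seen: set = set()
    unique: list[TagRecord] = []
    for tag in sorted(tags, key=lambda t: (t.chrom, t.start, t.end, t.strand)):
        key = _dup_key(tag, full_interval_key)
        if key not in seen:
            seen.add(key)
            unique.append(tag)
    metrics = ComplexityMetrics(
        total_tags=len(tags),
        distinct_positions=len(counts),
        one_read_positions=sum(1 for c in counts.values() if c == 1),
        two_read_positions=sum(1 for c in counts.values() if c == 2),
    )
    return unique, metrics


def organelle_fraction(tags, chrom_sizes: ChromSizes) -> float:
    """Fraction of tags mapped to organelle chromosomes (0.0 if no tags)."""
    total = 0
    organelle = 0
    for tag in tags:
        total += 1
        if chrom_sizes.is_organelle(tag.chrom):
            organelle += 1
    if total == 0:
        warnings.warn("organelle_fraction of empty tag list; returning 0.0", stacklevel=2)
        return 0.0
    return organelle / total
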
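"""Readers and writers for the on-disk formats the toolkit touches.

All internal coordinates are 0-based half-open (BED convention).  GFF3 is
converted at the boundary.  Every text format may be gzip-compressed; a
``.gz`` suffix triggers transparent (de)compression.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ChromSizes",
    "TagRecord",
    "FragmentRecord",
    "GeneModel",
    "Peak",
    "FormatError",
    "ValidationError",
    "open_text",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tagalign",
    "write_tagalign",
    "read_bedpe_fragments",
    "write_bedpe_fragments",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gff3_genes",
    "write_gff3_genes",
    "write_bedgraph",
]

DEFAULT_ORGANELLE_REGEX = r"(?i)(Mt|Pt)"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


def open_text(path, mode: str = "rt"):
    """Open ``path`` for text I/O, gzip-transparently by suffix.

    Written gzip members carry ``mtime=0`` so identical content produces
    byte-identical files (needed for deterministic fixtures).
    """
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            raw = open(path, "wb")
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            return io.TextIOWrapper(gz, encoding="utf-8", newline="")
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


class ChromSizes:
    """Ordered map chromosome name -> length, with per-chromosome organelle flag.

    Parameters
    ----------
    sizes
        Mapping or iterable of ``(name, length)`` pairs.  Order is preserved.
    organelle
        Either an explicit set of organelle chromosome names or ``None`` to
        flag names matching ``organelle_regex``.
    organelle_regex
        Pattern searched against each name (default: contains ``Mt`` or
        ``Pt``, case-insensitive).
    """

    def __init__(self, sizes, organelle=None, organelle_regex: str = DEFAULT_ORGANELLE_REGEX):
        items = list(sizes.items()) if hasattr(sizes, "items") else list(sizes)
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValidationError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
            self._sizes[name] = length
        if organelle is not None:
            self._organelle = frozenset(organelle)
            unknown = self._organelle - set(self._sizes)
            if unknown:
                raise ValidationError(f"organelle names not in sizes: {sorted(unknown)}")
        else:
            pat = re.compile(organelle_regex)
            self._organelle = frozenset(n for n in self._sizes if pat.search(n))

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ChromSizes)
            and self._sizes == other._sizes
            and self._organelle == other._organelle
        )

    def items(self):
        return self._sizes.items()

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    @property
    def organelle_names(self) -> frozenset[str]:
        return self._organelle

    def is_organelle(self, name: str) -> bool:
        return name in self._organelle

    @property
    def nuclear_names(self) -> list[str]:
        return [n for n in self._sizes if n not in self._organelle]

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    @property
    def nuclear_length(self) -> int:
        return sum(l for n, l in self._sizes.items() if n not in self._organelle)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r}, organelle={sorted(self._organelle)!r})"


@dataclass(frozen=True, slots=True)
class TagRecord:
    """One aligned read (tag): a single Tn5 insertion observation."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid tag interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.mapq < 0:
            raise ValidationError(f"negative MAPQ {self.mapq}")

    @property
    def cut_site(self) -> int:
        """Strand-specific 5' cut coordinate (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True, slots=True)
class FragmentRecord:
    """One sequenced fragment, both Tn5 cut sites known."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid fragment interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene span with strand-aware TSS/TES coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid gene span for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True, slots=True)
class Peak:
    """A candidate or reproducible open-chromatin region (narrowPeak semantics).

    ``summit`` is the offset in bp from ``start``.  ``pvalue`` and ``qvalue``
    are on the -log10 scale, as in narrowPeak columns 8 and 9.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    pileup: float = 0.0
    pvalue: float = 0.0
    qvalue: float = 0.0
    fold_enrichment: float = 0.0
    summit: int = 0
    idr_value: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid peak interval [{self.start}, {self.end})")
        if not (0 <= self.summit < self.end - self.start):
            raise ValidationError(
                f"summit offset {self.summit} outside peak of length {self.end - self.start}"
            )
        if self.pvalue < 0 or self.qvalue < 0:
            raise ValidationError("-log10 p/q must be >= 0")

    @property
    def summit_pos(self) -> int:
        """Absolute genomic coordinate of the summit."""
        return self.start + self.summit

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------


def read_chrom_sizes(path, organelle_regex: str = DEFAULT_ORGANELLE_REGEX) -> ChromSizes:
    """Read a two-column ``name<TAB>length`` table."""
    pairs = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length field: {exc}") from None
    return ChromSizes(pairs, organelle_regex=organelle_regex)


def write_chrom_sizes(chrom_sizes: ChromSizes, path) -> None:
    with open_text(path, "wt") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# tagAlign (BED6)
# ---------------------------------------------------------------------------


def _validate_against(chrom_sizes: ChromSizes | None, chrom: str, end: int, where: str):
    if chrom_sizes is None:
        return
    if chrom not in chrom_sizes:
        raise ValidationError(f"{where}: unknown chromosome {chrom!r}")
    if end > chrom_sizes[chrom]:
        raise ValidationError(
            f"{where}: interval end {end} exceeds {chrom!r} length {chrom_sizes[chrom]}"
        )


def read_tagalign(
    path,
    chrom_sizes: ChromSizes | None = None,
    mapq_in_score: bool = True,
) -> list[TagRecord]:
    """Read a BED6 tagAlign file into :class:`TagRecord` objects.

    tagAlign has no dedicated MAPQ field; by convention the BED score column
    carries it when the source documents it as such (``mapq_in_score``,
    default on; off stores MAPQ 255 = unknown).
    """
    tags: list[TagRecord] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                score = int(float(fields[4])) if fields[4] != "." else 0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            strand = fields[5]
            try:
                rec = TagRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    mapq=score if mapq_in_score else 255,
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            _validate_against(chrom_sizes, chrom, end, f"{path}:{lineno}")
            tags.append(rec)
    return tags


def write_tagalign(tags: Iterable[TagRecord], path) -> None:
    with open_text(path, "wt") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\tN\t{t.mapq}\t{t.strand}\n")


# ---------------------------------------------------------------------------
# BEDPE fragments
# ---------------------------------------------------------------------------


def read_bedpe_fragments(
    path,
    chrom_sizes: ChromSizes | None = None,
    with_stats: bool = False,
):
    """Read a BEDPE file; each proper pair becomes one fragment.

    The fragment spans ``min(start1, start2)`` to ``max(end1, end2)``.
    Cross-chromosome pairs are skipped with a warning; pass
    ``with_stats=True`` to also receive the skipped-pair count.
    """
    fragments: list[FragmentRecord] = []
    skipped = 0
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE requires >= 6 columns")
            try:
                c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if c1 != c2:
                skipped += 1
                continue
            start, end = min(s1, s2), max(e1, e2)
            try:
                rec = FragmentRecord(chrom=c1, start=start, end=end)
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            _validate_against(chrom_sizes, c1, end, f"{path}:{lineno}")
            fragments.append(rec)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} cross-chromosome pair(s)", stacklevel=2)
    if with_stats:
        return fragments, skipped
    return fragments


def write_bedpe_fragments(fragments: Iterable[FragmentRecord], path) -> None:
    with open_text(path, "wt") as fh:
        for f in fragments:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.chrom}\t{f.start}\t{f.end}\tN\t0\t+\t-\n"
            )


# ---------------------------------------------------------------------------
# narrowPeak (ENCODE BED6+4)
# ---------------------------------------------------------------------------

_NP_FLOAT = "{:.6g}".format


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    """Write 10-column ENCODE narrowPeak; column 10 is the summit offset."""
    with open_text(path, "wt") as fh:
        for i, p in enumerate(peaks, 1):
            name = p.name if p.name != "." else f"peak_{i}"
            score = int(min(1000, round(10 * p.pvalue)))
            fh.write(
                "\t".join(
                    (
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        name,
                        str(score),
                        ".",
                        _NP_FLOAT(p.fold_enrichment),
                        _NP_FLOAT(p.pvalue),
                        _NP_FLOAT(p.qvalue),
                        str(p.summit),
                    )
                )
                + "\n"
            )


def read_narrowpeak(path, chrom_sizes: ChromSizes | None = None) -> list[Peak]:
    peaks: list[Peak] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            try:
                peak = Peak(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    fold_enrichment=float(fields[6]),
                    pvalue=float(fields[7]),
                    qvalue=float(fields[8]),
                    summit=int(fields[9]),
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            _validate_against(chrom_sizes, peak.chrom, peak.end, f"{path}:{lineno}")
            peaks.append(peak)
    return peaks


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

_GFF_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3_genes(path, chrom_sizes: ChromSizes | None = None) -> list[GeneModel]:
    """Extract ``gene`` features from GFF3, converting 1-based inclusive
    coordinates to the internal 0-based half-open convention."""
    genes: list[GeneModel] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 requires 9 columns")
            if fields[2] != "gene":
                continue
            m = _GFF_ID.search(fields[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: gene feature lacks ID attribute")
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            try:
                gene = GeneModel(
                    gene_id=m.group(1),
                    chrom=fields[0],
                    start=start1 - 1,
                    end=end1,
                    strand=fields[6],
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            _validate_against(chrom_sizes, gene.chrom, gene.end, f"{path}:{lineno}")
            genes.append(gene)
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path) -> None:
    with open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpolyatac\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BAM adapter (optional; requires pysam)
# ---------------------------------------------------------------------------


def read_bam_tags(path, min_mapq: int = 0, require_paired: bool = False) -> list[TagRecord]:
    """Thin adapter emitting :class:`TagRecord` from a coordinate-space BAM.

    Unmapped, secondary and supplementary records are skipped.  The rest of
    the toolkit never sees alignment internals; all downstream code stays
    format-agnostic.  Requires :mod:`pysam`.
    """
    import pysam

    tags: list[TagRecord] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if require_paired and not read.is_proper_pair:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tags.append(
                TagRecord(
                    chrom=read.reference_name,
                    start=read.reference_start,
                    end=read.reference_end,
                    strand="-" if read.is_reverse else "+",
                    mapq=read.mapping_quality,
                )
            )
    return tags


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(track, path, precision: int = 6) -> None:
    """Write a per-base coverage track run-length encoded as bedGraph.

    ``track`` maps chromosome name -> numpy array of per-base signal.
    Zero runs are omitted, as is customary.
    """
    import numpy as np

    fmt = f"{{:.{precision}g}}".format
    with open_text(path, "wt") as fh:
        for chrom, values in track.items():
            values = np.asarray(values)
            if values.size == 0:
                continue
            change = np.flatnonzero(values[1:] != values[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{fmt(float(v))}\n")
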
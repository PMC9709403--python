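# polyatac

A self-contained ATAC-seq analysis toolkit aimed at large (polyploid) plant
genomes. It takes aligned Tn5 tag/fragment data — tagAlign (BED6) or BEDPE —
plus a chromosome-sizes table and gene models (GFF3), and produces
reproducible open-chromatin regions together with a full QC battery, with no
external tool calls:

- **Read processing** — MAPQ filtering (default: drop MAPQ < 5), PCR
  duplicate removal keyed on the strand-specific 5' cut site, ENCODE library
  complexity metrics (NRF / PBC1 / PBC2), organelle-contamination accounting.
- **Signal tracks** — cut-site pileup with `--shift -75 --extsize 150`
  semantics, SPMR normalization, bedGraph output, binned Pearson correlation,
  scale-regions metagene matrices (`-b 3000 -a 3000 -m 5000`), and a
  flank-normalized TSS enrichment score.
- **Peak calling** — a native Poisson local-background caller (10 kb sliding
  window floored by the genome-wide rate, genome-wide Benjamini–Hochberg
  q-values, merge gap, summit at the leftmost pileup maximum). Verified
  against an independent per-base brute-force oracle.
- **Reproducibility** — pseudo-replicate splitting and IDR consistent-peak
  selection (two-component Gaussian copula mixture fitted by EM) with the
  ENCODE-style three-way analysis: true replicates at IDR 0.05, self
  pseudo-replicates at 0.02, pooled pseudo-replicates at 0.01.
- **QC metrics** — FRiP, SPOT (binomial hotspot model with a 50 kb local
  background), fragment-length histograms with nucleosome-band fractions and
  a periodicity score.
- **Saturation** — subsample at 10%…100%, call peaks, fit a saturating curve
  (Michaelis–Menten by default), extrapolate to virtual depths (110%…200%),
  report the saturation fraction/depth.
- **Annotation** — peak classification into promoter (TSS −4 kb … +1.5 kb,
  inclusive, gene-oriented), genebody, intergenic upstream/downstream;
  accessibility-related gene labeling; joins with expression tables.
- **Simulator** — synthetic genomes, gene models, truth peaks and fragment
  libraries (nucleosome-periodic lengths, promoter-enriched cuts, organelle
  contamination, PCR duplicates) so everything is testable offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance suite, including
exact oracle-equivalence checks of the peak caller and ground-truth recovery
on simulated replicate libraries.

## CLI

Every stage is a subcommand of `polyatac`; all text formats may be
gzip-compressed.

```sh
# synthetic fixture with known ground truth
polyatac simulate --seed 42 --outdir fixtures/

# step ii: filter + dedup + complexity stats
polyatac filter fixtures/tags.tagAlign.gz clean.tagAlign.gz \
    --chrom-sizes fixtures/chrom.sizes --mapq-min 5 --stats stats.tsv

# step iv: native peak calling
polyatac callpeaks clean.tagAlign.gz --chrom-sizes fixtures/chrom.sizes \
    --shift -75 --extsize 150 --qcut 0.05 --out peaks.narrowPeak

# steps iii+v: IDR consistent peaks from two replicates
polyatac idr rep1.tagAlign.gz rep2.tagAlign.gz \
    --chrom-sizes fixtures/chrom.sizes --seed 17 \
    --out final.narrowPeak --report idr_report.tsv

# QC battery, tracks, correlation, metagene, saturation, annotation
polyatac qc --tags clean.tagAlign.gz --peaks final.narrowPeak \
    --fragments fixtures/fragments.bedpe.gz --genes fixtures/genes.gff3 \
    --chrom-sizes fixtures/chrom.sizes --out qc.tsv
polyatac track clean.tagAlign.gz signal.bedGraph.gz --chrom-sizes fixtures/chrom.sizes
polyatac corr rep1.tagAlign.gz rep2.tagAlign.gz --chrom-sizes fixtures/chrom.sizes --out corr.tsv
polyatac metagene clean.tagAlign.gz fixtures/genes.gff3 \
    --chrom-sizes fixtures/chrom.sizes --out metagene.tsv
polyatac saturate clean.tagAlign.gz --chrom-sizes fixtures/chrom.sizes \
    --seed 7 --read-length 150 --out saturation.tsv --plot saturation.png
polyatac annotate final.narrowPeak fixtures/genes.gff3 \
    --out annot.tsv --gene-report genes.tsv --expression fixtures/expr.tsv

# or everything at once from a manifest (library<TAB>tagalign[<TAB>bedpe])
polyatac run --manifest libs.tsv --genes genes.gff3 \
    --chrom-sizes chrom.sizes --outdir out/ --seed 7 [--saturate]
```

`polyatac run` writes per-library cleaned tags, SPMR bedGraph tracks,
narrowPeak files, the IDR-consistent final peak set, annotations, a TSV QC
report and a Markdown summary.

## Conventions

Internal coordinates are uniformly 0-based half-open (BED); GFF3 is
converted at the boundary. The tagAlign score column is treated as MAPQ by
default (`--no-mapq-in-score` to disable). Organelle chromosomes are
recognized by a configurable regex (default: names containing `Mt` or `Pt`,
case-insensitive). bedGraph is the native track output; bigWig conversion is
left to external tools.
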
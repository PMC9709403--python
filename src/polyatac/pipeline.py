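"""End-to-end orchestration of the five-step analysis flow.

Given a manifest of aligned tag libraries: (ii) filter and deduplicate,
(iii) build pseudo-replicates, (iv) call peaks per replicate and pooled,
(v) select consistent peaks by IDR — then assemble the full QC battery
(complexity, organelle fraction, fragment profile, correlation, TSS
enrichment, FRiP, SPOT) plus annotation proportions into one report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as anno
from . import qc_metrics as qc
from .io_formats import (
    ChromSizes,
    write_bedgraph,
    write_narrowpeak,
    write_tagalign,
)
from .peak_calling import PeakCallConfig, call_peaks
from .read_processing import FilterConfig, deduplicate, filter_tags, organelle_fraction
from .reproducibility import IDRConfig, consistent_peaks
from .saturation import saturation_analysis
from .signal_tracks import PileupConfig, binned_correlation, pileup, tss_enrichment

logger = logging.getLogger("polyatac")

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    libraries: dict[str, list]          # name -> list of TagRecord (or path resolved upstream)
    chrom_sizes: ChromSizes
    genes: list = field(default_factory=list)
    fragments: dict[str, list] = field(default_factory=dict)
    outdir: Path | None = None
    seed: int = 0
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    peak_config: PeakCallConfig = field(default_factory=PeakCallConfig)
    idr_config: IDRConfig = field(default_factory=IDRConfig)
    annotation_config: anno.AnnotationConfig = field(default_factory=anno.AnnotationConfig)
    run_idr: bool = True
    run_saturation: bool = False
    read_length: int | None = None
    correlation_bin: int = 10_000

    def __post_init__(self):
        if not self.libraries:
            raise ValueError("pipeline requires >= 1 library")
        if self.run_idr and len(self.libraries) < 2:
            raise ValueError(
                "the IDR stage requires >= 2 replicate libraries; "
                "got 1 (disable with run_idr=False)"
            )


@dataclass
class PipelineResult:
    qc_table: pd.DataFrame
    correlation: np.ndarray | None
    final_peaks: list
    per_library_peaks: dict[str, list]
    reproducibility_report: object | None
    annotations: list
    category_proportions: dict | None
    saturation: object | None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    clean: dict[str, list] = {}
    rows = []
    tracks = []
    spmr_conf = PileupConfig(
        shift=config.peak_config.pileup.shift,
        extsize=config.peak_config.pileup.extsize,
        spmr=True,
    )
    for name, tags in config.libraries.items():
        logger.info("[%s] filtering %d tags", name, len(tags))
        kept, fstats = filter_tags(tags, config.filter_config, config.chrom_sizes)
        unique, complexity = deduplicate(kept)
        logger.info(
            "[%s] kept %d/%d after filter, %d unique after dedup",
            name, fstats.kept, fstats.total, len(unique),
        )
        clean[name] = unique
        row = {
            "library": name,
            "total_tags": fstats.total,
            "filtered_tags": fstats.kept,
            "unique_tags": len(unique),
            "nrf": complexity.nrf,
            "pbc1": complexity.pbc1,
            "pbc2": complexity.pbc2,
            "organelle_fraction": organelle_fraction(kept, config.chrom_sizes),
        }
        track = pileup(unique, spmr_conf, config.chrom_sizes)
        tracks.append(track)
        if config.genes:
            row["tss_enrichment"] = tss_enrichment(track, config.genes)
        row["spot"] = qc.spot(unique, config.chrom_sizes)
        if name in config.fragments:
            profile = qc.fragment_length_profile(config.fragments[name])
            row["nfr_fraction"] = profile.nfr_fraction
            row["mono_nucleosome_fraction"] = profile.mono_fraction
            row["periodicity"] = profile.periodicity
        rows.append(row)
        if outdir is not None:
            write_tagalign(unique, outdir / f"{name}.clean.tagAlign.gz")
            write_bedgraph(track, outdir / f"{name}.spmr.bedGraph.gz")

    names = list(config.libraries)
    corr = binned_correlation(tracks, config.correlation_bin) if len(tracks) >= 2 else None

    per_library_peaks = {}
    for name in names:
        peaks = call_peaks(clean[name], config.peak_config, config.chrom_sizes)
        per_library_peaks[name] = peaks
        logger.info("[%s] %d peaks", name, len(peaks))
        if outdir is not None:
            write_narrowpeak(peaks, outdir / f"{name}.narrowPeak")

    report = None
    if config.run_idr:
        rep_names = names[:2]
        idr_conf = config.idr_config
        if idr_conf.seed != config.seed:
            idr_conf = IDRConfig(
                **{**idr_conf.__dict__, "seed": config.seed}
            )
        final, report = consistent_peaks(
            [clean[n] for n in rep_names],
            idr_conf,
            config.peak_config,
            config.chrom_sizes,
            rep_peaks=[per_library_peaks[n] for n in rep_names],
        )
        logger.info("consistent peaks: %d", len(final))
    else:
        final = per_library_peaks[names[0]]
    if outdir is not None:
        write_narrowpeak(final, outdir / "final.narrowPeak")

    for row, name in zip(rows, names):
        row["frip"] = qc.frip(clean[name], final)

    annotations = []
    proportions = None
    if config.genes and final:
        annotations = anno.annotate_peaks(final, config.genes, config.annotation_config)
        proportions = anno.category_proportions(annotations)

    sat = None
    if config.run_saturation:
        pooled = [t for n in names for t in clean[n]]
        sat = saturation_analysis(
            pooled,
            config.peak_config,
            config.chrom_sizes,
            seed=config.seed,
            read_length=config.read_length,
        )

    qc_table = pd.DataFrame(rows)
    if outdir is not None:
        qc_table.to_csv(outdir / "qc_report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        if corr is not None:
            pd.DataFrame(corr, index=names, columns=names).to_csv(
                outdir / "correlation.tsv", sep="\t", float_format=_FLOAT_FMT
            )
        if annotations:
            pd.DataFrame(
                [
                    {
                        "peak": a.peak_name,
                        "chrom": a.chrom,
                        "summit": a.summit_pos,
                        "gene_id": a.gene_id,
                        "distance_to_tss": a.distance_to_tss,
                        "category": a.category,
                    }
                    for a in annotations
                ]
            ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        _write_summary(outdir / "summary.md", qc_table, corr, names, report, proportions, sat)
    return PipelineResult(
        qc_table=qc_table,
        correlation=corr,
        final_peaks=final,
        per_library_peaks=per_library_peaks,
        reproducibility_report=report,
        annotations=annotations,
        category_proportions=proportions,
        saturation=sat,
    )


def _write_summary(path, qc_table, corr, names, report, proportions, sat) -> None:
    lines = ["# polyatac pipeline summary", "", "## Library QC", ""]
    lines.append("```")
    lines.append(qc_table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    lines.append("```")
    if corr is not None:
        lines += ["", "## Binned Pearson correlation", "", "```"]
        lines.append(
            pd.DataFrame(corr, index=names, columns=names).to_string(
                float_format=lambda v: f"{v:.4g}"
            )
        )
        lines.append("```")
    if report is not None:
        lines += ["", "## Reproducibility", ""]
        lines.append(f"- N_true: {report.n_true}")
        lines.append(f"- N_self: {report.n_self}")
        lines.append(f"- N_pooled_pseudo: {report.n_pooled_pseudo}")
        lines.append(f"- rescue ratio: {report.rescue_ratio}")
        lines.append(f"- self-consistency ratio: {report.self_consistency_ratio}")
        for flag in report.flags:
            lines.append(f"- FLAG: {flag}")
    if proportions is not None:
        lines += ["", "## Peak category proportions", ""]
        for c, v in proportions.items():
            lines.append(f"- {c}: {v:.4f}")
    if sat is not None:
        lines += ["", "## Saturation", ""]
        lines.append(f"- f*: {sat.saturation_fraction}")
        lines.append(f"- Vmax: {sat.vmax}, K: {sat.k}")
        if sat.saturation_gb is not None:
            lines.append(f"- saturation depth: {sat.saturation_gb:.3f} Gb")
    Path(path).write_text("\n".join(lines) + "\n")
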
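"""End-to-end orchestration: demux -> tail calling -> non-A -> gene/APA.

The genome alignment itself is an explicit external step: the pipeline
consumes a SAM/BAM of the demultiplexed clean reads and never shells
out to an aligner.  :data:`RECOMMENDED_ALIGNER_CMD` prints the spliced
alignment invocation this pipeline expects (secondary alignments
suppressed).  Re-running with identical inputs yields byte-identical
tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pysam

from . import __version__
from .demux import DemuxReport, ProbeSet, demux_to_files
from .gene_apa import (
    DISCARDED_MULTI,
    apa_class_table,
    assign_gene,
    build_exon_index,
    call_polya_sites,
    compare_sites_to_reference,
    sites_to_bed,
)
from .io import alignment_from_pysam, filter_by_passes, read_ccs
from .nona import fraction_with_internal_non_a, positional_histogram, run_spectrum_table
from .report import (
    gene_summary_frame,
    global_length_report,
    long_tail_report,
    non_a_frequency_panel,
    replicate_correlation,
)
from .tails import TailCall, Rejection, extract_tail, summarize_genes, tail_table

logger = logging.getLogger(__name__)

RECOMMENDED_ALIGNER_CMD = (
    "minimap2 -ax splice -uf -C5 --secondary=no <genome.fa> <sample>.clean.fastq"
)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, **info) -> None:
        self.stages[name] = info

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def call_tails_and_genes(
    sam_path: str | Path,
    reads_by_id: dict[str, tuple[str, int]],
    gtf_path: Optional[str | Path] = None,
    min_passes: int = 10,
) -> tuple[list[TailCall], list[Rejection], dict]:
    """Tail-call every primary alignment and assign genes when a GTF is given.

    ``reads_by_id`` maps read_id -> (clean sequence in read orientation,
    num_passes); reads below ``min_passes`` are skipped before calling.
    Returns accepted tails (with gene and cleavage-site context),
    rejections, and counters.
    """
    index = build_exon_index(gtf_path) if gtf_path is not None else None
    tails: list[TailCall] = []
    rejections: list[Rejection] = []
    counters = {"alignments": 0, "low_pass": 0, "multi_gene": 0, "no_gene": 0}
    path = Path(sam_path)
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh.fetch(until_eof=True):
            counters["alignments"] += 1
            if rec.query_name not in reads_by_id:
                continue
            clean_seq, passes = reads_by_id[rec.query_name]
            if passes < min_passes:
                counters["low_pass"] += 1
                continue
            if rec.is_unmapped:
                rejections.append(Rejection(rec.query_name, "unmapped"))
                continue
            aln = alignment_from_pysam(rec)
            result = extract_tail(aln, clean_seq)
            if isinstance(result, Rejection):
                rejections.append(result)
                continue
            result.num_passes = passes
            if index is not None:
                gene = assign_gene(aln, index)
                if gene == DISCARDED_MULTI:
                    counters["multi_gene"] += 1
                    continue
                if gene is None:
                    counters["no_gene"] += 1
                result.gene_id = gene
            tails.append(result)
    return tails, rejections, counters


def run_pipeline(
    reads_path: str | Path,
    barcodes_path: str | Path,
    out_dir: str | Path,
    sam_path: Optional[str | Path] = None,
    gtf_path: Optional[str | Path] = None,
    ref_bed: Optional[str | Path] = None,
    five_prime_primer: str = "",
    min_passes: int = 10,
    min_len: int = 50,
    max_edits: int = 2,
    min_reads: int = 3,
    corr_min_reads: int = 10,
    apa_window: int = 24,
    apa_min_support: int = 2,
    plots: bool = False,
) -> RunManifest:
    """Run demux and, when alignments are supplied, all downstream stages."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "reads": str(reads_path),
            "barcodes": str(barcodes_path),
            "sam": str(sam_path) if sam_path else None,
            "gtf": str(gtf_path) if gtf_path else None,
            "min_passes": min_passes,
            "min_len": min_len,
            "max_edits": max_edits,
            "apa_window": apa_window,
            "apa_min_support": apa_min_support,
        }
    )

    probes = ProbeSet.from_tsv(barcodes_path, five_prime_primer=five_prime_primer, max_edits=max_edits)
    demux_dir = out_dir / "demux"
    report: DemuxReport = demux_to_files(read_ccs(reads_path), probes, demux_dir, min_len=min_len)
    manifest.add_stage(
        "demux",
        input=str(reads_path),
        output=str(demux_dir),
        total=report.total,
        assigned=report.assigned,
        ambiguous=report.ambiguous,
        unassigned=report.unassigned,
        concatemers=report.concatemers,
    )

    if sam_path is None:
        manifest.warnings.append(
            "no alignments supplied; stopped after demux. Align with: " + RECOMMENDED_ALIGNER_CMD
        )
        manifest.write(out_dir / "manifest.json")
        return manifest

    tails_by_sample: dict[str, list[TailCall]] = {}
    summaries_by_sample = {}
    for sample in sorted(probes.probes):
        fastq = demux_dir / f"{sample}.clean.fastq"
        reads_by_id = {
            r.read_id: (r.sequence, r.num_passes)
            for r in read_ccs(fastq, fmt="fastq")
        }
        tails, rejections, counters = call_tails_and_genes(
            sam_path, reads_by_id, gtf_path, min_passes=min_passes
        )
        tails_by_sample[sample] = tails
        tail_table(tails).to_csv(out_dir / f"{sample}.tails.tsv", sep="\t", index=False)
        summaries = summarize_genes(tails, min_reads=min_reads)
        summaries_by_sample[sample] = gene_summary_frame(summaries)
        summaries_by_sample[sample].to_csv(
            out_dir / f"{sample}.gene_summary.tsv", sep="\t", index=False
        )
        manifest.add_stage(
            f"tails:{sample}",
            input=str(sam_path),
            n_clean_reads=len(reads_by_id),
            n_tails=len(tails),
            n_rejections=len(rejections),
            counters=counters,
        )

    all_tails = [t for ts in tails_by_sample.values() for t in ts]

    # non-A profiling (pass threshold already applied at tail calling)
    run_spectrum_table(all_tails).to_csv(out_dir / "nona_run_spectrum.tsv", sep="\t", index=False)
    positional_histogram(all_tails).to_csv(
        out_dir / "nona_positional.tsv", sep="\t", index=False
    )
    frac, binned = fraction_with_internal_non_a(all_tails)
    binned.to_csv(out_dir / "nona_by_length.tsv", sep="\t", index=False)
    frac_raw, _ = fraction_with_internal_non_a(all_tails, strip_terminal=False)
    manifest.add_stage(
        "nona",
        n_tails=len(all_tails),
        internal_fraction_stripped=frac,
        internal_fraction_raw=frac_raw,
    )

    # polyadenylation sites from tail-bearing reads
    if gtf_path is not None:
        index = build_exon_index(gtf_path)
        end_records = [
            (t.gene_id, index.genes[t.gene_id]["strand"], t.cleavage_pos)
            for t in all_tails
            if t.gene_id and t.cleavage_pos is not None and t.gene_id in index.genes
        ]
        sites = call_polya_sites(end_records, window=apa_window, min_support=apa_min_support)
        chrom_of_gene = {g: v["chrom"] for g, v in index.genes.items()}
        sites_to_bed(sites, chrom_of_gene).to_csv(
            out_dir / "polya_sites.bed", sep="\t", index=False, header=False
        )
        apa_class_table(sites).to_csv(out_dir / "apa_classes.tsv", sep="\t", index=False)
        manifest.add_stage("apa", n_sites=len(sites), n_end_records=len(end_records))
        if ref_bed is not None:
            overlap = compare_sites_to_reference(sites, ref_bed, chrom_of_gene)
            overlap.to_csv(out_dir / "apa_reference_overlap.tsv", sep="\t", index=False)

    # cross-sample report
    global_length_report(tails_by_sample).to_csv(
        out_dir / "length_distribution.tsv", sep="\t", index=False
    )
    long_tail_report(tails_by_sample).to_csv(out_dir / "long_tails.tsv", sep="\t", index=False)
    non_a_frequency_panel(tails_by_sample).to_csv(
        out_dir / "non_a_frequency.tsv", sep="\t", index=False
    )
    samples = sorted(tails_by_sample)
    if len(samples) >= 2:
        corr = replicate_correlation(
            summaries_by_sample[samples[0]], summaries_by_sample[samples[1]],
            min_reads=corr_min_reads,
        )
        manifest.add_stage("correlation", samples=samples[:2], **corr)
    if plots:
        from .report import plot_length_distributions

        plot_length_distributions(tails_by_sample, out_dir / "length_distribution.png")

    manifest.write(out_dir / "manifest.json")
    return manifest
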
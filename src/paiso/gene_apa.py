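"""Gene assignment via merged exons and polyadenylation-site calling.

Reads are assigned to genes by overlapping their aligned blocks with
merged, deduplicated exon intervals from the annotation; reads
overlapping exons of two or more genes are discarded.  Cleavage sites
(strand-aware genomic 3' ends of tail-bearing reads) are clustered by
single-linkage within a fixed window to call polyadenylation sites; a
gene with two called sites exhibits one alternative-polyadenylation
(APA) event, with three sites two APAs, and so on.  The site clustering
is a deliberately simple, documented replacement for a full APA
pipeline, so comparisons with published APA counts are qualitative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .io import AlignmentRecord

logger = logging.getLogger(__name__)

#: Sentinel for reads overlapping exons of two or more genes.
DISCARDED_MULTI = "discarded_multi"


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/duplicate half-open intervals into a sorted set."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(set(intervals)):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class ExonIndex:
    """Merged exon intervals per gene plus a genome interval tree."""

    genes: dict[str, dict] = field(default_factory=dict)  # gene_id -> {chrom, strand, exons}
    trees: dict[str, IntervalTree] = field(default_factory=dict)  # chrom -> tree of gene_ids

    def add_gene(self, gene_id: str, chrom: str, strand: str, exons: list[tuple[int, int]]) -> None:
        merged = merge_intervals(exons)
        self.genes[gene_id] = {"chrom": chrom, "strand": strand, "exons": merged}
        tree = self.trees.setdefault(chrom, IntervalTree())
        for start, end in merged:
            tree[start:end] = gene_id

    def overlapping_genes(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self.trees.get(chrom)
        if tree is None or start >= end:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def build_exon_index(gtf_path: str | Path) -> ExonIndex:
    """Index exons from a GTF/GFF annotation.

    Exons are merged per gene and duplicates removed; GTF 1-based
    inclusive coordinates become 0-based half-open internally.
    Unparseable lines and exons without a gene_id are skipped with a
    log message rather than aborting the run.
    """
    per_gene: dict[str, dict] = {}
    n_skipped = 0
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception:
                n_skipped += 1
                continue
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
            except KeyError:
                logger.warning("exon without gene_id at %s:%s skipped", feat.seqid, feat.start)
                n_skipped += 1
                continue
            entry = per_gene.setdefault(
                gene_id, {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
            )
            entry["exons"].append((feat.start - 1, feat.end))
    if n_skipped:
        logger.warning("%d annotation lines skipped", n_skipped)
    index = ExonIndex()
    for gene_id in sorted(per_gene):
        e = per_gene[gene_id]
        index.add_gene(gene_id, e["chrom"], e["strand"], e["exons"])
    return index


def aligned_blocks(aln: AlignmentRecord) -> list[tuple[int, int]]:
    """Reference blocks covered by M/=/X/D runs, split at introns (N)."""
    blocks: list[tuple[int, int]] = []
    pos = aln.ref_start
    block_start: Optional[int] = None
    for op, n in aln.cigar_ops():
        if op in "M=XD":
            if block_start is None:
                block_start = pos
            pos += n
        elif op == "N":
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += n
        # S/H/I consume no reference
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks


def assign_gene(aln: AlignmentRecord, index: ExonIndex) -> Optional[str]:
    """Assign a primary alignment to a gene by exon overlap.

    Returns the gene_id on a unique (>=1 bp) exon overlap, ``None`` for
    intergenic alignments and :data:`DISCARDED_MULTI` when exons of two
    or more genes are touched.
    """
    if aln.is_secondary or aln.is_supplementary:
        return None
    genes: set[str] = set()
    for start, end in aligned_blocks(aln):
        genes |= index.overlapping_genes(aln.ref_name, start, end)
    if not genes:
        return None
    if len(genes) > 1:
        return DISCARDED_MULTI
    return genes.pop()


@dataclass
class PolyASite:
    gene_id: str
    position: int  # strand-aware cleavage coordinate (modal cluster end)
    strand: str
    support: int
    cluster_width: int


def _cluster_ends(ends: Sequence[int], window: int) -> list[list[int]]:
    """Single-linkage clustering of 1-D positions: split at gaps > window."""
    if not ends:
        return []
    ends = sorted(ends)
    clusters = [[ends[0]]]
    for e in ends[1:]:
        if e - clusters[-1][-1] <= window:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    return clusters


def call_polya_sites(
    end_records: Iterable[tuple[str, str, int]],
    window: int = 24,
    min_support: int = 2,
) -> list[PolyASite]:
    """Cluster strand-aware read 3' ends into polyadenylation sites.

    ``end_records`` are (gene_id, strand, cleavage_pos) triples from
    tail-bearing reads.  The site position is the modal end of the
    cluster (ties resolved to the most distal end: downstream on "+",
    upstream coordinate-wise on "-"); clusters with fewer than
    ``min_support`` reads are dropped.  Sites are returned ordered
    5'->3' along the transcript, most proximal first.
    """
    by_gene: dict[str, dict] = {}
    for gene_id, strand, pos in end_records:
        entry = by_gene.setdefault(gene_id, {"strand": strand, "ends": []})
        entry["ends"].append(pos)
    sites: list[PolyASite] = []
    for gene_id in sorted(by_gene):
        strand = by_gene[gene_id]["strand"]
        clusters = _cluster_ends(by_gene[gene_id]["ends"], window)
        gene_sites = []
        for cluster in clusters:
            if len(cluster) < min_support:
                continue
            counts = Counter(cluster)
            top = max(counts.values())
            modes = [p for p, c in counts.items() if c == top]
            position = max(modes) if strand == "+" else min(modes)
            gene_sites.append(
                PolyASite(gene_id, position, strand, len(cluster), max(cluster) - min(cluster))
            )
        # proximal first: ascending genomic position on "+", descending on "-"
        gene_sites.sort(key=lambda s: s.position, reverse=(strand == "-"))
        sites.extend(gene_sites)
    return sites


def apa_class_table(sites: Sequence[PolyASite]) -> pd.DataFrame:
    """Classify genes by number of called sites.

    Convention: a gene with two polyadenylation sites shows "1 APA
    site", three sites "2 APAs", more than three ">=3 APA sites";
    single-site genes are reported separately as "no APA".
    """
    n_sites = Counter(s.gene_id for s in sites)
    classes = Counter()
    for gene_id, k in n_sites.items():
        if k == 1:
            classes["no APA"] += 1
        elif k == 2:
            classes["1 APA site"] += 1
        elif k == 3:
            classes["2 APAs"] += 1
        else:
            classes[">=3 APA sites"] += 1
    order = ["no APA", "1 APA site", "2 APAs", ">=3 APA sites"]
    return pd.DataFrame(
        {"apa_class": order, "n_genes": [classes.get(c, 0) for c in order]}
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Minimal BED reader (chrom, start, end; extra columns preserved)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


def compare_sites_to_reference(
    sites: Sequence[PolyASite],
    reference_bed: str | Path | pd.DataFrame,
    chrom_of_gene: dict[str, str],
    slack: int = 24,
) -> pd.DataFrame:
    """Fraction of called sites within ``slack`` nt of a reference record.

    ``chrom_of_gene`` maps gene_id to chromosome (e.g. from the
    :class:`ExonIndex`).  An empty reference yields fraction 0 with a
    warning.
    """
    ref = reference_bed if isinstance(reference_bed, pd.DataFrame) else read_bed(reference_bed)
    trees: dict[str, IntervalTree] = {}
    for _, row in ref.iterrows():
        trees.setdefault(str(row["chrom"]), IntervalTree())[
            int(row["start"]) : max(int(row["end"]), int(row["start"]) + 1)
        ] = True
    if not len(ref):
        logger.warning("empty reference site set; overlap fraction is 0")
    n_overlap = 0
    for site in sites:
        chrom = chrom_of_gene.get(site.gene_id)
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(site.position - slack, site.position + slack + 1):
            n_overlap += 1
    n = len(sites)
    return pd.DataFrame(
        [
            {
                "n_sites": n,
                "n_overlapping": n_overlap,
                "fraction_overlapping": n_overlap / n if n else 0.0,
                "slack": slack,
            }
        ]
    )


def sites_to_bed(sites: Sequence[PolyASite], chrom_of_gene: dict[str, str]) -> pd.DataFrame:
    rows = [
        {
            "chrom": chrom_of_gene.get(s.gene_id, "."),
            "start": s.position,
            "end": s.position + 1,
            "name": s.gene_id,
            "score": s.support,
            "strand": s.strand,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def intron_chain(aln: AlignmentRecord) -> tuple[tuple[int, int], ...]:
    """The (start, end) reference coordinates of every intron (N run)."""
    introns = []
    pos = aln.ref_start
    for op, n in aln.cigar_ops():
        if op == "N":
            introns.append((pos, pos + n))
            pos += n
        elif op in "M=XD":
            pos += n
    return tuple(introns)


def group_isoforms(alns: Iterable[AlignmentRecord]) -> dict[tuple, list[str]]:
    """Group reads into splice isoforms by exact intron-chain identity."""
    groups: dict[tuple, list[str]] = {}
    for aln in alns:
        key = (aln.ref_name, intron_chain(aln))
        groups.setdefault(key, []).append(aln.read_id)
    return groups
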
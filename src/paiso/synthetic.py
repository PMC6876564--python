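"""Ground-truth simulator for barcoded full-length cDNA CCS datasets.

Emulates the library structure the pipeline consumes::

    5'primer -- cDNA -- poly(A) tail -- revcomp(barcode probe)

on a toy genome (about 20 multi-exon genes on two chromosomes), with
per-gene lognormal tail lengths, internal U/G/C residues injected at a
configurable rate with 5'-biased positions (plus an optional extra
3'-enriched G mode), terminal non-A additions, concatemers, a
CCS-like pass-number distribution and an optional per-base error
model.  Alignments are emitted as SAM by construction — the planted
tail appears as the read-3' terminal soft-clip — so no aligner is
needed to test the downstream stages.  Every emitted read is
reconstructable byte-for-byte from the truth table before error
injection, and a fixed seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .demux import ProbeSet
from .io import CcsRead, write_fastq
from .sequtils import revcomp
from .spikein import SpikeInPanel, builtin_panel

_BASES = np.array(list("ACGT"))
_NON_A = np.array(list("TGC"))

#: Shared 5' cDNA (ISPCR) primer and the first six TSO bases completing
#: each 22-nt demultiplexing probe.
FIVE_PRIME_PRIMER = "AAGCAGTGGTATCAACGCAGAGT"
TSO_PREFIX = "AAGCAG"


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a transcriptionally silent oocyte-like sample:
    lognormal per-gene tails centred near 60 nt, ~0.7% of tail bases
    carrying internal non-A residues with 5'-biased positions, reads
    dominated by >=10-pass consensus calls, and no sequencing error
    (ground-truth mode; raise ``error_rate`` to degrade gracefully).
    """

    seed: int = 0
    samples: tuple[str, ...] = ("s01", "s02")
    n_genes: int = 20
    n_reads: int = 2000
    # toy genome layout
    n_chroms: int = 2
    exons_per_gene: tuple[int, int] = (1, 4)
    exon_length: tuple[int, int] = (150, 500)
    intron_length: tuple[int, int] = (100, 400)
    intergenic_gap: tuple[int, int] = (200, 500)
    # per-gene tail model: lognormal(mu_g, sigma_g), truncated
    tail_log_mu_mean: float = float(np.log(60.0))
    tail_log_mu_sd: float = 0.4
    tail_log_sigma: float = 0.5
    max_tail: int = 500
    # internal non-A modification model
    mod_rate: float = 0.007
    mod_positional_tau: float = 0.3  # 5'-biased exp(-relpos/tau) weight
    g3_mode: bool = False
    g3_rate: float = 0.002  # extra 3'-enriched G injection when g3_mode
    terminal_mod_rate: float = 0.02
    # error and read-level models
    error_rate: float = 0.0
    error_shares: tuple[float, float, float] = (0.75, 0.125, 0.125)  # sub, ins, del
    pass_poisson_mean: float = 14.0  # num_passes = 1 + Poisson(mean)
    concatemer_rate: float = 0.01
    flip_fraction: float = 0.5  # reads stored in reverse orientation
    # alternative polyadenylation
    apa_fraction: float = 0.5  # genes carrying a second (proximal) site
    apa_offset: int = 150  # nt removed from the 3' end at the proximal site
    min_clean_len: int = 50
    max_edits: int = 2

    def validate(self) -> None:
        for name in ("mod_rate", "g3_rate", "terminal_mod_rate", "error_rate",
                     "concatemer_rate", "flip_fraction", "apa_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("sample ids must be unique")
        if abs(sum(self.error_shares) - 1.0) > 1e-9:
            raise ValueError("error_shares must sum to 1")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, 0-based half-open
    mu: float
    sigma: float
    # 3' truncation offsets defining polyadenylation sites; 0 = distal site
    site_offsets: list[int] = field(default_factory=lambda: [0])

    def transcript(self, genome: dict[str, str], offset: int = 0) -> str:
        """Sense-strand transcript sequence, 3'-truncated by ``offset`` nt."""
        parts = [genome[self.chrom][s:e] for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq[: len(seq) - offset] if offset else seq

    def cleavage_pos(self, offset: int = 0) -> int:
        """Genomic coordinate of the transcript 3' end for one site."""
        if self.strand == "+":
            return self.exons[-1][1] - offset
        return self.exons[0][0] + offset


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    probes: ProbeSet
    reads: list[CcsRead]
    truth: pd.DataFrame
    clean_reads: dict[str, tuple[str, int]]  # read_id -> (clean seq, passes)
    paths: dict[str, Path] = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_probe_set(
    samples: Sequence[str], rng: np.random.Generator, max_edits: int = 2
) -> ProbeSet:
    """Random 16-nt barcodes at pairwise edit distance > 2*max_edits."""
    from .matching import edit_distance

    barcodes: list[str] = []
    while len(barcodes) < len(samples):
        cand = _rand_seq(rng, 16)
        if all(edit_distance(cand, b) > 2 * max_edits for b in barcodes):
            barcodes.append(cand)
    probes = {s: bc + TSO_PREFIX for s, bc in zip(samples, barcodes)}
    return ProbeSet(probes, five_prime_primer=FIVE_PRIME_PRIMER, max_edits=max_edits)


def build_toy_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with genes laid out left to right on each chromosome."""
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    g = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        seq_parts: list[str] = []
        pos = 0
        while g < config.n_genes and g < (c + 1) * per_chrom:
            gap = int(rng.integers(*config.intergenic_gap))
            seq_parts.append(_rand_seq(rng, gap))
            pos += gap
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons = []
            for e in range(n_exons):
                if e > 0:
                    intron = int(rng.integers(*config.intron_length))
                    seq_parts.append(_rand_seq(rng, intron))
                    pos += intron
                ex_len = int(rng.integers(*config.exon_length))
                seq_parts.append(_rand_seq(rng, ex_len))
                exons.append((pos, pos + ex_len))
                pos += ex_len
            strand = "+" if rng.random() < 0.5 else "-"
            mu = rng.normal(config.tail_log_mu_mean, config.tail_log_mu_sd)
            offsets = [0]
            if rng.random() < config.apa_fraction:
                # proximal site must stay inside the 3'-terminal exon
                last = exons[-1] if strand == "+" else exons[0]
                if last[1] - last[0] > config.apa_offset + config.min_clean_len:
                    offsets.append(config.apa_offset)
            genes.append(
                GeneModel(
                    gene_id=f"gene{g + 1:03d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    mu=float(mu),
                    sigma=config.tail_log_sigma,
                    site_offsets=offsets,
                )
            )
            g += 1
        tail_gap = int(rng.integers(*config.intergenic_gap))
        seq_parts.append(_rand_seq(rng, tail_gap))
        genome[chrom] = "".join(seq_parts)
    return genome, genes


def _sample_tail(
    gene: GeneModel, config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str]], str]:
    """One tail: sequence, internal modification (pos, base) list, terminal add."""
    L = int(np.clip(round(rng.lognormal(gene.mu, gene.sigma)), 1, config.max_tail))
    tail = ["A"] * L
    mods: list[tuple[int, str]] = []
    k = rng.binomial(L, config.mod_rate)
    if k:
        rel = (np.arange(L) + 0.5) / L
        w = np.exp(-rel / config.mod_positional_tau)
        positions = rng.choice(L, size=min(k, L), replace=False, p=w / w.sum())
        for p in sorted(int(x) for x in positions):
            base = str(_NON_A[rng.integers(0, 3)])
            tail[p] = base
            mods.append((p, base))
    if config.g3_mode:
        k2 = rng.binomial(L, config.g3_rate)
        if k2:
            rel = (np.arange(L) + 0.5) / L
            w = np.exp(-(1.0 - rel) / config.mod_positional_tau)
            positions = rng.choice(L, size=min(k2, L), replace=False, p=w / w.sum())
            for p in sorted(int(x) for x in positions):
                if tail[p] == "A":
                    tail[p] = "G"
                    mods.append((int(p), "G"))
    terminal = ""
    if rng.random() < config.terminal_mod_rate:
        n_term = int(rng.integers(1, 3))
        terminal = "".join(str(_NON_A[rng.integers(0, 3)]) for _ in range(n_term))
    mods.sort()
    return "".join(tail) + terminal, mods, terminal


def _mutate_segment(
    seq: str, config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Apply the per-base error model; returns (new seq, M/I/D cigar ops)."""
    if config.error_rate == 0.0:
        return seq, [("M", len(seq))] if seq else []
    sub_p, ins_p, del_p = (config.error_rate * s for s in config.error_shares)
    out: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for ch in seq:
        r = rng.random()
        if r < ins_p:
            out.append(str(_BASES[rng.integers(0, 4)]))
            push("I")
            out.append(ch)
            push("M")
        elif r < ins_p + del_p:
            push("D")
        elif r < ins_p + del_p + sub_p:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[rng.integers(0, 3)])
            push("M")
        else:
            out.append(ch)
            push("M")
    return "".join(out), ops


def _mutate_plain(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    return _mutate_segment(seq, config, rng)[0]


def _exon_query_lengths(gene: GeneModel, offset: int) -> list[int]:
    """Per-exon transcript lengths in sense order after 3' truncation."""
    lengths = [e - s for s, e in gene.exons]
    if gene.strand == "-":
        lengths = lengths[::-1]
    remaining = offset
    i = len(lengths) - 1
    while remaining > 0 and i >= 0:
        cut = min(remaining, lengths[i])
        lengths[i] -= cut
        remaining -= cut
        i -= 1
    return [x for x in lengths if x > 0]


def _cigar_and_pos(
    gene: GeneModel,
    offset: int,
    exon_ops: list[list[tuple[str, int]]],
    tail_len: int,
) -> tuple[str, int]:
    """SAM CIGAR and POS for a full-length sense read of one gene.

    ``exon_ops`` are per-exon M/I/D runs in sense order (post-error).
    For a minus-strand gene the stored record is the reverse complement,
    so exon order and per-exon ops are reversed and the tail soft-clip
    moves to the left end.
    """
    introns = [gene.exons[i + 1][0] - gene.exons[i][1] for i in range(len(gene.exons) - 1)]
    if gene.strand == "+":
        stored_ops = exon_ops
        stored_introns = introns
        pos = gene.exons[0][0]
        parts = []
        for i, ops in enumerate(stored_ops):
            parts.extend(ops)
            if i < len(stored_ops) - 1:
                parts.append(("N", stored_introns[i]))
        if tail_len:
            parts.append(("S", tail_len))
    else:
        # sense order reversed back to genomic order; ops within an exon
        # reversed too (revcomp reverses the base order).  The sense-3'
        # truncation shortens the genomic-first exon from its left edge.
        stored_ops = [[(op, n) for op, n in reversed(ops)] for ops in reversed(exon_ops)]
        stored_introns = introns
        pos = gene.exons[0][0] + offset
        parts = [("S", tail_len)] if tail_len else []
        for i, ops in enumerate(stored_ops):
            parts.extend(ops)
            if i < len(stored_ops) - 1:
                parts.append(("N", stored_introns[i]))
    merged: list[tuple[str, int]] = []
    for op, n in parts:
        if n <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    cigar = "".join(f"{n}{op}" for op, n in merged)
    return cigar, pos


def generate_dataset(config: SimConfig, out_dir: Optional[str | Path] = None) -> SimResult:
    """Simulate one dataset; optionally write all files to ``out_dir``.

    Emits reads FASTQ, truth TSV, toy genome FASTA, GTF, barcode TSV and
    a SAM of the clean reads with the tail as the 3' soft-clip.  The
    same seed always yields byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probes = make_probe_set(config.samples, rng, config.max_edits)
    genome, genes = build_toy_genome(config, rng)

    reads: list[CcsRead] = []
    truth_rows: list[dict] = []
    clean_reads: dict[str, tuple[str, int]] = {}
    sam_records: list[dict] = []

    for i in range(config.n_reads):
        read_id = f"sim/{i}/ccs"
        sample = config.samples[rng.integers(0, len(config.samples))]
        gene = genes[rng.integers(0, len(genes))]
        site_idx = int(rng.integers(0, len(gene.site_offsets)))
        offset = gene.site_offsets[site_idx]
        cdna = gene.transcript(genome, offset)
        tail, mods, terminal = _sample_tail(gene, config, rng)
        passes = 1 + int(rng.poisson(config.pass_poisson_mean))

        # per-exon error injection so the SAM CIGAR stays consistent
        exon_lengths = _exon_query_lengths(gene, offset)
        exon_ops: list[list[tuple[str, int]]] = []
        mutated_exons: list[str] = []
        start = 0
        for ex_len in exon_lengths:
            mut, ops = _mutate_segment(cdna[start : start + ex_len], config, rng)
            mutated_exons.append(mut)
            exon_ops.append(ops)
            start += ex_len
        cdna_obs = "".join(mutated_exons)
        tail_obs = _mutate_plain(tail, config, rng)
        clean_seq = cdna_obs + tail_obs

        probe_rc = revcomp(probes.probes[sample])
        unit = (
            _mutate_plain(FIVE_PRIME_PRIMER, config, rng)
            + clean_seq
            + _mutate_plain(probe_rc, config, rng)
        )
        is_concat = bool(rng.random() < config.concatemer_rate)
        if is_concat:
            other = genes[rng.integers(0, len(genes))]
            other_cdna = other.transcript(genome)
            other_tail, _, _ = _sample_tail(other, config, rng)
            front = (
                _mutate_plain(FIVE_PRIME_PRIMER, config, rng)
                + _mutate_plain(other_cdna, config, rng)
                + _mutate_plain(other_tail, config, rng)
                + _mutate_plain(probe_rc, config, rng)
            )
            raw = front + unit
        else:
            raw = unit
        flipped = bool(rng.random() < config.flip_fraction)
        stored = revcomp(raw) if flipped else raw
        reads.append(CcsRead(read_id, stored, passes))
        clean_reads[read_id] = (clean_seq, passes)

        cigar, pos = _cigar_and_pos(gene, offset, exon_ops, len(tail_obs))
        stored_aln = clean_seq if gene.strand == "+" else revcomp(clean_seq)
        sam_records.append(
            {
                "read_id": read_id,
                "chrom": gene.chrom,
                "pos": pos,
                "strand": gene.strand,
                "cigar": cigar,
                "seq": stored_aln,
                "passes": passes,
            }
        )
        truth_rows.append(
            {
                "read_id": read_id,
                "sample": sample,
                "gene_id": gene.gene_id,
                "transcript_id": f"{gene.gene_id}.t{site_idx + 1}",
                "site_index": site_idx,
                "tail_seq": tail,
                "tail_length": len(tail),
                "mod_positions": ";".join(f"{p}:{b}" for p, b in mods),
                "n_internal_mods": len(mods),
                "terminal_mod": terminal,
                "is_concatemer": is_concat,
                "cleavage_pos": gene.cleavage_pos(offset),
                "chrom": gene.chrom,
                "gene_strand": gene.strand,
                "num_passes": passes,
                "flipped": flipped,
            }
        )

    truth = pd.DataFrame(truth_rows)
    result = SimResult(
        config=config,
        genome=genome,
        genes=genes,
        probes=probes,
        reads=reads,
        truth=truth,
        clean_reads=clean_reads,
    )
    result.sam_records = sam_records  # type: ignore[attr-defined]
    if out_dir is not None:
        result.paths = _write_outputs(result, sam_records, Path(out_dir))
    return result


def _write_outputs(result: SimResult, sam_records: list[dict], out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": out_dir / "reads.fastq",
        "truth": out_dir / "truth.tsv",
        "genome": out_dir / "genome.fa",
        "gtf": out_dir / "annotation.gtf",
        "sam": out_dir / "alignments.sam",
        "barcodes": out_dir / "barcodes.tsv",
    }
    write_fastq(result.reads, paths["reads"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["genome"], "w") as fh:
        for chrom, seq in result.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gtf(result.genes, paths["gtf"])
    write_sam(sam_records, result.genome, paths["sam"])
    with open(paths["barcodes"], "w") as fh:
        fh.write("barcode_id\tprobe\n")
        for bid, probe in result.probes.probes.items():
            fh.write(f"{bid}\t{probe}\n")
    return paths


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Toy annotation: gene/transcript/exon features, 1-based inclusive."""
    with open(path, "w") as fh:
        for gene in genes:
            g_start = gene.exons[0][0] + 1
            g_end = gene.exons[-1][1]
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            tid = f"{gene.gene_id}.t1"
            t_attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
            fh.write(
                f"{gene.chrom}\tsim\ttranscript\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\t{t_attrs}\n"
            )
            for s, e in gene.exons:
                fh.write(
                    f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{t_attrs}\n"
                )


def write_sam(sam_records: list[dict], genome: dict[str, str], path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": len(seq)} for chrom, seq in genome.items()],
    }
    ref_ids = {chrom: i for i, chrom in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for rec in sam_records:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = rec["read_id"]
            seg.query_sequence = rec["seq"]
            seg.flag = 16 if rec["strand"] == "-" else 0
            seg.reference_id = ref_ids[rec["chrom"]]
            seg.reference_start = rec["pos"]
            seg.mapping_quality = 60
            seg.cigarstring = rec["cigar"]
            seg.set_tag("np", rec["passes"])
            fh.write(seg)


def generate_spikein_reads(
    n_per_design: int,
    seed: int = 0,
    panel: Optional[SpikeInPanel] = None,
    error_rate: float = 0.0,
    pass_poisson_mean: float = 14.0,
) -> tuple[list[CcsRead], pd.DataFrame]:
    """Simulated spike-in reads (every design, known tails) plus truth."""
    panel = panel or builtin_panel()
    rng = np.random.default_rng(seed)
    cfg = SimConfig(error_rate=error_rate)
    reads: list[CcsRead] = []
    rows: list[dict] = []
    i = 0
    for design in panel.designs:
        for _ in range(n_per_design):
            tail = "A" * design.designed_tail
            raw = panel.read_for(design, tail)
            if error_rate > 0.0:
                raw = _mutate_plain(raw, cfg, rng)
            flipped = bool(rng.random() < 0.5)
            stored = revcomp(raw) if flipped else raw
            passes = 1 + int(rng.poisson(pass_poisson_mean))
            read_id = f"spike/{i}/ccs"
            reads.append(CcsRead(read_id, stored, passes))
            rows.append(
                {
                    "read_id": read_id,
                    "design_id": design.design_id,
                    "designed_tail": design.designed_tail,
                    "flipped": flipped,
                    "num_passes": passes,
                }
            )
            i += 1
    return reads, pd.DataFrame(rows)


@dataclass
class VnSimConfig:
    """Conditions for a conventional oligo(dT)-T30VN Iso-seq simulation."""

    seed: int = 0
    n_reads: int = 1000
    model_b_fraction: float = 0.05
    double_anchor_fraction: float = 0.2  # of model-b reads, anchors of 2 bases
    terminal_a: int = 30  # complement of the primer's T30
    body_a_range: tuple[int, int] = (5, 16)  # A's 5' of a model-b anchor
    error_rate: float = 0.0


def generate_isoseq_vn(
    config: VnSimConfig, sim: Optional[SimResult] = None
) -> tuple[list[CcsRead], pd.DataFrame]:
    """Simulate T30VN-primed reads with known anchoring models.

    Model a: the primer anchored at the 3'-UTR end, leaving only the
    terminal A stretch.  Model b: anchored at 1-2 internal non-A bases,
    leaving A residues between the UTR and the anchor.  Truth carries
    the model, anchor bases and the UTR end coordinate.
    """
    rng = np.random.default_rng(config.seed)
    if sim is None:
        sim = generate_dataset(SimConfig(seed=config.seed, n_reads=1))
    cdnas = [g.transcript(sim.genome) for g in sim.genes]
    cfg = SimConfig(error_rate=config.error_rate)
    reads: list[CcsRead] = []
    rows: list[dict] = []
    for i in range(config.n_reads):
        cdna = cdnas[rng.integers(0, len(cdnas))]
        is_b = rng.random() < config.model_b_fraction
        if is_b:
            n_anchor = 2 if rng.random() < config.double_anchor_fraction else 1
            anchor = "".join(str(_NON_A[rng.integers(0, 3)]) for _ in range(n_anchor))
            j = int(rng.integers(*config.body_a_range))
            tail = "A" * j + anchor + "A" * config.terminal_a
        else:
            anchor = ""
            tail = "A" * config.terminal_a
        seq = cdna + tail
        if config.error_rate > 0.0:
            seq = cdna + _mutate_plain(tail, cfg, rng)  # keep utr_end exact
        read_id = f"vn/{i}/ccs"
        reads.append(CcsRead(read_id, seq, 1 + int(rng.poisson(14.0))))
        rows.append(
            {
                "read_id": read_id,
                "model": "b" if is_b else "a",
                "anchor_bases": anchor,
                "utr_end": len(cdna),
            }
        )
    return reads, pd.DataFrame(rows)
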
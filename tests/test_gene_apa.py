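import numpy as np
import pandas as pd
import pytest

from paiso.gene_apa import (
    DISCARDED_MULTI,
    PolyASite,
    apa_class_table,
    assign_gene,
    build_exon_index,
    call_polya_sites,
    compare_sites_to_reference,
    group_isoforms,
    intron_chain,
    merge_intervals,
)
from paiso.io import AlignmentRecord


def _write_gtf(path, lines):
    path.write_text("".join(line + "\n" for line in lines))
    return path


def _exon(chrom, start, end, gene, strand="+"):
    return (
        f'{chrom}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t'
        f'gene_id "{gene}"; transcript_id "{gene}.t1";'
    )


def _aln(cigar, ref_start, read_id="r", chrom="chr1", strand="+"):
    return AlignmentRecord(
        read_id=read_id, ref_name=chrom, ref_strand=strand, cigar=cigar, ref_start=ref_start
    )


class TestExonIndex:
    def test_overlapping_exons_merged(self, tmp_path):
        gtf = _write_gtf(
            tmp_path / "a.gtf",
            [_exon("chr1", 100, 200, "g1"), _exon("chr1", 150, 250, "g1")],
        )
        index = build_exon_index(gtf)
        assert index.genes["g1"]["exons"] == [(99, 250)]

    def test_duplicate_exons_removed(self, tmp_path):
        gtf = _write_gtf(
            tmp_path / "b.gtf",
            [_exon("chr1", 100, 200, "g1"), _exon("chr1", 100, 200, "g1")],
        )
        index = build_exon_index(gtf)
        assert index.genes["g1"]["exons"] == [(99, 200)]

    def test_two_disjoint_genes_independent(self, tmp_path):
        gtf = _write_gtf(
            tmp_path / "c.gtf",
            [_exon("chr1", 100, 200, "g1"), _exon("chr1", 1000, 1200, "g2")],
        )
        index = build_exon_index(gtf)
        assert set(index.genes) == {"g1", "g2"}

    def test_bad_lines_skipped(self, tmp_path):
        gtf = _write_gtf(
            tmp_path / "d.gtf",
            ["# comment", "garbage line without tabs", _exon("chr1", 100, 200, "g1")],
        )
        index = build_exon_index(gtf)
        assert set(index.genes) == {"g1"}

    def test_merge_intervals_helper(self):
        assert merge_intervals([(5, 10), (0, 3), (9, 12), (5, 10)]) == [(0, 3), (5, 12)]


class TestAssign:
    @pytest.fixture
    def index(self, tmp_path):
        gtf = _write_gtf(
            tmp_path / "g.gtf",
            [
                _exon("chr1", 101, 300, "g1"),
                _exon("chr1", 501, 700, "g1"),
                _exon("chr1", 651, 900, "g2"),  # overlaps g1's second exon
                _exon("chr1", 5001, 5400, "g3"),
            ],
        )
        return build_exon_index(gtf)

    def test_unique_overlap_assigned(self, index):
        assert assign_gene(_aln("100M", 120), index) == "g1"

    def test_spanning_two_genes_discarded(self, index):
        # block overlapping both g1 (501-700) and g2 (651-900)
        assert assign_gene(_aln("200M", 600), index) == DISCARDED_MULTI

    def test_intergenic_none(self, index):
        assert assign_gene(_aln("50M", 2000), index) is None

    def test_intron_gap_not_counted(self, index):
        # N across g2's exon must not pick up g2
        aln = _aln("100M300N100M", 120)
        # blocks: 120-220 (g1 exon1), 520-620 (g1 exon2)
        assert assign_gene(aln, index) == "g1"

    def test_order_independence(self, index, rng):
        alns = [_aln("100M", 120, read_id=f"r{i}") for i in range(10)]
        expected = [assign_gene(a, index) for a in alns]
        order = rng.permutation(10)
        assert [assign_gene(alns[i], index) for i in order] == [expected[i] for i in order]


def brute_single_linkage(ends, window):
    """Oracle: exhaustive single-linkage by pairwise chaining."""
    ends = sorted(ends)
    clusters = []
    for e in ends:
        placed = False
        for c in clusters:
            if any(abs(e - x) <= window for x in c):
                c.append(e)
                placed = True
                break
        if not placed:
            clusters.append([e])
    # merge transitively
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(abs(a - b) <= window for a in clusters[i] for b in clusters[j]):
                    clusters[i] += clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(sorted(c) for c in clusters)


class TestClustering:
    def test_two_close_ends_one_site(self):
        sites = call_polya_sites([("g1", "+", 1000), ("g1", "+", 1003)], window=24)
        assert len(sites) == 1 and sites[0].support == 2

    def test_two_far_ends_two_sites(self):
        sites = call_polya_sites(
            [("g1", "+", 1000), ("g1", "+", 1000), ("g1", "+", 1050), ("g1", "+", 1050)],
            window=24,
        )
        assert len(sites) == 2
        assert apa_class_table(sites).set_index("apa_class").loc["1 APA site", "n_genes"] == 1

    def test_identical_ends_zero_width(self):
        sites = call_polya_sites([("g1", "+", 500)] * 5, window=24)
        assert len(sites) == 1 and sites[0].cluster_width == 0 and sites[0].position == 500

    def test_modal_position_tie_breaks_distal(self):
        ends = [("g1", "+", 100), ("g1", "+", 100), ("g1", "+", 110), ("g1", "+", 110)]
        assert call_polya_sites(ends, window=24)[0].position == 110
        ends_minus = [("g1", "-", 100), ("g1", "-", 100), ("g1", "-", 110), ("g1", "-", 110)]
        assert call_polya_sites(ends_minus, window=24)[0].position == 100

    def test_min_support_filters(self):
        sites = call_polya_sites([("g1", "+", 0), ("g1", "+", 500)], window=24, min_support=2)
        assert sites == []

    def test_proximal_site_first(self):
        ends = [("g1", "-", 100)] * 3 + [("g1", "-", 500)] * 3
        sites = call_polya_sites(ends, window=24)
        # on the minus strand the proximal (most 5'-ward on the transcript)
        # site has the larger genomic coordinate
        assert [s.position for s in sites] == [500, 100]

    def test_matches_exhaustive_single_linkage(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            ends = sorted(int(x) for x in rng.integers(0, 500, n))
            window = int(rng.integers(1, 60))
            sites = call_polya_sites(
                [("g", "+", e) for e in ends], window=window, min_support=1
            )
            oracle = brute_single_linkage(ends, window)
            got = sorted([s.support for s in sites])
            assert got == sorted(len(c) for c in oracle)


class TestApaClasses:
    def test_classification_convention(self):
        def site(g, pos):
            return PolyASite(g, pos, "+", 3, 0)

        sites = (
            [site("a", 0)]
            + [site("b", 0), site("b", 100)]
            + [site("c", 0), site("c", 100), site("c", 200)]
            + [site("d", p) for p in (0, 100, 200, 300)]
        )
        table = apa_class_table(sites).set_index("apa_class")["n_genes"]
        assert table["no APA"] == 1
        assert table["1 APA site"] == 1
        assert table["2 APAs"] == 1
        assert table[">=3 APA sites"] == 1


class TestReferenceComparison:
    def test_site_at_reference_overlaps(self):
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1001]})
        sites = [PolyASite("g1", 1010, "+", 3, 0)]
        out = compare_sites_to_reference(sites, ref, {"g1": "chr1"}, slack=24)
        assert out["fraction_overlapping"].iloc[0] == 1.0

    def test_distant_site_no_overlap(self):
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1001]})
        sites = [PolyASite("g1", 2000, "+", 3, 0)]
        out = compare_sites_to_reference(sites, ref, {"g1": "chr1"}, slack=24)
        assert out["fraction_overlapping"].iloc[0] == 0.0

    def test_empty_reference_zero_fraction(self):
        ref = pd.DataFrame(columns=["chrom", "start", "end"])
        sites = [PolyASite("g1", 2000, "+", 3, 0)]
        out = compare_sites_to_reference(sites, ref, {"g1": "chr1"})
        assert out["fraction_overlapping"].iloc[0] == 0.0


def test_planted_sites_recovered_from_simulation(sim_small):
    """Each gene's planted cleavage sites (separated by far more than the
    clustering window) are recovered exactly at the planted positions."""
    truth = sim_small.truth
    strand_of = {g.gene_id: g.strand for g in sim_small.genes}
    end_records = [
        (row.gene_id, strand_of[row.gene_id], row.cleavage_pos)
        for row in truth.itertuples()
    ]
    sites = call_polya_sites(end_records, window=24, min_support=2)
    called = {}
    for s in sites:
        called.setdefault(s.gene_id, set()).add(s.position)
    for gene in sim_small.genes:
        planted = {
            gene.cleavage_pos(off)
            for off in gene.site_offsets
            if (truth[(truth.gene_id == gene.gene_id)
                      & (truth.cleavage_pos == gene.cleavage_pos(off))].shape[0] >= 2)
        }
        assert called.get(gene.gene_id, set()) == planted


def test_intron_chain_grouping():
    a1 = _aln("50M100N50M20S", 100, read_id="r1")
    a2 = _aln("30M100N70M", 120, read_id="r2")  # same intron (150,250)? no: (150,250) vs (150,250)
    a3 = _aln("50M200N50M", 100, read_id="r3")
    assert intron_chain(a1) == ((150, 250),)
    groups = group_isoforms([a1, a2, a3])
    chains = {k[1]: v for k, v in groups.items()}
    assert chains[((150, 250),)] == ["r1", "r2"]
    assert chains[((150, 350),)] == ["r3"]
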
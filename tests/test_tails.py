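import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paiso.io import AlignmentRecord
from paiso.sequtils import revcomp
from paiso.tails import (
    GeneTailSummary,
    Rejection,
    TailCall,
    check_tail_criteria,
    extract_tail,
    gene_geometric_mean,
    length_distribution,
    long_tail_table,
    summarize_genes,
)

BASES = "ACGT"


def _aln(cigar, strand="+", read_id="r", secondary=False, supplementary=False):
    return AlignmentRecord(
        read_id=read_id,
        ref_name="chr1",
        ref_strand=strand,
        cigar=cigar,
        ref_start=100,
        is_secondary=secondary,
        is_supplementary=supplementary,
    )


class TestExtractTail:
    def test_pure_a_homopolymer_accepted(self):
        clean = "C" * 50 + "A" * 20
        out = extract_tail(_aln("50M20S"), clean)
        assert isinstance(out, TailCall)
        assert out.tail_seq == "A" * 20
        assert out.tail_length == 20

    def test_fourteen_nt_clip_too_short(self):
        clean = "C" * 50 + "A" * 14
        out = extract_tail(_aln("50M14S"), clean)
        assert isinstance(out, Rejection) and out.reason == "short_clip"

    def test_no_five_a_run_rejected(self):
        clip = "ACGT" * 5
        out = extract_tail(_aln("50M20S"), "C" * 50 + clip)
        assert isinstance(out, Rejection) and out.reason == "no_A5_run"

    def test_twenty_non_a_rejected(self):
        clip = "A" * 20 + "G" * 20  # 20 non-A is not < 20
        out = extract_tail(_aln("50M40S"), "C" * 50 + clip)
        assert isinstance(out, Rejection) and out.reason == "too_many_nonA"

    def test_minus_strand_clip_is_left_of_stored(self):
        # read: 60 nt cDNA + 30 nt tail; stored as reverse complement, the
        # tail becomes the soft-clip at the left end
        clean = "C" * 60 + "A" * 25 + "G" + "A" * 4
        out = extract_tail(_aln("30S60M", strand="-"), clean)
        assert isinstance(out, TailCall)
        assert out.tail_seq == "A" * 25 + "G" + "A" * 4
        assert out.cleavage_pos == 100  # ref_start on the minus strand

    def test_plus_strand_cleavage_position(self):
        out = extract_tail(_aln("50M2D10M20S"), "C" * 60 + "A" * 20)
        assert isinstance(out, TailCall)
        assert out.cleavage_pos == 100 + 50 + 2 + 10

    def test_hard_clip_recovered_from_clean_seq(self):
        clean = "C" * 50 + "A" * 20
        out = extract_tail(_aln("50M20H"), clean)
        assert isinstance(out, TailCall)
        assert out.tail_seq == "A" * 20

    def test_secondary_and_supplementary_rejected(self):
        clean = "C" * 50 + "A" * 20
        assert extract_tail(_aln("50M20S", secondary=True), clean).reason == "nonprimary"
        assert extract_tail(_aln("50M20S", supplementary=True), clean).reason == "nonprimary"

    def test_suspicious_five_prime_clip_rejected(self):
        # both ends carry a plausible tail: flagged, not called
        clean = "A" * 20 + "C" * 50 + "A" * 20
        out = extract_tail(_aln("20S50M20S"), clean)
        assert isinstance(out, Rejection) and out.reason == "suspicious_5prime"

    def test_planted_tails_recovered_exactly(self, sim_clean):
        """On error-free synthetic alignments every planted tail >= 15 nt
        is recovered with zero length error."""
        truth = sim_clean.truth.set_index("read_id")
        n_checked = 0
        for rec in sim_clean.sam_records:
            aln = AlignmentRecord(
                read_id=rec["read_id"],
                ref_name=rec["chrom"],
                ref_strand=rec["strand"],
                cigar=rec["cigar"],
                ref_start=rec["pos"],
            )
            clean_seq, _ = sim_clean.clean_reads[rec["read_id"]]
            row = truth.loc[rec["read_id"]]
            out = extract_tail(aln, clean_seq)
            if row.tail_length >= 15:
                assert isinstance(out, TailCall)
                assert out.tail_seq == row.tail_seq
                assert out.cleavage_pos == row.cleavage_pos
                n_checked += 1
        assert n_checked > 100


def brute_force_decision(clip):
    """Re-check the three criteria naively."""
    if len(clip) < 15:
        return False
    if "AAAAA" not in clip:
        return False
    non_a = sum(1 for c in clip if c != "A")
    return non_a / len(clip) < 0.5 and non_a < 20


def test_criteria_match_brute_force_oracle(rng):
    for _ in range(2000):
        length = int(rng.integers(1, 80))
        a_bias = rng.random()
        clip = "".join(
            "A" if rng.random() < a_bias else BASES[int(rng.integers(0, 4))]
            for _ in range(length)
        )
        assert (check_tail_criteria(clip) is None) == brute_force_decision(clip)


class TestGeneSummaries:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([50], 50.0), ([25, 100], 50.0), ([30, 30, 30], 30.0), ([25, 100, 50], 50.0)],
    )
    def test_geometric_mean(self, lengths, expected):
        assert gene_geometric_mean(lengths) == pytest.approx(expected)

    def test_geometric_mean_empty_raises(self):
        with pytest.raises(ValueError):
            gene_geometric_mean([])

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=50))
    def test_am_gm_inequality(self, lengths):
        geo = gene_geometric_mean(lengths)
        arith = sum(lengths) / len(lengths)
        assert geo <= arith + 1e-9
        if len(set(lengths)) == 1:
            assert geo == pytest.approx(arith)

    def test_min_reads_threshold(self):
        tails = [
            TailCall("r1", "A" * 25, gene_id="g1"),
            TailCall("r2", "A" * 100, gene_id="g1"),
            TailCall("r3", "A" * 50, gene_id="g1"),
            TailCall("r4", "A" * 30, gene_id="g2"),
            TailCall("r5", "A" * 30, gene_id="g2"),
        ]
        summaries = summarize_genes(tails, min_reads=3)
        assert [s.gene_id for s in summaries] == ["g1"]
        assert summaries[0].geo_mean_length == pytest.approx(50.0)
        assert len(summarize_genes(tails, min_reads=1)) == 2

    def test_pooled_non_a_ratio(self):
        tails = [
            TailCall("r1", "A" * 9 + "G", gene_id="g1"),  # 10 nt, 1 non-A
            TailCall("r2", "A" * 90, gene_id="g1"),
        ]
        (summary,) = summarize_genes(tails, min_reads=2)
        assert summary.non_a_ratio == pytest.approx(0.01)


class TestLengthDistribution:
    def test_empty_input_all_zero(self):
        df = length_distribution([], bin_width=10, max_length=50)
        assert df["count"].sum() == 0

    def test_single_tail_in_correct_long_bin(self):
        df = long_tail_table([205])
        row = df[(df.bin_start == 200) & (df.bin_end == 220)]
        assert row["count"].tolist() == [1]

    def test_counts_conserved(self, rng):
        lengths = np.clip(rng.lognormal(4, 0.5, 500).round().astype(int), 1, None)
        df = length_distribution(lengths.tolist(), bin_width=10)
        assert df["count"].sum() == 500


def test_parameter_recovery_per_gene_geometric_mean(sim_clean):
    """With per-gene lognormal(mu, sigma) tails the per-gene geometric mean
    estimates exp(mu) to within 3 sigma/sqrt(n) on the log scale."""
    mu_by_gene = {g.gene_id: g.mu for g in sim_clean.genes}
    sigma = sim_clean.config.tail_log_sigma
    truth = sim_clean.truth
    for gene_id, group in truth.groupby("gene_id"):
        lengths = group["tail_length"].tolist()
        if len(lengths) < 10:
            continue
        geo = gene_geometric_mean(lengths)
        tol = 3 * sigma / math.sqrt(len(lengths)) + 0.02  # integer rounding slack
        assert abs(math.log(geo) - mu_by_gene[gene_id]) < tol
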
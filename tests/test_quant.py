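"""Unit and property tests for the amplicon quantification chain."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnaedit import quant
from rnaedit.quant import NucleotideCounts, Read

from conftest import write_sam


class TestFilterReads:
    def test_short_read_rejected(self):
        reads = [Read("r1", "A" * 99, "I" * 99)]  # mean Q40
        kept, tally = quant.filter_reads(reads)
        assert kept == [] and tally.too_short == 1

    def test_low_quality_rejected(self):
        # mean Phred 19.9 < 20: mix of Q19 and Q20+ characters
        qual = chr(19 + 33) * 135 + chr(28 + 33) * 15  # mean = (19*135+28*15)/150 = 19.9
        reads = [Read("r1", "A" * 150, qual)]
        kept, tally = quant.filter_reads(reads)
        assert kept == [] and tally.low_quality == 1

    def test_boundaries_retained(self):
        reads = [
            Read("len100", "A" * 100, chr(20 + 33) * 100),  # exactly at both bounds
        ]
        kept, tally = quant.filter_reads(reads)
        assert len(kept) == 1 and tally.total == 0

    def test_empty_input(self):
        kept, tally = quant.filter_reads([])
        assert kept == [] and tally.too_short == 0 and tally.low_quality == 0

    def test_missing_quality_is_error(self):
        with pytest.raises(ValueError, match="r7"):
            quant.filter_reads([Read("r7", "A" * 150, None)])


class TestCheckDepth:
    @pytest.mark.parametrize(
        "depth,passes", [(19_999, False), (20_000, True), (0, False), (25_000, True)]
    )
    def test_boundary(self, depth, passes):
        assert quant.check_depth({("s1", "GENE"): depth})[("s1", "GENE")] is passes


class TestPileup:
    def test_matching_reads_tally_reference_base(self, toy_design, tmp_path):
        ref = toy_design.reference
        sam = write_sam(tmp_path / "a.sam", toy_design, [(f"r{i}", 101, ref) for i in range(10)])
        counts = quant.pileup_counts(sam, toy_design)
        assert counts[104] == NucleotideCounts(a=10)
        assert counts[105] == NucleotideCounts(g=10)

    def test_mixed_base_tally(self, toy_design, tmp_path):
        ref = toy_design.reference
        edited = ref[:3] + "G" + ref[4:]  # G at site A (offset 3)
        reads = [(f"a{i}", 101, ref) for i in range(8)] + [
            (f"g{i}", 101, edited) for i in range(2)
        ]
        counts = quant.pileup_counts(write_sam(tmp_path / "b.sam", toy_design, reads), toy_design)
        assert counts[104].a == 8 and counts[104].g == 2

    def test_read_not_overlapping_contributes_nothing(self, toy_design, tmp_path):
        # read covers only the first 10 bases; sites B (114) and C (122) untouched
        sam = write_sam(
            tmp_path / "c.sam", toy_design, [("r0", 101, toy_design.reference[:10])]
        )
        counts = quant.pileup_counts(sam, toy_design)
        assert 114 not in counts and 122 not in counts and 104 in counts

    def test_unknown_reference_is_error(self, toy_design, tmp_path):
        path = tmp_path / "d.sam"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:chrX\tLN:10000\n")
            fh.write("r0\t0\tchrX\t101\t60\t5M\t*\t0\t0\tACGTA\tIIIII\n")
        with pytest.raises(ValueError, match="chrX"):
            quant.pileup_counts(str(path), toy_design)

    def test_order_independence(self, toy_design, tmp_path):
        ref = toy_design.reference
        edited = ref[:3] + "G" + ref[4:]
        reads = [(f"a{i}", 101, ref) for i in range(5)] + [
            (f"g{i}", 101, edited) for i in range(3)
        ]
        fwd = quant.pileup_counts(write_sam(tmp_path / "e.sam", toy_design, reads), toy_design)
        rev = quant.pileup_counts(
            write_sam(tmp_path / "f.sam", toy_design, reads[::-1]), toy_design
        )
        assert fwd == rev


class TestEditingPercent:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (NucleotideCounts(a=80, g=20, c=1), 20.0),
            (NucleotideCounts(a=0, g=50), 100.0),
            (NucleotideCounts(a=10, g=0), 0.0),
        ],
    )
    def test_formula(self, counts, expected):
        assert quant.editing_percent(counts) == expected

    def test_no_ag_coverage_is_missing_not_zero(self):
        assert math.isnan(quant.editing_percent(NucleotideCounts(c=100, t=50)))

    @given(
        a=st.integers(0, 1000),
        g=st.integers(0, 1000),
        c=st.integers(0, 1000),
        t=st.integers(0, 1000),
        n=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=200)
    def test_invariant_under_ctn_reads(self, a, g, c, t, n):
        base = quant.editing_percent(NucleotideCounts(a=a, g=g))
        with_ctn = quant.editing_percent(NucleotideCounts(a=a, g=g, c=c, t=t, n=n))
        assert (math.isnan(base) and math.isnan(with_ctn)) or base == with_ctn

    def test_minus_strand_uses_tc(self):
        counts = NucleotideCounts(t=80, c=20, a=5, g=5)
        assert quant.site_editing_percent(counts, "-") == 20.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            NucleotideCounts(a=-1)


class TestDetectSites:
    def test_strict_threshold(self):
        percents = {1: 0.10, 2: 0.11, 3: 0.0, 4: float("nan")}
        assert quant.detect_sites(percents) == [2]

    def test_all_zero_sample(self):
        assert quant.detect_sites({1: 0.0, 2: 0.0}) == []


class TestIsoforms:
    def _reads_for_patterns(self, design, spec):
        """Build (name, pos, seq) reads realizing {pattern: count}."""
        reads = []
        i = 0
        for pattern, count in spec.items():
            seq = list(design.reference)
            if pattern != "WT":
                for ch in pattern:
                    seq[design.site_positions[design.site_labels.index(ch)] - design.start] = "G"
            for _ in range(count):
                reads.append((f"r{i}", design.start, "".join(seq)))
                i += 1
        return reads

    def test_hand_tally(self, toy_design, tmp_path):
        reads = self._reads_for_patterns(toy_design, {"WT": 50, "A": 30, "AC": 20})
        sam = write_sam(tmp_path / "iso.sam", toy_design, reads)
        props, tally = quant.isoform_proportions(sam, toy_design)
        assert props == {"WT": 50.0, "A": 30.0, "AC": 20.0}
        assert tally.eligible == 100

    def test_marginal_consistency_with_site_percent(self, toy_design, tmp_path):
        reads = self._reads_for_patterns(toy_design, {"WT": 50, "A": 30, "AC": 20})
        sam = write_sam(tmp_path / "iso2.sam", toy_design, reads)
        counts = quant.pileup_counts(sam, toy_design)
        site_a = quant.editing_percent(counts[104])
        assert site_a == 50.0  # 30 (A) + 20 (AC) of 100 reads carry G at site A

    def test_single_site_design_equivalence(self, tmp_path):
        d = quant.AmpliconDesign(
            target_name="ONE", chrom="chr1", reference="CCAGGTCC", start=11,
            site_positions=(13,),
        )
        seq_wt, seq_ed = "CCAGGTCC", "CCGGGTCC"
        reads = [(f"w{i}", 11, seq_wt) for i in range(7)] + [
            (f"e{i}", 11, seq_ed) for i in range(3)
        ]
        sam = write_sam(tmp_path / "one.sam", d, reads)
        props, _ = quant.isoform_proportions(sam, d)
        pct = quant.editing_percent(quant.pileup_counts(sam, d)[13])
        assert props["A"] == pytest.approx(pct) and props["WT"] == pytest.approx(100 - pct)

    def test_proportions_sum_to_100_before_drop(self, toy_design, tmp_path):
        rng = np.random.default_rng(5)
        patterns = ["WT", "A", "B", "C", "AB", "AC", "BC", "ABC"]
        spec = {p: int(c) for p, c in zip(patterns, rng.integers(1, 50, len(patterns)))}
        sam = write_sam(
            tmp_path / "sum.sam", toy_design, self._reads_for_patterns(toy_design, spec)
        )
        props, _ = quant.isoform_proportions(sam, toy_design, min_proportion=0.0)
        assert sum(props.values()) == pytest.approx(100.0, abs=1e-6)

    def test_non_ag_read_excluded_and_tallied(self, toy_design, tmp_path):
        bad = list(toy_design.reference)
        bad[3] = "T"  # site A carries a T: ineligible
        reads = self._reads_for_patterns(toy_design, {"WT": 9}) + [
            ("bad", 101, "".join(bad))
        ]
        sam = write_sam(tmp_path / "bad.sam", toy_design, reads)
        props, tally = quant.isoform_proportions(sam, toy_design)
        assert tally.non_ag_base == 1 and tally.eligible == 9
        assert props["WT"] == 100.0

    def test_zero_site_design_is_error(self):
        with pytest.raises(ValueError):
            d = quant.AmpliconDesign(
                target_name="X", chrom="c", reference="CC", start=1, site_positions=()
            )
            quant.isoform_proportions([], d, parsed=True)


class TestAluEditingIndex:
    def test_hand_sum(self):
        table = pd.DataFrame(
            dict(in_alu=[True, True], a_reads=[90, 50], g_reads=[10, 50])
        )
        assert quant.alu_editing_index(table) == pytest.approx(30.0)

    def test_no_g_reads(self):
        table = pd.DataFrame(dict(in_alu=[True], a_reads=[100], g_reads=[0]))
        assert quant.alu_editing_index(table) == 0.0

    def test_non_alu_positions_ignored(self):
        table = pd.DataFrame(
            dict(in_alu=[True, True, False], a_reads=[90, 50, 0], g_reads=[10, 50, 100])
        )
        assert quant.alu_editing_index(table) == pytest.approx(30.0)

    def test_zero_alu_coverage_is_missing(self):
        table = pd.DataFrame(dict(in_alu=[False], a_reads=[10], g_reads=[10]))
        assert math.isnan(quant.alu_editing_index(table))

    def test_coverage_edited_columns_fallback(self):
        table = pd.DataFrame(dict(in_alu=[True, True], coverage=[100, 100], edited_reads=[10, 50]))
        assert quant.alu_editing_index(table) == pytest.approx(30.0)
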
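"""Tests for the synthetic cohort, site-table and read generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnaedit import quant, synthetic
from rnaedit.synthetic import CohortSpec, EffectSpec


class TestGenerateCohort:
    def test_validation_cohort_sizes(self):
        spec = CohortSpec(n_per_group={"CTRL": 143, "DEP": 267}, seed=0)
        samples = synthetic.generate_cohort(spec)
        assert len(samples) == 410
        assert sum(s.group == "CTRL" for s in samples) == 143
        assert sum(s.group == "DEP" for s in samples) == 267

    def test_determinism(self):
        spec = CohortSpec(n_per_group={"CTRL": 30, "UN": 20, "BD": 10}, n_batches=2, seed=7)
        f1 = synthetic.cohort_frame(synthetic.generate_cohort(spec))
        f2 = synthetic.cohort_frame(synthetic.generate_cohort(spec))
        pd.testing.assert_frame_equal(f1, f2)

    def test_ages_respect_inclusion_window(self):
        spec = CohortSpec(n_per_group={"CTRL": 200}, seed=3)
        ages = [s.age for s in synthetic.generate_cohort(spec)]
        assert min(ages) >= 18 and max(ages) <= 65

    def test_subtype_only_for_depressed(self):
        spec = CohortSpec(n_per_group={"CTRL": 10, "BD": 10}, seed=1)
        for s in synthetic.generate_cohort(spec):
            if s.group == "CTRL":
                assert s.subtype is None
            else:
                assert s.subtype == "BD"

    def test_age_difference_un_vs_bd_detectable(self):
        # UN mean 36.3 SD 13.4 (n=160) vs BD mean 44.3 SD 10.9 (n=95), ages
        # truncated to the 18-65 inclusion window. The generator's Welch
        # rejection rate at p < 0.001 over 100 seeds must match an
        # independent truncated-normal Monte-Carlo oracle.
        def trunc(rng, mean, sd, n):
            a, b = (18 - mean) / sd, (65 - mean) / sd
            return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

        oracle_rng = np.random.default_rng(12345)
        oracle_hits = sum(
            stats.ttest_ind(
                trunc(oracle_rng, 36.3, 13.4, 160),
                trunc(oracle_rng, 44.3, 10.9, 95),
                equal_var=False,
            ).pvalue
            < 0.001
            for _ in range(400)
        )
        oracle_rate = oracle_hits / 400

        hits = 0
        for seed in range(100):
            spec = CohortSpec(n_per_group={"UN": 160, "BD": 95}, seed=seed)
            samples = synthetic.generate_cohort(spec)
            un = [s.age for s in samples if s.subtype == "UN"]
            bd = [s.age for s in samples if s.subtype == "BD"]
            if stats.ttest_ind(un, bd, equal_var=False).pvalue < 0.001:
                hits += 1
        assert hits / 100 == pytest.approx(oracle_rate, abs=0.12)
        assert hits >= 70  # the age gap remains strongly detectable

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_group={"CTRL": 0})
        with pytest.raises(ValueError):
            CohortSpec(n_per_group={"XYZ": 5})
        with pytest.raises(ValueError):
            CohortSpec(n_per_group={"CTRL": 5}, sex_ratio={"CTRL": 1.5})

    def test_batch_assignment_balanced(self):
        spec = CohortSpec(n_per_group={"CTRL": 50, "DEP": 50}, n_batches=2, seed=0)
        frame = synthetic.cohort_frame(synthetic.generate_cohort(spec))
        counts = frame["batch"].value_counts()
        assert set(counts.index) == {"batch0", "batch1"} and counts.min() == 50


class TestSeverity:
    @pytest.mark.parametrize(
        "madrs,idsc30,expected",
        [
            (15, None, "low"),
            (36, None, "severe"),
            (10, 30, "moderate"),  # MADRS low band, IDS-C30 moderate: max wins
            (3, 5, "subthreshold"),
            (None, 40, "severe"),
            (20, 12, "moderate"),
        ],
    )
    def test_bands(self, madrs, idsc30, expected):
        assert synthetic.severity_class(madrs=madrs, idsc30=idsc30) == expected

    def test_requires_a_score(self):
        with pytest.raises(ValueError):
            synthetic.severity_class()
        with pytest.raises(ValueError):
            synthetic.severity_class(madrs=-1)


class TestSiteTable:
    def _cohort(self, n0, n1, n_batches=1, seed=0):
        return synthetic.generate_cohort(
            CohortSpec(n_per_group={"CTRL": n0, "DEP": n1}, n_batches=n_batches, seed=seed)
        )

    def test_null_effects_no_group_difference(self):
        cohort = self._cohort(60, 60)
        sites = [
            synthetic.EditingSite(chrom="chr1", pos=1000 + i, gene=f"G{i}")
            for i in range(200)
        ]
        table = synthetic.simulate_site_table(cohort, sites, [], coverage_mean=100, seed=1)
        meta = synthetic.cohort_frame(cohort).set_index("sample_id")
        merged = table.merge(meta[["group"]], left_on="sample_id", right_index=True)
        diffs = (
            merged.groupby(["chrom", "pos", "group"])["editing_pct"].mean().unstack()
        )
        mean_diff = (diffs["DEP"] - diffs["CTRL"]).mean()
        assert abs(mean_diff) < 0.5

    def test_planted_effect_converges_binomially(self):
        cohort = self._cohort(40, 40)
        site = synthetic.EditingSite(chrom="chr1", pos=500, gene="G")
        eff = EffectSpec(site_id="chr1:500", baseline_editing=17.0, delta=7.0)
        table = synthetic.simulate_site_table(
            cohort, [site], [eff], coverage_mean=5000, coverage_dispersion=1e6, seed=2
        )
        meta = synthetic.cohort_frame(cohort).set_index("sample_id")
        dep = table[table["sample_id"].map(meta["group"]) == "DEP"]["editing_pct"]
        se = np.sqrt(0.24 * 0.76 / 5000) * 100 / np.sqrt(len(dep))
        assert abs(dep.mean() - 24.0) < 3 * se + 0.05  # small slack for NB coverage

    def test_batch_shift_by_construction(self):
        cohort = self._cohort(60, 60, n_batches=2, seed=4)
        sites = [synthetic.EditingSite(chrom="chr1", pos=1000 + i, gene="G") for i in range(50)]
        table = synthetic.simulate_site_table(
            cohort, sites, [], coverage_mean=2000,
            batch_shift={"batch0": 2.0, "batch1": -2.0}, seed=3,
        )
        meta = synthetic.cohort_frame(cohort).set_index("sample_id")
        by_batch = table.groupby(table["sample_id"].map(meta["batch"]))["editing_pct"].mean()
        assert by_batch["batch0"] - by_batch["batch1"] == pytest.approx(4.0, abs=0.5)

    def test_unknown_effect_site_rejected(self):
        cohort = self._cohort(5, 5)
        with pytest.raises(ValueError, match="unknown site"):
            synthetic.simulate_site_table(
                cohort,
                [synthetic.EditingSite(chrom="chr1", pos=1, gene="G")],
                [EffectSpec(site_id="chr9:99", baseline_editing=10, delta=1)],
            )

    def test_clipping_warns(self):
        cohort = self._cohort(5, 5)
        site = synthetic.EditingSite(chrom="chr1", pos=1, gene="G")
        eff = EffectSpec(site_id="chr1:1", baseline_editing=97.0, delta=2.0)
        with pytest.warns(UserWarning, match="clipped"):
            synthetic.simulate_site_table(
                cohort, [site], [eff], batch_shift={"batch0": 5.0}, seed=0
            )

    def test_effect_spec_invariants(self):
        with pytest.raises(ValueError):
            EffectSpec(site_id="x", baseline_editing=0.0, delta=1.0)
        with pytest.raises(ValueError):
            EffectSpec(site_id="x", baseline_editing=95.0, delta=6.0)


class TestAmpliconReads:
    def test_unedited_distribution_quantifies_to_zero(self, tmp_path):
        design = synthetic.default_designs()["LYN"]
        sam = tmp_path / "lyn.sam"
        synthetic.simulate_amplicon_reads(
            design, {"WT": 1.0}, depth=500, seed=0, sam_path=str(sam)
        )
        counts = quant.pileup_counts(str(sam), design)
        for pos in design.site_positions:
            assert quant.editing_percent(counts[pos]) == 0.0

    def test_two_site_pattern_converges(self, tmp_path):
        design = synthetic.default_designs()["GAB2"]
        sam = tmp_path / "gab2.sam"
        synthetic.simulate_amplicon_reads(
            design, {"AB": 0.5, "WT": 0.5}, depth=20_000, seed=1, sam_path=str(sam)
        )
        counts = quant.pileup_counts(str(sam), design)
        se3 = 3 * np.sqrt(0.25 / 20_000) * 100
        for lab, pos in zip(design.site_labels, design.site_positions):
            pct = quant.editing_percent(counts[pos])
            if lab in "AB":
                assert abs(pct - 50.0) < se3
            else:
                assert pct == 0.0
        props, _ = quant.isoform_proportions(str(sam), design)
        assert abs(props["AB"] - 50.0) < se3

    def test_same_seed_byte_identical_fastq(self, tmp_path):
        design = synthetic.default_designs()["MDM2"]
        paths = [tmp_path / "a.fastq", tmp_path / "b.fastq"]
        for p in paths:
            synthetic.simulate_amplicon_reads(
                design, {"A": 0.3, "WT": 0.7}, depth=300, error_rate=0.01, seed=9,
                fastq_path=str(p),
            )
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_truth_table_matches_depth(self, tmp_path):
        design = synthetic.default_designs()["PRKCB"]
        truth = synthetic.simulate_amplicon_reads(design, {"WT": 1.0}, depth=123, seed=0)
        assert len(truth) == 123

    def test_invalid_inputs(self):
        design = synthetic.default_designs()["LYN"]
        with pytest.raises(ValueError, match="depth"):
            synthetic.simulate_amplicon_reads(design, {"WT": 1.0}, depth=0)
        with pytest.raises(ValueError, match="sum"):
            synthetic.simulate_amplicon_reads(design, {"WT": 0.5}, depth=10)
        with pytest.raises(ValueError, match="outside the design"):
            synthetic.simulate_amplicon_reads(design, {"Z": 1.0}, depth=10)
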
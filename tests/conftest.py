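"""Shared fixtures: toy amplicon designs, SAM builders and filter fixtures."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from rnaedit.quant import AmpliconDesign


@pytest.fixture
def toy_design() -> AmpliconDesign:
    """A 30-nt amplicon with three candidate A sites (labels A, B, C)."""
    #          0         1         2
    #          0123456789012345678901234567890
    reference = "CCTAGGTCAGTCCATGGTCCGATCCGGTCC"
    # A sites at offsets 3, 13, 21 -> genomic 104, 114, 122
    return AmpliconDesign(
        target_name="TOY",
        chrom="chrT",
        reference=reference,
        start=101,
        site_positions=(104, 114, 122),
    )


def write_sam(path, design: AmpliconDesign, reads: list[tuple[str, int, str]]) -> str:
    """Write a minimal SAM file of (name, 1-based genomic pos, sequence)."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{design.chrom}\tLN:{design.end + 1000}",
    ]
    for name, pos, seq in reads:
        qual = "I" * len(seq)
        lines.append(
            f"{name}\t0\t{design.chrom}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}"
        )
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


@pytest.fixture
def stringent_fixture() -> tuple[pd.DataFrame, set[str], dict[str, str]]:
    """Ten hand-constructed candidate sites: seven fail exactly one stringent
    criterion each (including the SNP-proximity case) and three pass all.

    Returns (stats table, expected survivor ids, expected first failure per
    removed site).
    """
    base = dict(
        region="intron",
        snp_dist=1000.0,
        fraction_of_samples=0.5,
        mean_coverage=60.0,
        median_coverage=60.0,
        fold_change=1.5,
        p_value=0.01,
        auc=0.8,
    )
    rows = {}
    rows["s0"] = {**base, "region": "intergenic"}
    rows["s1"] = {**base, "snp_dist": 50.0}
    rows["s2"] = {**base, "fraction_of_samples": 0.10}
    rows["s3"] = {**base, "mean_coverage": 20.0, "median_coverage": 25.0}
    rows["s4"] = {**base, "fold_change": 1.0}
    rows["s5"] = {**base, "p_value": 0.20}
    rows["s6"] = {**base, "auc": 0.65}
    rows["s7"] = dict(base)
    rows["s8"] = {**base, "fold_change": 0.7}  # passes on the low side
    rows["s9"] = {**base, "p_value": 0.049, "auc": 0.71}
    stats = pd.DataFrame.from_dict(rows, orient="index")
    expected_survivors = {"s7", "s8", "s9"}
    expected_first = {
        "s0": "intergenic",
        "s1": "near_snp",
        "s2": "sample_fraction",
        "s3": "coverage",
        "s4": "fold_change",
        "s5": "p_value",
        "s6": "auc",
    }
    return stats, expected_survivors, expected_first


def enumeration_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Independent O(n^2) pair-enumeration AUC oracle."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
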
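"""Biomarker discovery filtering on editome site tables.

Two filter tiers are implemented, with full provenance of which rule
removed which call:

* high-confidence call filters — per-call quality thresholds applied to
  discovery RNA-Seq editing calls (base quality, mapping quality, coverage,
  edited-read support, editing degree, removal of 100%-edited positions
  that are likely genomic SNVs, and a per-site group-comparison p value);
* stringent biomarker criteria — six site-level inclusion rules combining
  annotation (non-intergenic, SNP-free neighbourhood), prevalence,
  coverage, a two-sided fold-change band, significance and discriminative
  power (ROC AUC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import differential

__all__ = [
    "EditingSite",
    "ConfidenceCriteria",
    "StringentCriteria",
    "apply_confidence_filters",
    "apply_stringent_criteria",
    "volcano_table",
    "site_statistics",
]

REGIONS = ("intron", "3UTR", "5UTR", "exonic", "intergenic", "other")


@dataclass(frozen=True)
class EditingSite:
    """A genomic A position with its discovery annotation (GRCh38, 1-based)."""

    chrom: str
    pos: int
    gene: str
    ensembl_id: str = ""
    region: str = "intron"
    in_alu: bool = False
    snp_dist: float = math.inf  # bp to nearest known SNP; inf if none supplied

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in {REGIONS}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class ConfidenceCriteria:
    """High-confidence editing-call thresholds (discovery tier)."""

    min_base_quality: float = 25.0
    min_mapq: float = 20.0
    min_coverage: float = 30.0
    min_edited_reads: int = 2
    min_editing_degree: float = 10.0  # percent, in at least one group
    drop_full_editing: bool = True
    wilcoxon_alpha: float = 0.05


@dataclass
class StringentCriteria:
    """The six site-level biomarker inclusion rules (i)-(vi)."""

    exclude_intergenic: bool = True
    snp_exclusion_radius: float = 100.0  # bp
    min_sample_fraction: float = 0.25
    min_coverage: float = 30.0  # median OR mean
    fc_low: float = 0.8
    fc_high: float = 1.20
    alpha: float = 0.05
    min_auc: float = 0.7

    def __post_init__(self) -> None:
        if not (self.fc_low < 1 < self.fc_high):
            raise ValueError("fold-change band must straddle 1")


# ordered rule names, used for first-failing attribution
_CONFIDENCE_ORDER = (
    "base_quality",
    "mapping_quality",
    "coverage",
    "edited_reads",
    "editing_degree",
    "full_editing",
    "wilcoxon_p",
)

_STRINGENT_ORDER = (
    "intergenic",
    "near_snp",
    "sample_fraction",
    "coverage",
    "fold_change",
    "p_value",
    "auc",
)


def apply_confidence_filters(
    calls: pd.DataFrame, criteria: ConfidenceCriteria | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the high-confidence call filters.

    ``calls`` must carry columns ``base_quality``, ``mapping_quality``,
    ``coverage``, ``edited_reads`` and ``editing_degree`` (percent); a
    ``p_value`` column activates the group-comparison rule. A call survives
    iff it passes every rule; removal counts partition the removed calls by
    the FIRST failing rule in the listed order, so counts plus survivors
    always sum to the input size.
    """
    criteria = criteria or ConfidenceCriteria()
    required = [
        "base_quality",
        "mapping_quality",
        "coverage",
        "edited_reads",
        "editing_degree",
    ]
    for col in required:
        if col not in calls.columns:
            raise ValueError(f"calls table missing required column {col!r}")
    c = criteria
    fails = {
        "base_quality": calls["base_quality"] <= c.min_base_quality,
        "mapping_quality": calls["mapping_quality"] <= c.min_mapq,
        "coverage": _coverage_fail(calls, c.min_coverage),
        "edited_reads": calls["edited_reads"] < c.min_edited_reads,
        "editing_degree": _degree_fail(calls, c.min_editing_degree),
        "full_editing": (
            calls["editing_degree"] >= 100.0
            if c.drop_full_editing
            else pd.Series(False, index=calls.index)
        ),
        "wilcoxon_p": (
            calls["p_value"] >= c.wilcoxon_alpha
            if "p_value" in calls.columns
            else pd.Series(False, index=calls.index)
        ),
    }
    return _partition(calls, fails, _CONFIDENCE_ORDER)


def _coverage_fail(calls: pd.DataFrame, threshold: float) -> pd.Series:
    # mean/median coverage: pass if either summary clears the bar
    mean_cov = calls.get("mean_coverage", calls["coverage"])
    median_cov = calls.get("median_coverage", calls["coverage"])
    return ~((mean_cov > threshold) | (median_cov > threshold))


def _degree_fail(calls: pd.DataFrame, threshold: float) -> pd.Series:
    # per-site editing degree >= threshold in at least one group; with a
    # single degree column the rule reduces to that column
    cols = [c for c in calls.columns if c.startswith("editing_degree")]
    best = calls[cols].max(axis=1)
    return best < threshold


def apply_stringent_criteria(
    stats: pd.DataFrame, criteria: StringentCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the six stringent biomarker criteria to per-site statistics.

    ``stats`` carries one row per candidate site with columns ``region``,
    ``snp_dist``, ``fraction_of_samples``, ``mean_coverage`` and/or
    ``median_coverage``, ``fold_change``, ``p_value``, ``auc``.

    A site survives iff it is not intergenic, lies more than the SNP
    exclusion radius from any known SNP, is detected in at least the
    required fraction of samples, has median or mean coverage at the
    threshold, falls outside the null fold-change band (FC <= 0.8 or
    FC >= 1.20), is significant (p < alpha) and discriminative
    (AUC strictly > 0.7).

    Returns (survivors, provenance); the provenance table lists EVERY
    failed criterion per removed site plus the first failure for ordered
    attribution.
    """
    criteria = criteria or StringentCriteria()
    c = criteria
    mean_cov = stats.get("mean_coverage", stats.get("coverage"))
    median_cov = stats.get("median_coverage", stats.get("coverage"))
    if mean_cov is None and median_cov is None:
        raise ValueError("stats table carries no coverage column")
    fails = {
        "intergenic": (
            (stats["region"] == "intergenic")
            if c.exclude_intergenic
            else pd.Series(False, index=stats.index)
        ),
        "near_snp": stats["snp_dist"] <= c.snp_exclusion_radius,
        "sample_fraction": stats["fraction_of_samples"] < c.min_sample_fraction,
        "coverage": ~(
            (pd.Series(median_cov) >= c.min_coverage)
            | (pd.Series(mean_cov) >= c.min_coverage)
        ),
        "fold_change": ~(
            (stats["fold_change"] <= c.fc_low) | (stats["fold_change"] >= c.fc_high)
        ),
        "p_value": stats["p_value"] >= c.alpha,
        "auc": stats["auc"] <= c.min_auc,
    }
    survivors, counts = _partition(stats, fails, _STRINGENT_ORDER)
    removed_idx = stats.index.difference(survivors.index)
    prov_rows = []
    for idx in removed_idx:
        failed = [name for name in _STRINGENT_ORDER if bool(fails[name].loc[idx])]
        prov_rows.append(
            dict(site=idx, failed_criteria=";".join(failed), first_failure=failed[0])
        )
    provenance = pd.DataFrame(
        prov_rows, columns=["site", "failed_criteria", "first_failure"]
    )
    return survivors, provenance


def _partition(table, fails, order):
    any_fail = pd.Series(False, index=table.index)
    remaining = pd.Series(True, index=table.index)
    counts: dict[str, int] = {}
    for name in order:
        f = fails[name].fillna(True).astype(bool)
        first = f & remaining
        counts[name] = int(first.sum())
        remaining &= ~f
        any_fail |= f
    return table[~any_fail].copy(), counts


def volcano_table(stats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready table of log2 fold change vs -log10 p with flags."""
    if len(stats) == 0:
        return pd.DataFrame(
            columns=["log2_fold_change", "neg_log10_p", "significant", "plottable"]
        )
    fc = stats["fold_change"].to_numpy(dtype=float)
    p = stats["p_value"].to_numpy(dtype=float)
    plottable = (fc > 0) & ~np.isnan(fc) & ~np.isnan(p)
    out = pd.DataFrame(index=stats.index)
    out["log2_fold_change"] = np.where(plottable, np.log2(np.where(fc > 0, fc, 1.0)), np.nan)
    out["neg_log10_p"] = np.where(plottable, -np.log10(p), np.nan)
    out["significant"] = plottable & (p < alpha)
    out["plottable"] = plottable
    return out


def site_statistics(
    site_table: pd.DataFrame,
    metadata: pd.DataFrame,
    reference: str,
    affected: str,
    detect_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-site discovery statistics from a long-format editome table.

    ``site_table`` is the per-sample x per-site table (columns
    ``sample_id``, ``chrom``, ``pos``, ``gene``, ``region``, ``in_alu``,
    ``snp_dist``, ``coverage``, ``edited_reads``, ``editing_pct``);
    ``metadata`` maps ``sample_id`` to ``group``. Editing percentages per
    group are compared with the data-driven test of the differential
    module; fold changes are oriented affected over reference.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    groups = meta["group"]
    rows = []
    for (chrom, pos), sub in site_table.groupby(["chrom", "pos"], sort=True):
        sub = sub.set_index("sample_id")
        g = groups.reindex(sub.index)
        x = sub.loc[(g == reference).to_numpy(), "editing_pct"].to_numpy(dtype=float)
        y = sub.loc[(g == affected).to_numpy(), "editing_pct"].to_numpy(dtype=float)
        n_detect = int((sub["editing_pct"] > detect_threshold).sum())
        test = differential.select_test(x, y)
        p = differential.diff_test(x, y, test)
        fc, fm = differential.fold_changes(x, y)
        scores = np.concatenate([x, y])
        labels = np.concatenate([np.zeros(len(x)), np.ones(len(y))])
        auc = differential.empirical_auc(scores, labels)
        first = sub.iloc[0]
        rows.append(
            dict(
                site_id=f"{chrom}:{pos}",
                chrom=chrom,
                pos=pos,
                gene=first["gene"],
                region=first["region"],
                in_alu=bool(first["in_alu"]),
                snp_dist=float(first["snp_dist"]),
                n_samples_detected=n_detect,
                fraction_of_samples=n_detect / len(sub),
                mean_coverage=float(sub["coverage"].mean()),
                median_coverage=float(sub["coverage"].median()),
                mean_reference=float(np.nanmean(x)) if len(x) else np.nan,
                mean_affected=float(np.nanmean(y)) if len(y) else np.nan,
                fold_change=fc,
                fold_median=fm,
                test_used=test,
                p_value=p,
                auc=auc,
            )
        )
    out = pd.DataFrame(rows).set_index("site_id")
    return out
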
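"""Pipeline orchestration: simulate -> quantify -> discover -> diffstats ->
tei -> classify -> report.

Each stage is a plain function over DataFrames so it can run standalone
from prior outputs; :func:`run_pipeline` chains them under a single
validated configuration and seed and emits a machine-readable run report.
All tabular outputs are tab-separated; the report is JSON without
timestamps so identical config + seed reproduce it byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, differential, discovery, quant, synthetic, tei

logger = logging.getLogger("rnaedit")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "write_report",
    "site_table_to_matrix",
    "synthetic_benchmark",
]

CONTRASTS = {
    "CTRL-vs-DEP": ("CTRL", "DEP", "group"),
    "UN-vs-BD": ("UN", "BD", "subtype"),
}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    outdir: str = "rnaedit_out"
    seed: int = 0
    contrast: str = "CTRL-vs-DEP"
    # simulation block (used when no site_table/metadata paths are given)
    n_per_group: dict = field(
        default_factory=lambda: {"CTRL": 60, "UN": 40, "BD": 20}
    )
    n_batches: int = 2
    batch_shift: tuple = (2.0, -2.0)
    coverage_mean: float = 1000.0
    coverage_dispersion: float = 10.0
    effects: list = field(default_factory=list)  # dicts -> EffectSpec
    # input paths (optional; override simulation)
    site_table_path: str | None = None
    metadata_path: str | None = None
    # criteria / model settings
    confidence: discovery.ConfidenceCriteria = field(
        default_factory=discovery.ConfidenceCriteria
    )
    stringent: discovery.StringentCriteria = field(
        default_factory=discovery.StringentCriteria
    )
    multds: classify.MultDSConfig = field(default_factory=classify.MultDSConfig)
    alpha: float = 0.05
    include_tei_features: bool = True

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(
                f"unknown contrast {self.contrast!r}; options: {sorted(CONTRASTS)}"
            )
        if isinstance(self.confidence, dict):
            self.confidence = discovery.ConfidenceCriteria(**self.confidence)
        if isinstance(self.stringent, dict):
            self.stringent = discovery.StringentCriteria(**self.stringent)
        if isinstance(self.multds, dict):
            self.multds = classify.MultDSConfig(**self.multds)
        self.batch_shift = tuple(float(x) for x in self.batch_shift)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return _jsonable(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**dict(d))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


# ---------------------------------------------------------------------------
# stage helpers


def site_table_to_matrix(site_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long site table into a samples x biomarkers percent matrix.

    Editing percentages are recomputed from the read counts through the
    G/(G+A) formula (A-supporting reads = coverage - edited reads), so the
    matrix is consistent with the quantification chain regardless of what
    the ``editing_pct`` column claims.
    """
    t = site_table.copy()
    pct = []
    for a, g in zip(t["coverage"] - t["edited_reads"], t["edited_reads"]):
        pct.append(quant.editing_percent(quant.NucleotideCounts(a=int(a), g=int(g))))
    t["pct"] = pct
    t["biomarker_id"] = (
        t["gene"].astype(str) + ":" + t["chrom"].astype(str) + ":" + t["pos"].astype(str)
    )
    return t.pivot_table(index="sample_id", columns="biomarker_id", values="pct")


def _contrast_labels(meta: pd.DataFrame, contrast: str) -> pd.Series:
    ref, aff, col = CONTRASTS[contrast]
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    lab = m[col].astype(str)
    keep = lab.isin([ref, aff])
    return lab[keep]


def _covariate_frame(meta: pd.DataFrame) -> pd.DataFrame:
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    cov = pd.DataFrame(index=m.index)
    cov["age"] = m["age"].astype(float)
    cov["sex_female"] = (m["sex"] == "F").astype(float)
    for c in m.columns:
        if c.startswith("treat_") or c.startswith("addiction_"):
            col = m[c].astype(float)
            if col.nunique() > 1:  # constant indicators carry no information
                cov[c] = col
    return cov


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages end to end; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(config.to_dict()), "stages": {}}

    # -- simulate / load ---------------------------------------------------
    if config.site_table_path and config.metadata_path:
        site_table = pd.read_csv(config.site_table_path, sep="\t", comment="#")
        meta = pd.read_csv(config.metadata_path, sep="\t", comment="#")
        report["stages"]["load"] = {
            "site_table": config.site_table_path,
            "metadata": config.metadata_path,
            "n_samples": int(meta.shape[0]),
        }
    else:
        spec = synthetic.CohortSpec(
            n_per_group=dict(config.n_per_group),
            n_batches=config.n_batches,
            batch_shift=config.batch_shift,
            seed=config.seed,
        )
        cohort = synthetic.generate_cohort(spec)
        meta = synthetic.cohort_frame(cohort)
        sites = synthetic.default_sites()
        effects = [synthetic.EffectSpec(**e) for e in config.effects]
        shift = {f"batch{i}": s for i, s in enumerate(config.batch_shift)}
        site_table = synthetic.simulate_site_table(
            cohort,
            sites,
            effects,
            coverage_mean=config.coverage_mean,
            coverage_dispersion=config.coverage_dispersion,
            batch_shift=shift,
            seed=config.seed + 1,
        )
        meta.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
        site_table.to_csv(outdir / "site_table.tsv", sep="\t", index=False)
        report["stages"]["simulate"] = {
            "n_samples": len(cohort),
            "n_sites": len(sites),
            "n_effects": len(effects),
            "seed": config.seed,
        }

    ref, aff, _col = CONTRASTS[config.contrast]
    labels = _contrast_labels(meta, config.contrast)
    if labels.nunique() < 2:
        raise ValueError(f"contrast {config.contrast} groups missing from metadata")

    # -- quantify ----------------------------------------------------------
    matrix = site_table_to_matrix(site_table).loc[lambda d: d.index.isin(labels.index)]
    report["stages"]["quantify"] = {
        "n_samples": int(matrix.shape[0]),
        "n_biomarkers": int(matrix.shape[1]),
    }

    # -- discover (site-level statistics + stringent provenance) -----------
    meta_idx = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    contrast_meta = pd.DataFrame(
        {"sample_id": labels.index, "group": labels.to_numpy()}
    )
    stats = discovery.site_statistics(
        site_table[site_table["sample_id"].isin(labels.index)],
        contrast_meta,
        reference=ref,
        affected=aff,
    )
    survivors, provenance = discovery.apply_stringent_criteria(stats, config.stringent)
    volcano = discovery.volcano_table(stats, alpha=config.alpha)
    stats.to_csv(outdir / "site_stats.tsv", sep="\t")
    survivors.to_csv(outdir / "stringent_survivors.tsv", sep="\t")
    provenance.to_csv(outdir / "stringent_provenance.tsv", sep="\t", index=False)
    volcano.to_csv(outdir / "volcano.tsv", sep="\t")
    report["stages"]["discover"] = {
        "n_candidates": int(stats.shape[0]),
        "n_stringent_survivors": int(survivors.shape[0]),
        "n_removed": int(provenance.shape[0]),
    }

    # -- diffstats (batch/covariate adjustment + differential table) -------
    batches = meta_idx.loc[matrix.index, "batch"]
    covariates = _covariate_frame(meta_idx.loc[matrix.index])
    if batches.nunique() > 1:
        adjusted = differential.batch_adjust(
            matrix, batches, covariates=covariates, group=labels.loc[matrix.index]
        )
    else:
        adjusted = matrix.copy()
    diff = differential.differential_analysis(
        adjusted, labels, reference=ref, affected=aff
    )
    diff.to_csv(outdir / "differential.tsv", sep="\t")
    n_sig = int((diff["p_value"] < config.alpha).sum())
    report["stages"]["diffstats"] = {
        "n_biomarkers": int(diff.shape[0]),
        "n_significant": n_sig,
        "alpha": config.alpha,
    }

    # -- tei ---------------------------------------------------------------
    # biomarker selection is done on the training split only, so held-out
    # performance is not inflated by selection leakage
    y = (labels.loc[matrix.index] == aff).astype(int)
    train_ids, test_ids = classify.split_train_test(
        labels.loc[matrix.index], config.multds.train_fraction, seed=config.multds.seed
    )
    diff_train = differential.differential_analysis(
        adjusted.loc[train_ids], labels.loc[train_ids], reference=ref, affected=aff
    )
    sig_ids = list(diff_train.index[diff_train["p_value"] < config.alpha])
    if not sig_ids:
        logger.warning("no significant biomarkers; falling back to all biomarkers")
        sig_ids = list(diff_train.index)
    genes = sorted({b.split(":")[0] for b in sig_ids})
    tei_models = {}
    tei_cols = {}
    for gene in genes:
        cols = [b for b in sig_ids if b.split(":")[0] == gene]
        sub = adjusted.loc[train_ids, cols].dropna(axis=1, how="any")
        if sub.shape[1] == 0 or sub.std().max() == 0:
            continue
        model = tei.fit_tei(sub, y.loc[train_ids].to_numpy(), gene=gene)
        tei_models[gene] = model
        tei_cols[f"TEI_{gene}"] = tei.apply_tei(model, adjusted[list(model.biomarker_ids)])
    tei_frame = pd.DataFrame(tei_cols, index=adjusted.index)
    if tei_models:
        tei_sig = tei.tei_significance(
            tei_frame.loc[test_ids], y.loc[test_ids].to_numpy(), alpha=config.alpha
        )
        tei_sig.to_csv(outdir / "tei_significance.tsv", sep="\t")
        with open(outdir / "tei_models.json", "w") as fh:
            json.dump({g: m.to_dict() for g, m in tei_models.items()}, fh, indent=2)
    report["stages"]["tei"] = {
        "n_genes": len(tei_models),
        "n_significant_biomarkers_used": len(sig_ids),
    }

    # -- classify ----------------------------------------------------------
    features = adjusted[sig_ids].copy()
    if config.include_tei_features and not tei_frame.empty:
        features = pd.concat([features, tei_frame], axis=1)
    features = features.dropna(axis=1, how="any")
    cfg = config.multds
    model = classify.fit_ensemble(features, labels.loc[matrix.index], cfg)
    perf, roc = classify.evaluate(
        model, features.loc[list(model.test_ids)], labels.loc[list(model.test_ids)]
    )
    roc.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    report["stages"]["classify"] = {
        "n_models": cfg.n_models,
        "n_features": int(features.shape[1]),
        "n_train": len(model.train_ids),
        "n_test": len(model.test_ids),
        "chosen_mtry": [int(m) for m in model.chosen_mtry],
    }
    report["performance"] = {
        "contrast": config.contrast,
        "auc": perf.auc,
        "ci_low": perf.ci_low,
        "ci_high": perf.ci_high,
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "threshold": perf.threshold,
        "summary": perf.summary(),
    }
    write_report(report, outdir)
    return report


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write the JSON report plus a human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    lines = ["rnaedit run report", "=" * 30]
    for stage, rec in report.get("stages", {}).items():
        lines.append(f"[{stage}] " + ", ".join(f"{k}={v}" for k, v in rec.items()))
    if "performance" in report:
        lines.append(report["performance"]["summary"])
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# end-to-end synthetic benchmark


def synthetic_benchmark(
    seed: int,
    with_effects: bool = True,
    n_per_group: dict | None = None,
    outdir: str | None = None,
    multds: classify.MultDSConfig | None = None,
) -> dict:
    """One end-to-end recovery run on the planted-effect synthetic cohort.

    Cohort: two groups (CTRL/DEP) with batch structure; eight target genes
    with two biomarkers each; three genes carry planted effects of 0.8
    observed-SD on both their biomarkers when ``with_effects`` is set.
    Returns the run report of :func:`run_pipeline` (heldout AUC under
    ``performance.auc``).
    """
    n_per_group = n_per_group or {"CTRL": 100, "DEP": 100}
    coverage_mean = 1000.0
    batch_shift = (2.0, -2.0)
    # observed per-group SD of a biomarker under these conditions: binomial
    # noise at the baseline rate plus the between-batch shift variance
    baseline = 18.0
    binom_sd = float(np.sqrt(baseline / 100 * (1 - baseline / 100) / coverage_mean) * 100)
    batch_sd = float(np.std(batch_shift))
    obs_sd = float(np.hypot(binom_sd, batch_sd))
    delta = 0.8 * obs_sd
    sites = synthetic.default_sites()
    effects = []
    if with_effects:
        affected_genes = {"GAB2", "IFNAR1", "PRKCB"}
        for s in sites:
            if s.gene in affected_genes:
                effects.append(
                    dict(
                        site_id=s.site_id,
                        baseline_editing=baseline,
                        delta=delta,
                        affected_contrast="CTRL-vs-DEP",
                    )
                )
    cfg = PipelineConfig(
        outdir=outdir or f"scratch/benchmark_seed{seed}",
        seed=seed,
        contrast="CTRL-vs-DEP",
        n_per_group=n_per_group,
        n_batches=2,
        batch_shift=batch_shift,
        coverage_mean=coverage_mean,
        effects=effects,
        multds=multds
        or classify.MultDSConfig(
            n_models=8, ntree=100, nodesize=25, mtry_grid=(2, 4), cv_folds=5, seed=seed,
            positive_label="DEP",
        ),
    )
    cfg.multds.positive_label = "DEP"
    return run_pipeline(cfg)
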
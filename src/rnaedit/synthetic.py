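"""Synthetic cohorts, editome tables and amplicon reads with known truth.

The clinical data behind the blood RNA-editing biomarker studies are not
publicly deposited, so every downstream stage of this package is exercised
on synthetic inputs with planted ground truth. The generator emulates the
structure of a two-step depression study:

* a cohort of healthy controls (CTRL) and depressed patients (DEP), the
  latter subtyped unipolar (UN) / bipolar (BD) / uncertain, with per-group
  age distributions, sex ratios, BMI, clinician severity scores (MADRS,
  IDS-C30, YMRS), five psychotropic-treatment classes and addiction flags;
* an editome-level site table (per sample x site coverage, edited reads,
  editing percent, annotation) with planted group effects and additive
  batch shifts;
* targeted-amplicon reads (FASTQ + SAM) drawn from a known edited-isoform
  distribution, with a truth table of per-read pattern assignments.

Default parameter values mirror the published validation-cohort structure
(143 CTRL / 267 DEP; 160 UN / 95 BD / 12 uncertain; older BD patients;
antipsychotic/antiepileptic skew toward BD). Per-site patient-level
variation is modelled as binomial sampling around the group editing rate
— an explicit assumption, not an inference from any clinical dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

from .discovery import EditingSite
from .quant import AmpliconDesign

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SampleMeta",
    "GROUP_PARAMS",
    "generate_cohort",
    "cohort_frame",
    "severity_class",
    "simulate_site_table",
    "simulate_amplicon_reads",
    "default_designs",
    "default_sites",
    "validation_cohort_spec",
]

TREATMENT_CLASSES = (
    "anxiolytics",
    "hypnotics_sedatives",
    "antidepressants",
    "antipsychotics",
    "antiepileptics",
)
ADDICTIONS = ("tobacco", "alcohol", "other_substances")

# Per-group generator parameters emulating the published validation-cohort
# demographics: age mean/SD (years), fraction female, BMI mean/SD (kg/m2),
# clinician score means/SDs and treatment/addiction prevalences.
GROUP_PARAMS: dict[str, dict] = {
    "CTRL": dict(
        age=(39.4, 14.1), female=0.629, bmi=(24.6, 4.8),
        madrs=(0.8, 1.2), idsc30=(2.0, 2.4), ymrs=(0.0, 0.5),
        treatments=dict(zip(TREATMENT_CLASSES, (0.0, 0.0, 0.0, 0.0, 0.0))),
        addictions=dict(zip(ADDICTIONS, (0.182, 0.0, 0.0))),
    ),
    "UN": dict(
        age=(36.3, 13.4), female=0.688, bmi=(23.1, 5.1),
        madrs=(30.7, 7.6), idsc30=(37.4, 8.9), ymrs=(1.4, 2.7),
        treatments=dict(zip(TREATMENT_CLASSES, (0.688, 0.138, 0.731, 0.356, 0.106))),
        addictions=dict(zip(ADDICTIONS, (0.488, 0.15, 0.156))),
    ),
    "BD": dict(
        age=(44.3, 10.9), female=0.726, bmi=(24.9, 4.9),
        madrs=(28.2, 6.8), idsc30=(35.3, 7.8), ymrs=(2.7, 4.4),
        treatments=dict(zip(TREATMENT_CLASSES, (0.632, 0.189, 0.495, 0.642, 0.432))),
        addictions=dict(zip(ADDICTIONS, (0.526, 0.084, 0.116))),
    ),
    "UNCERTAIN": dict(
        age=(38.5, 11.8), female=0.667, bmi=(24.0, 5.0),
        madrs=(29.8, 5.5), idsc30=(34.8, 6.9), ymrs=(2.0, 3.5),
        treatments=dict(zip(TREATMENT_CLASSES, (0.917, 0.25, 0.833, 0.417, 0.083))),
        addictions=dict(zip(ADDICTIONS, (0.583, 0.167, 0.333))),
    ),
    # plain DEP (unsubtyped) falls back to the pooled depressed profile
    "DEP": dict(
        age=(39.3, 13.0), female=0.700, bmi=(23.8, 5.0),
        madrs=(29.7, 8.2), idsc30=(36.6, 8.2), ymrs=(1.8, 3.3),
        treatments=dict(zip(TREATMENT_CLASSES, (0.678, 0.161, 0.652, 0.461, 0.221))),
        addictions=dict(zip(ADDICTIONS, (0.506, 0.127, 0.15))),
    ),
}

_SUBTYPES = {"UN", "BD", "UNCERTAIN"}


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``n_per_group`` maps group labels (CTRL, DEP, or the DEP subtypes UN /
    BD / UNCERTAIN) to sample counts. Remaining fields override the
    published-structure defaults in :data:`GROUP_PARAMS`.
    """

    n_per_group: dict[str, int]
    age_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    sex_ratio: dict[str, float] = field(default_factory=dict)
    n_batches: int = 1
    batch_shift: tuple[float, ...] = ()  # percentage points, one per batch
    treatment_prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUP_PARAMS:
                raise ValueError(f"unknown group label {g!r}")
            if n <= 0:
                raise ValueError(f"group {g} count must be > 0, got {n}")
        for g, f in self.sex_ratio.items():
            if not 0 <= f <= 1:
                raise ValueError(f"sex ratio for {g} outside [0,1]: {f}")
        for g, tp in self.treatment_prevalence.items():
            if set(tp) - set(TREATMENT_CLASSES):
                raise ValueError(
                    f"unknown treatment classes for {g}: {set(tp) - set(TREATMENT_CLASSES)}"
                )
            for cls, f in tp.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"prevalence outside [0,1]: {g}/{cls}={f}")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.batch_shift and len(self.batch_shift) != self.n_batches:
            raise ValueError("batch_shift must have one entry per batch")


@dataclass(frozen=True)
class EffectSpec:
    """A planted differential-editing effect at one site.

    ``delta`` is the signed group difference in percentage points applied
    to the affected group of the named contrast (DEP for CTRL-vs-DEP,
    BD for UN-vs-BD).
    """

    site_id: str
    baseline_editing: float  # percent, in (0, 100)
    delta: float  # percentage points, signed
    affected_contrast: str = "CTRL-vs-DEP"

    def __post_init__(self) -> None:
        if not 0 < self.baseline_editing < 100:
            raise ValueError("baseline_editing must lie in (0, 100)")
        if not 0 < self.baseline_editing + self.delta < 100:
            raise ValueError("baseline + delta must stay in (0, 100)")
        if self.affected_contrast not in ("CTRL-vs-DEP", "UN-vs-BD"):
            raise ValueError(f"unknown contrast {self.affected_contrast!r}")


@dataclass
class SampleMeta:
    """One synthetic participant."""

    sample_id: str
    group: str  # CTRL or DEP
    subtype: str | None  # UN / BD / UNCERTAIN for DEP, else None
    age: float
    sex: str  # 'F' / 'M'
    bmi: float
    batch: str
    treatments: dict[str, bool]
    addictions: dict[str, bool]
    madrs: int
    idsc30: int
    ymrs: int


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.normal(mean, sd, size=need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def generate_cohort(spec: CohortSpec) -> list[SampleMeta]:
    """Draw a cohort deterministically from ``spec``.

    Group sizes are exact; ages come from per-group normals truncated to
    the study's 18-65 year inclusion window; sex, treatments and
    addictions are Bernoulli at the per-group prevalences; clinician
    scores are rounded truncated normals (>= 0). Batch labels are assigned
    by a random permutation balanced across batches.
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[SampleMeta] = []
    i = 0
    for glabel in sorted(spec.n_per_group):
        n = spec.n_per_group[glabel]
        params = GROUP_PARAMS[glabel]
        age_mean, age_sd = spec.age_params.get(glabel, params["age"])
        female = spec.sex_ratio.get(glabel, params["female"])
        treat = {**params["treatments"], **spec.treatment_prevalence.get(glabel, {})}
        ages = _truncated_normal(rng, age_mean, age_sd, 18, 65, n)
        sexes = rng.random(n) < female
        bmi = _truncated_normal(rng, *params["bmi"], 15, 45, n)
        madrs = np.clip(np.rint(rng.normal(*params["madrs"], n)), 0, 60).astype(int)
        idsc = np.clip(np.rint(rng.normal(*params["idsc30"], n)), 0, 84).astype(int)
        ymrs = np.clip(np.rint(rng.normal(*params["ymrs"], n)), 0, 60).astype(int)
        tdraw = {cls: rng.random(n) < p for cls, p in treat.items()}
        adraw = {a: rng.random(n) < p for a, p in params["addictions"].items()}
        group = "CTRL" if glabel == "CTRL" else "DEP"
        subtype = glabel if glabel in _SUBTYPES else None
        for j in range(n):
            samples.append(
                SampleMeta(
                    sample_id=f"S{i:04d}",
                    group=group,
                    subtype=subtype,
                    age=float(ages[j]),
                    sex="F" if sexes[j] else "M",
                    bmi=float(bmi[j]),
                    batch="",
                    treatments={cls: bool(v[j]) for cls, v in tdraw.items()},
                    addictions={a: bool(v[j]) for a, v in adraw.items()},
                    madrs=int(madrs[j]),
                    idsc30=int(idsc[j]),
                    ymrs=int(ymrs[j]),
                )
            )
            i += 1
    batches = np.array(
        [f"batch{k % spec.n_batches}" for k in range(len(samples))]
    )
    rng.shuffle(batches)
    for s, b in zip(samples, batches):
        s.batch = str(b)
    return samples


def cohort_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    """Flatten a cohort into the metadata table consumed by the pipeline."""
    rows = []
    for s in samples:
        row = dict(
            sample_id=s.sample_id, group=s.group, subtype=s.subtype or "",
            age=s.age, sex=s.sex, bmi=s.bmi, batch=s.batch,
            madrs=s.madrs, idsc30=s.idsc30, ymrs=s.ymrs,
        )
        row.update({f"treat_{k}": int(v) for k, v in s.treatments.items()})
        row.update({f"addiction_{k}": int(v) for k, v in s.addictions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# severity bands

_MADRS_BANDS = ((7, 19, "low"), (20, 34, "moderate"), (35, np.inf, "severe"))
_IDSC30_BANDS = ((12, 23, "low"), (24, 36, "moderate"), (37, np.inf, "severe"))
_SEVERITY_RANK = {"subthreshold": 0, "low": 1, "moderate": 2, "severe": 3}


def severity_class(madrs: int | None = None, idsc30: int | None = None) -> str:
    """Depression severity from MADRS and/or IDS-C30 clinician scores.

    Bands: MADRS 7-19 / 20-34 / >=35 and IDS-C30 12-23 / 24-36 / >=37 map
    to low / moderate / severe. When the two scales disagree the more
    severe band wins (conservative clinical reading); scores below both
    low bands are 'subthreshold'.
    """
    if madrs is None and idsc30 is None:
        raise ValueError("at least one score is required")
    labels = []
    for score, bands in ((madrs, _MADRS_BANDS), (idsc30, _IDSC30_BANDS)):
        if score is None:
            continue
        if score < 0:
            raise ValueError(f"scores must be >= 0, got {score}")
        label = "subthreshold"
        for lo, hi, name in bands:
            if lo <= score <= hi:
                label = name
        labels.append(label)
    return max(labels, key=_SEVERITY_RANK.__getitem__)


# ---------------------------------------------------------------------------
# site-table simulation


def simulate_site_table(
    cohort: list[SampleMeta] | pd.DataFrame,
    sites: list[EditingSite],
    effects: list[EffectSpec],
    coverage_mean: float = 1000.0,
    coverage_dispersion: float = 10.0,
    batch_shift: dict[str, float] | None = None,
    baseline_editing: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an editome site table with planted effects.

    Per sample x site, coverage is negative-binomial around
    ``coverage_mean`` (gamma-Poisson with shape ``coverage_dispersion``)
    and the edited-read count is binomial(coverage, p) where p is the
    site's baseline editing rate, plus the planted delta when the sample
    belongs to the affected group of the effect's contrast, plus the
    sample's batch shift (percentage points), clipped to [0, 1] with a
    warning counting clipped cells.

    Returns the long-format table with columns sample_id, chrom, pos,
    gene, region, in_alu, snp_dist, coverage, edited_reads, editing_pct.
    """
    meta = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    effect_by_site = {}
    site_ids = {s.site_id for s in sites}
    for e in effects:
        if e.site_id not in site_ids:
            raise ValueError(f"effect references unknown site {e.site_id!r}")
        effect_by_site[e.site_id] = e
    rng = np.random.default_rng(seed)
    batch_shift = batch_shift or {}
    n = len(meta)
    shifts = meta["batch"].map(lambda b: batch_shift.get(b, 0.0)).to_numpy(dtype=float)
    is_dep = (meta["group"] == "DEP").to_numpy()
    is_bd = (meta.get("subtype", pd.Series([""] * n)) == "BD").to_numpy()
    rows = []
    clipped = 0
    for site in sites:
        eff = effect_by_site.get(site.site_id)
        base = eff.baseline_editing if eff else baseline_editing
        p = np.full(n, base, dtype=float)
        if eff is not None:
            affected = is_dep if eff.affected_contrast == "CTRL-vs-DEP" else is_bd
            p[affected] += eff.delta
        p = (p + shifts) / 100.0
        out_of_range = (p < 0) | (p > 1)
        clipped += int(out_of_range.sum())
        p = np.clip(p, 0.0, 1.0)
        shape = coverage_dispersion
        lam = rng.gamma(shape, coverage_mean / shape, size=n)
        coverage = np.maximum(rng.poisson(lam), 1)
        edited = rng.binomial(coverage, p)
        pct = edited / coverage * 100.0
        for k in range(n):
            rows.append(
                (
                    meta["sample_id"].iloc[k], site.chrom, site.pos, site.gene,
                    site.region, site.in_alu, site.snp_dist,
                    int(coverage[k]), int(edited[k]), float(pct[k]),
                )
            )
    if clipped:
        warnings.warn(f"{clipped} sample x site editing probabilities clipped to [0,1]")
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "pos", "gene", "region", "in_alu",
            "snp_dist", "coverage", "edited_reads", "editing_pct",
        ],
    )


# ---------------------------------------------------------------------------
# amplicon-read simulation

_PHRED37 = chr(37 + 33)


def simulate_amplicon_reads(
    design: AmpliconDesign,
    isoform_dist: dict[str, float],
    depth: int,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 150,
    fastq_path: str | None = None,
    sam_path: str | None = None,
    truth_path: str | None = None,
) -> pd.DataFrame:
    """Simulate single-end amplicon reads from an isoform distribution.

    Each read is assigned one isoform pattern (a label over the design's
    site letters, 'WT' for unedited); G is written at its edited sites and
    A at the others, and uniform substitution errors at ``error_rate``
    are applied at non-site positions. Reads are written as Phred+33
    FASTQ and/or as SAM records with a complete header; the per-read
    pattern truth table is returned (and written as TSV when
    ``truth_path`` is given).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    labels = design.site_labels
    for pattern in isoform_dist:
        if pattern != "WT" and any(ch not in labels for ch in pattern):
            raise ValueError(f"pattern {pattern!r} uses sites outside the design")
    probs = np.array(list(isoform_dist.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"isoform probabilities sum to {probs.sum()}, not 1")
    patterns = list(isoform_dist)
    rng = np.random.default_rng(seed)
    length = min(read_length, len(design.reference))
    ref = np.frombuffer(design.reference[:length].encode("ascii"), dtype=np.uint8)
    site_rel = np.array([p - design.start for p in design.site_positions])
    if site_rel.max(initial=-1) >= length:
        raise ValueError("read_length does not span all design sites")

    assign = rng.choice(len(patterns), size=depth, p=probs)
    seqs = np.tile(ref, (depth, 1))
    for pi, pattern in enumerate(patterns):
        if pattern == "WT":
            continue
        idx = site_rel[[labels.index(ch) for ch in pattern]]
        seqs[np.ix_(assign == pi, idx)] = ord("G")
    if error_rate > 0:
        err = rng.random(seqs.shape) < error_rate
        err[:, site_rel] = False  # errors only outside the phased sites
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        repl = bases[rng.integers(0, 4, size=seqs.shape)]
        same = repl == seqs
        repl[same] = bases[(np.searchsorted(bases, repl[same]) + 1) % 4]
        seqs[err] = repl[err]

    names = [f"read{k:06d}" for k in range(depth)]
    qual = _PHRED37 * length
    truth = pd.DataFrame({"read_id": names, "pattern": [patterns[a] for a in assign]})

    seq_strings = [bytes(s).decode("ascii") for s in seqs]
    if fastq_path:
        with open(fastq_path, "w") as fh:
            for name, s in zip(names, seq_strings):
                fh.write(f"@{name}\n{s}\n+\n{qual}\n")
    if sam_path:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": design.chrom, "LN": design.end + 1000}],
            "PG": [{"ID": "rnaedit-sim", "PN": "rnaedit-sim"}],
        }
        with pysam.AlignmentFile(sam_path, "w", header=header) as out:
            for name, s in zip(names, seq_strings):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = name
                rec.query_sequence = s
                rec.flag = 0
                rec.reference_id = 0
                rec.reference_start = design.start - 1  # genomic, 0-based in SAM
                rec.mapping_quality = 60
                rec.cigartuples = [(0, length)]
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(rec)
    if truth_path:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# default designs and panels (synthetic stand-ins)

_PANEL_GENES = (
    ("CAMK1D", "chr10", 12378385),
    ("GAB2", "chr11", 78330944),
    ("IFNAR1", "chr21", 33355807),
    ("KCNJ15", "chr21", 38287526),
    ("LYN", "chr8", 56012553),
    ("MDM2", "chr12", 68821612),
    ("PRKCB", "chr16", 23920896),
    ("PDE8A", "chr15", 84980000),
)


def default_designs(
    n_sites: int = 3, amplicon_length: int = 150, seed: int = 20210504
) -> dict[str, AmpliconDesign]:
    """Synthetic amplicon designs for the eight-gene validation panel.

    Reference sequences are random (seeded) stand-ins — the real amplicon
    sequences are proprietary to the assay — with ``n_sites`` candidate A
    positions spaced across each amplicon. Gene names and genomic anchors
    follow the published panel so outputs read like the real study's.
    """
    rng = np.random.default_rng(seed)
    designs = {}
    for gene, chrom, gstart in _PANEL_GENES:
        seq = rng.choice(list("ACGT"), size=amplicon_length)
        offsets = np.linspace(20, amplicon_length - 20, n_sites).astype(int)
        for off in offsets:
            seq[off] = "A"
        designs[gene] = AmpliconDesign(
            target_name=gene,
            chrom=chrom,
            reference="".join(seq),
            start=gstart,
            site_positions=tuple(int(gstart + o) for o in offsets),
        )
    return designs


def default_sites(n_per_gene: int = 2, snp_dist: float = 1e6) -> list[EditingSite]:
    """A synthetic editome panel: ``n_per_gene`` intronic/UTR sites per gene."""
    sites = []
    regions = ("intron", "3UTR")
    for gi, (gene, chrom, gstart) in enumerate(_PANEL_GENES):
        for k in range(n_per_gene):
            sites.append(
                EditingSite(
                    chrom=chrom,
                    pos=gstart + 10 * k,
                    gene=gene,
                    ensembl_id=f"ENSG_SYN{gi:03d}",
                    region=regions[k % 2],
                    in_alu=(k % 2 == 0),
                    snp_dist=snp_dist,
                )
            )
    return sites


def validation_cohort_spec(seed: int = 0, n_batches: int = 2) -> CohortSpec:
    """The published validation-cohort template: 143 CTRL, 160 UN, 95 BD,
    12 uncertain (267 depressed in total)."""
    return CohortSpec(
        n_per_group={"CTRL": 143, "UN": 160, "BD": 95, "UNCERTAIN": 12},
        n_batches=n_batches,
        seed=seed,
    )


def write_manifest(path: str, spec: CohortSpec, extra: dict | None = None) -> None:
    """JSON manifest of the generator configuration (spec + seed)."""
    payload = asdict(spec)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
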
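"""Quantification of A-to-I editing from targeted amplicon sequencing.

Inosine is read as guanosine by the sequencer, so editing at a genomic A
appears as an A->G mismatch in aligned reads. This module implements the
quantification chain for ultra-deep single-end amplicon data: read
pre-filters, per-position nucleotide counting, the editing-percent formula
G/(G+A)*100, automatic site detection, per-read phasing of edited-isoform
patterns, and the coverage-weighted Alu editing index.
"""

from __future__ import annotations

import string
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Read",
    "AmpliconDesign",
    "NucleotideCounts",
    "RejectionTally",
    "read_fastq",
    "filter_reads",
    "check_depth",
    "pileup_counts",
    "editing_percent",
    "site_editing_percent",
    "detect_sites",
    "isoform_proportions",
    "alu_editing_index",
    "SampleEditingProfile",
    "quantify_sample",
]

_BASE_INDEX = np.full(256, 4, dtype=np.int8)  # everything else -> N slot
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[ord(chr(_b).lower())] = _i


class Read(NamedTuple):
    """A sequencing read with its Phred+33 quality string."""

    name: str
    sequence: str
    quality: str | None


@dataclass(frozen=True)
class AmpliconDesign:
    """One targeted amplicon: reference span plus its candidate A sites.

    Site labels are single letters 'A', 'B', 'C', ... assigned in ascending
    genomic order, matching the field's convention of naming edited-isoform
    patterns by the letters of their edited sites (e.g. isoform "BC").
    Coordinates are 1-based inclusive (SAM convention).
    """

    target_name: str
    chrom: str
    reference: str
    start: int  # 1-based genomic coordinate of reference[0]
    site_positions: tuple[int, ...]  # genomic, 1-based, ascending
    strand: str = "+"

    def __post_init__(self) -> None:
        pos = tuple(sorted(self.site_positions))
        object.__setattr__(self, "site_positions", pos)
        end = self.start + len(self.reference) - 1
        for p in pos:
            if not (self.start <= p <= end):
                raise ValueError(
                    f"site position {p} outside amplicon span [{self.start}, {end}]"
                )
        if len(pos) > 26:
            raise ValueError("at most 26 labelled sites per amplicon")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: len(self.site_positions)])

    @property
    def end(self) -> int:
        return self.start + len(self.reference) - 1

    def label_for(self, position: int) -> str:
        return self.site_labels[self.site_positions.index(position)]


@dataclass
class NucleotideCounts:
    """Read-base tally at one genomic position."""

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    n: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t, self.n) < 0:
            raise ValueError("nucleotide counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.n


@dataclass
class RejectionTally:
    """Counts of reads removed by the pre-filters, by first failing rule."""

    too_short: int = 0
    low_quality: int = 0

    @property
    def total(self) -> int:
        return self.too_short + self.low_quality


def read_fastq(path: str) -> list[Read]:
    """Load a FASTQ file (Phred+33) into memory."""
    out = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out.append(Read(rec.name, rec.sequence, rec.quality))
    return out


def filter_reads(
    reads: Iterable[Read],
    min_length: int = 100,
    min_avg_quality: float = 20.0,
) -> tuple[list[Read], RejectionTally]:
    """Apply the length and mean-quality pre-filters.

    A read is retained iff its length is >= ``min_length`` nucleotides AND
    its mean Phred quality is >= ``min_avg_quality``. Rejections are
    tallied by the first failing rule (length checked first).
    """
    kept: list[Read] = []
    tally = RejectionTally()
    for r in reads:
        if r.quality is None:
            raise ValueError(f"read {r.name!r} carries no quality string")
        if len(r.sequence) < min_length:
            tally.too_short += 1
            continue
        q = np.frombuffer(r.quality.encode("ascii"), dtype=np.uint8).astype(float) - 33
        if q.mean() < min_avg_quality:
            tally.low_quality += 1
            continue
        kept.append(r)
    return kept, tally


def check_depth(
    depths: Mapping[tuple[str, str], int] | Mapping[str, int],
    min_depth: int = 20_000,
) -> dict:
    """Minimum-depth rule per sample x target, applied after read filtering.

    Depth exactly at the minimum passes (inclusive boundary). Failing
    entries are excluded from downstream statistics by the caller.
    """
    return {key: depth >= min_depth for key, depth in depths.items()}


# ---------------------------------------------------------------------------
# SAM parsing


def _iter_alignments(alignments, design: AmpliconDesign):
    """Yield (ref_start_1based, sequence) for usable records.

    Records that are unmapped, secondary, supplementary, indel-containing
    or non-unique are skipped (they are expected to have been removed
    upstream); a record aligned to a reference other than the design's
    target raises.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            yield from _iter_alignments(fh, design)
        return
    known = {design.target_name, design.chrom}
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.reference_name not in known:
            raise ValueError(
                f"alignment to unknown reference {rec.reference_name!r}; "
                f"expected one of {sorted(known)}"
            )
        if rec.cigartuples is None:
            continue
        if any(op not in (0, 7, 8) for op, _ in rec.cigartuples):
            continue  # indel / clipped records are removed upstream
        yield rec.reference_start + 1, rec.query_sequence


def _read_matrix(alignments, design: AmpliconDesign, parsed: bool = False):
    """Group usable reads by (start, length) into byte-code matrices.

    ``parsed`` marks ``alignments`` as an iterable of already-extracted
    (start, sequence) pairs, bypassing SAM record screening.
    """
    pairs = alignments if parsed else _iter_alignments(alignments, design)
    groups: dict[tuple[int, int], list[bytes]] = defaultdict(list)
    for start, seq in pairs:
        groups[(start, len(seq))].append(seq.encode("ascii"))
    for (start, length), seqs in groups.items():
        raw = np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(len(seqs), length)
        yield start, _BASE_INDEX[raw]


def pileup_counts(
    alignments, design: AmpliconDesign, parsed: bool = False
) -> dict[int, NucleotideCounts]:
    """Per-position nucleotide tallies over retained alignments.

    ``alignments`` may be a SAM path or an iterable of pysam records
    aligned to the design's reference. Positions never covered by any read
    are absent from the returned mapping (keys are 1-based genomic
    positions). Tally order is read-order independent.
    """
    span = len(design.reference)
    tally = np.zeros((span, 5), dtype=np.int64)
    covered = np.zeros(span, dtype=bool)
    for start, codes in _read_matrix(alignments, design, parsed=parsed):
        off = start - design.start
        n_reads, length = codes.shape
        lo, hi = max(off, 0), min(off + length, span)
        if lo >= hi:
            continue
        sub = codes[:, lo - off : hi - off]
        for b in range(5):
            tally[lo:hi, b] += (sub == b).sum(axis=0)
        covered[lo:hi] = True
    out: dict[int, NucleotideCounts] = {}
    for i in np.flatnonzero(covered):
        a, c, g, t, n = (int(v) for v in tally[i])
        out[design.start + int(i)] = NucleotideCounts(a, c, g, t, n)
    return out


# ---------------------------------------------------------------------------
# editing formula


def editing_percent(counts: NucleotideCounts) -> float:
    """Editing percent at a reference-A position: G/(G+A) x 100.

    C, T and N reads are ignored by the formula. When no A or G read
    covers the position the value is undefined and NaN is returned (never
    0, which would assert an unedited site without evidence).
    """
    denom = counts.g + counts.a
    if denom == 0:
        return float("nan")
    return counts.g / denom * 100.0


def site_editing_percent(counts: NucleotideCounts, strand: str = "+") -> float:
    """Strand-aware editing percent.

    On the minus strand the edited base pair appears as T->C on the
    forward genomic strand, so the formula becomes C/(C+T) x 100.
    """
    if strand == "+":
        return editing_percent(counts)
    denom = counts.c + counts.t
    if denom == 0:
        return float("nan")
    return counts.c / denom * 100.0


def detect_sites(
    position_percents: Mapping[int, float], threshold: float = 0.1
) -> list[int]:
    """Positions whose editing percent strictly exceeds ``threshold``.

    Detection is per sample; panels are defined as the union of detected
    positions across samples. The threshold is on the percent scale
    (0.1 means one edited read per thousand).
    """
    return sorted(
        p
        for p, pct in position_percents.items()
        if not np.isnan(pct) and pct > threshold
    )


# ---------------------------------------------------------------------------
# isoform phasing


@dataclass
class IsoformTally:
    """Bookkeeping for isoform phasing: why reads were ineligible."""

    eligible: int = 0
    not_spanning: int = 0
    non_ag_base: int = 0


def isoform_proportions(
    alignments,
    design: AmpliconDesign,
    min_proportion: float = 0.1,
    parsed: bool = False,
) -> tuple[dict[str, float], IsoformTally]:
    """Relative proportions of edited-isoform patterns, phased per read.

    An isoform is the combination of edited sites carried by one molecule:
    a read with G at sites B and C and A elsewhere is isoform "BC"; a read
    edited nowhere is "WT". Only reads spanning ALL of the design's sites
    are eligible (patterns from partial reads would be ambiguous); reads
    with a non-A/G base at any site are excluded and tallied, consistent
    with the site formula ignoring C/T/N.

    Proportions are percentages of eligible reads and sum to 100 before
    the ``min_proportion`` cut (default 0.1%), which drops rare patterns
    from the biomarker set.
    """
    if not design.site_positions:
        raise ValueError(f"design {design.target_name!r} has no sites")
    site_idx = np.array([p - design.start for p in design.site_positions])
    labels = design.site_labels
    patterns: Counter[str] = Counter()
    tally = IsoformTally()
    for start, codes in _read_matrix(alignments, design, parsed=parsed):
        off = start - design.start
        n_reads, length = codes.shape
        rel = site_idx - off
        if rel.min() < 0 or rel.max() >= length:
            tally.not_spanning += n_reads
            continue
        bases = codes[:, rel]  # n_reads x n_sites
        ok = np.all((bases == 0) | (bases == 2), axis=1)  # A or G at every site
        tally.non_ag_base += int((~ok).sum())
        tally.eligible += int(ok.sum())
        edited = bases[ok] == 2
        for row in edited:
            lab = "".join(l for l, e in zip(labels, row) if e) or "WT"
            patterns[lab] += 1
    if tally.eligible == 0:
        return {}, tally
    props = {
        lab: cnt / tally.eligible * 100.0 for lab, cnt in sorted(patterns.items())
    }
    return {k: v for k, v in props.items() if v >= min_proportion}, tally


# ---------------------------------------------------------------------------
# Alu editing index


def alu_editing_index(site_table: pd.DataFrame) -> float:
    """Coverage-weighted Alu editing index for one sample.

    AEI = sum of G-supporting reads over Alu positions divided by the sum
    of (A+G)-supporting reads over the same positions, x 100 — a global
    editing summary dominated by the highly covered positions rather than
    an average of per-site rates.

    The table must carry ``in_alu`` plus either (``a_reads``, ``g_reads``)
    or (``coverage``, ``edited_reads``), in which case A is taken as
    coverage minus edited reads. Zero Alu coverage is undefined (NaN).
    """
    alu = site_table[site_table["in_alu"].astype(bool)]
    if {"a_reads", "g_reads"}.issubset(alu.columns):
        g = alu["g_reads"].to_numpy(dtype=float)
        a = alu["a_reads"].to_numpy(dtype=float)
    else:
        g = alu["edited_reads"].to_numpy(dtype=float)
        a = alu["coverage"].to_numpy(dtype=float) - g
    denom = (a + g).sum()
    if denom == 0:
        return float("nan")
    return float(g.sum() / denom * 100.0)


# ---------------------------------------------------------------------------
# per-sample profile


@dataclass
class SampleEditingProfile:
    """Quantification output for one sample over one or more amplicons."""

    sample_id: str
    site_percent: dict[tuple[str, str], float] = field(default_factory=dict)
    isoform_percent: dict[tuple[str, str], float] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    depth_pass: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(type="site", target=t, label=l, value=v)
            for (t, l), v in self.site_percent.items()
        ] + [
            dict(type="isoform", target=t, label=l, value=v)
            for (t, l), v in self.isoform_percent.items()
        ]
        return pd.DataFrame(rows, columns=["type", "target", "label", "value"])


def quantify_sample(
    alignments_by_target: Mapping[str, object],
    designs: Mapping[str, AmpliconDesign],
    sample_id: str,
    min_depth: int = 20_000,
    min_isoform_pct: float = 0.1,
) -> SampleEditingProfile:
    """Quantify sites and isoforms for one sample across its amplicons.

    ``alignments_by_target`` maps target name to a SAM path or record
    iterable. Targets failing the depth rule keep their depth record but
    contribute no site/isoform values (isoform proportions are computed
    only on depth-passing targets).
    """
    profile = SampleEditingProfile(sample_id=sample_id)
    for target, aln in alignments_by_target.items():
        design = designs[target]
        records = list(_iter_alignments(aln, design))
        profile.depth[target] = len(records)
        profile.depth_pass[target] = len(records) >= min_depth
        if not profile.depth_pass[target]:
            continue
        counts = pileup_counts(records, design, parsed=True)
        for pos, lab in zip(design.site_positions, design.site_labels):
            nc = counts.get(pos)
            pct = site_editing_percent(nc, design.strand) if nc else float("nan")
            profile.site_percent[(target, lab)] = pct
        props, _tally = isoform_proportions(
            records, design, min_proportion=min_isoform_pct, parsed=True
        )
        for lab, pct in props.items():
            profile.isoform_percent[(target, lab)] = pct
    return profile
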
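"""Variant- and sample-level quality control, and split-read deletion calling.

Variant filtering retains biallelic SNVs with read depth >= 300 whose
FILTER column carries none of the caller's failure flags (base quality,
strand bias, slippage, weak evidence, germline, position) and whose
position is outside the polyC/G homopolymer mask; indels are excluded
outright.  Samples are excluded for contamination, haplogroup-discordant
variants, predicted NUMT variants, low coverage, low mtDNA copy number,
or an outlying heteroplasmy count.  Large deletions are called from
split-read junctions supported by at least two reads whose mates all map
to the mitochondrial contig.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_VAF_THRESHOLD = 0.05
DEFAULT_MIN_DEPTH = 300
DEFAULT_CN_CUTOFF = 40.0
DEFAULT_MAX_HET_COUNT = 5          # counts of 6 or more are excluded
DEFAULT_MIN_BASE_COVERAGE = 100.0  # config default, not an established cutoff
DEFAULT_MEAN_BASE_COVERAGE = 500.0  # config default, not an established cutoff
DEFAULT_NUMT_VARIANT_CUTOFF = 2
MIN_DELETION_SUPPORT = 2

#: caller FILTER flags that fail a variant, keyed by their prose names
FILTER_FLAG_MAP = {
    "base quality": "base_qual",
    "strandedness": "strand_bias",
    "slippage": "slippage",
    "weak evidence": "weak_evidence",
    "germline": "germline",
    "position": "position",
}
FAILING_FILTER_FLAGS = frozenset(FILTER_FLAG_MAP.values())


def classify_vaf(vaf: float, threshold: float = DEFAULT_VAF_THRESHOLD) -> str:
    """Classify an allele fraction as heteroplasmic / homoplasmic / subthreshold.

    Fractions within [threshold, 1 - threshold] are heteroplasmic; above
    1 - threshold the variant allele is effectively fixed (homoplasmic);
    below the threshold the call is ignored (the sample's major allele is
    treated as homoplasmic reference).  Thresholds of 0.03 and 0.10 are
    supported for sensitivity analyses.
    """
    if not 0.0 < vaf < 1.0:
        raise ValueError(f"VAF {vaf} outside (0, 1): not a variant call")
    if not 0.0 < threshold < 0.5:
        raise ValueError(f"threshold {threshold} must lie in (0, 0.5)")
    if vaf < threshold:
        return "subthreshold"
    if vaf > 1.0 - threshold:
        return "homoplasmic"
    return "heteroplasmic"


@dataclass
class VariantRecord:
    """One parsed VCF record for one sample."""

    sample_id: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    filters: frozenset = frozenset()

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"


@dataclass
class HeteroplasmyCall:
    """One retained sample-variant observation."""

    sample_id: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    filter_flags: frozenset
    state: str
    consequence: object | None = None
    mlc: float | None = None


def read_vcf_calls(path, sample_id: str | None = None) -> list[VariantRecord]:
    """Parse per-sample variant records from a VCF via cyvcf2.

    AF is taken from the FORMAT AF field (fallback: INFO AF), DP from
    FORMAT/INFO DP.  Multi-allelic records yield one row per alt.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples or [sample_id or "sample"]
    records: list[VariantRecord] = []
    for var in vcf:
        filters = frozenset(var.FILTER.split(";")) if var.FILTER else frozenset()
        for alt_i, alt in enumerate(var.ALT):
            for s_i, sample in enumerate(samples):
                af = None
                try:
                    fmt_af = var.format("AF")
                    if fmt_af is not None:
                        af = float(fmt_af[s_i][min(alt_i, fmt_af.shape[1] - 1)])
                except (KeyError, TypeError):
                    pass
                if af is None:
                    info_af = var.INFO.get("AF")
                    if isinstance(info_af, tuple):
                        info_af = info_af[alt_i]
                    af = float(info_af) if info_af is not None else float("nan")
                dp = None
                try:
                    fmt_dp = var.format("DP")
                    if fmt_dp is not None:
                        dp = int(fmt_dp[s_i][0])
                except (KeyError, TypeError):
                    pass
                if dp is None:
                    dp = int(var.INFO.get("DP", 0))
                records.append(
                    VariantRecord(sample, var.POS, var.REF, alt, af, dp, filters)
                )
    return records


@dataclass
class RejectionLedger:
    """Partition of filtered inputs: every rejection carries one reason."""

    rejected: list = field(default_factory=list)  # (record, reason) pairs

    def add(self, record, reason: str) -> None:
        self.rejected.append((record, reason))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for _, reason in self.rejected:
            out[reason] += 1
        return dict(out)

    def __len__(self) -> int:
        return len(self.rejected)


def homopolymer_mask(sequence: str, min_run: int = 5, bases: str = "CG") -> set[int]:
    """1-based positions inside runs of >= min_run identical C/G bases.

    The published analyses mask polyC homopolymer tracts; their exact
    coordinates are not enumerated, so the default mask is recomputed
    from the packaged reference as a stand-in and can be overridden with
    a BED-derived set.
    """
    mask: set[int] = set()
    n = len(sequence)
    i = 0
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if sequence[i] in bases and j - i >= min_run:
            mask.update(range(i + 1, j + 1))
        i = j
    return mask


def read_bed_mask(path) -> set[int]:
    """Load a BED (0-based half-open) mask into a 1-based position set."""
    mask: set[int] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _, start, end = line.split()[:3]
            mask.update(range(int(start) + 1, int(end) + 1))
    return mask


def filter_variant_records(
    records,
    homopolymer: set[int] | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    failing_flags: frozenset = FAILING_FILTER_FLAGS,
) -> tuple[list[VariantRecord], RejectionLedger]:
    """Apply the variant-level filter cascade.

    A record is retained iff it is an SNV, has depth >= min_depth, carries
    no failing FILTER flag, and lies outside the homopolymer mask.  Each
    rejection is recorded with its first matching reason, in that order.
    """
    homopolymer = homopolymer or set()
    retained: list[VariantRecord] = []
    ledger = RejectionLedger()
    for rec in records:
        if not isinstance(rec, VariantRecord):
            ledger.add(rec, "malformed record")
            continue
        if not rec.is_snv:
            ledger.add(rec, "indel")
        elif rec.depth < min_depth:
            ledger.add(rec, "low depth")
        elif rec.filters & failing_flags:
            flag = sorted(rec.filters & failing_flags)[0]
            ledger.add(rec, f"filter flag: {flag}")
        elif rec.pos in homopolymer:
            ledger.add(rec, "homopolymer region")
        else:
            retained.append(rec)
    return retained, ledger


@dataclass
class SampleQCRecord:
    """Per-sample QC metrics consumed by the exclusion cascade."""

    sample_id: str
    mtdna_cn: float | None
    heteroplasmy_count: int
    contamination_flag: bool = False
    haplogroup_discordant_variants: int = 0
    numt_predicted_variants: int = 0
    min_base_coverage: float = float("inf")
    mean_base_coverage: float = float("inf")
    excluded: bool = False
    exclusion_reasons: list = field(default_factory=list)


def apply_sample_qc(
    samples,
    cn_cutoff: float = DEFAULT_CN_CUTOFF,
    cn_strict: bool = False,
    max_het_count: int = DEFAULT_MAX_HET_COUNT,
    min_coverage_floor: float = DEFAULT_MIN_BASE_COVERAGE,
    mean_coverage_floor: float = DEFAULT_MEAN_BASE_COVERAGE,
    numt_cutoff: int = DEFAULT_NUMT_VARIANT_CUTOFF,
) -> tuple[list[SampleQCRecord], list[SampleQCRecord]]:
    """Apply the sample-exclusion cascade; reasons accumulate per sample.

    ``cn_strict=True`` excludes copy number <= cutoff instead of < cutoff
    (the two conventions that appear across cohorts).  Returns (analysis
    set, excluded) with ``excluded``/``exclusion_reasons`` filled in.
    """
    kept: list[SampleQCRecord] = []
    dropped: list[SampleQCRecord] = []
    for s in samples:
        reasons = []
        if s.contamination_flag:
            reasons.append("contamination")
        if s.haplogroup_discordant_variants >= 2:
            reasons.append("haplogroup-discordant variants")
        if s.numt_predicted_variants >= numt_cutoff:
            reasons.append("NUMT-predicted variants")
        if s.min_base_coverage < min_coverage_floor:
            reasons.append("low minimum base coverage")
        if s.mean_base_coverage < mean_coverage_floor:
            reasons.append("low mean base coverage")
        if s.mtdna_cn is None:
            reasons.append("missing copy number")
        elif (s.mtdna_cn <= cn_cutoff) if cn_strict else (s.mtdna_cn < cn_cutoff):
            reasons.append("low mtDNA copy number")
        if s.heteroplasmy_count > max_het_count:
            reasons.append("heteroplasmy count outlier")
        s.exclusion_reasons = reasons
        s.excluded = bool(reasons)
        (dropped if s.excluded else kept).append(s)
    return kept, dropped


@dataclass(frozen=True)
class DeletionCall:
    """A split-read supported deletion junction."""

    junction_5p: int
    junction_3p: int
    support: int
    vaf: float | None = None

    @property
    def name(self) -> str:
        return f"{self.junction_5p}_{self.junction_3p}del"


def call_deletions(
    split_reads: pd.DataFrame,
    spanning_counts: dict[tuple[int, int], int] | None = None,
    min_support: int = MIN_DELETION_SUPPORT,
    mito_contig: str = "chrM",
) -> tuple[list[DeletionCall], list[tuple[int, int]]]:
    """Group split reads by junction and emit supported deletion calls.

    ``split_reads`` columns: read_id, end3 (1st alignment 3' end), start5
    (2nd alignment 5' start), mate_chrom, orientation.  Junction groups
    containing any read whose mate maps off the mitochondrial contig are
    suppressed as possible NUMT artifacts and returned separately.  When
    ``spanning_counts`` supplies reads crossing the junction without a
    split, VAF = support / (support + spanning).
    """
    calls: list[DeletionCall] = []
    suppressed: list[tuple[int, int]] = []
    for (end3, start5), group in split_reads.groupby(["end3", "start5"]):
        end3, start5 = int(end3), int(start5)
        if start5 <= end3:
            raise ValueError(f"junction {end3}->{start5} is not a deletion (3' <= 5')")
        if (group["mate_chrom"] != mito_contig).any():
            suppressed.append((end3, start5))
            continue
        support = len(group)
        if support < min_support:
            continue
        vaf = None
        if spanning_counts is not None:
            span = spanning_counts.get((end3, start5), 0)
            vaf = support / (support + span) if support + span > 0 else None
        calls.append(DeletionCall(end3, start5, support, vaf))
    return sorted(calls, key=lambda c: (c.junction_5p, c.junction_3p)), suppressed


def attach_states(
    records,
    threshold: float = DEFAULT_VAF_THRESHOLD,
) -> list[HeteroplasmyCall]:
    """Wrap retained variant records as calls with their VAF state."""
    return [
        HeteroplasmyCall(
            sample_id=r.sample_id, pos=r.pos, ref=r.ref, alt=r.alt,
            vaf=r.vaf, depth=r.depth, filter_flags=r.filters,
            state=classify_vaf(r.vaf, threshold),
        )
        for r in records
    ]
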
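"""Descriptive population-genetic summaries of mtDNA variant tables.

Ti/Tv and dN/dS are unique-variant count ratios (carrier multiplicity is
ignored unless requested), saturation summaries partition observed unique
variants into heteroplasmic-only / homoplasmic-only / both per region,
pair sharing measures the fraction of variants common to both members of
related pairs, and the median-VAF contrast compares per-variant median
allele fractions between consequence classes with a rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import GENOME_LENGTH, GeneMap

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _variant_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    return pd.DataFrame(list(variants), columns=["pos", "ref", "alt"])


def titv_ratio(variants, unique: bool = True) -> float:
    """Transition / transversion ratio over a variant set.

    ``unique=True`` (default) deduplicates on (pos, ref, alt) so each
    variant counts once; ``unique=False`` weights by carrier rows.  Zero
    transversions yields ``inf`` as a flagged sentinel.
    """
    df = _variant_frame(variants)
    if df.empty:
        raise ValueError("cannot compute Ti/Tv of an empty variant set")
    if unique:
        df = df.drop_duplicates(subset=["pos", "ref", "alt"])
    is_ts = [(r, a) in TRANSITIONS for r, a in zip(df["ref"], df["alt"])]
    n_ts = int(np.sum(is_ts))
    n_tv = len(df) - n_ts
    if n_tv == 0:
        return math.inf
    return n_ts / n_tv


NONSYNONYMOUS_KINDS = ("missense", "stop_gained", "start_lost", "stop_lost")


def dnds_ratio(consequence_kinds) -> float:
    """Nonsynonymous / synonymous unique-variant count ratio.

    ``consequence_kinds`` is an iterable of consequence-kind strings for
    unique protein-coding variants.  Zero synonymous counts yield ``inf``
    as a flagged sentinel.
    """
    kinds = list(consequence_kinds)
    if not kinds:
        raise ValueError("cannot compute dN/dS of an empty set")
    n_nonsyn = sum(k in NONSYNONYMOUS_KINDS for k in kinds)
    n_syn = sum(k == "synonymous" for k in kinds)
    if n_syn == 0:
        return math.inf
    return n_nonsyn / n_syn


@dataclass
class RegionSummary:
    """Saturation of possible substitutions in one genome region."""

    region: str
    n_sites_possible: int
    n_observed: int
    n_het_only: int
    n_hom_only: int
    n_both: int


def saturation_summary(
    het_variants,
    hom_variants,
    genemap: GeneMap,
    masked_positions: set[int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-region counts of possible vs observed unique substitutions.

    Possible substitutions are 3 per unmasked position.  A variant seen
    in both the heteroplasmic and homoplasmic tables counts as "both".
    Variants at masked positions are an integrity error: they should have
    been removed by the filter cascade.
    """
    masked = masked_positions or set()
    het = _variant_frame(het_variants).drop_duplicates(subset=["pos", "ref", "alt"])
    hom = _variant_frame(hom_variants).drop_duplicates(subset=["pos", "ref", "alt"])
    for name, df in (("heteroplasmic", het), ("homoplasmic", hom)):
        bad = set(df["pos"]) & masked
        if bad:
            raise ValueError(
                f"{name} variants at masked positions {sorted(bad)[:5]}: "
                "mask filtering must run before summarization"
            )

    het_set = set(map(tuple, het[["pos", "ref", "alt"]].itertuples(index=False)))
    hom_set = set(map(tuple, hom[["pos", "ref", "alt"]].itertuples(index=False)))
    both = het_set & hom_set

    region_of = {p: genemap.classify_region(p) for p in range(1, GENOME_LENGTH + 1)}
    rows = []
    regions = sorted({region_of[p] for p in region_of})
    for region in regions:
        positions = {p for p, r in region_of.items() if r == region and p not in masked}
        possible = 3 * len(positions)
        h_only = sum(1 for v in het_set - both if v[0] in positions)
        m_only = sum(1 for v in hom_set - both if v[0] in positions)
        b = sum(1 for v in both if v[0] in positions)
        rows.append(RegionSummary(region, possible, h_only + m_only + b, h_only, m_only, b))

    table = pd.DataFrame([vars(r) for r in rows])
    overall = {
        "n_het_only": len(het_set - both),
        "n_hom_only": len(hom_set - both),
        "n_both": len(both),
        "n_observed": len(het_set | hom_set),
        "n_possible": 3 * (GENOME_LENGTH - len(masked)),
    }
    return table, overall


@dataclass
class PairSharing:
    """Variant sharing pooled over all pairs of one relationship type."""

    pair_type: str
    n_pairs: int
    n_unique_variants: int
    n_shared: int

    @property
    def fraction_shared(self) -> float:
        if self.n_unique_variants == 0:
            return float("nan")
        return self.n_shared / self.n_unique_variants


def pair_sharing(pairs, calls: pd.DataFrame) -> dict[str, PairSharing]:
    """Fraction of heteroplasmies shared within related pairs, by type.

    ``pairs`` is an iterable of (id1, id2, relationship); ``calls`` holds
    heteroplasmic calls with columns sample_id, pos, ref, alt.  For each
    pair, every variant carried by either member counts once toward the
    type's unique-variant total, and toward the shared total iff it is
    heteroplasmic in both members; totals are pooled over pairs of the
    same type.
    """
    by_sample: dict[str, set] = {
        sid: set(map(tuple, grp[["pos", "ref", "alt"]].itertuples(index=False)))
        for sid, grp in calls.groupby("sample_id")
    }
    acc: dict[str, PairSharing] = {}
    for id1, id2, ptype in pairs:
        if id1 == id2:
            raise ValueError(f"self-pair {id1!r} rejected")
        v1 = by_sample.get(id1, set())
        v2 = by_sample.get(id2, set())
        entry = acc.setdefault(ptype, PairSharing(ptype, 0, 0, 0))
        entry.n_pairs += 1
        entry.n_unique_variants += len(v1 | v2)
        entry.n_shared += len(v1 & v2)
    return acc


def median_vaf_contrast(
    variant_medians: pd.DataFrame,
    group_col: str = "group",
    vaf_col: str = "median_vaf",
) -> dict:
    """Compare per-variant median VAFs between two groups.

    Input has one row per unique variant with its median VAF across
    carriers and a group label (e.g. nonsynonymous vs synonymous).
    Returns group medians and, when exactly two groups each have >= 2
    variants, the two-sided Wilcoxon rank-sum p-value; otherwise the test
    is skipped with a notice.
    """
    groups = {
        name: grp[vaf_col].to_numpy()
        for name, grp in variant_medians.groupby(group_col)
    }
    medians = {name: float(np.median(v)) for name, v in groups.items()}
    result = {"medians": medians, "p_value": None, "notice": None}
    eligible = [name for name, v in groups.items() if len(v) >= 2]
    if len(groups) != 2:
        result["notice"] = f"need exactly 2 groups for the rank test, got {len(groups)}"
        return result
    if len(eligible) < 2:
        small = sorted(set(groups) - set(eligible))
        result["notice"] = f"group(s) {small} have < 2 variants; test skipped"
        return result
    a, b = (groups[name] for name in sorted(groups))
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    result["p_value"] = float(stat.pvalue)
    return result
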
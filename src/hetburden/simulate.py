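"""Synthetic cohort generator for the heteroplasmy burden pipeline.

Emulates the statistical structure the analysis modules assume, so the
whole pipeline runs and is tested without access-controlled data:

* a site-frequency database whose observed counts are Poisson around a
  simple transition/transversion rate model, depleted region-by-region
  to create a constraint landscape (RNA genes and Complexes I/IV most
  constrained, Complex V and the D-loop least);
* per-sample heteroplasmy counts that are Poisson with a log-linear
  age + smoking mean (optional age x smoking interaction) and a gamma
  frailty calibrated so the count distribution has the observed zero
  fraction (~70%) and rare 4+ tail;
* variant allele fractions concentrated at low values, shifted lower for
  high-constraint variants;
* exponential (optionally Weibull) survival under a proportional-hazards
  linear predictor with configurable burden, count-category and
  cause-specific effects, center-specific baselines and administrative
  censoring;
* related pairs with configurable maternal transmission, split-read
  tables with planted deletions and NUMT decoys, and QC-failing samples
  and variant records that exercise every exclusion rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import qc
from .constraint import MLCTrack, SiteFrequencyDB, variant_mlc
from .reference import GENOME_LENGTH, GeneMap

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """All generator knobs; the defaults define the emulated study.

    Effect-size defaults are the published headline estimates (per-unit
    burden hazard ratio 1.28; 4+-heteroplasmy hazard ratio 1.50 when the
    count-category effect is switched on; leukemia-specific burden
    hazard ratio 4.97 with a null accident effect).  Ages are uniform on
    the recruitment window 40-69 years; maternal transmission is 0.30.
    """

    n_samples: int = 5_000
    # covariate structure
    age_range: tuple = (40.0, 69.0)
    p_male: float = 0.46
    smoking_probs: tuple = (0.55, 0.345, 0.105)   # never, former, current
    alcohol_probs: tuple = (0.08, 0.045, 0.875)   # never, former, current
    haplogroups: tuple = ("H", "U", "JT", "R0", "R", "N", "M", "L")
    haplogroup_probs: tuple = (0.44, 0.16, 0.17, 0.07, 0.06, 0.04, 0.03, 0.03)
    n_centers: int = 6
    center_log_hazard_sd: float = 0.25
    # heteroplasmy count model (log-linear, age centred at 54.5 y)
    count_intercept: float = -1.10
    count_age_coef: float = 0.020          # per year
    count_former_coef: float = 0.05
    count_current_coef: float = 0.15
    count_age_current_interaction: float = 0.0
    count_frailty_var: float = 0.40        # gamma frailty: fattens the 4+ tail
    # mutation spectrum and VAF model
    transition_fraction: float = 28.7 / 29.7
    vaf_alpha: float = 0.8
    vaf_beta: float = 4.0
    vaf_mlc_shift: float = 2.0             # extra beta mass at low VAF per MLC unit
    mean_depth: float = 1100.0
    # survival model
    loghr_mss: float = math.log(1.28)
    loghr_count_4plus: float = 0.0         # switched on for count-category harnesses
    loghr_age: float = 0.085               # per year
    loghr_male: float = 0.40
    loghr_former: float = 0.20
    loghr_current: float = 0.60
    baseline_hazard: float = 0.018         # per year
    weibull_shape: float = 1.0             # 1.0 = exponential
    followup_years: float = 15.0           # administrative censoring horizon
    # competing causes: name -> (baseline hazard share, burden log-HR)
    competing_causes: bool = False
    cause_spec: dict = field(default_factory=lambda: {
        "leukemia": (0.010, math.log(4.97)),
        "accident": (0.030, 0.0),
        "other": (0.960, math.log(1.28)),
    })
    # heritability
    maternal_transmission_p: float = 0.30
    twin_transmission_p: float = 0.95
    sibling_transmission_p: float = 0.30
    # constraint-landscape depletion factors (observed / expected)
    depletion: dict = field(default_factory=lambda: {
        "rRNA": 0.20, "tRNA": 0.25, "ComplexIV": 0.40, "ComplexI": 0.45,
        "ComplexIII": 0.60, "unassigned": 0.80, "D-loop": 0.95, "ComplexV": 1.00,
    })
    gene_depletion: dict = field(default_factory=dict)  # per-gene overrides
    expected_scale: float = 6.0
    ts_weight: float = 28.7
    tv_weight: float = 1.0
    strand_factor: float = 1.3             # heavy-strand pyrimidine refs
    # QC exercise
    qc_fail_fraction: float = 0.02

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# -- constraint database ------------------------------------------------------

def gen_constraint_db(genemap: GeneMap, config: SimConfig, seed: int) -> SiteFrequencyDB:
    """Synthetic site-frequency database over all possible substitutions.

    Expected counts follow a 3-parameter rate model (transition weight,
    transversion weight, strand factor for pyrimidine reference bases);
    observed counts are Poisson around expected times a region- or
    gene-specific depletion factor.  Depletion factor 1 everywhere gives
    genome-wide mean oe ~= 1.
    """
    for name, factor in {**config.depletion, **config.gene_depletion}.items():
        if factor <= 0:
            raise ValueError(f"depletion factor for {name!r} must be > 0")
    rng = np.random.default_rng(seed)
    seq = genemap.sequence
    gene_factor: dict[int, float] = {}
    for gene, factor in config.gene_depletion.items():
        feats = [f for f in genemap.features if f.name == gene]
        if not feats:
            raise ValueError(f"unknown gene {gene!r} in gene_depletion")
        for f in feats:
            for p in f.positions():
                gene_factor[p] = factor

    rows = []
    base = config.expected_scale / (config.ts_weight + 2 * config.tv_weight)
    for pos in range(1, genemap.genome_length + 1):
        ref = seq[pos - 1]
        region = genemap.classify_region(pos)
        depl = gene_factor.get(pos, config.depletion.get(region, 1.0))
        strand = config.strand_factor if ref in "CT" else 1.0
        for alt in "ACGT":
            if alt == ref:
                continue
            w = config.ts_weight if _TRANSITION_PARTNER[ref] == alt else config.tv_weight
            expected = base * w * strand
            observed = rng.poisson(expected * depl)
            rows.append((pos, ref, alt, observed, expected))
    table = pd.DataFrame(rows, columns=SiteFrequencyDB.COLUMNS)
    return SiteFrequencyDB(table, genemap.genome_length)


# -- cohort -------------------------------------------------------------------

def _annotation_cache(genemap: GeneMap):
    cache: dict[tuple[int, str], object] = {}

    def get(pos: int, alt: str):
        key = (pos, alt)
        if key not in cache:
            cache[key] = genemap.annotate_substitution(pos, genemap.base(pos), alt)
        return cache[key]

    return get


def _draw_variants(rng, n: int, genemap: GeneMap, config: SimConfig,
                   positions: np.ndarray) -> tuple[np.ndarray, list, list]:
    pos = rng.choice(positions, size=n)
    refs = [genemap.base(int(p)) for p in pos]
    alts = []
    for r in refs:
        if rng.random() < config.transition_fraction:
            alts.append(_TRANSITION_PARTNER[r])
        else:
            choices = [b for b in "ACGT" if b != r and b != _TRANSITION_PARTNER[r]]
            alts.append(choices[rng.integers(2)])
    return pos, refs, alts


def gen_cohort(
    config: SimConfig,
    genemap: GeneMap,
    track: MLCTrack,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Simulate a cohort: covariates, calls, survival and QC metrics.

    Returns ``(cohort, calls, metrics)``: the per-sample table with
    covariates, heteroplasmy count, burden score (MSS), follow-up and
    event columns; the per-variant heteroplasmic call table (with some
    QC-failing raw records when ``qc_fail_fraction > 0``); and the
    per-sample QC metric records.
    """
    rng = np.random.default_rng(seed)
    n = config.n_samples
    mask = qc.homopolymer_mask(genemap.sequence)
    ok_positions = np.array(
        [p for p in range(1, GENOME_LENGTH + 1) if p not in mask]
    )
    annotate = _annotation_cache(genemap)

    age = rng.uniform(*config.age_range, size=n)
    male = rng.random(n) < config.p_male
    smoking = rng.choice(["never", "former", "current"], size=n,
                         p=config.smoking_probs)
    alcohol = rng.choice(["never", "former", "current"], size=n,
                         p=config.alcohol_probs)
    bmi = rng.normal(27.2, 4.6, size=n).clip(15, 55)
    wbc = rng.lognormal(math.log(6.7), 0.25, size=n)
    haplogroup = rng.choice(config.haplogroups, size=n, p=config.haplogroup_probs)
    center = rng.integers(config.n_centers, size=n)
    mtdna_cn = rng.lognormal(math.log(95.0), 0.30, size=n)

    # heteroplasmy counts
    age_c = age - 54.5
    log_mu = (
        config.count_intercept
        + config.count_age_coef * age_c
        + config.count_former_coef * (smoking == "former")
        + config.count_current_coef * (smoking == "current")
        + config.count_age_current_interaction * age_c * (smoking == "current")
    )
    if config.count_frailty_var > 0:
        shape = 1.0 / config.count_frailty_var
        frailty = rng.gamma(shape, scale=1.0 / shape, size=n)
    else:
        frailty = np.ones(n)
    counts = rng.poisson(np.exp(log_mu) * frailty)

    # variants
    sample_ids = np.array([f"S{i:06d}" for i in range(n)])
    total = int(counts.sum())
    owner = np.repeat(np.arange(n), counts)
    pos, refs, alts = _draw_variants(rng, total, genemap, config, ok_positions)
    kinds, mlcs = [], []
    for p, a in zip(pos, alts):
        cons = annotate(int(p), a)
        kinds.append(cons.kind)
        mlcs.append(variant_mlc(cons, track, int(p)))
    mlcs = np.array(mlcs) if total else np.zeros(0)
    vaf = 0.05 + 0.90 * rng.beta(
        config.vaf_alpha, config.vaf_beta + config.vaf_mlc_shift * mlcs
    ) if total else np.zeros(0)
    depth = rng.poisson(config.mean_depth, size=total)

    calls = pd.DataFrame(
        {
            "sample_id": sample_ids[owner],
            "pos": pos.astype(int),
            "ref": refs,
            "alt": alts,
            "vaf": vaf,
            "depth": np.maximum(depth, 300),
            "filters": ["PASS"] * total,
            "state": "heteroplasmic",
            "consequence": kinds,
            "mlc": mlcs,
        }
    )

    mss = np.zeros(n)
    np.add.at(mss, owner, mlcs)
    has_kind = {}
    for label, kindset in (
        ("has_nonsense", {"stop_gained"}),
        ("has_synonymous", {"synonymous"}),
        ("has_nonsynonymous", {"missense", "stop_gained", "start_lost", "stop_lost"}),
    ):
        flag = np.zeros(n, dtype=bool)
        sel = np.isin(calls["consequence"].to_numpy(), list(kindset))
        np.logical_or.at(flag, owner[sel], True)
        has_kind[label] = flag

    # survival
    center_loghr = rng.normal(0.0, config.center_log_hazard_sd, size=config.n_centers)
    lp_common = (
        config.loghr_age * age_c
        + config.loghr_male * male
        + config.loghr_former * (smoking == "former")
        + config.loghr_current * (smoking == "current")
        + center_loghr[center]
    )

    def draw_times(rate):
        u = rng.random(n)
        if config.weibull_shape == 1.0:
            return -np.log(u) / rate
        return (-np.log(u) / rate) ** (1.0 / config.weibull_shape)

    if not config.competing_causes:
        lp = lp_common + config.loghr_mss * mss \
            + config.loghr_count_4plus * (counts >= 4)
        t_event = draw_times(config.baseline_hazard * np.exp(lp))
        followup = np.minimum(t_event, config.followup_years)
        event = (t_event <= config.followup_years).astype(int)
        cause = np.where(event == 1, "all", "")
    else:
        shares = {c: s for c, (s, _) in config.cause_spec.items()}
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ValueError("cause baseline shares must sum to 1")
        times, names = [], []
        for cname, (share, loghr_cause) in config.cause_spec.items():
            lp = lp_common + loghr_cause * mss
            times.append(draw_times(config.baseline_hazard * share * np.exp(lp)))
            names.append(cname)
        times = np.vstack(times)
        first = times.argmin(axis=0)
        t_event = times.min(axis=0)
        followup = np.minimum(t_event, config.followup_years)
        event = (t_event <= config.followup_years).astype(int)
        cause = np.where(event == 1, np.array(names)[first], "")
    if event.sum() == 0:
        raise ValueError(
            "no events generated: hazard/censoring configuration infeasible"
        )

    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": np.where(male, "M", "F"),
            "male": male.astype(int),
            "smoking": smoking,
            "alcohol": alcohol,
            "bmi": bmi,
            "wbc": wbc,
            "haplogroup": haplogroup,
            "center": center,
            "mtdna_cn": mtdna_cn,
            "heteroplasmy_count": counts,
            "mss": mss,
            **has_kind,
            "entry_time": 0.0,
            "followup_time": followup,
            "event": event,
            "cause": cause,
        }
    )

    metrics = _gen_metrics(cohort, rng, config)
    calls = _seed_failing_calls(calls, cohort, rng, config, genemap, mask)
    return cohort, calls, metrics


_QC_FAILURES = (
    "low_cn", "contamination", "haplogroup", "numt",
    "min_coverage", "mean_coverage", "high_count",
)


def _gen_metrics(cohort: pd.DataFrame, rng, config: SimConfig) -> list:
    """Per-sample QC records; a configured fraction fail one rule each."""
    metrics = []
    n = len(cohort)
    fail = rng.random(n) < config.qc_fail_fraction
    modes = rng.choice(len(_QC_FAILURES), size=n)
    for i, row in enumerate(cohort.itertuples()):
        rec = qc.SampleQCRecord(
            sample_id=row.sample_id,
            mtdna_cn=float(row.mtdna_cn),
            heteroplasmy_count=int(row.heteroplasmy_count),
            min_base_coverage=float(rng.uniform(300, 900)),
            mean_base_coverage=float(rng.uniform(800, 1500)),
        )
        if fail[i]:
            mode = _QC_FAILURES[modes[i]]
            if mode == "low_cn":
                rec.mtdna_cn = float(rng.uniform(5, 39))
            elif mode == "contamination":
                rec.contamination_flag = True
            elif mode == "haplogroup":
                rec.haplogroup_discordant_variants = int(rng.integers(2, 6))
            elif mode == "numt":
                rec.numt_predicted_variants = int(rng.integers(2, 5))
            elif mode == "min_coverage":
                rec.min_base_coverage = float(rng.uniform(5, 90))
            elif mode == "mean_coverage":
                rec.mean_base_coverage = float(rng.uniform(50, 450))
            elif mode == "high_count":
                rec.heteroplasmy_count = int(rng.integers(6, 12))
        metrics.append(rec)
    return metrics


def _seed_failing_calls(calls, cohort, rng, config, genemap, mask) -> pd.DataFrame:
    """Append raw records that the variant filter must reject."""
    if config.qc_fail_fraction <= 0 or len(cohort) == 0:
        return calls
    n_bad = max(1, int(config.qc_fail_fraction * len(cohort)))
    owners = rng.choice(cohort["sample_id"].to_numpy(), size=4 * n_bad)
    rows = []
    masked = sorted(mask)
    for i in range(n_bad):
        pos = int(rng.integers(1, GENOME_LENGTH + 1))
        ref = genemap.base(pos)
        alt = _TRANSITION_PARTNER[ref]
        common = dict(ref=ref, alt=alt, vaf=float(rng.uniform(0.05, 0.5)),
                      state="heteroplasmic", consequence="unannotated", mlc=np.nan)
        rows.append(dict(sample_id=owners[4 * i], pos=pos, depth=int(rng.integers(30, 299)),
                         filters="PASS", **common))
        rows.append(dict(sample_id=owners[4 * i + 1], pos=pos, depth=600,
                         filters="strand_bias", **common))
        indel = dict(common, alt=ref + "AC")
        rows.append(dict(sample_id=owners[4 * i + 2], pos=pos, depth=600,
                         filters="PASS", **indel))
        if masked:
            mpos = masked[int(rng.integers(len(masked)))]
            mref = genemap.base(mpos)
            rows.append(dict(sample_id=owners[4 * i + 3], pos=mpos, depth=600,
                             filters="PASS", **dict(common, ref=mref,
                                                    alt=_TRANSITION_PARTNER[mref])))
    return pd.concat([calls, pd.DataFrame(rows)], ignore_index=True)


# -- related pairs ------------------------------------------------------------

def gen_relative_pairs(
    config: SimConfig,
    cohort: pd.DataFrame,
    calls: pd.DataFrame,
    seed: int,
    n_mother_child: int = 100,
    n_twin: int = 10,
    n_sibling: int = 0,
    keep_child_somatic: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Designate related pairs and rewrite the second member's calls.

    For a mother/child pair each maternal heteroplasmy is transmitted
    independently with the configured probability; twins and siblings
    use their own probabilities.  By default the second member's calls
    are replaced by the transmitted set (so the pooled shared fraction
    converges to the transmission probability); ``keep_child_somatic``
    retains their own variants as well.
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_mother_child + n_twin + n_sibling
    ids = cohort["sample_id"].to_numpy()
    if 2 * n_pairs > len(ids):
        raise ValueError(f"{n_pairs} pairs need {2 * n_pairs} samples, "
                         f"cohort has {len(ids)}")
    chosen = rng.choice(ids, size=2 * n_pairs, replace=False)
    types = (["mother_child"] * n_mother_child + ["monozygotic_twin"] * n_twin
             + ["full_sibling"] * n_sibling)
    probs = {"mother_child": config.maternal_transmission_p,
             "monozygotic_twin": config.twin_transmission_p,
             "full_sibling": config.sibling_transmission_p}

    pair_rows = []
    keep = calls.copy()
    new_rows = []
    for j, ptype in enumerate(types):
        id1, id2 = chosen[2 * j], chosen[2 * j + 1]
        pair_rows.append((id1, id2, ptype))
        donor = calls[calls["sample_id"] == id1]
        transmitted = donor[rng.random(len(donor)) < probs[ptype]].copy()
        transmitted["sample_id"] = id2
        if not keep_child_somatic:
            keep = keep[keep["sample_id"] != id2]
        new_rows.append(transmitted)
    adjusted = pd.concat([keep] + new_rows, ignore_index=True)
    pairs = pd.DataFrame(pair_rows, columns=["id1", "id2", "relationship"])
    return pairs, adjusted


# -- split reads --------------------------------------------------------------

def gen_split_reads(
    seed: int,
    planted: list[tuple[int, int, int]] = ((314, 955, 5), (8482, 13446, 3)),
    n_singletons: int = 4,
    n_numt_decoys: int = 2,
    decoy_support: int = 3,
) -> pd.DataFrame:
    """Split-read table with planted deletions, singletons and NUMT decoys.

    Planted junctions (5' end, 3' start, support) must be recovered by
    the caller when support >= 2; singleton junctions must not; decoy
    junctions have one mate on an autosome and must be suppressed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    rid = 0

    def add(end3, start5, mate, n_reads):
        nonlocal rid
        if not (1 <= end3 < start5 <= GENOME_LENGTH):
            raise ValueError(f"junction ({end3}, {start5}) outside genome bounds")
        for _ in range(n_reads):
            rows.append((f"r{rid:05d}", end3, start5, mate, "+"))
            rid += 1

    for end3, start5, support in planted:
        add(end3, start5, "chrM", support)
    for _ in range(n_singletons):
        e = int(rng.integers(100, 8000))
        s = e + int(rng.integers(200, 6000))
        add(e, s, "chrM", 1)
    for i in range(n_numt_decoys):
        e = int(rng.integers(100, 8000))
        s = e + int(rng.integers(200, 6000))
        add(e, s, "chrM", decoy_support - 1)
        add(e, s, "chr1", 1)  # one off-contig mate poisons the group
    return pd.DataFrame(rows, columns=["read_id", "end3", "start5",
                                       "mate_chrom", "orientation"])


# -- convenience --------------------------------------------------------------

def write_vcf(calls: pd.DataFrame, path, sample_id: str) -> None:
    """Write one sample's calls as a minimal VCF 4.2 file."""
    sub = calls[calls["sample_id"] == sample_id]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("##contig=<ID=chrM,length=16569>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
        for row in sub.itertuples():
            flt = row.filters if row.filters != "PASS" else "PASS"
            fh.write(
                f"chrM\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t{flt}\t.\t"
                f"AF:DP\t{row.vaf:.4f}:{row.depth}\n"
            )
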
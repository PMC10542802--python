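# Methods

`hetburden` implements a blood-derived mtDNA heteroplasmy burden
analysis: functional annotation of mitochondrial single-nucleotide
variants (SNVs), a local-constraint positional score, a per-individual
burden score, the variant/sample QC cascade, descriptive
population-genetic summaries, and the survival / competing-risks
association suite.  Everything is exercisable end to end on synthetic
cohorts produced by the `simulate` module.

## Reference annotation

The mitochondrial genome is modelled as a 16,569-bp circle.  Gene
coordinates follow the public mitochondrial gene structure, with three
1-bp boundary adjustments at genuinely ambiguous junctions (MT-TK
8295–8365, MT-CO2 7586–8270, MT-ATP6 8527–9207 with MT-CO3 at
9208–9990) chosen so that the eight-way region partition — Complex I /
III / IV / V, D-loop, tRNA, rRNA, unassigned intergenic spacers — has
unique-base tallies of 6349 / 1141 / 3010 / 842 / 1122 / 1505 / 2513 /
87, summing to exactly 16,569.  Overlapping genes (MT-ATP8/MT-ATP6,
MT-ND4L/MT-ND4, MT-TI/MT-TQ, MT-TC/MT-TY) always share a region label,
so the labelling is a strict partition.  These boundary choices are the
package's own convention; published totals constrain but do not uniquely
determine them.

The packaged reference sequence (`data/mtdna_synthetic.fasta`) is a
**synthetic stand-in**, not the rCRS: a seeded random sequence
constrained so every protein gene is a clean open reading frame under
the vertebrate mitochondrial code (translation table 2; AGA/AGG stops,
ATA Met, TGA Trp), with the documented stop-gain examples built in
(m.3308 T>G reads ATA>AGA in MT-ND1; m.15327 C>G reads ACA>AGA in
MT-CYB).  Genes whose length is not a codon multiple end in 1–2 trailing
bases completed to TAA by polyadenylation; substitutions there are
annotated by the completed-codon convention and flagged
(`Consequence.incomplete_stop`).  Light-strand genes (MT-ND6 and eight
tRNAs) are evaluated on the reverse complement.  A position inside two
protein genes is annotated in both frames and the most severe
consequence is reported (stop_gained > start/stop_lost > missense >
synonymous).  A supplied `ref` allele that contradicts the packaged
base is an error, never a silent re-anchor: the pipeline assumes
consensus-adjusted calls upstream.

## Local constraint score (MLC) and burden (MSS)

Input is a site-frequency database with an observed count and a positive
expected count for each of the 49,707 possible SNVs.  For every window
start 1…16,569 (circular wrap at the origin is the default and is
config-visible), the observed and expected counts inside a k-bp window
are summed — at protein-coding positions only missense substitutions
contribute (a change counts as missense if it is missense in **any**
overlapping frame); elsewhere all substitutions contribute — and the
observed:expected ratio's 90% upper confidence bound (OEUF) is computed.
The window length k defaults to 30 bp; it is a required, documented
configuration parameter rather than a published constant.

The confidence bound treats the window's observed total as Poisson and
uses the exact (Garwood) chi-square limits by default; a
profile-likelihood bound is available behind `ci_method="profile"`.
Windows with zero total expected count are flagged and excluded from
position means; positions covered only by flagged windows propagate as
missing.

Each position's mean OEUF over the k windows covering it is
percentile-ranked **descending** to a positional score in [0, 1]: the
largest mean OEUF maps to 0, the smallest (most constrained) to 1, tie
groups share their mean fractional rank, and an all-tied track maps to
0.5 everywhere.  Values closer than 1e-9 (relative) are treated as tied
so running-sum rounding noise cannot split genuine ties.  Note that
because the score is a rank, depleting one region strictly lowers its
mean OEUF pointwise but need not raise every single position's score
(edge positions can be overtaken by interior ones); the region's mean
score does rise, and both behaviours are tested.

Per-variant scores follow the class rule: missense, tRNA, rRNA and
non-coding variants take the positional score; synonymous variants score
0.0, stop gains 1.0, and start/stop losses 0.70.  The per-individual
burden, the MLC score sum (MSS), is the sum of the sample's heteroplasmy
scores, so 0 ≤ MSS ≤ heteroplasmy count.

## QC cascade

Variant level: retain biallelic SNVs with depth ≥ 300 whose FILTER
column carries none of {base_qual, strand_bias, slippage, weak_evidence,
germline, position} (a mapping from the prose flag names is packaged)
and whose position is outside the homopolymer mask; indels are excluded.
The default mask is recomputed from the packaged reference as runs of
≥ 5 identical C/G bases — a stand-in, overridable by a BED file.  Every
rejection carries its first matching reason and retained + rejected
partition the input.

Allele-fraction states: variant alleles at 5–95% are heteroplasmic;
above 95% homoplasmic; below 5% ignored (subthreshold).  The threshold
is configurable (3% and 10% supported for sensitivity analyses) and the
heteroplasmic sets nest monotonically in it.

Sample level: exclude for contamination, ≥ 2 haplogroup-discordant
variants, ≥ 2 predicted-NUMT variants (the count threshold is an
assumption, config-exposed), minimum base coverage < 100x or mean
< 500x (floors are package defaults, not published values), mtDNA copy
number < 40 (a strict ≤ 40 convention is available via `cn_strict`),
missing copy number, or heteroplasmy count ≥ 6.  Reasons accumulate.

Deletions: split reads are grouped by (1st-alignment 3' end,
2nd-alignment 5' start); groups with ≥ 2 supporting reads whose mates
all map to the mitochondrial contig become calls, with VAF
support/(support + spanning) when spanning counts are supplied; a group
containing any off-contig mate is suppressed as a possible NUMT artifact.

## Descriptive summaries

Ti/Tv and dN/dS are unique-variant count ratios (carrier multiplicity
available behind `unique=False`); zero denominators return an infinite
sentinel rather than raising.  Saturation summaries count 3 possible
substitutions per unmasked position per region and split observed unique
variants into heteroplasmic-only / homoplasmic-only / both.  Pair
sharing counts, pooled by relationship type, each pair's union of
heteroplasmies toward the denominator and the intersection toward the
numerator.  The median-VAF contrast applies a two-sided Wilcoxon
rank-sum test to per-variant median VAFs (the choice of test is an
assumption; the comparison is skipped with a notice when a group has
fewer than two variants).

## Association models

Restricted cubic splines use the truncated-power natural-spline basis
with df columns from df + 1 quantile knots (Harrell placement; df = 4
uses the 5th/27.5th/50th/72.5th/95th percentiles); the basis is linear
beyond the boundary knots.

Cox models use the partial likelihood with Efron tie handling,
stratification (separate baseline hazards per assessment center), and
left truncation via an entry column for late-entry designs (prevalent
cases followed from the visit date).  Cause-specific analyses censor
competing causes.  Newton convergence is tightened to 1e-10 so that
degenerate cases are reproducible to numerical accuracy.

The heteroplasmy-count model is a log-linear Poisson regression on an
age spline (4 df), smoking (never reference) and their interaction; the
interaction is tested by likelihood ratio against the reduced model with
a chi-square reference whose df is the number of interaction columns.

Prevalence ratios use marginal standardization of a logistic model: the
mean predicted prevalence with every subject's burden incremented by
one unit divided by the mean prediction at observed values, with a
delta-method CI on the log ratio from the logistic coefficient
covariance.

The subdistribution-hazards (Fine–Gray) fit keeps subjects with a
competing event in the risk set after their event, down-weighted by the
censoring-survival ratio G(t)/G(T), where G is the Kaplan–Meier curve of
the censoring distribution (left-continuous evaluation); the weighted
risk sets are expanded at the event times of interest and fitted as a
weighted start–stop Cox model.  With no competing events the fit
coincides with the cause-specific Cox model (verified to 1e-6 relative).
Standard errors are model-based, not sandwich; the tests cross-check the
coefficient against an independent competing-risks regression routine.

Meta-analysis pools log-scale estimates with fixed-effect inverse
variance by default and reports Cochran's Q and I²; DerSimonian–Laird
random effects are behind a flag (which convention a multi-cohort
replication used is not recoverable, so both are provided).  FDR control
is Benjamini–Hochberg.  `random_heteroplasmy_pick` selects one
heteroplasmy per sample uniformly and reproducibly under a seed.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume:

* **Constraint landscape** — expected counts from a 3-parameter rate
  model (transition weight 28.7, transversion weight 1, strand factor
  1.3 for pyrimidine references); observed counts Poisson around
  expected times a region depletion factor ordered rRNA 0.20 < tRNA
  0.25 < Complex IV 0.40 < Complex I 0.45 < Complex III 0.60 < D-loop
  0.95 < Complex V 1.00, echoing the observed constraint ordering.
* **Covariates** — ages uniform on 40–69 (the recruitment window), 46%
  male, smoking never/former/current at 55/34.5/10.5%, six assessment
  centers with log-normal baseline-hazard offsets (SD 0.25).
* **Heteroplasmy counts** — Poisson with log-mean linear in centred age
  (0.02/yr) and smoking (former +0.05, current +0.15; optional
  age x current interaction), multiplied by a gamma frailty with
  variance 0.4.  The intercept and frailty are calibrated to the
  published count distribution: ~70% zeros, mean ~0.37, and a 4+ tail
  near 0.2% (a pure Poisson underpredicts the tail by ~4x).
* **Variants and VAF** — positions uniform over unmasked sites; alts
  are the transition partner with probability 28.7/29.7; VAF = 0.05 +
  0.90 x Beta(0.8, 4 + 2·MLC), so deleterious (high-MLC) variants sit at
  lower allele fractions, reproducing the nonsynonymous-below-synonymous
  median VAF contrast.
* **Survival** — exponential by default (closed forms for oracles;
  Weibull behind `weibull_shape`), baseline 0.018/yr with administrative
  censoring at 15 years, giving roughly one-third mortality — chosen as
  a long-follow-up cohort condition so that category-level effects are
  estimated with useful precision; hazard multipliers for age
  (0.085/yr), male sex (log-HR 0.40), smoking, and the configured burden
  and count-category effects.  Competing causes are latent exponential
  hazards (leukemia share 1% with per-unit-burden log-HR log 4.97;
  accidents 3% with a null effect; remainder with the all-cause burden
  effect).
* **Effect-size defaults** are the published headline estimates: hazard
  ratio 1.28 per burden unit, 1.50 for 4+ heteroplasmies vs none (used
  when the count-category effect is switched on, with categories 1–3
  null), 4.97 for leukemia mortality.
* **Heritability** — each maternal heteroplasmy is transmitted to the
  child with probability 0.30 (twins 0.95); by default the child's calls
  are replaced by the transmitted set so the pooled shared fraction
  converges to the transmission probability, with `keep_child_somatic`
  for more realistic mixtures.
* **QC exercise** — 2% of samples receive one randomly chosen failing
  metric and failing raw variant records (low depth, caller flag, indel,
  masked position) are appended, so every exclusion reason fires under
  the default configuration.

What the generator does **not** emulate: read-level sequencing error,
NUMT misalignment, haplogroup phylogenetic structure, non-proportional
hazards, or correlation between copy number and heteroplasmy.  Passing
tests therefore demonstrate correctness of the estimators under the
stated models, not robustness to those real-data features.

## Reproduction harnesses and problem sizes

The recovery harnesses simulate cohorts of n = 50,000 over 20 seeded
replicates (per-unit burden and 4+-category effects; the Monte-Carlo
mean is reported with its Monte-Carlo standard error) and n = 30,000
over 6 replicates for the competing-risks leukemia effect.  Test-suite
simulations use 2,000–30,000 samples.  Tolerances follow from the
Monte-Carlo standard errors (estimates are required to sit within two of
them), the exactness of structural constants, and a 1e-6 relative bound
for the competing-risks degeneracy.

## Known limitations

* The packaged sequence is synthetic; annotation results at specific
  real positions (beyond the built-in documented examples) will not
  match the real genome.
* The Fine–Gray implementation reports model-based standard errors and
  expands risk sets at event times, which is O(competing subjects x
  event times); it is intended for cohorts up to the tens of thousands,
  not millions.
* dN/dS is an unnormalized count ratio (per the source definition), not
  a substitution-opportunity-corrected estimator.
* Whether the published score averaged OEUF before or after ranking is
  not recoverable; the literal order (mean OEUF, then rank) is
  implemented.
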
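# hetburden

Mitochondrial DNA exists in hundreds to thousands of copies per cell, so
a somatic mutation is usually **heteroplasmic**: present in only a
fraction of the molecules (operationally, a variant allele fraction of
5–95% in blood sequencing).  `hetburden` is a toolkit for asking whether
the *functional burden* of a person's heteroplasmies — not merely how
many they carry — predicts mortality and disease.  It is aimed at
epidemiologists and statistical geneticists working with cohort-scale
mtDNA variant calls.

Its core is a constraint-based burden score:

1. **MLC (mitochondrial local constraint) positional score.**  For a
   database of observed and expected counts for every possible mtDNA
   substitution, a k-bp window slides over the circular 16,569-bp
   genome.  Per window, oe = Σobs/Σexp (missense changes only inside
   protein genes) and OEUF = the 90% upper confidence bound of oe
   (exact Poisson).  Each position's mean OEUF over its k covering
   windows is percentile-ranked descending to a score in [0, 1], with 1
   the most constrained position.
2. **Per-variant MLC.**  Missense, tRNA, rRNA and non-coding variants
   take their positional score; synonymous, stop-gain and
   start/stop-loss variants take fixed class scores 0.0, 1.0 and 0.70.
3. **MSS (MLC score sum).**  A person's burden is the sum of their
   heteroplasmy scores: MSS = Σᵢ MLCᵢ, so 0 ≤ MSS ≤ heteroplasmy count.

Around the score sit the pieces a full analysis needs: a packaged gene
map with consequence annotation under the vertebrate mitochondrial
genetic code (the reference sequence is a constrained synthetic
stand-in — see `docs/methods.md`); the variant/sample QC cascade (depth
≥ 300, caller FILTER flags, homopolymer mask, indel exclusion, copy
number < 40, heteroplasmy count ≥ 6, contamination/NUMT/coverage
rules); split-read deletion calling; descriptive genetics (Ti/Tv,
dN/dS, saturation, relative-pair sharing, median-VAF contrasts); and the
association suite (stratified Cox with restricted cubic splines and late
entry, Poisson count models with an age x smoking interaction LRT,
marginal prevalence ratios with delta-method CIs, Fine–Gray
subdistribution hazards, Benjamini–Hochberg FDR, inverse-variance
meta-analysis).  A synthetic-cohort generator reproduces the statistical
structure these analyses assume, so everything runs without
access-controlled data.

## Worked example

```python
import numpy as np
from hetburden import load_gene_map
from hetburden.constraint import positional_scores, window_oe, variant_mlc, mss
from hetburden.simulate import SimConfig, gen_constraint_db, gen_cohort
from hetburden.assoc import fit_cox

genemap = load_gene_map()
config = SimConfig(n_samples=20_000)

# constraint landscape and positional scores
db = gen_constraint_db(genemap, config, seed=11)
track = positional_scores(window_oe(db, genemap, k=30))

# a stop-gain variant scores 1.0 by the class rule
cons = genemap.annotate_substitution(3308, "T", "G")
print(cons.kind, variant_mlc(cons, track, 3308))   # stop_gained 1.0

# simulate a cohort and estimate the burden-mortality association
cohort, calls, metrics = gen_cohort(config, genemap, track, seed=5)
est, _ = fit_cox(
    cohort, exposure="mss",
    covariates=[("rcs", "age", 4), "male", ("cat", "smoking", "never")],
    strata="center",
)
e = est["mss"]
print(f"HR per 1-unit MSS: {e.estimate:.2f} ({e.ci_low:.2f}, {e.ci_high:.2f})")
```

Output from this exact script:

```
stop_gained 1.0
HR per 1-unit MSS: 1.22 (1.15, 1.30)
```

The generator's true per-unit-MSS hazard ratio is 1.28 by default; the
fitted 1.22 with a CI of (1.15, 1.30) is one stratified Cox draw
recovering it from 20,000 simulated subjects (the recovery harness in
`hetburden.harness` averages twenty such replicates).

A thin CLI wraps the same functions:

```sh
hetburden simulate --n 5000 --seed 1 --out-dir sim/
hetburden mlc --db sim/site_frequency.tsv -k 30 --out sim/track.tsv
hetburden qc --vcf calls.vcf --out-calls calls.tsv --out-ledger ledger.json
hetburden assoc --cohort sim/cohort.tsv --strata center --out assoc.json
```

## Layout

```
src/hetburden/
  reference.py    gene map, genetic code, consequence annotation
  constraint.py   windowed OEUF, positional scores, variant MLC, MSS
  qc.py           variant/sample filter cascade, deletion calling
  cohortstats.py  Ti/Tv, dN/dS, saturation, pair sharing, VAF contrasts
  assoc.py        Cox / Poisson / PR / Fine-Gray / meta / FDR
  simulate.py     synthetic cohort generator
  harness.py      seeded parameter-recovery harnesses
  data/           gene map TSV + synthetic reference FASTA
docs/methods.md   model and design notes
```
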
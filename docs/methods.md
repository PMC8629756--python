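# Methods

This note documents the statistical procedure `rarescreen` implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details that affect
results.

## The screening procedure

The pipeline decides, for every (gene, phecode, model) triple, whether the
pair is a population-screening candidate. Five stages run in order:

1. **Collapse.** Variants and CNVs are qualified clause by clause
   (consequence set, deleteriousness, frequency; CNV type, exon overlap,
   QC, frequency) and collapsed to a binary samples × genes burden matrix
   per model (`coding`, `lof`). Genes with zero carriers keep all-zero
   columns so the gene universe is stable across stages.
2. **Phenotype.** Dated ICD events map to phecodes through per-dialect
   maps; case status is "phecode recorded at least once". The five-year
   history rule gates only age at first diagnosis, not case membership:
   the history requirement exists to make onset ages trustworthy, and
   excluding short-history cases from case status would discard true
   diagnoses. Phenotypes must have ≥ 1 case in the larger cohort and ≥ 30
   in the smaller.
3. **Associate.** Firth-penalized logistic regression of phenotype on
   burden plus age, sex, age·sex, age², sex·age². Alongside the test, the
   2×2 table, Haldane–Anscombe-corrected odds ratio, and stratified PPVs
   are computed from the same columns.
4. **Meta-analysis.** METAL-style weighted Z with effective-sample-size
   weights n_eff = 4/(1/cases + 1/controls) — the standard choice for
   binary traits, since a cohort's information is governed by its case
   count, not its raw size; raw-n weighting is available as a config
   option. Significance requires ≥ 1 carrier in both cohorts, meta p
   strictly better than both cohort p values, and meta p < 1×10⁻⁹.
5. **Screen.** Candidate iff risk-increasing and PPV ≥ 0.3 in both cohorts
   in the all-ages or the 60+ stratum.

## Open choices and how they were resolved

- **"Not PolyPhen or SIFT benign."** Read conjunctively against benignness:
  a variant is dropped if *either* predictor calls it benign
  (`benign_rule="either"`, the stricter reading, matching the intent of
  enriching for damaging variants). The lenient both-benign reading is a
  config switch.
- **Missing deleteriousness scores** count as *not* benign. The predictors
  do not score non-missense consequences; treating missing as benign would
  delete every LoF variant from the coding model, contradicting the nested
  structure of the two consequence sets.
- **Missing gnomAD population frequencies** are treated as 0 — absence of
  evidence of commonness. The frequency rule is strict (< 0.1%), applied to
  the maximum over populations and the local frequency.
- **Test statistic.** The production analysis this models uses whole-genome
  ridge regression to absorb relatedness and stratification at biobank
  scale; with unrelated samples those terms vanish and the test reduces to
  a covariate-adjusted logistic regression. Firth's Jeffreys-prior penalty
  handles the separation and imbalance regime (a gene with 10 carriers, all
  cases, still yields a finite estimate). P-values come from the penalized
  likelihood-ratio statistic; the constrained (null) fit keeps the burden
  column in the design with its coefficient fixed at zero, so both
  likelihoods share one penalty (the `logistf` convention). Wald p-values
  are a config option.
- **Odds ratios** are reported from the contingency table (with the 0.5
  correction applied to all cells only when some cell is zero), not from
  the regression; the regression beta is reported alongside.
- **60+ stratum** is defined by age at data extraction, approximating
  lifetime risk with a cohort old enough to have expressed it; age at
  diagnosis would conflate onset timing with risk.
- **Under-sized 60+ strata.** When one cohort's 60+ stratum has no or
  too few (< 5) carrier cases while the other cohort passes there, the
  default policy lets that cohort's all-ages PPV stand in, flagging the
  triple for manual review. This keeps genuinely high-PPV genes whose few
  carriers happen to be young from failing on an empty denominator. A
  strict policy is a config switch.
- **Protective associations** (z_meta < 0) are excluded from PPV screening
  but retained in the full table — "carriers develop the disease" is not a
  useful screening message when carriage lowers risk.
- **Meta-better-than-both** and Bonferroni comparisons are strict
  inequalities.
- **Controls** are "phecode absent"; phecode exclusion ranges are not
  applied. Sex-restricted analyses are supported by filtering samples and
  dropping the sex terms from the design.

## The synthetic-data generator

`generate_cohorts` emulates the study design the analysis assumes: two
cohorts of unequal size (defaults 20,000 and 5,000), different sex ratios
(55% vs 68% female), age ranges (40–69 vs 18–89), ICD dialect mixes
(ICD-9 + ICD-10 vs ICD-9 + ICD-10-CM), and CNV calling in the smaller
cohort only. Per gene it draws carriers at the configured frequency,
assigns each carrier a qualifying event (LoF or damaging missense site, or
an exonic deletion for a configurable fraction of carriers in CNV-enabled
cohorts), and interleaves four decoy classes — synonymous, benign missense,
gnomAD-common, locally-common — plus QC-fail, common, and duplication CNV
decoys, one per filter clause, so each clause is independently exercised.

Carriers of a causal gene acquire its target phecode with probability
exactly equal to the configured penetrance; non-carriers with the
background prevalence. Cases emit ICD codes that resolve through the
bundled fixture map back to exactly the intended phecode; a configurable
fraction (default 90%) of records satisfy the five-year history rule. All
draws flow from generators keyed by (seed, cohort, gene/phecode index):
output is bit-reproducible and appending genes leaves earlier draws
untouched.

Default causal genes span penetrance 0.8–0.4 and carrier frequency
0.4–0.15%, the regime where a dual-cohort screen at this scale retains
power (at penetrance near the 0.3 threshold the screen is borderline *by
construction*: the observed PPV of a gene with true penetrance 0.3 falls
below 0.3 about half the time). Variant records carry the generative
allele frequency rather than the in-sample count ratio, as a production
annotation computed on the full source population would; at reduced cohort
sizes the in-sample ratio of a truly rare allele would overstate its
frequency and mis-trip the 0.1% filter.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, relatedness, population stratification, ancestry-
specific frequencies, sequencing/annotation error, phecode hierarchies, or
age-dependent onset (penetrance is lifetime by default). Passing tests
therefore certify the decision logic and its statistical calibration under
the stated sampling model, not robustness to those real-data complications
— in production those are handled upstream (whole-genome regression,
ancestry covariates, VEP annotation).

## Calibration studies and problem sizes

- **Null p-value uniformity** runs at 2,000 samples, 100 genes × 10
  phenotypes, carrier fraction 10%, prevalence 20% — a moderate-count
  regime where the χ²₁ asymptotics of the penalized LRT hold. At
  rare-variant carrier counts (tens of carriers) the null p-value
  distribution is inherently discrete and conservative; no continuous
  uniformity check is meaningful there. P-values are spread over several
  independent phenotype draws because tests sharing one phenotype
  realization are correlated, inflating the empirical-CDF variance the KS
  test measures.
- **Type-I control at rare-variant scale** uses all-null two-cohort runs
  (3,000 + 1,200 samples, 100 genes × 10 phecodes, carrier frequency 0.3%,
  prevalence 5%) and counts triples passing the full significance gate;
  with ~1,000 triples per run and α = 10⁻⁹ the expected count is ~0 and
  the study requires exactly 0.
- **Penetrance recovery** runs the full pipeline (coding model — it
  contains every qualifying event, so recovery does not depend on the LoF
  mixture) on default-scale replicates and checks that carrier-case counts
  fall in the central 95% binomial band around true penetrance, and that
  causal genes come out as candidates.

These sizes were chosen so each study completes in minutes on one CPU
while keeping ≥ 10 expected carriers per gene in the smaller cohort.

## Numerical details

- Firth–Newton iterations use the modified score
  U*(β) = Xᵀ(y − μ + h(½ − μ)) with hat diagonals h from the full-design
  information matrix, step-halving on the penalized likelihood, and
  convergence at step < 10⁻⁹. Covariate columns are centered and scaled
  internally (the burden coefficient is unaffected); collinear covariates
  are dropped by pivoted QR with a warning.
- P-values are floored at the smallest positive double so downstream
  log-transforms and strict-inequality gates behave.
- PPV with zero carriers in a stratum is a distinguished *undefined* value
  (None/NaN), never 0 — the screen treats "no evidence" differently from
  "evidence of 0".
- Ties in report ordering are broken by stable sorts on (candidacy,
  meta p), and per-gene best-PPV selection on (min-across-cohorts PPV,
  meta p), so output files are deterministic.
- ICD codes and phecodes are strings everywhere; decimal points and
  leading zeros survive every round trip.

## Known limitations

- Exactly two cohorts; the meta-analysis interface would generalize but is
  deliberately not generalized here.
- No phecode hierarchy roll-ups or PheWAS exclusion ranges.
- The Firth LRT is asymptotic; at very small carrier counts its p-values
  are conservative (this is the safe direction for a Bonferroni screen).
- CNV–gene overlap is taken from the caller's table as given; events are
  not re-intersected with exon models.
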
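# Methods

## Scope and model

The package implements the analysis chain of a haplotype fine-mapping
study of a single LD block: case/control cohorts genotyped at a small
ordered panel of biallelic markers (here 10: four SNPs and six deletions
at 5q22.1, deletion alleles written `-`), EM phasing, per-haplotype 2×2
association, haplotype-guided selection of a targeted-sequencing subset,
read-level QC, an exact co-segregation scan, and a gene-level LOF burden
test.  Because the markers sit in one block of strong LD (r² ≥ 0.80), no
recombination or LD-decay modelling is attempted anywhere: a haplotype is
simply an allele string over the panel.

Alignment, variant calling and annotation are out of scope; the variant
stage consumes a VCF (GT fields only, biallelic sites) plus an
ANNOVAR-style annotation table and a cohort-label table.

## Haplotype frequency estimation (EM)

Under random mating the observed-data likelihood of genotype *g* is
Σ over compatible diplotypes of (2 − δ) f_{h1} f_{h2}; a genotype with
*h* heterozygous markers has 2^(h−1) compatible diplotypes, enumerated
explicitly (≤ 512 for 10 markers).  The EM fixed-point map alternates
expected diplotype counts with frequency updates f = counts / 2n;
individuals are grouped by identical genotype pattern so the E-step cost
scales with the number of distinct patterns, not individuals.

Numerical choices:

* **Acceleration.** The EM map is accelerated with safeguarded SQUAREM:
  two plain steps, extrapolation along the fixed-point residual, and a
  fallback to the plain double step whenever the extrapolated point does
  not improve the likelihood.  This preserves EM's monotone likelihood
  (asserted at every accepted iterate) while converging superlinearly on
  the near-flat ridges where plain EM needs 10⁴–10⁶ iterations.
* **Multistart.** The likelihood of small multilocus samples can be
  multimodal: the natural single start (product of per-marker allele
  frequencies) demonstrably lands in local optima on some small instances.
  The map is therefore run from a fixed list of starts — the product
  start, the uniform vector, and eight Dirichlet draws from a hard-coded
  seed — and the highest-likelihood stationary point is kept.  The start
  list is the same on every run, so the estimator remains fully
  deterministic.
* **Convergence** at |Δ log L| < 1e-8 (default) or 1000 EM-map
  applications, counted across starts.
* **Missing data.** Individuals with any missing genotype are excluded
  before the EM with a logged count; no imputation.  This is the
  conservative reproducible choice for a panel whose missingness process
  is unknown.
* **Per-cohort frequencies** are the final E-step's expected haplotype
  counts of each cohort's individuals divided by twice the cohort size —
  one pooled likelihood, cohort-resolved read-out.
* **Assignments** are the maximum-posterior compatible diplotype under the
  final frequencies; exact posterior ties are broken by lexicographic
  order of the sorted allele-string pair (tested).  Haplotypes with pooled
  frequency below 1e-7 are pruned from the table unless referenced by an
  assignment.
* **Labels** H1..Hk are assigned in lexicographic order of allele string.
  Published haplotype labels follow a different (unstated) numbering, so
  cross-referencing between the two is by allele string only.

This estimator deliberately replaces a coalescent-prior MCMC phaser: at
the scale of one LD block the estimand (the haplotype frequency vector)
is identical, and a deterministic EM is exactly reproducible and directly
testable against an independent likelihood maximiser.

### Validation against an independent oracle

The test suite maximises the same likelihood by SLSQP on the frequency
simplex (analytic gradient, 13 deterministic starts) — an optimisation
route that shares no code with the EM — and requires total-variation
agreement within 1e-4 on 100 random 3-marker instances of ≤ 20
individuals.  About 2% of unconstrained random draws have a non-identified
maximum (the oracle itself finds distinct equal-likelihood optima, e.g.
symmetric double-heterozygote configurations); frequency comparison is
ill-posed there, so the instance generator redraws them, with the
detection based solely on the oracle's own multi-start spread.  EM
likelihood-level global optimality (ll_EM ≥ ll_oracle − 1e-6) is asserted
on every instance, identified or not.

## Association statistics

All tests share one statistic on a 2×2 allele-count table: Pearson χ²
(1 df, no continuity correction; Yates' correction behind a flag), odds
ratio ad/bc, and the Woolf log-OR interval with z = 1.96.  Recomputation
from the published integer counts reproduces the printed gene-level values
exactly at 2 decimals (e.g. χ² 15.72, OR 0.33, CI 0.19–0.58 for the top
gene), which is what fixed the no-correction and Woolf choices.  A few
published rows differ by one unit in the last printed digit from any
integer-count recomputation (they were evidently computed from unrounded
intermediates); these are asserted to one printed ulp and not chased
further.  One published row is internally inconsistent (a zero alt cell
alongside OR 1.07) and is treated as an erratum.

Zero cells make the OR/CI undefined (returned NaN; χ²/p still computed
while both margins are positive); an empty allele margin voids the whole
test.  A Haldane–Anscombe +0.5 option exists but is off by default, and
raw p-values are reported (Bonferroni behind a flag), both matching the
emulated study's reporting.

Haplotype dosages for the scan are hard maximum-posterior calls, because
the downstream sample selection operates on discrete diplotype labels;
posterior-weighted dosages can be formed from the frequency table if
needed but are not the default.  r² between markers is computed on phased
haplotype counts, D²/(p₁q₁p₂q₂).

## Sequencing-sample selection

Four rules in strict order: (1) target-haplotype homozygotes, (2)
heterozygotes, (3) one carrier of each still-unrepresented common
haplotype (pooled frequency > 0.5%), (4) reference non-carriers (default
2).  Two design points were genuinely open and resolved as follows:

* A literal greedy reading lets rule 2 absorb every slot in a large
  cohort, making rules 3–4 unsatisfiable; rules 1–2 therefore admit a
  carrier only if enough capacity remains for one slot per unrepresented
  carried common haplotype plus the outstanding reference quota (a
  conservative bound — one diplotype can cover two haplotypes).
  Non-carriers admitted by any rule count toward the reference quota.
* Case/control balance is enforced by alternating cohort picks within
  each rule (the emulated study's 8/8 split is otherwise unexplained),
  ties broken by sample_id, and remaining slack is backfilled (target
  carriers first) so a sufficient cohort yields exactly n_total samples.

DNA-quality screening is modelled as an optional boolean eligibility map
(all eligible by default).  The procedure is deterministic given its
inputs.

## Read QC

A read is removed iff it contains the adapter as an exact substring, or
strictly more than 50% of its bases have Phred ≤ 5, or strictly more than
10% are `N`; attribution is to the first violated rule in that order.
`N` bases keep whatever quality the FASTQ assigns them in the low-quality
denominator.  Exact matching is the default because no published matching
algorithm is available; a max-mismatch option exists.  GC content is
(G+C)/(A+C+G+T) over clean reads, NaN for all-`N` input.  Adapter
sequence is a required argument — none is assumed.

## LOF classification, burden, co-segregation

The qualifying-variant ("LOF") definition — exonic, UTR (UTR3/UTR5),
splicing, upstream — is the emulated study's own and is intentionally
broader than molecular LOF; it is a configurable set precisely because it
is unconventional.  The burden test interprets the published "Alt (N) /
Ref (N)" columns as allele observations summed over LOF sites × samples
× 2 alleles; this interpretation reproduces the printed per-gene counts'
structure (cohort total = 2 × 8 samples × n_sites) and statistics exactly,
and is therefore adopted.  Genes with fewer than two qualifying sites are
reported untested.  The co-segregation scan requires exact equality of a
site's dosage vector with the target haplotype's copy-number vector over
all sequenced samples; an empty result is a valid outcome (and the
expected one under the default, no-planting configuration).

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
sequence-level realism:

* **Diplotypes** are drawn i.i.d. from cohort-specific haplotype frequency
  maps (cohort-wise random mating, Hardy–Weinberg within cohort — tested
  by χ² goodness of fit).  The default frequencies are the seven published
  common haplotypes (> 0.5%) with each cohort's column renormalised to sum
  to 1, since the full 62-haplotype vector was never published; cohort
  sizes default to 500/500 for desk-scale runs.  The published table marks
  deletion alleles typographically (strikethrough), which no plain-text
  encoding preserves, so deletion alleles are coded `-` and the
  deletion-bearing strings are this package's own consistent encoding.
* **LOF dosages** are Binomial(2, alt_freq) per sample×site with
  cohort-specific frequencies, independent of the diplotype — the null
  fixture, reflecting the published finding of no haplotype-linked
  variant.  Default per-gene site counts and alt frequencies are recovered
  from the published count structure.  An optional planted site tracks a
  target haplotype's copy number exactly (the positive control).
* **Reads** are constructed strictly beyond or strictly within each QC
  threshold with labelled ground truth; violating reads violate exactly
  one rule each.  No error-profile or fragment-length realism is
  attempted.
* **Determinism**: one master seed with fixed per-stage substreams;
  identical configuration gives bit-identical output (tested, including
  byte-identical pipeline summaries).

Consequences for interpretation: passing tests demonstrate correctness of
the estimators and procedures under the assumed generating model (random
mating, site independence, clean biallelic calls).  They do not speak to
genotyping error, population structure, relatedness, LD decay across
blocks, or alignment/calling artefacts, none of which the generator
emulates.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the checks
sharp but quick: oracle comparisons on 3-marker instances of ≤ 20
individuals (100 instances), frequency recovery at 2 000 individuals × 20
seeds (binomial s.e. ≈ 0.008 per frequency, against a 0.02 RMSE bound),
type-I calibration with 400 tests per statistic (binomial 95% band
0.05 ± 0.021), co-segregation recovery over 50 seeds of 16-sample
sequencing subsets, and read-filter fidelity over 3 000 constructed reads.
The published cohort scale (3 624 / 5 076) is used only where it enters a
closed-form computation (frequency-parameterised odds ratios).

## Known limitations

* Phase uncertainty is collapsed to hard diplotype calls downstream;
  credible intervals on haplotype frequencies are not produced.
* The burden statistic treats allele observations across sites within a
  sample as independent Bernoulli draws, as the emulated analysis did;
  within-gene LD between rare variants is ignored.
* χ² calibration degrades for very rare haplotypes (expected cell counts
  < 5); the type-I checks use designs with adequate expected counts, and
  no exact-test fallback is provided.
* The co-segregation criterion is exact equality; a single genotyping or
  phasing error breaks a true match.  This mirrors the emulated manual
  procedure and is intentional.
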
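# hapburden

Haplotype association and gene-level loss-of-function (LOF) burden analysis
for targeted case-control sequencing studies, modelled on the analysis of
the 5q22.1 atopic-dermatitis locus: a 10-marker haplotype block (4 SNPs +
6 deletions in strong LD, r² ≥ 0.80) is phased by EM in large case/control
cohorts, the top-associated haplotype guides selection of a small targeted
sequencing subset, and the sequencing data feed a co-segregation scan and a
per-gene LOF burden test.  A synthetic-data generator reproduces the
statistical structure of every stage, so the whole pipeline is testable
offline with known ground truth.

## Who it is for

Statistical geneticists who want a small, fully deterministic, testable
implementation of the classic haplotype fine-mapping workflow:
PHASE-style phasing is replaced by a deterministic Excoffier–Slatkin EM,
and PLINK-style association by an in-package Pearson χ² / odds-ratio /
Woolf-CI implementation, so every number is reproducible from first
principles.

## The statistics

For unphased genotypes *g* over a biallelic panel, haplotype frequencies
*f* maximise the random-mating likelihood

    P(g | f) = Σ_{ {h₁,h₂} compatible with g }  (2 − δ_{h₁h₂}) f_{h₁} f_{h₂}

via EM (expected diplotype counts ↔ frequency updates), accelerated by
safeguarded SQUAREM and run from a fixed set of starts.  Association and
burden tests share one 2×2 allele-count statistic, for case alt/ref counts
*a*,*b* and control counts *c*,*d*:

    χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d   (1 df)
    OR = ad / bc,   95% CI = exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))

with no continuity correction.  The gene-level burden test collapses each
gene's qualifying variants (annotated exonic / UTR / splicing / upstream)
into cohort allele observations (alt + ref = 2 × n_samples × n_sites) and
tests genes with ≥ 2 qualifying sites.  The co-segregation scan flags
sites whose alt-dosage vector equals the target haplotype's copy-number
vector exactly across all sequenced samples.

## Worked example

One command runs the full chain (simulate → phase → associate → select →
read QC → LOF classify → co-segregation → burden) at desk scale
(500 cases / 500 controls drawn from the seven common published
haplotypes):

```sh
hapburden run --out-dir demo --seed 1
```

prints

```
pipeline complete: target haplotype H3, 0 co-segregating site(s), 11 genes in burden table -> demo
```

The top of `demo/assoc.tsv` shows the scan that picked the target (counts
are haplotype copies among 2N chromosomes per cohort; frequencies in %):

```
hap_id  a   b    c   d    maf_case_pct  maf_control_pct  chi2   p        OR
H3      3   997  23  977  0.3           2.3              15.59  7.9e-05  0.13
H4      8   992  30  970  0.8           3.0              12.98  3.1e-04  0.26
```

H3/H4 are the two rare protective haplotypes of the simulated design (the
labels are lexicographic; the H15-like haplotype of the published study is
H4 in this run).  `demo/burden.tsv` starts with the TMEM232-like gene,
whose simulated case/control alt frequencies follow the published counts:

```
gene     n_lof_sites  alt_case  ref_case  alt_control  ref_control  chi2   p        OR
TMEM232  12           13        107       76           188          14.94  1.1e-04  0.30
```

and `demo/summary.json` collects every table.  Zero co-segregating sites is
the expected outcome under the default configuration, which plants none —
matching the published finding that no LOF variant tracked the risk
haplotype.

Each stage is also available on its own (`hapburden simulate | phase |
assoc | select | readqc | burden | coseg`); run any of them with `--help`.

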
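# ystrkit

Tools for Y-chromosome STR haplogroup analysis:

* **haplotype_io** — tab-separated Y-STR haplotype tables (Yfiler-style),
  per-locus mutation-rate tables, and a nested SNP hierarchy with paragroup
  terminal states and partial-typing codes. Yfiler normalization drops
  DYS385a/b and replaces DYS389II by DYS389II − DYS389I.
* **rho_dating** — haplogroup age estimation from STR variation with the
  mutation-rate-weighted ρ statistic (per-locus distances to the median
  haplotype scaled by mean/locus rate), its standard deviation, symmetric
  95% CIs, optional median+k·MAD outlier removal, an unweighted ρ for
  whole-chromosome derived-mutation counts, and per-population diversity
  reports (k, haplotype diversity, allele variance, pairwise-difference
  distributions).
* **subhaplogroup_freq** — terminal subhaplogroup frequencies per population
  when some individuals carry only partial SNP typings, by single-pass
  proportional allocation over the SNP tree (within-population proportions,
  pooled fallback).
* **synthetic_data** — a haploid coalescent simulator (constant size or
  exponential growth) with a Generalized Stepwise Mutation model
  (geometric step size, reflecting at repeat count 1), a multi-population
  study generator with known ground truth, and simulated partial typing.
  Hot loops are numba-compiled; the coalescent is cross-validated against
  msprime in the test suite.
* **abc_pipeline** — Approximate Bayesian Computation over the simulator:
  log-uniform/uniform priors, per-locus summary statistics (distinct
  alleles, gene diversity, allelic range, Garza–Williamson index; optional
  haplotype-level K/H components), model choice by rejection and weighted
  multinomial logistic regression, parameter estimation by
  Epanechnikov-weighted local-linear regression after a logtan transform,
  weighted 95% HPD intervals, and a PCA goodness-of-fit check.

## CLI

```sh
# simulate a haplotype table under exponential growth
ystrkit simulate --model growth --na 131 --nc 72811 --tstart 103 \
    --n 758 --gsm-p 0.046 --seed 1 --out haps.tsv

# weighted-rho ages per population (Table-3-shaped TSV)
ystrkit date --haps haps.tsv --group-by population \
    --generation-time 32.5 --outliers mad:5 --out ages.tsv

# unweighted rho from per-individual derived-mutation counts
ystrkit date-seq --counts counts.tsv --ypm 108.7

# subhaplogroup frequencies with partial-genotype allocation
ystrkit freq --haps haps.tsv --tree tree.yaml --out freqs.tsv

# ABC: reference table, then model choice + parameter estimation
ystrkit abc build-ref --models constant,growth --n-sims 20000 \
    --n-sample 758 --seed 1 --extra-haplotype-stats --out ref.tsv
ystrkit abc fit --ref ref.tsv --haps haps.tsv \
    --tolerances 0.005,0.01,0.05 --retain 0.05 --out result.json
```

A frozen example Yfiler mutation-rate table ships with the package
(`ystrkit.example_rates()`); pass `--rates your_rates.tsv` (columns `locus`,
`rate_per_generation`) to substitute your own.

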
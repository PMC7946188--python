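# Methods

Model definitions, parameter defaults, numerical choices, and the scope of
the synthetic generators. Units throughout: genetic positions in the
EIGENSTRAT `.snp` file are **Morgans**; ROH lengths and map-block sizes are
**centimorgans** (cM); physical positions are 1-based base pairs.

## Genotype representation

Genotypes are alt-allele dosages in an `individuals × SNPs` int8 array:
0/1/2 for diploid calls, 0/1 for pseudo-haploid, −1 for missing. Only the
ASCII EIGENSTRAT dialect is supported (one row per SNP, one digit per
individual, `9` = missing). `pseudo_haploidize` maps homozygotes
deterministically and resolves heterozygotes by a fair coin under the given
seed — the standard reduction when confident diploid calls are unavailable.

The genetic map defaults to sex-averaged lengths for the 22 human autosomes
(3545.0 cM total); all functions accept a custom `{chromosome: cM}` map so
reduced synthetic genomes flow through identical code paths.

## Authenticity QC and genetic sex (`paleokin.qc`)

Four count-based criteria, each `pass` / `fail` / `not_evaluable`:

| criterion | statistic | rule | default |
|---|---|---|---|
| damage | terminal C→T rate | rate ≥ threshold | 3% |
| mt consensus | match rate, 95% CI | CI upper bound > threshold | 98% |
| X polymorphism | poly-site rate in males | CI lower bound < threshold | 1%, needs ≥ 200 sites |
| genetic sex | Y/(X+Y) read fraction | male > 35%, female < 3% | strict inequalities |

Confidence bounds use the Wilson score interval (Clopper–Pearson available
via `ci_method="clopper-pearson"`); both are delegated to
`statsmodels.stats.proportion.proportion_confint` rather than reimplemented.
An individual passes overall iff damage passes and no other criterion fails;
`not_evaluable` (females for the X test, zero denominators) never fails
anyone.

## Pairwise kinship (`paleokin.kinship`)

For pseudo-haploid calls, the probability that two individuals' overlapping
calls differ is `(1 − φ)·base`, with φ the kinship coefficient and `base`
the unrelated-pair mismatch rate. With `b = base/2`,

```
r = 1 − ((x − b)/b) = 2 − x/b,    E[r] = 2φ.
```

`base` is calibrated as the **median** pairwise mismatch among individuals
with more than 100,000 covered SNPs (strict >), which is robust as long as
most pairs are unrelated. Pairs need ≥ 15,000 overlapping SNPs to be
classified (both floors are configurable and the pipeline caps them at
50% / 10% of the panel for small synthetic panels).

Mismatch and overlap counts are computed per 5-cM genetic-map block with
BLAS matrix products (`mism = B Cᵀ + C Bᵀ` for masked calls `B = m·a`,
`C = m·(1−a)`); the per-block counts feed a delete-one-block jackknife for
`se_r`, which is robust to linkage.

Degree windows on r are midpoints of the expected values on a halving scale:
identical ≥ 0.7, first [0.35, 0.7), second [0.1875, 0.35), third
[0.09375, 0.1875), unrelated below. An estimate within 2·`se_r` of a window
boundary is reported `unresolved` instead of forced into a class. "Close
kin" means third degree or closer.

## Pedigree consistency (`paleokin.pedigree`)

Expected kinship uses the full recursion `φ(a,a) = (1 + φ(father, mother))/2`
and `φ(a,b) = (φ(mother_a, b) + φ(father_a, b))/2`, recursing on the
individual with the deeper pedigree; founders are mutually unrelated but
inbreeding inside the pedigree is handled exactly. Consistency rules:

- **R1** a child shares the mother's mtDNA lineage;
- **R2** a son shares the father's Y lineage;
- **R3** each sampled pair's observed degree class matches the expected-r
  window (an `unresolved` estimate is accepted if within one class);
- **R4** proposed mothers/fathers have compatible sex calls.

Unsampled placeholder parents are exempt from R1/R2/R4. Relationships with
equal φ (half-siblings, avuncular, grandparent–grandchild, all φ = 1/8) are
one equivalence class for autosomal data; the checks preserve that ambiguity.
`lineage_diversity` counts distinct mtDNA lineages (everyone) and Y lineages
(males only); `unrelated_fraction` is the share of the cohort with no close
relative.

## ROH and effective size (`paleokin.roh`)

Per-individual summaries report total length in the > 4 / > 8 / > 12 / > 20 cM
classes (strict >) and segment counts in [4,8), [8,12), [12,20) cM. Any ROH
sum > 20 cM flags close-kin parental inbreeding. Individuals need ≥ 400,000
covered SNPs (inclusive) to enter cohort ROH statistics.

Under a constant-size panmictic coalescent, the two haplotypes coalesce `t`
generations ago with `P_N(t) = (1/2N)(1 − 1/2N)^(t−1)`, and conditional on
`t` homozygous tracts break at rate `2t` per Morgan. The expected number of
ROH of length `l ∈ [l₁, l₂]` Morgans sums over chromosomes of map length `G`:

```
E = Σ_c ∫_{l₁}^{l₂} Σ_t P_N(t) [ (G_c − l)(2t)² + 2(2t) ] e^{−2tl} dl
```

evaluated with closed-form integrals; the t-sum is truncated where
`exp(−2t·l₁) < 1e−15` (t ≤ 433 for l₁ = 4 cM), making the cost independent
of N rather than proportional to it. Nₑ is estimated by maximising the
Poisson likelihood of the three bin totals over `log₁₀N ∈ [2, 7]`
(`scipy.optimize.minimize_scalar`, bounded); the 95% CI is the profile
likelihood within 1.92 log-units of the maximum, found by `brentq`. With
zero observed segments the likelihood is monotone in N, so the estimate is
reported at the upper search bound with a one-sided CI and `at_bound=True`.

`simple_roh_caller` is deliberately minimal (1-cM windows with at most a
configurable number of heterozygous calls, runs ≥ 4 cM): it is plumbing for
dense synthetic diploid data, not a substitute for haplotype-copying callers
on sparse real data.

## f4 and admixture (`paleokin.admixture`)

`f4(A,B;C,D)` is the complete-case mean of `(p_A − p_B)(p_C − p_D)`; its
standard error is a weighted delete-one block jackknife over 5-cM map blocks.
`qpadm_lite` models a target's f4-vector `F_t[j] = f4(T,O₁;O_j,O₁)` as a
weighted sum of the sources' vectors, solving a sum-to-one-constrained GLS
with the block-jackknife covariance of the residual vector as weight matrix
(two-step feasible GLS: OLS weights first, covariance at those weights, then
the GLS re-fit). All statistics for one fit share a single complete-case SNP
mask so f4 linearity holds exactly. Weight standard errors come from
delete-one-block re-estimation. Indistinguishable sources raise
`SingularModelError` (SVD rank check on the centred source design); a
numerically singular jackknife covariance falls back to its diagonal, and an
exactly zero one (noise-free data) to ordinary least squares. This is a
deliberately reduced qpAdm: one mixture fit, no rank tests or nested-model
p-values.

## Synthetic generators (`paleokin.simulate`)

- **Genotypes**: founders draw alleles from shared frequencies
  (uniform on [0.05, 0.95] by default); children by Mendelian transmission,
  either per-SNP independent (correct for all mismatch/kinship expectations)
  or as linked haplotype mosaics with Poisson crossovers at 1/Morgan when
  ROH realism matters. Per-individual coverage is uniform on [0.85, 1.0].
- **Read counts**: binomial draws around configurable damage and
  contamination rates; Y-read fraction centres at 0.45 (males) / 0.005
  (females).
- **ROH lengths**: a renewal approximation of the coalescent along the
  chromosome. The first segment draws the stationary time
  `t ~ Geometric(1/2N)` with residual length `Exp(2t)`; **subsequent segments
  draw the size-biased time** `t = G₁ + G₂ − 1` (two geometrics), because the
  tract covering a random point along the genome is length-biased — using
  the stationary law here would understate long-ROH counts. The default
  `fast` mode simulates exactly only "slow" segments capable of reaching the
  4-cM reporting floor (t ≤ ⌈22/(2·floor)⌉, beyond which
  `P(length ≥ floor) < 3e−10`) and aggregates each intervening run of fast
  segments by a moment-matched normal for its summed length (exact
  closed-form moments). `exact` mode walks every segment and is used to
  validate `fast` in the tests; both match the analytic expected counts
  within Monte-Carlo error.
- **Admixed frequencies**: Balding–Nichols drift
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` on a small population tree; the target is
  drifted from `α·S1 + (1−α)·S2`, and two outgroups share internal branches
  with the sources so the mixture is identifiable.

Limits: no background LD beyond pedigree transmission, no sequencing-error
model in genotypes, constant population size only for ROH, biallelic SNPs
with complete frequency tables for admixture. These match the scope of the
analyses they exercise, not real-data complexity.

## Pipeline and reproducibility

`run_pipeline` drives all stages from one `RunConfig`; a single seed is
split into named substreams (`numpy` `SeedSequence.spawn`), so a rerun with
the same config is bit-identical, and the report carries a SHA-256 hash of
the config. The `potocani-like` preset generates a 38-individual cohort
(four small pedigrees, 11 close kin, 27 singletons, 20 F / 18 M, 30 mtDNA
and 6 Y lineages) plus read counts and ROH segments at Nₑ = 5000, and the
report includes the planted truth for comparison.

## Design decisions

- Pseudo-haploid mismatch kinship (rather than genotype-likelihood methods)
  because it is the method of record for sparse aDNA cohorts and is exactly
  calibratable from the data.
- Median (not mean) baseline: tolerant of close kin in the calibration set.
- Poisson likelihood on bin totals: segments are approximately independent
  given N at these densities; the CI coverage test (0.95 ± 0.04) validates
  the approximation at cohort scale.
- Thresholds are module-level constants, not buried literals, and every
  boundary (strict vs inclusive) is pinned by a unit test.
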
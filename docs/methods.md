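# Methods

This note records the statistical model, the synthetic-cohort design,
and the numerical choices behind `mhcfinemap`, in enough detail to
re-derive every number the package produces.

## 1. Association model

Case-control status is modelled by binomial logistic regression with
additive allelic effects on the log-odds scale:

    logit P(y_i = 1) = alpha + beta * d_i + gamma' z_i

* `d_i` ∈ [0, 2] — imputed allele dosage of the tested marker;
* `z_i` — covariates: age (years), age² , BMI (kg/m²) and the top 20
  principal components by default;
* `beta` — log-odds change per allele copy; `exp(beta)` is the allelic
  odds ratio (OR).

**Estimation.** Maximum likelihood by iteratively reweighted least
squares (IRLS). Convergence requires a relative log-likelihood change
≤ 1e-10 *and* score max-norm < 1e-6 (at most 100 iterations).
Rank-deficient designs are repaired by pivoted QR: dependent columns
are dropped and recorded, never silently absorbed. The log-likelihood
is accumulated as `y·eta + log_expit(-eta)`, which is stable for large
|eta|. Standard errors come from the inverse observed information at
the optimum.

**Quasi-separation** (any |beta| > 15 or SE > 100) marks the fit
non-converged; no penalization is applied. Confidence bounds of
separated markers may overflow to infinity and are reported as such.

**Per-marker tests.** The reported p is the Wald test
`2·Phi(-|beta/se|)`; a likelihood-ratio p against the covariates-only
null is emitted alongside (`p_lrt`). The 95% CI uses the fixed quantile
z = 1.959964 so output is reproducible bit for bit across platforms.

**Omnibus position test.** A position with `m` residues is tested by
`deviance = 2(ll_full − ll_null)` where the full model adds the `m − 1`
residue dosage columns after dropping the most frequent residue as
reference, referred to χ² with df equal to the rank of the added block
(`m − 1` when independent; reductions are flagged `rank_reduced`). The
deviance is invariant to which residue is dropped (property-tested);
the most-frequent-reference rule only fixes a reproducible
parameterization.

**Conditioning.** Conditional scans append the lead markers' dosage
columns to every null and full design; a marker whose conditional p
rises above the strict genome-wide threshold 5.0e-8 is interpreted as
tagging the lead. Lead selection is deterministic: minimum p among
converged records, ties broken by larger |beta|, then lexicographic id.

## 2. Marker encoding

Starting from 4-digit classical-allele dosages (e.g. `B*52:01`):

* **2-digit alleles** — sum of the member 4-digit dosages
  (`B*52 = B*52:01 + B*52:02 + …`);
* **residue markers** — for each polymorphic amino-acid position `q`
  of the gene, the dosage of residue R is the summed dosage of the
  alleles carrying R at `q` (marker id `HLA-B_<q>_<R>`);
* **position groups** — each retained position contributes one group
  of its `m ≥ 2` residue markers for the omnibus test.

Alleles with an unknown residue at a position are excluded from that
position (logged), so residue sums there fall short of the gene total
by exactly the unknown alleles' dosage. Positions left with fewer than
two known residues are dropped as monomorphic. On noise-free dosages
the encoding conserves dosage exactly (to 1e-9): per individual,
2-digit sums and fully-known-position residue sums equal the gene's
total allele dosage. On noisy dosages residue sums can exceed 2 because
the summands carry independent noise; they are clamped to [0, 2] with a
log entry.

**Filters.** Markers are kept when MAF ≥ 0.01 in cases *and* controls
and the estimated imputation r² is ≥ 0.5 or missing (derived markers
carry no r² of their own); the analysis region is chromosome 6,
24–36 Mb (GRCh37), inclusive. The two filters commute
(property-tested).

## 3. Synthetic cohort generator

The generator exists so the pipeline can be validated end to end with
a known truth. It emulates:

* a **haplotype panel**: 7 HLA-B alleles and ≥ 20 background SNVs on
  four haplotype classes constructed analytically so that the causal
  allele sits at its target frequency exactly and the designated tag
  SNV at the target LD. Given target r², the disequilibrium is
  `D = sqrt(r² · pA(1−pA) pB(1−pB))`, checked against the Lewontin
  bound `D ≤ min(pA(1−pB), (1−pA)pB)`; the realized panel r² matches
  the target to 1e-9.
* **retrospective case-control sampling**: individuals are drawn from
  the population model until the case and control quotas are met. The
  intercept is solved by bisection (tolerance 1e-6) so the population
  prevalence matches `baseline_prevalence`; the OR is invariant to
  outcome-dependent sampling, so the generating `beta` remains the
  estimand. Case cohort labels are drawn at the study's eligible-count
  proportions (538 : 94 : 72 across three batches).
* **covariates**: age uniform on [18, 100], BMI truncated normal
  (mean 22.5, SD 3.5), 20 standard-normal PCs; all with zero effect by
  default so they are pure precision variables.
* **imputation noise and the estimated-r² statistic** (§4).

Defaults are the package's reference study scale — 704 cases, 39 556
controls, causal allele `B*52:01` at control frequency 0.109, allelic
OR 1.60, tag SNV r² 0.90, prevalence 0.01 — chosen as a realistic,
well-powered HLA fine-mapping configuration; experiments use reduced
quotas (e.g. 700 / 10 000) purely for runtime.

It does **not** emulate: phasing or imputation from a real reference
panel, population substructure (PCs are noise), genotyping batch
artefacts beyond labels, sex chromosomes, or more than one gene.

All randomness descends from a single integer seed through
`numpy.random.SeedSequence.spawn`, so every output is bit-identical
under the same seed, and replicate seeds never collide. All derived
seeds are reduced below 2³¹.

## 4. Imputation noise model

Imputed dosages are modelled by shrinkage toward the mean plus matched
noise. For quality `q ∈ (0, 1]` and true dosage vector `x` with mean
`mu` and variance `v`:

    noisy = mu + q (x − mu) + sqrt(q (1 − q) v) · Z,   Z ~ N(0, 1)

clamped to [0, 2]. Two properties motivate this form over simple
additive noise:

* `corr²(true, noisy) = q` — the quality parameter *is* the squared
  correlation lost to imputation;
* `Var(noisy) = q · v` before clamping, so the minimac-style estimated
  r² statistic, `Var(dosage) / (2 p̂ (1 − p̂))` with `p̂ = mean/2`
  capped at 1, concentrates near `q`. Additive noise would *inflate*
  the variance and pin the statistic at its cap of 1, making the
  quality filter vacuous; under shrinkage a variant simulated at
  quality 0.3 is correctly removed by the ≥ 0.5 filter.

Monomorphic variants have an undefined statistic: recorded as missing
and flagged. `q = 1` returns the dosages untouched.

## 5. Quality control

Filters run in a fixed order, and each excluded sample or variant
carries the first filter that removed it: per-cohort sample call rate
(< 0.99 discovery / < 0.95 and < 0.97 replication batches) → per-cohort
variant call rate → cross-cohort allele-frequency discordance (> 0.20
between any pair) → within-case batch association (logistic LRT
p < 1e-7) → indels and duplicated positions (positional markers only;
derived HLA markers deliberately share the gene coordinate) →
relatedness → PCA outliers → MAF ≥ 0.01 → HWE (exact p ≥ 1e-6,
controls by default). Because removing samples changes the statistics
the variant filters see (and vice versa), the whole sequence is
repeated until a pass excludes nothing (EIGENSTRAT-style iterative
outlier removal taken to a fixed point; non-convergence within 25
rounds is logged). QC is therefore idempotent: running it on its own
output excludes nothing (tested).

* **HWE**: the exact conditional distribution of heterozygote counts
  given allele margins, computed via log-gamma; p is the mass of
  outcomes no more probable than the observed (tie tolerance 1e-12 in
  log space). Validated against an independent mode-anchored ratio
  recurrence for every margin with n ≤ 200.
* **Relatedness**: PLINK method-of-moments PI_HAT from IBS counts and
  allele frequencies on hard genotypes (dosages rounded within 0.1,
  else missing); pairs need ≥ 500 overlapping variants; above 0.125
  the lower-call-rate member is excluded. No finite-sample allele-count
  corrections are applied — adequate at the panel sizes used here.
* **PCA**: greedy positional LD pruning (r² < 0.2), frequency
  standardization `(g − 2p)/sqrt(2p(1−p))`, SVD; |score| > 6 SD on any
  of the top 10 components flags an outlier; components are recomputed
  on survivors. PCA is computed on the study matrix alone (no external
  reference projection).

## 6. Numerical choices

* IRLS weights clipped at 1e-10; information matrix inverted directly,
  with failure reported rather than regularized.
* χ² deviances clamped at 0; negative deviances beyond −1e-8 are
  flagged, not hidden.
* `-log10(p)` capped at 320 (the double-precision underflow sentinel).
* LD r² is the squared Pearson correlation of dosages over pairwise
  non-missing samples, requiring ≥ 30 overlapping samples.
* Thresholds are strict or inclusive exactly as stated: genome-wide
  significance `p < 5e-8` strict; MAF and imputation-r² filters
  inclusive; frequency discordance strict `> 0.20`.

## 7. Validation experiments

* **Parameter recovery** (`recovery_experiment`): ≥ 200 replicates at
  700 / 10 000; the mean estimated OR must sit within 2 Monte-Carlo SE
  of the generating 1.60 and ~95% of per-replicate CIs must cover it.
  Noise-free dosages are analysed so the experiment measures the
  association stage, not regression dilution. Observed (seed 1):
  mean OR 1.5907, MC SE 0.0081, coverage 0.965.
* **Omnibus calibration** (`omnibus_calibration`): 2000 null replicates
  at m ∈ {2, 3, 5}; empirical type-I error at 0.05 within 3 binomial
  SE and Kolmogorov-Smirnov uniformity p > 1e-3.
* **Conditional extinction** (`conditional_extinction`): with the
  default panel, conditioning on the causal allele removes genome-wide
  significance of the tag SNV in ≥ 95% of replicates.

## 8. Limitations

* The simulator draws haplotypes from a single homogeneous panel; it
  cannot produce confounding by ancestry, so the PCs only demonstrate
  covariate plumbing.
* The noise model is marginal per variant; real imputation errors are
  correlated along haplotypes.
* The protein dictionary covers six illustrative positions of one
  gene; it is a schema, not a biological resource.
* No Firth or other penalized fallback for separated fits (flagged
  only); no FDR machinery (single strict threshold); no phasing, no
  multi-gene conditioning across genes.
* PI_HAT omits finite-sample corrections and can drift slightly
  negative for unrelated pairs; values are clamped only within the
  probability simplex.
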
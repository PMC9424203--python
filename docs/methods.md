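# Methods

## The generative model

`simulate.simulate_study` produces one twin cohort per call. The model is
deliberately the smallest one in which the downstream estimators' target
quantities are well defined.

**Variants.** `n_snps` biallelic loci with ancestral effect-allele
frequencies drawn uniformly from `maf_range` (default 0.1–0.5) and
non-strand-ambiguous allele pairs. Loci are unlinked by default so
meiosis is exact and fast; setting `rho_ld > 0` generates haplotypes from
a first-order Gaussian-threshold copula within `n_blocks` contiguous
blocks (adjacent latent correlation `rho_ld`), which exists to exercise
the SBLUP step, not to mimic a realistic LD map.

**Population structure.** With `n_subpops > 1`, subpopulation allele
frequencies follow the Balding–Nichols model,
`f_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `E[f_k] = p` and
`Var[f_k] = F p(1−p)`; draws are clipped to (0.001, 0.999). Families are
assigned to subpopulations round-robin. There is no admixture.

**Mating.** Parents are drawn at Hardy–Weinberg equilibrium within their
subpopulation. Assortative mating is *phenotypic*: each sex's phenotype
ranks are matched against one margin of a latent bivariate Gaussian with
correlation `rho_mate`, within subpopulation. The spousal polygenic-score
correlation is therefore an emergent quantity (roughly
`rho_mate · δ²` for this model), not a dial. One consequence worth
recording: under spousal polygenic-value correlation ρ the DZ co-twin
polygenic-value Pearson correlation in the offspring generation is
`(1+ρ)/(2+ρ)`, not `(1+ρ)/2` — the sibling covariance is the mid-parent
variance `σ²(1+ρ)/2`, but the offspring variance is `σ²(2+ρ)/2` because
the Mendelian segregation variance (`σ²/2`) is unaffected by parental
assortment. Both expressions reduce to 0.5 at ρ = 0. The property test
asserts the former; brute-force simulation confirms it.

**Meiosis.** Each twin receives one allele per parent per locus, the
transmitting parental slot chosen uniformly and independently across loci.
MZ pairs duplicate a single meiosis. The per-family transmission record
makes identity-by-descent sharing exactly computable: per locus the share
is (matching transmissions)/2; across L unlinked loci the mean share for
DZ pairs is 0.5 with between-pair SD `sqrt(0.125/L)`.

**Effects and phenotype.** True per-variant effects on standardized
genotypes are `b_v ~ N(0, 1/M)`; the emulated GWAS observes
`b_v + N(0, gwas_noise_sd²)` (no GWAS is actually run). Both are exported
as dosage-scale weight tables. Twin phenotypes are

```
y_ij = delta * g_ij + eta * gbar_j + s(subpop_j) + c_j + e_ij
```

with `g` the twin's true polygenic value standardized within the twin
generation, `gbar` the mid-parent value (the passive gene–environment
correlation channel), `s` a mean-centred per-subpopulation shift in steps
of `stratum_effect`, `c_j ~ N(0, sigma_c²)` shared by co-twins, and the
residual SD set so the total variance is 1 (an over-budget configuration
is an error that reports the component budget).

**Item-level data.** The family-environment items (two Poisson counts, an
ordinal 0–4 item, a binary item) are generated from a latent enrichment
score `enrichment_loading · z(gbar) + noise`, shared by co-twins. The
discrimination subtests (pitch 0–27, melody 0–18, rhythm 0–18), tapping
trials (six trials at target intervals 524–1024 ms, log tap CV decreasing
in the phenotype) and flow subscales load on the simulated phenotype with
independent item noise.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `n_families` | 2500 | registry-scale complete-pair count |
| `prop_mz` | 0.4 | typical MZ share of a volunteer twin cohort |
| `n_snps` | 500 | enough loci that per-pair IBD noise is small, still desk-scale |
| `delta` | 0.38 | direct-effect variance δ² ≈ 0.145, a typical SNP-heritability for a behavioural trait |
| `eta` | 0.0 | no genetic nurture in the reference configuration |
| `sigma_c` | 0.4 | moderate shared family environment (16% of variance) |
| `rho_mate` | 0.2 | modest phenotypic spousal similarity |
| `fst`, `stratum_effect` | 0 | homogeneous population unless stratification is under study |
| `gwas_noise_sd` | 0.1 | per-variant estimation noise; with M = 500 gives a score–genetic-value correlation ≈ 0.4, i.e. an observed standardized effect ≈ 0.15 |
| `enrichment_loading` | 0.3 | produces a small positive score–environment correlation of the size seen in family studies |

The strengths of the nurture, assortment and stratification channels in
real cohorts are not identifiable from published summaries, so these
defaults are illustrative study conditions, chosen once; analyses that
need a specific channel set it explicitly.

What the simulator deliberately does **not** emulate: realistic LD and
allele-frequency spectra, genotyping error and missingness patterns,
multi-generation equilibrium assortative mating, admixture,
X-chromosome, selection, or item nonresponse. Passing tests therefore
demonstrate estimator correctness under the stated model, not robustness
to every feature of real registry data.

## Estimation details

**Scoring.** Allele matching is deterministic: exact match keeps the
dosage, swapped alleles flip it (`2 − d`), strand-ambiguous pairs (A/T,
C/G) are dropped with a logged count, allele-set mismatches are dropped.
Missing dosages are replaced by `2 × frequency`. MZ co-twins missing a
score inherit the co-twin's score; DZ twins never do.

**SBLUP.** Marginal effects are re-estimated per LD block by solving
`(R + κI) b = β` with `κ = M(1/h²_snp − 1)/N`. The parameterization was
validated against the individual-level identity: with `R = X'X/n` and
`N = n` the system is exactly ridge regression with penalty
`λ = M(1/h²_snp − 1)`; the test suite checks agreement to machine
precision. With `R = I` the estimator shrinks uniformly by `1/(1+κ)`.

**Association.** OLS with an explicit rank check; cluster-robust
covariance `(X'X)⁻¹(Σ_g X_g'e_g e_g'X_g)(X'X)⁻¹` scaled by
`G/(G−1)·(n−1)/(n−k)`, so singleton clusters reduce to HC1; t reference
distribution with `G−1` degrees of freedom. ΔR² is the R² difference of
nested fits (clamped at 0 against round-off); point estimates are
identical under any clustering, so the reported R² is the plain-fit R².
p-values are two-sided and unadjusted for multiple outcomes.

**Family decomposition.** Scores of complete DZ pairs are split exactly
into family mean and deviation. The random-intercept model is fitted by
REML, profiled over `θ = var_family/var_resid`: for pairs
`V_j⁻¹ = I − θ/(1+2θ) J`, so all GLS quantities reduce to whole-sample
and family-sum cross products; a bounded scalar minimization of the
restricted criterion over `log θ ∈ [−12, 6]` is compared against the
`θ = 0` boundary, which is allowed and reported (and reproduces OLS
exactly). Standard errors come from the GLS covariance at the optimum;
95% CIs are normal-approximation (`± 1.96 SE`). The fit matches
statsmodels' MixedLM (REML) to four decimals and a dense grid search of
the criterion to 1e−6 on toy data. Age is not a covariate here — twins
share age exactly, making it collinear with the family intercept — sex
and the top PCs are. The between-minus-within contrast is tested with a
Wald z using the joint covariance of the two fixed effects; the cruder
CI-overlap indicator is reported alongside because applied papers often
quote it.

**Correlation diagnostics.** Pearson correlations with Fisher-z 95%
intervals (`atanh r ± 1.96/√(n−3)`, back-transformed). The DZ co-twin
correlation uses one deterministic entry per pair (twins ordered
lexicographically by sample id), not double-entry ICC: with n = the
number of pairs this reproduces published interval widths. A CI bound
lying exactly on 0.50 counts as containing it. The environment index is
PC1 of the item correlation matrix, sign-anchored so the music-education
item loads positively; constant items are dropped with a warning.

**PCA.** Variants are mean-imputed (PCA only), standardized, and
decomposed by SVD; components are eigenvalue-ordered with the sign fixed
by the largest-magnitude loading. Requesting more components than the
matrix rank is an error naming the rank. MAF filtering uses strict
inequality (`> 0.05`), with an epsilon guard so binary round-off at the
boundary cannot flip the rule; LD pruning is a greedy left-to-right
sliding-window scan (defaults: window 50 variants, step 5 — declared
defaults, since pruning windows are rarely printed) dropping the later
variant of any pair at or above the r² threshold.

## Numerical and design choices

* Practice-hours categories have no canonical midpoints; the scorer takes
  a configurable midpoint table (default
  0, 0.5, 1.5, 3, 5, 7.5, 10.5, 15, 25, 40 h/week) and is documented as
  an approximation. Both start/end ages missing is read as "never
  played" (0 h); partial missingness propagates.
* The ISIP motor-timing score is the *negative* mean CV across trials, so
  0 is the best attainable score. Start-age of playing is passed through
  as-is (lower = earlier).
* All scorers are missing-transparent: missing inputs give missing
  outputs, never silent zeros.
* Standardization uses the n−1 denominator and is idempotent; sex, age,
  and PCs are exempt by convention.
* Complete-case analysis per outcome with logged drop counts; incomplete
  DZ pairs are dropped before the decomposition.
* The pipeline is deterministic given config and seed: repeated runs
  produce byte-identical result files.

## Problem sizes used in the checks

The reference checks simulate 1000–4000 families at 120–500 unlinked
loci: large enough that the Mendelian constants (co-twin score
correlation 0.50, IBD share 50%) are measured with sampling error well
inside their tolerances (SE ≈ 0.012 for the correlation at 4000 pairs,
≈ 0.03 pp for IBD at 1000 pairs × 200 loci), and the estimator-equality
and calibration suites use 200–2000 replicates of small fits. These sizes
are the package's own reference configuration for its validation suite.

## Known limitations

* Single-generation assortative mating only; no equilibrium dynamics.
* The REML fitter is specialized to balanced twin pairs (the design it
  serves); it does not handle general cluster sizes.
* The SBLUP step assumes block-diagonal LD supplied by the caller; no
  reference-panel management.
* Ordinal/binary outcomes are analysed linearly, as in common applied
  practice for these designs.
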
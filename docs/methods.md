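# Methods

`icsgwis` implements a two-stage genome-wide interaction study (GWIS) of
a binary treatment-response phenotype — poor versus good response to
inhaled corticosteroids (ICS) in asthma, where a "case" is a patient who
experienced at least one exacerbation while on ICS — with patient age as
the interacting exposure. The package covers the complete analytical
chain: cohort simulation under the study's generative model, variant
quality control, per-variant logistic interaction regression,
discovery/replication filtering with weighted Z-score joint analysis,
candidate-gene proxy annotation, and an empirical power calculator for
gene-by-environment interactions with binary outcomes.

## Generative model and simulator

All synthetic data are drawn from the logistic interaction model

    logit P(Y = 1 | G, E) = β₀ + β_G·G + β_E·E + β_I·G·E

with defaults β₀ = −0.32, β_G = 0.17, β_E = 0.97 and minor-allele
frequency 0.49 — the fitted values for the strongest observed
interaction signal — and stage sizes n = 783 (discovery) and n = 538
(replication). Genotype dosages G ∈ {0, 1, 2} are Binomial(2, MAF)
draws, i.e. Hardy–Weinberg equilibrium; the exposure E is i.i.d.
standard normal, representing age after rank-based inverse-normal
transformation. Outcomes are drawn unconditionally (no case/control
ascertainment), so observed case counts match their expectation only on
average; this mirrors how the original power calculation was set up.

The single-SNP model is generalised to `n_variants` columns with a
designated causal subset (the first `n_causal` variants). Non-causal
variants are independent HWE noise with no outcome effect, giving the
genome-wide filtering stages a testable target. Covariates (sex ~
Bernoulli(0.5), BMI ~ Normal(26, 4²), study ~ uniform categorical) are
generated independently of G and E: they exist to exercise the
covariate-adjustment machinery, not to confound. The reported
interaction effect's sign is ambiguous in its source (a magnitude near
0.8–1.0 with inconsistent sign conventions), so β_I is a free signed
parameter and the default grids use the negative orientation.

Randomness is organised as named independent streams (genotypes /
exposure / outcome / missingness / covariates, with a sub-stream per
variant) spawned from one root seed, so enlarging the variant panel
never perturbs the exposure or outcome draws, and every result is
bit-reproducible from `(params, seed)`.

What the simulator deliberately does **not** emulate: linkage
disequilibrium, imputation uncertainty, population stratification
(a two-subpopulation generator exists only as a PCA test fixture),
confounding between covariates and genotype, and case/control
ascertainment. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to the
correlation structure of real genotype panels.

## Variant QC

Exclusion thresholds follow genome-wide convention: MAF < 1%, genotype
call rate < 90%, imputation INFO score < 0.9, Hardy–Weinberg exact-test
P < 1e-5. All rules are strictly-below: a variant exactly at a
threshold passes. The HWE test is the standard conditional exact test:
given the observed allele counts, all heterozygote counts of matching
parity are enumerated, and the two-sided P value sums the probabilities
of configurations no more likely than the observed one (ties included
at 1e-9 relative tolerance; no mid-P correction). It is evaluated in
log space via log-gamma, which the test suite checks against an exact
integer-arithmetic enumeration to 1e-12 for all genotype triples ≤ 30.
HWE is computed on hard calls (dosages rounded to the nearest integer)
over all samples; dosage-based HWE is out of scope. Exclusions are
attributed to the first failing rule in the fixed order call-rate, MAF,
HWE, INFO, so per-rule counts always sum to the number excluded.

Ancestry principal components are computed from mean-imputed dosages
standardised by √(2p(1−p)) via SVD; scores are orthogonal, ordered by
explained variance, and a ±6 SD outlier flag emulates
ancestry-exclusion reporting (sample exclusion itself is out of scope).

## Interaction scan

Each variant is tested in

    logit P(case) = b₀ + b_G·G + b_E·E + b_I·(G×E) + covariates

with G the additive minor-allele dosage and E the Blom inverse-normal
transform of age, Φ⁻¹((rank − 3/8)/(n + 1/4)) with average ranks for
ties, applied within each stage separately. The transformed age is used
for both the main effect and the interaction. Categorical covariates
(study) are one-hot encoded against the first level; BMI enters
untransformed.

Fitting is maximum likelihood by damped Newton/IRLS with per-element
step-halving against the deviance (convergence when the maximum step
falls below 1e-10, cap 50 iterations). Fits are stacked along a batch
axis and solved with batched normal equations — the same code path
serves single fits, the genome-wide scan and the power simulator —
and missing dosages are handled by zero observation weights, which is
algebraically identical to per-variant complete-case analysis.
Inference on b_I is a Wald test (z = b_I/se, two-sided), matching the
convention of the standard GWAS toolchain; the 95% CI is
exp(b_I ± 1.96·se). Quasi-separation is flagged when any |b| exceeds 15
or the information matrix is singular (e.g. a monomorphic variant);
flagged fits are retained in the output with `converged = False` and
excluded from downstream filtering, never silently dropped. No Firth
correction is applied.

Diagnostics: the genomic inflation factor λ = median(χ²_obs)/0.4549
and QQ-plot coordinate tables. For null calibration of λ the package
pools interaction P values over independent synthetic cohorts
(20 × 5,000 variants by default) rather than scanning one cohort: with
a single shared outcome vector, all per-variant P values are correlated
through the cohort draw and the realised λ of even 100,000 variants
fluctuates by ±0.02 from cohort to cohort, which says nothing about the
test's calibration. Pooling across cohorts yields effectively
independent null P values, and λ sits within 0.98–1.02.

## Two-stage filter and joint analysis

A variant advances when p_disc < 1e-5 (genome-wide suggestive),
p_rep < 0.05 (nominal), and the interaction estimates agree in sign.
Survivors are combined with the sample-size-weighted Z-score (Stouffer,
METAL convention): z_i = sign(b_I,i)·Φ⁻¹(1 − p_i/2), w_i = √n_i,
z_joint = Σw_i z_i / √(Σw_i²), with the joint P two-sided and compared
against 5e-8. Signed deviates are evaluated through the log-quantile
function (`ndtri_exp`) so P values remain convertible down to the
smallest positive float. Stage sample sizes default to 783/538 but the
per-variant `n` from each scan is used, which accommodates missingness.
Variants with mismatched allele orientation between stages are dropped
with a count recorded on the output table; variants absent from either
stage are simply not replicable.

The published top-20 table's joint P column cannot be reproduced from
its rounded stage P values: recombining the printed stage Ps under the
√n-weighted Z gives joint Ps uniformly larger than the printed joint
column (driver `analysis/07_reported_interval_checks.py` computes
this). Joint-analysis correctness is therefore established against
closed-form and quadrature oracles, not against those cells. Stage-level
cells, by contrast, are reproducible: Wald P values rebuilt from the
printed ORs and 95% CIs (se = ln(CI_hi/CI_lo)/3.92) agree with the
printed stage Ps to within CI-rounding error (max |Δlog₁₀ P| ≈ 0.21,
headline SNPs < 0.1).

## Power calculator

Empirical power for the interaction term: each replicate draws a fresh
cohort under the generative model, fits the three-term logistic model
(G, E, G×E; no covariates, exactly as the original calculation
specifies), and power is the fraction of converged replicates with
interaction P < α. Defaults: n = 783, MAF 0.49, α = 5e-8, 10,000
replicates, β_I grid −1.00 … −0.75 by 0.05 (six points). Non-converged
replicates are excluded from the denominator and reported in
`n_failed_fits`. All grid points share one RNG stream seeded from the
run seed (common random numbers), which makes power monotone in |β_I|
replicate-by-replicate. The test suite checks the simulator against an
asymptotic Wald power oracle built from the expected information matrix
(Gauss–Hermite integration over E, exact summation over genotype
classes). Tests and the acceptance script use 2,000 replicates per grid
point (Monte-Carlo SE ≤ ~0.011), the package's reduced default for
interactive use; the CLI exposes the full 10,000.

## Gene proxy annotation

Each candidate gene (defaults: DPP10, HDAC9, TBXAS1, FBXL7,
GSDMB/ORMDL3; coordinates always supplied by the user) is represented
by the lowest-P scan variant within the gene body ± 10 kb, inclusive at
both boundaries, in 1-based coordinates (BED input is converted from
0-based half-open on read). Ties are broken by smaller position, then
lexicographic variant id. "Within 10 kb" is interpreted as gene body
± flank, not TSS ± flank. Chromosome labels are normalised across the
`chr1`/`1` conventions.

## Numerical and interface conventions

* Reported P values are clamped into (0, 1] at 1e-300.
* VCF: dosage precedence DS over GT; missing is `./.` or absent DS;
  multiallelic records skipped with a warning count; the minor
  (counted) allele is written as ALT.
* Dosage TSV is samples × variants with `NA` missing, plus a variant
  metadata sidecar.
* CLI exit codes: 0 success, 2 configuration error, 3 data error,
  4 numerical failure. Pipeline artifacts carry a manifest with the
  configuration hash and seed; identical configurations are
  byte-identical.

## Known limitations

* Wald inference only: no LRT, score, robust-sandwich or Firth options.
* The two-round (pre-imputation and post-merge) QC history of real
  array data is collapsed into one consolidated pass.
* No LD, so "top proxy SNP" selection cannot be validated against
  LD-based proxy choice.
* Real-cohort headline counts (230 suggestive, 107 replicated
  interactions) depend on individual-level data that are not available
  and are not reproduced here; the pipeline's correctness is
  established on synthetic data with known truth plus the published
  summary-statistics table.
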
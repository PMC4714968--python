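# Methods

This note records the models the package fits, the generative model behind
the synthetic cohorts, the numerical choices, and the limits of what the
test suite can show.

## Regression models

All association tests are per-allele: the genotype enters as a 0–2 dosage,
covariates as named numeric columns (top genotype principal components;
optionally the other phenotypes). Analyses are complete-case per
variant/phenotype; missing dosages are mean-imputed only inside PCA and
risk-score accumulation, never inside a regression.

- **Linear** (age at onset): OLS on the rank-based inverse-normal transform
  `Φ⁻¹((rank−½)/n)` with average ranks for ties, so effects are in SD units
  and invariant to any monotone rescaling of age. A z-score transform is
  available behind a flag; rank-based is the default because it is robust
  to the skew of onset-age distributions.
- **Binary logistic** (UC extent E3 vs E1+E2, upper-GI, perianal):
  maximum likelihood via IRLS; perfect separation is flagged non-converged
  (never silently dropped) with NaN effects.
- **Proportional-odds ordinal** (CD behaviour B1 < B2 < B3):
  `logit P(Y>k) = βg + γ'X − θₖ`. The latent direction is chosen so OR > 1
  means more complicated disease. Cutpoints are constrained increasing via
  a log-increment parameterisation; a non-monotone solution is flagged.
  The p-value is a 1-df likelihood-ratio test of β = 0 (with a closed-form
  category-frequency null when no covariates are present).
- **Baseline-category multinomial** (CD location; reference = colonic L2):
  per-contrast Wald SEs for the ileal-vs-colonic and ileocolonic-vs-colonic
  odds ratios; one overall p per variant from a (K−1)-df LRT on the
  genotype term.
- **Weibull AFT** (time to surgery/colectomy, right-censored):
  `log T = μ + βg + γ'X + σW`, W standard Gumbel. Implemented as a direct
  scipy (BFGS) maximisation of the censored log-likelihood with a numerical
  Hessian for the covariance; lifelines' independently coded fitter serves
  as the cross-check in the tests. Reported: the AFT coefficient, shape
  `k = 1/σ`, and `log HR = −βk` with a delta-method SE from the joint
  (β, log σ) covariance. A `fix_shape` option pins the shape (1 =
  exponential).
- **Meta-analysis**: fixed-effect inverse-variance pooling; used to combine
  CD and UC age scans and discovery with replication cohorts.

Conditioning on correlated phenotypes is covariate adjustment: location as
two dummies (L1, L3 vs L2), behaviour as an ordinal 0/1/2 code, age as its
inverse-normal score, extent as an E3 indicator. The functional form is a
design choice; the key property (a purely location-mediated behaviour
signal attenuates to null once location enters the model) is verified by
simulation in the tests.

**Genetic model selection** for a multicategory phenotype fits binary,
ordinal, and multinomial candidates at every variant of a designated panel
and sums BIC over the panel; the minimum-total-BIC model wins, with ties
within 2 BIC units resolved toward the simpler model. To make the binary
candidate's likelihood comparable on the same observations, it is scored as
a composite: a logistic top-category-vs-rest model times a genotype-free
multinomial split within the grouped categories. BIC was chosen for its
transparency of penalty; note that when the true category effects lie on a
single genetic axis (as in this package's default generator), the ordinal
model is genuinely the parsimonious description and is selected — the
multinomial wins only for truly unordered effects.

**Significance tiers** are two-tailed and fixed: genome-wide p < 5×10⁻⁸
(strict inequality), suggestive p < 1×10⁻⁵. Suggestive signals are combined
with a replication cohort by fixed-effect meta-analysis and promoted iff
the combined p crosses genome-wide; a threshold-replication mode
(same-direction nominal replication) is available behind a flag.

## Risk scores

Weights are per-locus natural-log odds ratios; HLA-allele dosages are
treated exactly like SNP dosages. In a case-only cohort the CD-vs-UC weight
is the case-case CD-vs-UC logistic log-OR (PC-adjusted, univariate by
default; a multivariable joint fit is behind a flag). With a control group
present, w_CD and w_UC are separate case-control log-ORs and the CD-vs-UC
weight is their difference. A sample's raw score is Σⱼ wⱼ·dosageᵢⱼ
(missing dosages mean-imputed); the standardized copy has mean 0, SD 1 over
the scoring cohort. Raw scores are cohort-mean-centred when the ±2 outlier
thresholds are applied, so the thresholds are interpreted on a natural-log
scale anchored at the cohort average.

Outlier rules are one-sided per diagnosis: CD with raw score ≤ −2 (more
UC-like than almost all UC) and UC with score ≥ +2. A separate extreme-tail
pair (−2, +3) is kept configurable for clinical-characteristics
comparisons. Each outlier receives one randomly drawn non-outlier
comparator from the same recruitment site where available. Enrichment of
revised diagnoses is tested by logistic regression of the revision flag on
outlier status with location dummies, falling back to Fisher's exact test
when any 2×2 cell is below 5.

Grouping evidence (two vs three genetic entities) compares, per locus,
Gaussian models of dosage with two group means (CD pooled) versus three
(ileal CD, colonic CD, UC), each with a common variance; ΔBIC = BIC₂ −
BIC₃ summed over loci, positive totals favouring three groups.

Cross-validated classification estimates weights on training sites only
(e.g. non-UK) and computes the rank-statistic AUC on held-out samples with
a stratified bootstrap percentile CI (2000 draws).

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
any real dataset. Defaults (chosen once): 30 000 cases; latent subtype base
probabilities (0.32, 0.25, 0.43) over ileal CD / colonic CD / UC giving a
57:43 CD:UC split; 160 background loci with ileal-vs-UC odds ratios of
magnitude 1.05–1.4 (random sign, MAF uniform 0.05–0.5) and colonic effect
exactly half the ileal one, making colonic CD genetically intermediate by
construction; three tagged loci — NOD2-like (MAF 0.024, ileal-vs-colonic
OR 2.5, surgery HR 1.31 per allele, age shift −0.16 SD/allele), MHC-like
(MAF 0.116, ileal-vs-colonic OR 0.45, extensive-UC OR 0.70, flagged HLA),
MST1-like (MAF 0.28, age shift −0.06). Five latent structure axes tilt
per-variant allele frequencies on the logit scale (SD 0.08) and weakly
enter the class predictors. Subtype intercepts are calibrated iteratively
so the mean class probabilities hit the configured base probabilities
regardless of how much variance the effects contribute.

Ileocolonic disease (L3) is the central band of the intercept-free
ileal-minus-colonic genetic axis (|Δ − median| < 0.40), so it is
genetically intermediate between L1 and L2 by construction; IBD-U is the
configured fraction (0.86%) of colonic/UC samples closest to the midpoint
of the colonic–UC genetic axis. Behaviour progresses by exponential B1→B2
waiting times with location-specific rates (0.105/0.055/0.040 per year for
L1/L3/L2) and a common B2→B3 rate (0.10/yr); behaviour at last follow-up is
recorded and the true transition times kept in the truth table. Surgery and
colectomy times are Weibull (shape 1.2) with location/extent-dependent
scales (CD: 8/11/19 years for L1/L3/L2; UC: 26/55/75 for E3/E2/E1), the
per-allele surgery hazard ratio entering as an AFT scale shift, censored at
an exponential follow-up (mean 11 years). Missingness is applied completely
at random at per-field rates mirroring a large multicentre cohort's missing
rows; misdiagnosis swaps CD↔UC labels at a configurable rate (default
0.5%), re-coding the swapped sample to the nearest valid Montreal state.
Masked re-phenotyping is emulated by revealing a swap with sensitivity 0.85
and doubting an unswapped diagnosis at a base rate of 0.08 — illustrative
values, configurable, since no real base rates are available.

One global seed spawns ordered sub-seeds per stage (genotypes, labels,
phenotypes, times, missingness, swaps, sites, effects), so identical
configurations are byte-identical and stages are independently
reproducible.

**What the generator does not model**: linkage disequilibrium between loci,
family structure, genotyping error, informative missingness, site-specific
phenotyping practices, or environmental effects. Passing tests therefore
demonstrate correctness of the estimators under the assumed generative
model, not performance on real Immunochip data. Two further consequences
worth knowing:

- *Marginal vs conditional effects.* Per-variant scans estimate marginal
  odds ratios; because many background loci share the ileal–colonic axis,
  logit non-collapsibility attenuates the marginal NOD2-like OR by roughly
  5–10% relative to its conditional generative value of 2.5. This is well
  inside the 3-SE recovery tolerance at the sizes used and mirrors the
  interpretation gap real studies face.
- *Grouping evidence at weak effects.* Under the Gaussian group-mean ΔBIC,
  per-locus evidence at OR ≈ 1.1 does not overcome the per-locus df
  penalty at 30 000 samples, so the default cohort favours two groups; the
  grouping analysis discriminates reliably once ileal and colonic allele
  frequencies genuinely differ (the scenario contrast exercised in the
  acceptance tests).

## Numerical choices

- Logistic/multinomial: Newton/IRLS, tolerance 1e-10, max 100–200
  iterations; ordinal: L-BFGS (pgtol 1e-12) polished by BFGS steps so the
  two-category collapse identities hold to 1e-6.
- Weibull: BFGS on (μ, β, γ, log σ) with z-clipping at ±700 to avoid
  overflow; covariance from a numerical Hessian (pseudo-inverse for
  near-singular cases).
- PCA: per-variant mean imputation, standardization, thin SVD; PC sign
  fixed by forcing the largest-magnitude sample loading positive; columns
  orthonormal.
- Cohort-summary percentages: half-up rounding to integers; denominators
  are the non-missing records including any OTHER category; missing is
  reported as a percentage of the group total.
- Problem sizes in the tests: type-I calibration uses 2000 null replicates
  of n = 500 per engine (99% binomial CI around 0.05); parameter recovery
  a 10 000-sample, 100-variant cohort; the misclassification experiment ten
  30 000-sample replicates spiked at 2.5% swaps (≈ 90 outliers per
  replicate, matching the ~97/95 arm design); grouping scenarios 100
  replicates of 2000 × 30.

## Known limitations

- The ordinal engine's proportional-odds assumption is never tested per
  variant; a strongly non-proportional effect would be mis-summarised.
- The variance decomposition conditions all models on one common
  complete-case subset (required for nested block comparisons), so heavy
  missingness shrinks its effective n.
- Score weights from univariate per-locus fits ignore inter-locus
  correlation; fine for independent simulated loci, attenuated under LD.
- The analytic power formula is a two-group normal approximation on the
  log-OR scale; it ignores covariate adjustment and case-only designs
  where the effective contrast differs from case-control.
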
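# Methods

## The model

`hurdleda` tests each microbial feature (taxon, gene, pathway) for
association with sample covariates using a two-part hurdle model:

- **Prevalence component.** The feature's presence/absence vector is
  regressed on the covariates by weighted logistic regression. Because
  presence patterns are often perfectly separable at realistic sample
  sizes, each original observation is augmented with one artificial
  presence and one artificial absence carrying the same covariates and
  weight `g/(2n)` (`g` = number of non-intercept design columns,
  `n` = samples), so the augmented rows carry total weight equivalent
  to `g` extra samples. This is a Diaconis–Ylvisaker-style conjugate
  prior centred at prevalence 1/2: estimates stay finite under complete
  separation and the device carries over unchanged to random-intercept
  models, which ordinary penalization tricks do not.
- **Abundance component.** The feature's log2 *nonzero* abundances are
  regressed on the covariates by OLS, or by REML random-intercept
  linear mixed models when a grouping factor is declared. Zeros are
  treated as true absences everywhere: no pseudo-counts.

Sequencing observes only relative abundances. Writing `A_ik` for
absolute abundance, `T_k = Σ_i A_ik`, and `P_ik = A_ik / T_k`, a slope
fitted on log2 relative data decomposes (densely sampled case) as
`β_ij^rel = β_ij^abs − β_j^tot`, where `β_j^tot` is the slope of
log2 total load on covariate `j`, shared by all features. When fewer
than half the features truly change, the across-feature median
`M_j = median_i(β_ij^rel)` consistently estimates that shared offset,
so testing each coefficient against the median recovers absolute-scale
inference from relative data. That median comparison is the default;
it is switched off automatically when the data are already on an
absolute scale (spike-in or total-load normalization).

### Median-comparison test

The statistic is `(β_ij − M_j) / sqrt(se_ij² + var(M_j))`. `var(M_j)`
is estimated by a seeded parametric bootstrap: B = 1000 draws of
`β* ~ Normal(β_ij, se_ij²)` independently across features, taking the
median of each draw, and using the variance of those medians. Fits
that errored are excluded from the median and the bootstrap. The
two-sided reference distribution is the feature's own residual-df t
(normal for mixed fits, which report no residual df). A normal
reference was considered and rejected: features present in barely more
samples than the design has columns produce near-saturated fits whose
residual variance — and hence standard error — is essentially noise,
and a normal reference converts those tiny standard errors into
astronomically small p-values. Referring each statistic to its own
residual-df t makes one-df fits appropriately uncertain; with the
typical tens of residual df the two references agree.

With an even feature count the sample median is the midpoint of the
two central order statistics (numpy convention). Optionally the median
is subtracted from the reported coefficients (`subtract_median`,
default off — raw relative-scale coefficients are easier to interpret;
the benchmark harness turns it on so fitted effects are comparable to
the planted absolute-scale effects).

### Screening abundance-induced prevalence effects

Finite read depth turns genuine abundance decreases into apparent
prevalence effects (the feature falls below detection). After the
prevalence fits, a plain linear fit of the log2 relative abundances is
tested against zero (not the median), and a prevalence association is
flagged *abundance-induced* when (1) that abundance q-value is below
the FDR level, (2) the two coefficients share a sign, and (3) the
abundance coefficient has the larger magnitude. The q-pool for this
screen is all features × coefficients of the screening fit (the
individual-vs-joint pooling question is not settled elsewhere; this
single convention is used throughout). Flagged associations stay in
the output but are not called significant while screening is on
(default).

### Combining the components

Under the null the two component p-values are independent (the
abundance model sees only the nonzero values; the prevalence model
only the mask), so the minimum of the two is Beta(1, 2) distributed
and the joint p-value is `1 − (1 − min)²`. Multiplicity is handled by
Benjamini–Hochberg in two pools: the *individual* pool contains all
error-free abundance (median-adjusted when the comparison is on) and
prevalence p-values together, plus any omnibus/ordered/contrast
p-values; the *joint* pool contains the per-(feature, covariate) joint
p-values. Intercepts never enter either pool. When exactly one
component errored, the joint p falls back to the surviving component
and the record is flagged `partial`. A record is significant when its
joint q is below the FDR level (default 0.1), it carries no fitting
error, and — if the post hoc coefficient threshold is set — its
|coefficient| exceeds the threshold. The threshold default is 0 (off);
1 is a useful conservative setting for longitudinal data (see the
benchmark discussion below).

### Extended tests

- *Omnibus*: all level coefficients of a categorical covariate zero —
  Wald F on the residual df for linear fits (equal to the ANOVA F),
  likelihood-ratio test for logistic fits with the augmentation rows
  and weights retained in both nested fits, Wald chi-square for mixed
  fits.
- *Ordered covariates*: treatment-coded in the model (no monotonicity
  imposed); consecutive-level differences tested by Wald contrasts,
  P − 1 tests for P levels, optionally against the across-feature
  median difference (same bootstrap machinery as the median test).
- *Contrasts*: arbitrary rows `c'β = rhs` by Wald tests against the
  fitted covariance.
- *Feature-specific covariates*: a samples × features table whose i-th
  column joins feature i's design (g+2 columns), e.g. log2 DNA
  abundance when modeling RNA, so transcriptional effects are separated
  from copy-number effects. The paired-table preprocessing follows a
  three-case rule: DNA nonzero — keep as-is; RNA nonzero with DNA zero
  — DNA set to log2(half the dataset-wide minimum nonzero DNA
  abundance), a below-detection sentinel; both zero — observation
  excluded. The sentinel uses the dataset-wide minimum (not
  per-feature), keeping the imputation scale common across features.

### Absolute-abundance protocols

With a spike-in reference of known absolute abundance,
`Â_ik = Â_ref,k · P̂_ik / P̂_ref,k`; within-sample ratios are
preserved and TSS of the scaled table returns the input relative
abundances. Samples where the reference was not observed cannot be
rescaled and are dropped with a warning (the alternative — abandoning
spike-in mode entirely — would discard information from the samples
where the reference was observed). The reference feature is excluded
from testing. With per-sample total-load estimates,
`Â_ik = P̂_ik · T̂_k`. Both switch the median comparison off.

## Numerical choices

- Logistic fits: IRLS (statsmodels GLM) with the augmentation weights
  as frequency weights, tolerance 1e-8, 200 iterations; non-convergence
  yields an error record, never a silent estimate.
- Mixed logistic fits: the random intercept is integrated out by
  25-node Gauss–Hermite quadrature and the weighted marginal likelihood
  maximized by L-BFGS-B; Wald standard errors from the numerical
  Hessian. No installed fitter handles observation weights in a
  logistic mixed model, so this component is implemented directly.
- Mixed linear fits: statsmodels MixedLM, REML; non-convergence or an
  indefinite covariance yields an error record.
- Rank-deficient designs, features with nonzero counts at or below the
  coefficient count, all-present and all-absent features all yield
  error records with descriptive strings.
- Missing metadata: complete-case per model with a logged count.
- A single master seed drives the median bootstrap and any simulation;
  all child generators derive from it deterministically.

## The synthetic-data generator

Features follow a zero-inflated log-normal null: baseline prevalence
`π_i`, log2 mean `μ_i`, log2 SD `σ_i`. Planted prevalence effects act
on `logit(π_i)`; abundance effects act additively on log2 absolute
abundance; both therefore exist on the absolute scale while the
observed data — multinomial reads at log-normal depth (mean 50,000,
natural-log SD 0.5) — are compositional. Default study conditions:
100 features, 5 covariates (3 binary, 2 continuous, from an
identity-covariance normal), 10% of feature–covariate pairs carrying
true effects uniform on 2.5–5 (half abundance/half prevalence, half
positive/half negative; fractional counts resolved by a seeded coin).

Template defaults — log2 means Normal(−13, 5), log2 SDs Uniform(1, 3),
prevalences Beta(1.0, 2.5) — were calibrated once so that the two zero
modes reproduce realistic stool-like sparsity: ~76% zeros with
zero-inflation and ~38% pure sampling zeros at the default depth.
Only the spread of the log2 means matters after normalization.

Additional modes: a spike-in extension (reference feature at 1–10% of
each sample's pre-spike total, added before read sampling); an
ordered-covariate generator (thermometer-encoded internally, total
effect Dirichlet(1)-partitioned across level steps, each step zeroed
and folded into the next with probability 1/2); a two-group generator
with multiplicative mean shifts (uniform 2.5–5) and 20% structural
zeros per group, reads by multinomial sampling of normalized profiles
(a close stand-in for rarefaction when depth ≫ features; structural
zeros enter the truth as prevalence rows of infinite magnitude); a
repeated-sampling mode with per-(feature, individual) random
intercepts of SD 1.0 (in log2 / log-odds units — a moderate,
realistic person-to-person effect; the source conditions do not pin
this down) on both abundance and prevalence; and a metadata-shuffle
null whose returned truth is empty.

What the generator does **not** emulate: phylogenetically structured
effects, batch effects, overdispersed (non-multinomial) read sampling,
and template parameters refit from real metagenomes. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated generative model, not performance guarantees on arbitrary real
data.

## Evaluation harness

Discoveries are matched to truth by (feature, metadatum) — `any_type`,
duplicates counted once — or by (feature, metadatum, type). Precision
with zero discoveries is reported missing and excluded from cell
means. Shrinkage error is `mean((|β̂| − |β|)/|β|)` over significant
type-matched true positives with finite truth effects (significant
false positives have no true coefficient and are excluded — the
alternative convention is undefined for them). Effect correlation is
the per-metadatum Spearman correlation of fitted versus true
coefficients (true 0 for null pairs, fitted coefficient taken from the
truth-typed component), averaged over metadata.

Benchmark cells in the test suite run at reduced replicate counts
(3–6) against a 0.15 band (the 0.1 benchmark tolerance plus a 0.05
Monte-Carlo allowance); `scripts/acceptance.py` runs the full 10–20
replicates per cell. Problem sizes throughout (50–1,000 samples, 100
features, 20 or fewer replicates per cell) are chosen so a full run
completes on a single desktop CPU in minutes.

## Known limitations

- Detection truncation biases abundance coefficients toward zero in
  zero-inflated data (the feature is missing exactly where it is
  rare); this is a property of conditioning on presence, shared by the
  hurdle approach generally, and is visible in the negative shrinkage
  metric at small depth.
- The augmentation prior mildly attenuates very large prevalence
  coefficients by design.
- The median comparison is valid for absolute-scale inference only
  when fewer than half the features change; otherwise it tests
  deviation from the typical feature–covariate association.
- Mixed-model p-values use the many-groups normal approximation for
  fixed effects; with very few groups they are anticonservative.
- Rarefaction is approximated by multinomial sampling in the two-group
  generator; the difference is negligible at depth much larger than
  the feature count.
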
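# Methods

## Model

A quantitative trait measured on the members of an extended twin family is
modelled as multivariate normal. For family $f$ with $m_f$ phenotyped
members,

$$ y_f \sim \mathcal N\!\left(X_f\beta,\;
   \sigma^2_A\,2\Phi_f + \sigma^2_D\,\Delta_{7,f} + \sigma^2_H\,H_f +
   \sigma^2_E\,I\right) $$

where $2\Phi$ is the additive relationship matrix (twice the kinship
coefficient), $\Delta_7$ the fraternity (dominance) matrix — the
probability that a pair shares both alleles identical by descent — $H$ a
0/1 household co-residence indicator, and $X\beta$ fixed effects
(intercept, linear age in years, a female-vs-male contrast). Families are
independent, so the log-likelihood is a sum of small dense blocks.
Broad-sense heritability is $(\sigma^2_A+\sigma^2_D)/\sum_c\sigma^2_c$.

The bivariate model replaces each scalar $\sigma^2_c$ with a $2\times 2$
matrix $C_c$; the stacked (individual-major) family covariance is
$\sum_c R_{c,f} \otimes C_c$. Standardising each $C_c$ gives the
per-component cross-trait correlations $r_c$, and
$C_c[1,2]\big/\sum_{c'}C_{c'}[1,2]$ the share of the phenotypic covariance
attributable to component $c$.

### Assumptions

- Founders are unrelated and non-inbred. The two-term fraternity identity
  $\Delta_7 = \varphi_{m_im_j}\varphi_{f_if_j} +
  \varphi_{m_if_j}\varphi_{f_im_j}$ assumes non-inbreeding; inbred
  pedigrees are detected and flagged with a warning, not modelled
  (generalised Jacquard coefficients are out of scope).
- MZ multiples are genetically identical: each MZ group is collapsed onto
  one genotype node before the kinship recursion, which makes group
  members interchangeable in every derived coefficient (e.g. an MZ twin
  shares 50% additively with the co-twin's children).
- Household sharing is binary: spouses, and parents with offspring aged
  ≤ 18, share; duration of co-residence is not weighted (the observed
  age-gradient in spouse resemblance is therefore outside the model).
  Household groups form a partition, so $H$ is block-diagonal and PSD.
  When a partnered individual is simultaneously an eligible child, the
  spouse group wins — the source data do not dictate this corner case.
- No assortative mating, sex-limitation, age-moderation or ascertainment
  correction. The dichotomous Type D classification is summarised by
  tetrachoric correlations only; it is not variance-decomposed.

## Estimation

Variance components are estimated by bounded (non-negative) L-BFGS-B on
the variance scale. The fixed effects are profiled out by GLS at every
evaluation, and the profile gradient is analytic:
$\partial \ell/\partial\sigma^2_c = -\tfrac12\sum_f\left[
\mathrm{tr}(\Sigma_f^{-1}R_{c,f}) - r_f^\top\Sigma_f^{-1}R_{c,f}
\Sigma_f^{-1}r_f\right]$ at the profiled residuals (envelope theorem).
Three dispersed starts (equal split, E-heavy, A-heavy) guard against local
optima; the best likelihood is kept. Observation blocks with identical
structure matrices are grouped so each Cholesky factorisation is shared by
all families of that shape, and mutually unlinked sub-blocks (no nonzero
off-diagonal in any structure matrix) are split apart — the likelihood is
identical either way. $\sigma^2_E$ is bounded below at a tiny positive
value so $\Sigma$ never degenerates.

Standard errors come from the observed information: central finite
differences of the analytic profile gradient (relative step $10^{-4}$) on
the interior components. Estimates on the zero bound are flagged and get
SE = NaN; derived quantities (broad-sense $h^2$) use the delta method on
the inverse information. The bivariate fit parameterises each $C_c$ by its
Cholesky factor (PSD by construction; the diagonal factors of $C_E$ are
bounded strictly positive), uses numerical gradients, and obtains its
information matrix from central function-value differences with an
absolute step of $10^{-3}$ — appropriate for a log-likelihood of order
$10^4$, where much smaller steps would be dominated by cancellation noise.

Likelihood-ratio tests are $-2(\ell_\text{reduced}-\ell_\text{full})$
against a central $\chi^2$ with the parameter-count difference as df. For
a single variance component tested on its zero boundary the central
$\chi^2_1$ is conservative, so the 50:50 $\chi^2_0{:}\chi^2_1$ mixture
p-value is also reported.

### Numerical details

- Tetrachoric correlation: two-step estimator — thresholds fixed at the
  marginal normal quantiles, then a 1-D bounded maximisation of the
  multinomial likelihood with bivariate-normal rectangle probabilities
  (`xatol` $10^{-7}$). Tables with an empty diagonal or off-diagonal are
  reported at the ±1 boundary with a flag; empty margins are undefined.
- Inverse normal transform: Blom offset, $\Phi^{-1}((r-3/8)/(n+1/4))$ with
  ties mid-ranked. The offset variant (Blom vs. van der Waerden etc.)
  changes results negligibly; Blom is the common default.
- Bootstrap CIs: percentile intervals resampling unordered pairs (matching
  the behaviour of the helper conventionally used for this table);
  degenerate resamples are skipped and counted.
- Symmetric pair types (twins, sibs, spouses) are double-entered for
  correlations, making estimates invariant to within-pair ordering;
  asymmetric types use a fixed role order (parent / elder first).
- Wave selection ties (same completeness, same relative count) resolve to
  the earliest wave, for reproducibility. Cross-wave imputation only draws
  from *earlier* waves of the same individual, most recent first; items
  still missing fall back to the person mean within the subscale (at most
  two), mirroring the two-step imputation of the source design. The
  ambiguous fallback "mean of the sum scores" is implemented as the
  person's own historical subscale information rather than a sample mean,
  and flagged here for users.

## Synthetic data

The generator draws families from a template mix (MZ/DZ pairs alone or
with phenotyped parents, added non-twin sibs, twins with spouses and adult
offspring, sib-only and half-sib households) whose default weights were
calibrated once to the composition of the motivating twin-register sample:
about 24% MZ individuals, 29% DZ, 23% parents, 15% non-twin sibs, and a
mean of ~2.7 phenotyped members per family. Ages are role-specific
truncated normals — twins centred on 28.3 y (SD 10), parents on 55.8 y
(SD 8, our choice of spread), partnered twins on 45 y so their offspring
are plausibly adult; twins aged ≤ 18 fall into the parental household.
Default true parameters are the full-model estimates of the motivating
study (NA: A = 0.11, D = 0.28, H = 0.066, E = 0.34; SI: 0.099/0.32/0.066/
0.36; component correlations 0.57/0.69/0.94/0.26; fixed effects
intercept 0.2, −0.006/y age slope, +0.18 female contrast — slopes are our
choice, small relative to the trait SD). Phenotypes are drawn per family
from the exact generative covariance via one Cholesky factor per family.
The dichotomous classification thresholds both traits at the quantile that
yields a joint prevalence of 21%.

Ordinal items are generated from the latent traits with a common loading
of 0.7 and synthetic thresholds chosen to give a right-skewed 0/1/2
distribution; they exist to exercise the scoring/imputation plumbing and
carry no psychometric claim. What the generator does **not** emulate:
assortative mating, registry ascertainment, longitudinal drift,
item-level measurement structure of the real instrument, and
household-duration effects. Passing recovery tests therefore demonstrate
correctness of the estimator under the stated model, not robustness to
these real-data features.

## Validation strategy and problem sizes

Every core computation has an independent oracle in the test suite:
kinship/fraternity recursions vs. gene-dropping Monte Carlo (allele
transmission simulated down the pedigree; 60k–200k drops, 3 MC SE
tolerance); the family likelihood vs. a dense multivariate-normal density;
the tetrachoric estimate vs. an exhaustive likelihood grid (step 1e-4);
Pearson correlation vs. the explicit product-moment formula; ML twin-pair
estimates vs. the Falconer-style moment solution. Parameter recovery runs
at 3,000 families × 20 replicates (each component within 2 reported SEs of
truth in ≥ 90% of replicates) and CI coverage at 500 families × 200
replicates (pooled 95% coverage within [0.92, 0.98]); these sizes keep the
full simulate-and-refit battery to a few minutes while leaving the
sampling error well below the effects being checked. Fitting an AE model
to A+D+H data reproduces the expected inflation of the additive estimate.

## Known limitations

- Fraternity coefficients are undefined under inbreeding (warned, not
  modelled); X-linked and mitochondrial sharing are out of scope.
- Boundary estimates ($\hat\sigma^2_c = 0$) make the usual SE and
  chi-square machinery only approximate; the mixture p-value option
  addresses the one-component case only.
- The bivariate information matrix from finite differences can be noisy
  when a component is nearly rank-0; correlations of such components are
  reported as NaN or at the ±1 boundary.
- `recovery_experiment` counts non-convergent replicates rather than
  repairing them; at the default sizes none occur.
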
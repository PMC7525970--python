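# Methods

## Problem and models

Surveys of adverse childhood experiences (ACEs) ask adults to report, for
a fixed battery of adversity events experienced before age 18, whether
(and for some items how often) each occurred. The battery modelled here
is the common 11-item one: five household-dysfunction items answered
yes/no (household mental illness, alcoholism, drug abuse, incarceration,
parental divorce) and six frequency items answered never / once / more
than once (household violence, physical abuse, emotional abuse, and
three sexual-adversity items). The analytic question is not whether
adversity predicts a binary adult health outcome but *how the adversity
information should enter the regression*. Three characterizations are
contrasted, all as logistic regressions sharing one covariate block
(sex, age, education, income, insurance, race, marital status,
reference-cell coded):

* **CRCn** — cumulative risk, continuous: the count of exposures (ACE
  score) enters as a single linear term,
  `logit P(Y=1) = β₀ + β₁·score (+ β₂·(score − mean)²)`, the quadratic
  variant relaxing the constant-per-event assumption;
* **CRCat** — cumulative risk, categorical: each score value gets its own
  dummy against the score-0 reference;
* **MIR** — multiple individual risk: all event indicators enter jointly,
  each coefficient adjusted for the co-occurring events.

Each family is further parameterized by the exposure threshold for the
frequency items ('once' = any occurrence; 'more than once' = repeated
only; yes/no items are unaffected) and by the item count (11, or 9 with
the three sexual items collapsed to one indicator by logical OR). That
gives 8 CRCn candidates (threshold × items × quadratic) and 4 each for
CRCat and MIR.

## Screening and coding rules

Rows with any missing covariate or outcome are dropped; rows with two or
more missing ACE items are dropped; rows with exactly one missing item
are kept with the item imputed to its unexposed level ('no' / 'never'),
so that all models are fitted to identical rows. Score cross-tabs
against the outcome and each covariate are screened for cells with fewer
than 20 cases; when the screen fails, the categorical coding collapses
the top score categories (e.g. `8+`) by the minimal amount restoring
compliance. Input codes such as "don't know"/"refused" are mapped to
missing at read time (configurable in the column map). The quadratic
CRCn term uses the mean-centered squared score to limit collinearity
with the linear term.

## Two-step comparison

Because the candidates share a covariate block but have non-nested
adversity blocks, ordinary likelihood-ratio testing does not apply.
Comparison uses the two-step procedure of Vuong (1989) on the
per-observation log-likelihood differences `m_i = ℓᵢ(A) − ℓᵢ(B)`:

1. **Distinguishability (Ω) test.** `n·ω̂²`, with `ω̂²` the sample
   variance of `m_i`, is referred to its null distribution
   `Σⱼ λⱼ²·χ²₁`, where λⱼ are the eigenvalues of the
   `(k_A+k_B)×(k_A+k_B)` block matrix assembled from the mean Hessians
   `A = (1/n)Σ ∂²ℓᵢ` and mean score cross-products
   `B = (1/n)Σ sᵢsᵢᵀ`, `B_AB = (1/n)Σ sᵢ(A)sᵢ(B)ᵀ`:
   `W = [[−B_A A_A⁻¹, −B_AB A_B⁻¹], [B_ABᵀ A_A⁻¹, B_B A_B⁻¹]]`.
   Failure to reject means the models are indistinguishable in
   population and step 2 is suppressed.
2. **Closeness test.** `z = Σ m_i / (√n·ω̂)` against the standard
   normal, two-sided; positive z favours model A (the "column" model in
   matrix renderings). Significant z gives the verdict `a_better` /
   `b_better`; a non-significant z on distinguishable models gives
   `distinguishable_equal_fit` (rendered "NDF").

The closeness statistic is unadjusted by default; AIC- and BIC-style
penalty corrections are available behind a flag. Nested pairs (the
covariate-only baseline against any adversity model) run through the
same machinery for workflow fidelity, with a warning and a classical
likelihood-ratio χ² reported alongside.

**Weighted-χ² tail.** The default evaluator is seeded Monte Carlo (10⁶
draws). The deterministic alternative is an Imhof (1961) numerical
inversion implemented as a vectorized midpoint rule: the step is tied to
the total phase rate (≥ 20 samples per oscillation) and the integral is
truncated where the integration-by-parts bound `(4/x)/(U·ρ(U))` on the
oscillatory tail falls below 1e-10; equal-weight and single-weight cases
use the exact scaled-χ² form. The two evaluators agree to ~3e-4 in
internal checks (tested at 1e-3). Eigenvalue weights below 1e-7 of the
largest are dropped; they are numerical noise from the shared covariate
block. Long simulation loops in the test and acceptance layers use the
Imhof evaluator because it is deterministic and orders of magnitude
faster at the matrix sizes involved.

## Selection workflow

Within each family, candidates are compared champion-vs-challenger in
enumeration order (11 items before 9, 'once' before 'more than once',
linear before quadratic — a declared convention, logged per pair so the
order's influence can be audited). A significant closeness verdict
decides a pair; otherwise the smaller AIC does, with ΔAIC > 50 flagged
as substantial support and smaller differences flagged weak; AIC ties
within 1e-6 go to the earlier (simpler-positioned) model. A family whose
internal decisions all fell to AIC is annotated "(by AIC)" in the
best-fit table. The three family champions and the covariate-only
baseline are then compared pairwise (6 comparisons), and an overall
champion pass in the order baseline → CRCn → CRCat → MIR applies the
same pair-resolution rule. Reported per champion: AIC, Nagelkerke R²
(Cox–Snell rescaled), the concordance statistic (Mann–Whitney rank
form, ties ½), and for MIR the adjusted odds ratios next to
single-event odds ratios (each event alone with the covariates) and the
range of variance inflation factors over the event indicators (OLS VIF
on the unweighted design; an information-weighted variant is behind a
flag).

## Fitting

Logistic MLE is an in-package Newton/IRLS iteration with step halving,
run to a sup-norm score tolerance of 1e-8 (max 100 iterations), keeping
the per-observation log-likelihoods, scores and the observed-information
Hessian the comparison machinery consumes. Standard errors come from
the inverse observed information. Separation and non-convergence are
hard errors (a coefficient beyond ±15 with SE above 10, a constant
outcome, or a singular information matrix), because downstream
quantities require finite per-observation log-likelihoods. Survey
weights are deliberately unsupported: the workflow targets unweighted
complete-case model comparison, where fit differences are attributable
to the predictor characterization alone.

## Synthetic data

The generator emulates the structure the analysis assumes rather than
any particular survey's empirical margins. Item responses come from a
Gaussian copula: one latent normal vector per respondent with
exchangeable correlation ρ = 0.4 by default (a full 11×11 matrix is
accepted), cut at the quantiles implied by per-item margins; three-level
items use two ordered cuts so higher latent adversity means more
frequent exposure. Default exposure prevalences span roughly 0.04–0.35
across items — rarer for forced sex, common for emotional abuse and
divorce — and are package choices, as are the covariate margins.
Covariates are independent of the items unless the optional
shared-latent linkage is switched on for confounding experiments.

Outcomes are Bernoulli draws from a logistic linear predictor under one
of four truths: `mir` (per-event log-ORs), `cr_linear` (score slope,
optional quadratic), `cr_categorical` (per-count step effects), or
`null`. Generative exposure uses the 'once' threshold unless configured.
The default `mir` truth uses heterogeneous per-event log-ORs
ln(2.89, 1.20, 0.96, 1.04, 0.93, 0.98, 1.29, 1.46, 1.74, 1.13, 1.28) —
one strong event, several near-null ones — with intercept −1.9 and mild
covariate gradients, giving an outcome prevalence around 0.15.
Missingness is MCAR per item cell only; no informative-missingness
mechanism is modelled.

What the generator does **not** emulate: survey design (stratification,
weights, state structure), item-specific correlation patterns beyond
exchangeability, covariate–item dependence (unless linked), and
recall-bias mechanisms. Passing tests therefore certify the machinery —
screening, coding, fitting, testing, selection — under a clean
generating process, not the substantive conclusions one would draw from
any real survey.

## Problem sizes and numerical conventions

The simulation-based guarantees run at the following sizes, chosen as
the package's standard desk-scale conditions: type-I calibration of the
distinguishability test at n = 2000 over 500 replicates (accepted inside
the exact binomial 95% band around 0.05); selection power under the
heterogeneous `mir` truth and consistency under the `cr_linear` truth at
n = 5000 over 100 replicates (≥ 90% each); pooled Wald 95% CI coverage
of the 11 event log-ORs at n = 5000 over 500 replicates (accepted in
[0.93, 0.97]). The acceptance script reruns the same computations at
reduced replicate counts (300/50/200) plus one full selection run and
the closed-form 2×2 slope ln 4.

α = 0.05 two-sided throughout, with 0.05/0.01/0.001 star annotations.
All randomness flows through `numpy.random.default_rng` seeds;
dataset-level sub-streams are derived with `SeedSequence` so the
response, outcome and missingness stages are independent.

## Known limitations

* The distinguishability-test asymptotics are evaluated at the fitted
  (pseudo-true) parameters; in very small samples (n below a few
  hundred) the weighted-χ² null is approximate and calibration is not
  guaranteed.
* The within-family champion order is a convention; pathological
  intransitive triples could in principle make the champion
  order-dependent, which is why every pairwise decision is logged.
* Comparisons require identical rows and outcomes; nothing is provided
  for comparing models across imputation schemes or subsamples.
* The categorical auto-collapse considers only top-category merges, the
  standard practice for right-skewed adversity scores.
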
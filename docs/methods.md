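# Methods

This note documents the statistical models implemented in `dogyears`, the
numerical choices behind them, what the synthetic-cohort generator does and
does not emulate, and the design decisions taken where more than one
reasonable construction existed.

## Data model

The unit of analysis is one death (or censoring) record: cohort label, sex,
age at death, a list of diagnoses present at death, a pre-assigned primary
diagnosis, and a two-axis cause-of-death classification derived from the
primary diagnosis — a *pathophysiological process* (PP: congenital,
degenerative, infectious, inflammatory, metabolic, neoplastic, toxic,
traumatic, vascular) and an *organ system* (OS: cardiovascular,
dermatologic, endocrine, gastrointestinal, hematopoietic, hepatic,
musculoskeletal, neurologic, ophthalmologic, respiratory, urogenital), each
admitting `unclassified`. The diagnosis→(PP, OS) mapping ships as an
editable CSV lookup table: the packaged default covers the synthetic
generator's vocabulary (~60 diagnoses), not a clinical ontology, and
real-data users are expected to substitute their own. Classification
depends only on the primary diagnosis; primacy is assigned upstream (as in
veterinary registries) and never re-derived here. Diagnosis matching is
case-insensitive after whitespace normalization.

Ages are years, intervals half-open [lo, hi). Veterinary-registry ages
arrive binned; the packaged bin scheme represents the three youngest bins
(0–2 weeks, 2 weeks–2 months, 2–6 months) by the single age 0.25 y, uses
arithmetic midpoints for bounded bins, and represents the open "over 15
years" bin as 17.5 y. Only those anchor bins are externally fixed; the
intermediate boundaries (0.5–1, 1–2, 2–4, 4–7, 7–10 y) are the package's
default and can be replaced by any CSV scheme.

Record filtering removes (1) deaths whose only diagnosis is euthanasia,
then (2) deaths unclassified on either cause axis. Checking euthanasia
first gives each removed record exactly one removal reason; the kept set is
identical under either order, and filtering is idempotent.

## Survival models

**Gompertz.** The hazard is μ(x) = α·e^{βx}; β (per year) is the rate of
aging. Exact-age likelihood: deaths contribute log μ(x) − H(x) with
H(x) = (α/β)(e^{βx} − 1); censored records contribute −H(x). Binned ages
use the interval-censored likelihood log[S(lo) − S(hi)] with S(x) =
e^{−H(x)} (open top bins: hi = ∞, contribution log S(lo)). Optimization is
unconstrained BFGS on (log α, β) — well-scaled, and β is deliberately not
clamped positive so a declining hazard is estimable — initialized from a
least-squares line through the log of a ~15-bin life-table
occurrence/exposure hazard, with a Nelder–Mead polish if BFGS reports
non-convergence. |β| < 1e−9 switches to the exponential-limit expressions.
Fitting bin-midpoint ages as if exact is badly biased (a slope of 0.021
refits as ≈0.16 on the default dog bins); the pipeline therefore detects
cohorts whose death ages all sit on scheme midpoints and routes them
through the interval likelihood, merging the three 0.25-y bins into one
[0, 0.5) interval.

**Kaplan–Meier and smoothed hazard.** The product-limit estimator is
delegated to `lifelines`. The smoothed hazard is a Ramlau–Hansen-type
estimator: Nelson–Aalen increments d/Y smoothed with an Epanechnikov kernel
(default bandwidth = data range / 10), each event's kernel mass renormalized
to the part falling inside the observed age range so the curve is not
biased downward at the boundaries.

**Sex contrast.** A one-covariate Cox partial likelihood with Breslow tie
handling, maximized by Newton's method (analytic first and second
derivatives, step clipped to ±2), with a Wald test. The estimate depends on
times only through their ranks; on tie-free data it matches `lifelines`'
Cox fit to 4 decimals (cross-checked in the tests).

## Morbidity models

Multimorbidity is the number of *distinct* diagnoses at death (duplicates
within a record collapse to one; a record whose only diagnosis is its cause
of death counts 1). Comorbidity for index condition c is the same count
excluding c itself for carriers, so a carrier's comorbidity is always its
multimorbidity minus one. Counts are modelled with a log-link NB2
negative-binomial regression (variance μ + μ²/θ, θ estimated jointly by
MLE via `statsmodels`) on age (years, continuous — binned midpoints are
treated as exact), sex (female = 0, male = 1), and either cause-category
dummies (reference = most frequent category; categories with < 2 records
excluded with a warning) or a binary index-condition flag. When the
dispersion estimate hits its boundary (data no more dispersed than Poisson)
the NB Hessian is singular, and inference falls back to the Poisson-limit
GLM. Adjusted means are predictions at the sample-average age and sex mix.

## Cause-of-death age trajectories

Among deaths at age x the cause probabilities follow a softmax over
per-cause quartic polynomials in age. Age is standardized, z = (x − c)/s
with c, s the death-age mean and SD, before polynomial expansion —
a numerically equivalent reparameterization (x⁴ at human ages reaches 10⁸
raw) whose constants are stored on the model for exact back-conversion of
hand-built raw-age models. The softmax is overparameterized, so the
alphabetically first cause is the reference with all parameters fixed at 0;
the likelihood is then concave and the fit unique (10-perturbed-start
agreement to 1e−6 is tested). Optimization is L-BFGS with the analytic
gradient Xᵀ(P − Y). A runaway fit (non-finite or |coefficient| > 50 on the
standardized scale, the signature of separation) is refitted with a small
ridge (1e−4) and a warning.

**Peak finding and age rescaling.** The age at which a cause's predicted
proportion is maximal is located by a 0.1-y grid scan bracketing a
golden-section refinement (ties toward the younger age; boundary maxima and
flat curves are flagged). The cross-cohort age scale is the ratio of the
two cohorts' neoplastic peak ages (human/dog ≈ 53/11.5 ≈ 4.6 for the
default generators); a boundary peak raises an error rather than silently
producing a meaningless scale.

**Odds-ratio curves.** log₂OR(x) = logit₂ p_human(x) − logit₂
p_dog(x/scale), with probabilities clipped to [ε, 1 − ε], ε = 1e−6, before
the logit (the statistic is undefined at 0 and 1); clipped evaluations are
flagged in the curve output. Positive values mean the cause is more likely
in the human cohort; a value of k means 2^k-fold odds.

**Confidence bands** are nonparametric bootstrap percentile intervals over
individuals (default B = 200, configurable; ≥ 50 enforced), reproducible
given a seed; more than 10% failed refits aborts. Pointwise coverage at a
fixed age is tested at ≈ 95% over 150 simulation replicates of a known
generator (n = 400, B = 60 — sizes chosen to keep the check inexpensive).

## Spectrum comparison

Per-cohort cause proportions are computed over the categories observed in
*both* cohorts and renormalized; the cancer-by-organ axis conditions on
PP = neoplastic. Spearman's ρ uses average ranks; for ≤ 8 categories the
two-sided p-value is the exact permutation probability of |ρ| at least as
large (the t approximation is poor at 7–9 categories, the regime these
comparisons live in), otherwise the t approximation.

"Age-related" (absolute deaths increasing with age) is a visual criterion
in origin; the package operationalizes it as a one-sided Mann–Kendall
trend test (Kendall τ of count vs bin index, p < 0.05) on deaths-per-bin
restricted to bins at or past the cohort's first quartile of death ages,
so an early-life mode (congenital, traumatic) does not mask — or fake —
a late-life rise. The output notes it is a surrogate.

## Synthetic cohorts

The generator encodes the study conditions as defaults: a human-like
cohort with Gompertz slopes 0.089 (female) / 0.080 (male) and baseline
hazards set for median lifespans of 80 / 75 y, exact ages, no
contamination; and a dog-like cohort with slopes 0.0214 / 0.0219, medians
12 y, registry-binned ages, 10% unclassified and 5% euthanasia-only
contamination, index-condition prevalences (obesity 8%, arthritis 10%,
chronic kidney disease 5%, hypothyroidism 4%, diabetes mellitus 3%), and a
multimorbidity model targeting ≈ 3 diagnoses per death with a positive age
effect and no sex effect. Cause-trajectory generators give the neoplastic
cause a concave-quadratic logit and the remaining causes mild linear
trends (congenital and traumatic declining, vascular and metabolic rising,
infectious flat). Because age-varying competitor logits shift a cause's
*proportion* peak off its *logit* vertex, the generator calibrates the
vertex by fixed-point iteration until the proportion peak sits at the
requested age (53 y human, 11.5 y dog, to 0.01 y) — the stated peaks are
properties of the generated data, not just of one coefficient.

Sampling: lifespans by inverse CDF, x = (1/β)ln(1 − (β/α)ln U) (β → 0:
exponential), clipped to the cause model's validity range (the implied
atom at the upper bound holds < 2% of mass at the defaults); causes drawn
per death from the softmax at its age; diagnosis counts 1 + NB(θ = 5) on
the log-link mean, raised when needed so the primary diagnosis and all
flagged index conditions fit in the list; fillers drawn without
replacement from the taxonomy vocabulary. Contamination relabels a
uniformly chosen subset. All stages draw from independent child streams of
one seed (regeneration is bit-identical; perturbing one stream leaves the
others unchanged).

What the generator does **not** emulate: breed/size structure, calendar
trends, realistic clinical vocabularies, correlated diagnosis co-occurrence
beyond the index-condition effects, referral bias, or censoring (all
records are deaths). Passing recovery tests therefore demonstrates that the
estimators invert the generating models at realistic sizes — not that real
registry data satisfy those models. One deliberate artifact mirrors real
count data: because fillers are drawn from a shared vocabulary, longer
diagnosis lists are mechanically more likely to contain any given index
condition, so naive case/non-case contrasts are confounded by list length
unless the count model adjusts for it.

## Problem sizes and tolerances

Recovery checks use 50,000 lifespans for Gompertz slopes (recovered within
2–3% of 0.089/0.080/0.0214, the binned dog protocol through 1-year
intervals), and 100,000 deaths per cohort for the peak-alignment scale
factor (within 5% of 53/11.5). The module test suite uses scaled-down
sizes (e.g. 30,000–40,000 for trajectory sup-norm recovery at 0.015) as
the package's chosen trade-off between statistical resolution and suite
runtime. Tolerances on hand-derived oracles are exact to 1e−6–1e−9;
tolerances on stochastic recoveries are set from binomial/asymptotic
standard errors at the stated n.

## Known limitations

* The Gompertz model has no Makeham (age-independent) term and no early-age
  truncation; cohorts with a strong juvenile mortality hump will show
  lower fitted slopes than their late-life hazard implies.
* The quartic softmax can oscillate at ages with little data (tails of the
  age distribution); predictions "mildly beyond" the fitted range are
  allowed but not trustworthy.
* The comorbidity design compares carriers to all non-carriers at death,
  which is cross-sectional; it cannot separate "condition causes
  comorbidity" from shared age/severity pathways.
* The exact-permutation Spearman p is feasible only to n = 8 categories
  (8! rank permutations); beyond that the t approximation is used.
* `unclassified` contamination is applied uniformly at random in the
  generator; real registries' unclassified records are likely non-random.
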
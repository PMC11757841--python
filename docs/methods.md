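# Methods

This note documents the models, defaults, numerical choices, and limitations
of `boosterdd`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Adjusting-amount titration

One condition presents six choices between an immediate amount and a fixed
delayed reward A (default $2,000). The offer starts at I = A/2 = $1,000; the
first adjustment is (A − I)/2 = $500 and every later adjustment is half of
the previous one, upward after a "delayed" choice, downward after an
"immediate" choice. After t applied choices the pending step is therefore
(A − I)/2^(t+1); the spec of the staircase is fully determined by the choice
sequence, and `indifference_point` is a pure replay function of it.

The estimate is the offer of a *hypothetical seventh trial*: the sixth
presented offer adjusted once more, by half the last applied step, in the
direction the sixth choice implies. This is the only reading consistent with
the consistently-halving rule, and it makes the estimate identical to the
state's offer after six applications of the update. Consequences at the
defaults:

* presented offers lie in [31.25, 1968.75] (after trial 1);
* estimates lie on a 15.625-wide grid in [15.625, 1984.375];
* for any deterministic responder with threshold V ∈ [0, 2000] (immediate
  iff offer ≥ V, ties to immediate — the tie-break needed for the boundary
  cases of the convergence argument), |estimate − V| ≤ 15.625. The test
  suite verifies this by sweeping V over a 1-unit grid against an
  independent replay oracle.

Offers are kept at full floating-point precision by default
(`currency_precision=None`): the halving sequence produces 62.5, 31.25, …,
and rounding would break the replay identities. Delay conditions are
administered in ascending order by default with an optional permutation;
AuC is order-invariant, which is asserted through the full pipeline.

## AuC

Day-values for the labels are the conventional 7 / 30 / 90 / 180 / 365 /
1095 / 3650 (a week, a 30-day month, a 365-day year); they are configurable
because the underlying operationalization is a choice, not a datum. The
normalized curve prepends the anchor (0, 1) — zero delay, undiscounted
value — and the statistic is the plain trapezoidal area. The anchor is
included so that a non-discounter reaches exactly 1 and the (0, 1] range
claim holds; spline or rank-based AuC variants are deliberately out of
scope. `fit_hyperbolic` estimates k in V = A/(1 + kD) by least squares on a
log-k parameterization (keeps k ≥ 0, with a collapse-to-zero rule below
1e-10); it exists for parameter-recovery diagnostics, not as the headline
statistic.

## Responder agents

Agents value the delayed reward hyperbolically (A/(1 + kD)), exponentially
(A·e^(−kD)), by a fixed currency threshold, or as one of the two constant
strategies. Choice noise is a logistic rule on the offer−value difference:
P(immediate) = expit((offer − V)/τ). The temperature τ nests the
deterministic agent continuously (τ → 0), which is why this form was chosen
over, e.g., an ε-lapse model; there is no empirical noise model to match.
Population discount rates follow log10 k ~ Normal(−2.2, 0.6) per day, chosen
to spread AuC broadly over (0, 1) with a median near 0.2; this is a
simulation convenience, not a claim about any real sample.

## Questionnaire scoring and exclusions

GAD-7 (7 items, 0–3), PHQ-9 (9 items, 0–3) and IUS-12 (12 items, 0–5) are
item sums with strict range/count validation. The psychological distress
index is z(GAD-7 total) + z(PHQ-9 total) with sample SD (n − 1); the
standardization population is the post-exclusion analytic sample, a choice
the pipeline makes explicit because the index is only defined relative to a
sample. Raw vaccination codes 1–2 map to vaccinated, 3–4 to unvaccinated,
5 ("prefer not to say") to missing; booster codes 0/1/2 map to no/yes/
missing. Exclusions run in a fixed order — unvaccinated first, then missing
booster response — and the reported counts always sum to the input n.
Participants with missing vaccination status were never asked the booster
question, so they fall out at the second step. Rater reliability for
categorical codings uses percent agreement (trace/total) and Cohen's kappa
with chance agreement from marginal products.

For modeling, gender is coded female = 1 / male = 0 and education as an
ordinal 0/1/2 (secondary/undergraduate/postgraduate) score; both codings are
overridable, since a single reported coefficient per variable implies scalar
codings without pinning down the reference levels.

## Synthetic cohort

The generator reproduces the study *design*, not its raw data. Per
participant: a country is drawn (uniform over the 13 recruitment countries —
per-country sizes are not public), a country intercept u_c ~ N(0, 0.41²) is
drawn once per country, covariates follow the reported marginals (age
truncated-Normal(30.92, 11.42) at 18+, relative income truncated-Normal
(38.83, 23.8) on [0, 100], 22% essential workers, 55.6% female, education
30/49/20%), questionnaire items are Binomial(max rating, severity) draws
from a shared latent severity (Beta(2, 5) for distress, Beta(2, 3) for
uncertainty intolerance — right-skewed totals typical of community samples,
with GAD-7/PHQ-9 correlated through the shared latent), and AuC is obtained
by running a hyperbolic agent through the actual titration engine, so the
measurement path and its quantization are exercised, never bypassed.

The outcome is Bernoulli(logit⁻¹(Xβ + u_c)) with β the reported fixed
effects (intercept 0.95; age 0.01; gender −0.23; education 0.02; relative
income −0.14; essential worker −0.08; distress 0.08; uncertainty intolerance
−0.08; AuC 0.67). Age, relative income, distress and IUS-12 are z-scored
within the generated sample before β is applied — the same transformation
the fitting side uses — while the binary, ordinal and unit-interval
predictors (gender, education, essential worker, AuC) enter raw: an AuC odds
ratio of ~1.95 over a (0, 1) predictor is only coherent unscaled.

What the generator does **not** emulate: attrition between study waves,
per-country composition differences, covariate correlations beyond the
GAD-7/PHQ-9 link, item-level response styles, attention-check failures, or
free-text reasons. Passing recovery tests therefore shows that the pipeline
is a consistent estimator of its own generating process under the reported
effect sizes — not that the original data meet these assumptions.

## Inference

With a single scalar random intercept the marginal likelihood factorizes by
country into 1-D integrals, evaluated by adaptive Gauss–Hermite quadrature:
each country's integrand is re-centred at its conditional mode (damped
Newton on a strictly concave function, steps clipped at ±4, gradient
tolerance 1e-10) and scaled by the local curvature; 15 nodes by default
(1 node = Laplace). (β, σ) are maximized jointly by L-BFGS-B with σ bounded
in [0, 10]; at the σ = 0 boundary the likelihood continuously equals the
ordinary logistic one (special-cased below σ = 1e-8), so zero-variance data
collapse to a plain Logit fit — asserted to 1e-4 in the tests. The toy-data
likelihood is checked against brute-force numerical integration (1e-6), and
a grouped fixture against `lme4::glmer` at matched nAGQ (1e-3).

Standard errors come from the finite-difference Hessian of the marginal
log-likelihood in β at the estimated σ (the same conditioning `glmer`'s
Wald table uses); z = b/SE, two-sided normal p-values, OR = exp(b) and
95% CI exp(b ± 1.96·SE) are pure transforms of (b, SE). The random part is
reported as the variance σ² with SD σ. Rows with any missing model variable
are dropped listwise; no imputation is attempted.

The LRT null keeps the country random intercept ("unconditional
intercept-only" read as fixed intercept + random intercept), so the test
isolates the fixed effects: statistic 2(ℓ_full − ℓ_null), df = difference in
fixed-effect counts, upper-tail χ². With all eight non-intercept predictors
the computed df is 8; the study prints χ²(7), consistent with its
results-section predictor list, which omits gender while its coefficient
table includes it. The implementation always reports the computed df. The
same source tension exists for three odds ratios printed slightly
differently in text and table (1.92/1.95, 0.86/0.87, 1.10/1.08); the table
values are treated as canonical in the recovery targets.

## Problem sizes and runtime choices

Recovery experiments use a single n = 20,000 cohort (CI-containment check
against the reported intervals) and 50 replicates at the study's n = 2,547
(bias check: mean estimated b within 3 empirical SEs of the generating
values) — sizes at which a full run of the suite stays in the low minutes on
a single core while the Monte-Carlo error on each mean coefficient is a few
hundredths of a log-odd. The convergence sweep uses every integer threshold
in [0, 2000]; quadrature checks use 12-row toys where dense integration is
exact to machine precision.

## Known limitations

* The per-participant titration loop is pure Python; generating cohorts of
  hundreds of thousands would call for vectorizing the staircase.
* σ is a single scalar — no crossed or nested random effects beyond one
  grouping factor, and no random slopes.
* Wald intervals can misbehave with few groups or σ near the boundary;
  profile intervals are not implemented.
* The agreement utility handles two raters; multi-rater generalizations
  (Fleiss) are out of scope.
* Qualitative coding of free-text reasons is out of scope; only the
  agreement statistics used to audit such codings are provided.
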
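# Methods

This note documents the statistical models implemented in `dcmkit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that affect results.

## Latent structure

A respondent's state is a binary symptom profile over K diagnostic
criteria; the 2^K profiles are enumerated in binary-counting order with
criterion 1 as the least-significant bit. The ordering is fixed so that
posterior vectors are comparable across runs and label switching is
impossible: classes are identified by their profile, never by index. K is
configurable (guarded to K ≤ 20); the DSM-style instrument the package is
designed around has K = 9 and a diagnostic rule of m = 5 or more criteria
present.

The Q-matrix (items × criteria, 0/1) is validated on construction: binary
entries, every item measuring at least one criterion. A criterion measured
by *no* item is a warning at the container level — a partial item pool is
a legitimate object — but a hard error at estimation time, and the
screening loop refuses any drop that would uncover a criterion (the item
is retained with a `forced_keep` flag).

## Item response models

The canonical internal representation of an item is the saturated table of
2^{K\*} endorsement probabilities, one per reduced profile (the profile
restricted to the item's measured criteria). The six family members are
design matrices over that table on a link scale: G-DINA (identity link,
full factorial), ACDM/LLM/RRUM (identity/logit/log link, intercept + main
effects), DINA (intercept + top-order interaction) and DINO (intercept +
a shared "any criterion" effect). This uniform representation makes three
things one-liners: expansion of any reduced model to an exactly equivalent
saturated parameter set (solve the invertible factorial design), Wald
restrictions (the left null space of the candidate design), and the
discrimination index (last minus first table entry).

Parameter sets whose implied probabilities leave [0, 1] raise an error;
they are never silently clipped, because clipping hides mis-specification.
Bounds are instead enforced during estimation by constrained updates
(below). Monotonicity — non-negative main effects, so endorsement
probability is non-decreasing in the profile partial order — is an
on-by-default estimation constraint for the reduced models, toggleable via
`GDINAEstimator(monotone=...)`; whether the original calibration imposed
it is not documented anywhere we could rely on, so both behaviours are
supported. The saturated table itself is estimated unconstrained.

## Estimation

Marginal maximum likelihood by EM. The E-step computes class posteriors by
Bayes' rule (log-space, `logsumexp`); the M-step updates each item from
expected endorsement counts per reduced-profile group — closed form
R_g/N_g for the saturated table, small constrained optimisations
(SLSQP/L-BFGS-B with analytic gradients, warm-started from the previous
iteration) for reduced models, with a generalised-EM guard that never
accepts an update lowering the item's expected complete-data likelihood.
Item probabilities are kept in [10⁻⁴, 1 − 10⁻⁴].

The structural model over class proportions defaults to the saturated
2^K vector with Laplace smoothing ε = 10⁻¹⁰ per class per M-step (avoiding
empty-class collapse at K = 9, n ≈ 1,300); `independent` (one prevalence
per criterion), `uniform` and `fixed` structures are available.
Initialisation: item tables start at the item's sample mean plus a ramp
increasing with reduced-profile criterion count (±0.02 seeded noise) —
the ramp orients every item so the "all criteria" class starts above the
"no criteria" class, which is what rules out attribute-flip solutions;
proportions start uniform. Convergence: max |Δ probability| < 10⁻⁴ *and*
|Δ log-likelihood| < 10⁻⁷, cap 1,000 iterations; non-convergence is
flagged, not fatal. Missing responses (NaN) are marginalised out of the
respondent's likelihood, never imputed; a respondent with no observed
responses gets the structural proportions as posterior, with a warning.

**Covariance.** Wald tests need the covariance of the saturated table
estimates. We use the outer-product-of-gradients (empirical information)
of the incomplete-data score, computed *jointly* over all item tables and
the free structural parameters, inverted once (tiny ridge 10⁻¹⁰·scale for
rank safety) with per-item blocks extracted from the inverse. A
block-per-item approximation was measurably anti-conservative for
3-criterion items — the sampling variability induced by co-estimating the
class proportions is not negligible — and the joint version restores
nominal behaviour (checks below).

## Model selection

For each item with K\* ≥ 2, each reduced candidate is tested against the
saturated estimate with W = (Rf(θ))′(RDΣD′R′)⁻¹(Rf(θ)): R spans the left
null space of the candidate design, f is the candidate link applied to
the table, D the delta-method Jacobian, and df = 2^{K\*} − p_candidate.
A candidate is acceptable when the test is non-significant (p > α,
default α = 0.05 — no significant loss of fit relative to the saturated
model); the acceptable candidate with the largest p-value is selected;
if none is acceptable the saturated G-DINA is kept, and single-criterion
items are labelled G-DINA without testing since all members coincide
there. All five candidates are tested for every multi-criterion item.

Calibration, measured by simulation (200 replicates each): type-I error
of the test for a true main-effects item at n = 5,000 is 0.045 at nominal
0.05; selection recovers the generating family — counting ACDM/LLM/RRUM
as one near-equivalence class, since with moderate effects the three
links produce nearly identical probability tables and the largest-p rule
picks among them essentially at random — for well over 70% of
multi-criterion items at n = 2,000.

## Item screening

Three screens per item, with keep ⇔ no reason code:

* **Discrimination** — table(all present) − table(none present); flagged
  when strictly below the cut (default 0.45, so exactly 0.45 is kept).
* **S-X² item fit** — respondents grouped by rest score (raw total on the
  other J−1 items); expected endorsement per score group from the fitted
  model via the Lord–Wingersky score-distribution recursion over classes;
  adjacent groups collapsed (sparsest into its smaller neighbour) until
  both expected cells reach 1; df = groups − free item parameters; flagged
  at p < 0.05. Requires complete responses. Simulated type-I rate 0.082
  (pooled over 20 items × 200 replicates at n = 1,000) at nominal 0.05 —
  slightly liberal, as expected when the statistic is evaluated at
  estimated parameters. Note the df is computed self-consistently from
  the collapsed grouping; published per-item tables in this genre
  sometimes print df values that exceed the score-group bound of the
  final instrument (they reflect the longer pre-screening pool), so df
  values are not comparable across instruments of different lengths.
* **DIF Wald test** — the studied item is split into a reference-only and
  a focal-only column (the other group's entries set missing), the model
  refitted with all other items anchored, and equality of the two
  saturated tables tested with the joint-OPG covariance of the difference
  (including the cross-block); df = 2^{K\*} regardless of the selected
  reduced model — the convention consistent with published df patterns
  (8/4/2 for 3/2/1-criterion items). Groups below 50 respondents
  (configurable) yield a not-computable result with a warning. Simulated
  type-I 0.06; power 1.0 for a 0.2 intercept shift at n = 1,000/group.

The screening loop refits, re-selects models, recomputes all screens, and
drops every flagged item *simultaneously* (deterministic, unlike
sequential dropping, and compatible with "repeat until nothing is
excluded"), then repeats; it terminates in at most J rounds. No
multiple-testing correction by default (the raw p < 0.05 rule); a
Benjamini–Hochberg option exists but is off.

## Scoring

From the joint posterior over classes: per-criterion EAP marginals (sum of
posterior mass where the criterion is present); the MAP profile (ties
broken toward fewer criteria, then lowest class index, so a uniform
posterior maps to all-absent); and the probability of meeting the
diagnostic rule (PPIA) as the joint-posterior mass on classes with at
least m criteria — never the product-of-marginals tail, which ignores
posterior dependence among criteria: a respondent can have eight marginals
near 0.96 and still have nearly all joint mass on rule-meeting profiles.
Diagnosis is strict: PPIA > 0.5 (a PPIA of exactly 0.5 is negative).

## Evaluation

Cronbach's alpha and the Guttman split-half (odd–even item split; the
split is not specified in the emulated workflow, odd–even is the
package's choice) on sum scores. Symptom-level classification-consistency
reliability is a simulation estimator: draw latent classes from the
fitted proportions, simulate two independent response vectors per draw,
classify each on every criterion by EAP ≥ 0.5, report per-criterion
agreement. The index it operationalises (probability of consistent
criterion classification across parallel administrations) is implemented
as stated because no closed form is available to us; it is labelled a
simulation estimator throughout. Accuracy metrics: confusion counts,
sensitivity/specificity, diagnostic odds ratio with log-normal Wald 95%
CI (Haldane 0.5 on zero cells, flagged), Mann–Whitney AUC (ties count
half; cross-checked against trapezoidal ROC integration), pooled-variance
two-sample t with Cohen's d, and Pearson correlations for external
criterion scores.

Recomputing the published validation comparison from its printed group
summaries (means 30.19/7.82, SDs 10.54/9.56, n = 96/199) gives t(293) =
18.21 against the printed 18.25 — the difference is rounding of the
inputs — and Cohen's d = 2.26 against the printed 2.23; the printed DOR
45.30 is likewise not exactly recoverable from the printed sensitivity,
specificity and group sizes. These are discrepancies in the source
material; we report our recomputed values and do not resolve them.

## Synthetic data: what it emulates, and what it does not

The generator's default scenario reproduces the emulated study's design:
K = 9 criteria; a 50-item instrument with 1–3 criteria per item, mean
about 1.46 and balanced coverage (items per criterion concentrated around
7–8, matching the published 5–10 range — a uniform random assignment
produced 4–15 and measurably degraded weakly covered criteria); a
complete design (each criterion has a single-criterion item) for
identifiability, which an expert-built Q-matrix provides implicitly and a
random generator must guarantee; item baselines U(0.10, 0.30) and
all-vs-none discriminations U(0.45, 0.65), the published range of the
retained items; a calibration sample of n = 1,263 (75% healthy-like, 25%
disordered-like so all profile regions are observed); and a validation
sample of 199 healthy + 96 disordered respondents.

Disordered-group profiles are a rule-mixture: with probability 0.9 a
clinically severe profile (independent Bernoulli(0.8) per criterion,
conditioned on meeting the ≥ 5 rule), otherwise a healthy-like draw
representing imperfect recruitment. The severe component matches the
published disordered-group posterior profile (mean PPIA near 0.9, members
mostly well above the 5-criterion boundary); a plain independent draw
with P(count ≥ 5) = 0.9 instead piles ~27% of cases at exactly five
criteria, which no scoring method separates reliably. Healthy-group
profiles are 85% low-prevalence (Bernoulli(0.2), typical members meeting
at most a couple of criteria) and 15% borderline — Bernoulli(0.45)
truncated below the rule (count ≤ 4) — emulating controls screened on
manifest behaviour rather than latent status.

With these defaults the full pipeline attains sensitivity ≈ 0.90–0.93,
specificity ≈ 0.96, AUC ≈ 0.99 against the generating diagnoses (means
over five replicate studies). This reproduces the qualitative pattern of
the published 0.935 / 0.815 / 0.919, not the numbers: the study's data
are not deposited, and its reference standard was the recruitment label,
not the latent rule — so its healthy-group "false positives" include
genuinely symptomatic controls, depressing published specificity in a way
a latent-truth simulation cannot and should not mimic. Passing the
synthetic checks shows the estimation, selection, screening and scoring
machinery is correct and well calibrated under the model's own
assumptions; it does not show the instrument works on real populations,
where local item dependence, polytomous information loss, and Q-matrix
mis-specification are all live threats the generator deliberately omits.

## Problem sizes used in the checks

Parameter recovery runs each family member at K = 3, J = 15, n = 2,000;
Wald calibration uses 200 replicates at n = 5,000 (type-I) and two
n = 2,000 datasets (family recovery); S-X² and DIF calibration use 200
replicates at n = 1,000–2,000; the end-to-end study is at full design
scale (1,263 + 295, K = 9) with five replicates. These sizes give
Monte-Carlo error comfortably inside each check's tolerance.

## Known limitations

Binary responses only (no polytomous items); no Bayesian/MCMC estimation;
no higher-order or regularised structural models; no DIF purification or
anchor refinement (all other items anchor); the S-X² screen requires
complete data; saturated structural estimation at K = 9 is noisy at
n ≈ 1,300 (the smoothing and the independent-structure option mitigate
but do not remove this); and the classification-consistency index is a
simulation estimator, not a closed form.
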
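# Methods

## The case/non-case design

`pvsignal` implements disproportionality analysis for spontaneous-reporting
(pharmacovigilance) databases. Within a database of individual case safety
reports (ICSRs), *cases* are reports of the adverse event of interest and
*non-cases* are all other reports. For an exposure E and the 2×2 table

|            | cases | non-cases |
|------------|-------|-----------|
| exposed    | a     | c         |
| unexposed  | b     | d         |

the crude **reporting odds ratio** is r-OR = ad/bc, with Woolf standard
error of the log r-OR, se = √(1/a + 1/b + 1/c + 1/d), and 95% CI
exp(log r-OR ± 1.96·se). The r-OR is a signal-detection statistic, not a
risk estimate: reporting is selective, denominators are unknown, and an
r-OR below 1 is never interpreted as protective.

The target study design is an analysis of delirium reporting and
antidepressant exposure among adults aged ≥ 65: a composite delirium
outcome over the preferred terms {Delirium, Confusional state,
Disorientation}; six exposure classes (NSMRI, SSRI, SNRI, MAOI,
alpha-2-adrenergic receptor antagonists, other antidepressants); exposure
counted in any reporter role (suspect, concomitant, interacting);
a per-drug analysis restricted to drugs mentioned in strictly more than
1000 reports; age-band subgroups (65–74 vs 75+); a concomitant
delirium + hyponatraemia outcome; three nested sensitivity definitions of
delirium; and positive (ATC N02AA, natural opium alkaloids) and negative
(ATC M05BA, bisphosphonates) control exposures.

## Adjusted estimates

Adjusted r-ORs are exp(β) from a multivariable logistic regression of case
status on exposure indicators and confounders, with Wald 95% CIs. The
default adjustment set is age band (reference 65–74), sex (reference F),
region (reference = most frequent level; missing region is its own
"Unknown" level), four co-prescription classes matched by ATC prefix
(opioids N02, antipsychotics N05A, anxiolytics N05B, hypnotics N05C), and
a dictionary of delirium-predisposing illnesses matched as single
preferred terms (dementia, dehydration, hyponatraemia, infection, etc.).
The illness→PT dictionary is deliberately flat and configurable — no
licensed terminology hierarchy is shipped or traversed.

Design-matrix conventions, all logged on the `DesignMatrix`:

- Constant adjustment columns are dropped (a subgroup makes the age band
  constant, for instance); a constant *exposure* column is an error.
- When an exposure lies inside a drug-ATC confounder's prefix (the
  positive control N02AA sits inside the opioid confounder N02), the
  confounder column is computed excluding the exposure's drugs, avoiding
  built-in collinearity.
- Adjustment columns with an empty outcome cell (no events among the
  exposed to that covariate, or none among the unexposed) have an infinite
  MLE and are dropped before fitting. Exposure columns are never silently
  dropped: an exposure with zero exposed cases keeps its zero-cell-corrected
  crude estimate and is excluded from the adjusted model with an explicit
  flag.

The exposure estimate is invariant to the reference-level choices; the
choices above are for numerical stability and are recorded per run.

## Numerical details

- **Fitting** is iteratively reweighted least squares (Newton–Raphson on
  the binomial log-likelihood). Convergence requires a relative deviance
  change < 1e-8 *and* a maximum coefficient step < 1e-6 (the extra Newton
  step, with quadratic convergence, pushes coefficient error far below the
  1e-6 agreement the 2×2 closed-form checks require). Cap: 100 iterations;
  exceeding it raises, never returns a silently unconverged fit.
- **Separation** is diagnosed when any slope passes |β| > 15 while still
  growing between iterations, or the information matrix becomes singular;
  the error names the offending column.
- **Intervals** use z = 1.96 exactly, for both Woolf and Wald CIs. Using
  the exact 97.5% normal quantile for one and 1.96 for the other would
  break the algebraic identity (for a saturated 2×2 model the inverse
  observed information is exactly 1/a + 1/b + 1/c + 1/d, so Wald = Woolf);
  the difference is ~4e-6 on the log scale, far below any reporting
  precision.
- **Zero cells**: Haldane–Anscombe, +0.5 on all four cells, applied only
  when a zero occurs, with the estimate flagged; `n_exposed_cases` always
  reports the uncorrected count. With correction disabled, a zero cell is
  an error rather than an infinite estimate.
- **Low counts**: estimates with fewer than 10 exposed cases carry a flag;
  they are reported, never suppressed.
- **Signal rule**: signal ⇔ lower 95% bound > 1. Estimates with point
  below 1 are no_signal by construction.
- **Collinearity**: classical VIFs on the dummy-coded covariate matrix,
  VIF_j = 1/(1−R²_j) with R²_j from an intercept-including OLS of column j
  on the rest; exact collinearity reports an infinite VIF naming the
  column; columns with VIF > 5 are flagged. Generalized VIFs for
  multi-level factors are not computed — the matrix is already
  dummy-coded, and the per-column diagnostic is what the flag acts on.
- No multiplicity correction is applied across exposures; the run
  manifest records the number of tests so a reader can apply their own.

## The synthetic generator

Real spontaneous-reporting databases are proprietary, so validation runs
on simulated ICSRs whose generative process makes the adjusted estimand
exact. Per report, with one seeded stream and a fixed draw order
(demographics → confounders → drugs → case → hyponatremia → events):

- age band 65–74 with probability 0.41 (else 75+, uniform ages, truncated
  at 95 — arbitrary and irrelevant to banded analyses); sex F with
  probability 0.54, missing with probability 0.005; region categorical.
- confounders Z_j ~ Bernoulli(π_j); an `event_pt` confounder adds its PT
  to the report, a `drug_atc` confounder adds a marker drug as a
  concomitant entry.
- exposures X_d ~ Bernoulli(logistic(α_d + Σ_j δ_dj Z_j)); reporter roles
  drawn 0.70/0.25/0.05 (suspect/concomitant/interacting) — downstream
  analysis is role-agnostic, so these weights only exercise the parser.
- case status Y ~ Bernoulli(logistic(β0 + Σ_d β_d X_d + Σ_j γ_j Z_j)):
  **exp(β_d) is exactly the adjusted odds ratio the pipeline estimates**,
  and is recorded as ground truth.
- hyponatremia H ~ Bernoulli(logistic(η0 + Σ_d η_d X_d)), adding the
  "Hyponatraemia" PT — a pathway by which a drug can raise the joint
  delirium + hyponatraemia outcome.
- a case draws one of {Delirium 0.3, Confusional state 0.5,
  Disorientation 0.2} (weights are invented and configurable; only
  membership matters to labelling); reports with no other event receive
  1–3 background PTs so every ICSR has at least one event.

Preset scenarios fix the study conditions used throughout testing:
`null` (all effects 0; n=5,000 — large enough that the Woolf interval's
asymptotic 2.5% one-sided tail is accurate at ~60 expected exposed
cases), `single_effect` (one drug, true OR 3, n=50,000), `confounded`
(no direct effect; dementia with γ = δ = log 3, n=20,000), `study_like`
(six classes with heterogeneous ORs between 1 and 3, an opioid
co-prescription confounder at prevalence 0.34, a dementia confounder at
prevalence 0.02, an SSRI hyponatremia pathway with η = log 4, n=30,000),
and `controls` (morphine OR 3, alendronate OR 1, n=30,000).

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: duplicate reports, reporting-delay and
notoriety dynamics, under-reporting (e.g. of hypoactive delirium),
country-specific reporting cultures, dose/time fields, real covariate
prevalences (dementia is famously under-recorded in ICSRs), and real
correlation structure among co-reported events beyond the modelled
confounders. The validation shows the estimators and pipeline are correct
under the stated model, not that the model is the world.

## Validation experiments

The acceptance suite (and `scripts/acceptance.py`, which recomputes the
same quantities from scratch) runs: exact agreement between the logistic
route and ad/bc with Woolf CIs on random 2×2 tables (50 tables, tolerance
1e-6); hand-checked closed forms; Woolf CI coverage at true OR 2 (2,000
tables of n=2,000); signal-rule calibration under the null (2,000
replicates, expected ~2.5% firing); confounding removal (200 seeds:
crude CI excludes 1 in ≥80%, adjusted contains 1 in ≥90%); parameter
recovery (200 seeds at n=50,000, median within 10% of OR 3); the control
harness (100 seeds, joint pass ≥95%); and structural invariants
(definition nesting, age-band partition, byte-level determinism, the
signal rule on the canonical control pattern 3.35 [3.25–3.44] /
1.04 [0.99–1.09]). Replicate counts and problem sizes are the package's
standing validation conditions; they are what the Monte-Carlo error bands
in the assertions were derived for.

## Known limitations

- Wald/Woolf intervals, not exact or Firth-penalized logistic regression:
  fine at database scale, anti-conservative for very sparse exposures
  (which is what the low-count flag marks).
- The class membership lists and the illness→PT dictionary are pragmatic
  defaults, not licensed reference vocabularies; both are configuration.
- Complete-case handling covers sex (and optionally region) only; no
  imputation is provided.
- The r-OR remains a reporting statistic; nothing here estimates incidence
  or risk.
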
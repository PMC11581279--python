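# Methods

This package compares two ways of predicting the 5-year survival status of
endometrial-cancer patients from 13 coded clinicopathological variables: a
tree-augmented naive Bayes (TAN) classifier and a Cox proportional-hazards
(CPH) model. The original registry extract (n = 618, SEER 2010–2015) and the
hospital validation cohort (n = 104) are not publicly deposited, so all
experiments here run on synthetic cohorts whose construction is described
below. This note records the models, the generator, the numerical choices,
and what the synthetic experiments can and cannot establish.

## Data model

A patient is a vector of 13 categorical levels (age group, tumor site,
grade, histological type, FIGO stage, radiotherapy/surgery sequence,
radiotherapy, chemotherapy, lymph-node resection, lymph-node metastasis,
tumor size, depth of invasion, distant metastasis; 38 levels in total),
plus follow-up months t ∈ [1, 60] and a death indicator. The 5-year label
is *Dead* if the event occurred within follow-up, *Alive* if the patient was
followed the full 60 months without the event, and *Indeterminate* if
censored alive earlier. Indeterminate patients cannot be classified either
way, so they are excluded from accuracy/AUC/Youden computations but retained
for Cox fitting and the C-index, which handle censoring natively. (The
source study never states its rule for such patients; this conservative
exclusion is our choice.)

Splitting is a seeded random partition with training size
round-half-up(n × fraction): 618 × 0.75 → 464/154, the study's sizes.

## Synthetic cohort generator

The generator is a first-class, tested component; its defaults *are* the
study conditions rather than tunable knobs.

* **Covariates.** Each variable's marginal level frequencies equal the
  published cohort's frequencies (e.g. tumor size <4 cm: 0.584; lymph-node
  metastasis absent: 0.763). Two published rows do not sum to one at the
  printed precision (tumor site: 0.999; grade: 0.990); all rows are
  renormalized. The published description gives only marginals, so the
  joint distribution is a modelling choice: a small DAG —
  stage → lymph-node metastasis → distant metastasis and
  grade → histological type — realized by iterative proportional fitting
  of a log-linear (ordinal odds-tilt) affinity onto the two marginals.
  IPF preserves every marginal exactly while inducing the positive
  clinical associations (metastasis more likely at higher stage, etc.).
* **Survival.** Proportional hazards by construction:
  T = b·(−ln U / e^{β'x})^{1/k} (Weibull baseline, shape k, scale b),
  discretized to whole months by ceiling (minimum 1) and administratively
  censored at 60 months, matching registry month-resolution follow-up.
  The per-level log-hazards β default to the published multivariate Cox
  coefficients (e.g. age >80: 1.456; undifferentiated grade: 1.770); the
  two univariately null variables get 0, and chemotherapy — whose
  multivariate row was not published — gets +0.35, a moderate adverse
  effect consistent with its univariate screen.
* **Calibration.** Shape k = 1.1 makes the simulated mean/median follow-up
  ≈ 50/60 months, matching the described cohort. The scale was then fixed
  once by bisection (`calibrate_baseline_scale`, kept in the package and
  covered by a test) so that the marginal 60-month death fraction over the
  covariate distribution equals 192/618 ≈ 0.311; the result,
  b = 4143.570637 months, is stored as the default constant.
* **Early censoring.** An optional rate parameter censors a random
  fraction uniformly over months 1–59, emulating the hospital cohort's
  incomplete follow-up (its minimum was 5 months). Default 0.

What the generator does **not** emulate: the true SEER joint covariate
distribution (only 13 marginals and 3 chosen dependencies), competing
risks, calendar-time effects, or any non-proportional hazards. Tests that
pass on these cohorts therefore establish the *correctness of the
machinery* under a proportional-hazards world matched to the published
margins — not the study's empirical findings, which depend on the
undeposited data. In particular, on these cohorts the CPH model is
correctly specified and typically edges out the TAN classifier
(test AUC ≈ 0.71–0.84 vs ≈ 0.61–0.76 over seeds at n = 618), whereas the
original study reported the reverse on real data.

## TAN classifier

Friedman's construction: the class is a parent of every attribute, and
attributes are joined by the maximum-weight spanning tree under the
class-conditional mutual information I(X_i; X_j | C), computed in bits from
empirical frequencies (0·log 0 := 0). Steps: pairwise CMI → undirected
maximum-weight spanning tree → orientation away from a root → CPT
estimation → exact posterior inference by normalized CPT products.

Numerical choices, all deterministic:

* **CMI is class-conditional.** Some descriptions of the four-step recipe
  say only "mutual information", but Friedman's tree-augmented classifier —
  the construction implemented here — weights edges by mutual information
  conditional on the class.
* **MST: Kruskal**, ties broken lexicographically by attribute order, so
  structures are reproducible across platforms. Correctness is tested
  against exhaustive enumeration of all n^(n−2) spanning trees (n ≤ 6).
* **Root.** The tree factorization encodes the same joint for any root, so
  the choice is cosmetic; the pipeline roots at the highest-ranked selected
  variable. Root invariance of posteriors is exact for maximum-likelihood
  CPTs and is tested at 1e−10; with smoothing it holds to O(alpha/n)
  (tested at 0.02), because additive smoothing perturbs each CPT
  separately.
* **Smoothing alpha = 1** (Laplace) by default: with 464 training records
  and CPT strata as fine as class × 4 parent levels × 5 child levels,
  unsmoothed cells are frequently empty. All posteriors are then strictly
  inside (0, 1).
* **Decision rule:** Alive iff P(Alive | x) ≥ threshold, ties to Alive;
  threshold 0.5 is the Bayes accuracy rule, and the pipeline can instead
  freeze a Youden threshold on the training set (below).

## Variable importance (MMFV) and selection

The importance measure is named "mean multi-state Fussell–Vesely" after
the reliability-engineering family it adapts, but no defining formula for
the original analysis is published and no candidate we tried reproduces
its reported values, so those values are treated as non-reproducible. The
measure implemented here — fixed in code and tested against its own
enumeration oracle — is computed from the *fitted network* by inference:
with P(D) the model's marginal death probability and P(D | V = j) obtained
exactly from the tree,

    MMFV(V) = (1/m) · Σ_j  max(0, P(D | V=j) − min_k P(D | V=k)) / P(D)

i.e. the average over the variable's m states of the positive part of the
relative excess death probability over its most favorable state. It is 0
exactly when the variable is independent of the outcome in the model,
non-negative, invariant to state relabeling, and monotone in the
class–variable dependence (all tested).

*Limitation:* plug-in inference at rare levels is noisy — a level observed
in ~2% of patients can earn a large MMFV from sampling fluctuation in its
CPT, so rankings of very rare levels should be read with caution.

Variables are ranked by descending MMFV (ties by codebook order). The
number kept follows the study's forward scheme: for each candidate k the
top-k variables are scored by stratified 5-fold cross-validated accuracy
on the training set; the best k wins, ties to the smaller k (the study
kept 10 of 13 but does not say how; this rule is our documented choice).

## Cox model

Written from scratch against the log partial likelihood. Categorical
variables are dummy-coded against their reference levels (25 columns for
the 13-variable scheme); a record at all reference levels has linear
predictor 0.

* **Ties:** Efron's correction by default (Breslow by flag) — month-valued
  times are heavily tied. Both reduce to the same expression for distinct
  times (tested to 1e−8).
* **Optimization:** Newton–Raphson from β = 0 with up to 10 step-halvings
  per iteration on likelihood decrease; converged when max |score| < 1e−8,
  cap 50 iterations. The covariance is the inverse observed information;
  a singular information matrix (separation / monotone likelihood) is
  reported as a warning with a pseudo-inverse fallback. The analytic score
  is validated against central finite differences (1e−6) and full fits
  against lifelines (1e−5).
* **Constant columns** (a level unobserved in training, common at n ≈ 450
  with 2% levels) are dropped with a warning, coefficient 0, rather than
  failing the fit.
* **Screen:** per-variable likelihood-ratio tests, df = observed levels − 1,
  p from chi-square; type-I error is verified by simulation.
* **Baseline & prediction:** Breslow cumulative-hazard increments
  d_t / Σ_{risk} e^{β'x} (Nelson–Aalen at β = 0, tested against a hand
  example); S(t|x) = S0(t)^{e^{β'x}}, with the last baseline value carried
  (and a warning) past the final event time.

## Evaluation

Positive class is Alive, matching the study's confusion-matrix layout.
Survival-probability scores are swept over observed thresholds for the ROC
curve; AUC is the trapezoidal area and equals the Mann–Whitney pair
probability with ties at 1/2 (tested to 1e−12 against the O(n²) count).
The operating threshold maximizes Youden's J = sensitivity + specificity − 1
over observed scores, smallest threshold on ties; it is derived on
*training* predictions and frozen before test evaluation (the study does
not say which set it used — this is logged prominently in every run).
Harrell's C-index uses the comparable-pair rule — pairs (i, j) with
t_i < t_j and patient i's event observed; risk ties count 1/2 — with the
Cox linear predictor and the TAN posterior death probability as risk
scores. No IPCW weighting, confidence intervals, or calibration measures.

## Pipeline and problem sizes

`run_pipeline` chains simulate/read → split → univariate screen →
multivariate Cox → importance ranking → CV selection → TAN fit → threshold
derivation → test (and optional external) evaluation, with per-stage seeds
derived from the single run seed, and `render_report` writes the tables
(univariate, multivariate, importance, confusion matrices, metric
summaries, ROC points, run log) with byte-stable content for a fixed
config. Simulation-backed tests use n = 618 cohorts (the study size) for
end-to-end checks, n = 1000–20000 for parameter-recovery checks, and 400
replicates at n = 200 for the type-I-error check of the univariate screen —
sizes at which the Monte-Carlo error is comfortably inside each asserted
band on a single CPU.
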
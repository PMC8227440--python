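# Methods

## The classification problem

MS typically begins with a relapsing–remitting (RR) course and later
converts to a secondary progressive (SP) course of steady disability
accrual. Registries record a neurologist-assigned phenotype and, for SP
patients, a transition date, but that assignment is retrospective and
rater-dependent. The package's core object is a fixed binary decision
tree over two cross-sectional variables — the most recent EDSS score
(ordinal, 0–10 in 0.5 steps with no 0.5 value) and the age at that
assessment — whose nine leaves partition the (EDSS × age) plane and carry
the training-cohort probability of SPMS. The label is SP exactly when
that probability exceeds 0.5.

### Boundary conventions

The printed age bands ("<56", "56–64", "⩾64") are implemented as
half-open intervals [0, 56), [56, 64), [64, ∞) — the only disjoint
reading — and likewise [0, 45)/[45, ∞). Behaviour exactly at ages 45, 56
and 64 is therefore a convention of this implementation, not something
the published rule table pins down; the constants are visible in
`published_tree.RULES`. Ages are real-valued by default; a `floor_age`
flag truncates to whole years for registries that store integer ages.
EDSS membership is exact membership on the 0.5 grid. If validation is
relaxed to admit a (nonexistent) EDSS of 0.5, it is folded into the
"EDSS < 3" leaf.

## CART trainer

`cart` re-derives trees of this kind by recursive partitioning:

* **Growth.** Greedy binary splits maximising the decrease in Gini
  impurity `G = 1 − p² − (1−p)²`; candidate thresholds are midpoints
  between consecutive distinct sorted feature values; growth stops at
  pure nodes, nodes smaller than `min_node_size` (default 20), or when no
  split has strictly positive gain. Tie-breaks go to the smaller
  threshold, then the earlier feature, so fits are bit-reproducible.
  Zero-gain splits are never taken; a pure interaction with no marginal
  signal (XOR) therefore yields a root leaf, matching rpart's behaviour.
* **Pruning.** Weakest-link cost-complexity pruning. For an internal node
  `t` with subtree `T_t`, `g(t) = [R(t) − R(T_t)] / (|leaves(T_t)| − 1)`,
  with `R` the count-weighted Gini risk, scaled by the root risk so that
  the complexity parameter cp is the fraction of total impurity a split
  must recover per leaf it adds. A split survives pruning iff its scaled
  per-leaf improvement strictly exceeds cp; collapsing proceeds
  iteratively from the weakest link, which yields nested subtrees along
  the cp path. The strict inequality is chosen so that cp = 0 leaves a
  grown tree unchanged while cp = 1 always collapses to the root, even
  for a perfectly separating split.
* **cp selection.** Stratified k-fold cross-validation (default 10 folds)
  over the pruning path of the full-data tree. Candidate cp values are
  geometric means of consecutive critical values, so each candidate
  indexes one distinct subtree. The cp with minimal mean misclassification
  error wins; ties go to the larger cp (simpler tree). No 1-SE rule is
  applied: on pure-noise labels the minimal-error rule selects the stump
  only about half the time (the independent rpart reference behaves the
  same); what it reliably does is collapse the tree to a small fraction
  of its grown size with cross-validation error at chance level, and that
  is what the tests assert.
* **Variable importance** is each variable's summed impurity improvement
  over the splits that use it, normalised to sum to one. Missing feature
  values are rejected; surrogate splits are not implemented.

On two-feature instances of up to 200 records the trainer's in-sample
predictions are checked against scikit-learn's `DecisionTreeClassifier`
with matched settings, and on 10,000 simulated patients labelled by the
rule table plus 5% label flips, cross-validated fitting recovers the
published EDSS groupings and age thresholds to within two years of
45/56/64 — the package's substitute for registry-scale validation, since
the underlying individual-level data are only available by agreement.

## Confirmed-progression detector

The longitudinal detector scans visits chronologically with a roving
baseline: the lowest EDSS among relapse-free visits seen so far. A
relapse-free visit is one with no relapse within `relapse_window_days`
(default 30) on either side; the window is our choice, as is the roving
baseline (a fixed first-visit baseline is available via
`baseline_mode="first"`). A candidate event is the first relapse-free
visit with EDSS ≥ baseline + 1.0 (baseline < 6) or + 0.5 (baseline ≥ 6)
and EDSS ≥ 4.0. The banded increase is keyed on the *baseline* EDSS;
keying on the event EDSS would also be defensible and is noted as
ambiguous. Confirmation requires a later relapse-free visit at least
`confirmation_days` (default 91 ≈ 3 months) after the event with EDSS
still at or above baseline + required increase, and every intervening
relapse-free visit staying at that level — standard sustained-progression
semantics. The conversion date is the event date, not the confirmation
date. The pyramidal functional-system criterion (FS ≥ 2 at event and
confirmation) is off by default — i.e. treated as satisfied — because
many registries do not record FS sub-scores; enabling it on data without
FS values makes conversion impossible and emits a warning. Patients with
fewer than two visits are labelled RR with a "no longitudinal data" flag.

## Evaluation

Diagnostic accuracy uses the standard confusion-matrix identities with RR
as the positive class by default (the reporting convention of the
registry study this package follows); swapping the positive class swaps
sensitivity↔specificity and PPV↔NPV exactly. Binomial 95% CIs are Wilson
score intervals by default (better small-sample behaviour than Wald,
which is available for comparison); the original report does not state
its interval method.

Kaplan–Meier curves are computed with lifelines (product-limit estimator,
Greenwood-based confidence band, Brookmeyer–Crowley-style median CI).
Time to SP is measured from birth or from symptom onset; patients without
an event under a given labeller are censored at their last visit. The
published tree yields a status, not a date, so its event time is the
earliest visit at which the tree classifies the patient SP — a
convention of this package. The confirmed-progression labeller uses its
event date; clinical labels use the recorded transition date (a bare
recorded year is imputed to July 1, flagged as imputed).

## Synthetic cohorts

No registry data ship with the package, so `simulate` draws cohorts from
the simplest generative model matching published marginal summaries:

| quantity | default | rationale |
|----------|---------|-----------|
| female fraction | 0.714 | registry marginal |
| onset age | N(32.4, 10.2) truncated to [5, 70] y | registry marginal; truncation bounds ours |
| disease duration at last visit | log-normal, median 14 y, log-SD 0.88 | median and IQR-matched |
| onset→SP latent time | log-normal, median 25 y, log-SD 0.5 | matches the clinical-label KM median; log-SD ours |
| visit interval | ~ Exp(1 y), clipped [0.25, 2.5] | roughly annual registry visits |
| relapse rate (RR phase) | 0.35/y decaying with half-life 15 y | declining relapse activity with duration |
| SP-phase EDSS drift | +0.35 points/y, ratcheted | steady progressive accrual |

A patient is SP when the latent transition time falls inside follow-up;
the assigned phenotype and transition date are taken from it (optionally
perturbed by `label_noise`). RR-phase disability is a per-patient stable
set point — a mild majority, N(1.5, 0.8) truncated to [0, 3.5], and a
12% severe tail uniform on [3.5, 6.5] — with fast mean-reverting
fluctuation (stationary SD 0.3, reversion 1/y, exact
Ornstein–Uhlenbeck transitions), so stable-but-disabled RR patients
exist: they are what a cross-sectional classifier misclassifies, while
confirmed progression stays rare in RR. Visits within 60 days after a
relapse get a transient +1.0 on the observed EDSS. Scores are snapped to
the valid 0.5 grid (0.5 itself maps to 0 or 1) and capped at 10.

The generator reproduces the configured *marginals*; it does not model
joint dependence beyond what the mechanism implies (e.g. onset age and
transition hazard are independent), treatment effects, historical-era
differences or registry missingness. Passing tests therefore show that
the algorithms behave as specified on data with the published summary
structure, not that registry-scale accuracies would be reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 10,000 patients for
calibration and survival checks, 3,000–4,000 for directional comparisons
and 200–400 for unit-level fits; these sizes put Monte-Carlo error well
inside the asserted tolerances while keeping the whole suite fast. Ages
use a 365.25-day year. Duplicate same-day visits collapse to the maximum
EDSS (conservative toward progression; configurable). Degenerate inputs
are defined rather than erroneous where a sensible value exists:
single-class training data give a depth-0 leaf, a leaf with SP fraction
exactly 0.5 is labelled RR, all-censored survival data report the median
as not reached.

## Known limitations

* The rule table's behaviour exactly at ages 45/56/64 is a convention.
* The detector's relapse window, confirmation semantics between sparse
  visits, and baseline banding are choices the source description leaves
  open; all are configurable.
* The simulator is calibrated to marginals of one historical registry
  snapshot and makes no claim of patient-level realism.
* CART here is binary-class, two-or-few-feature, no surrogate splits, no
  case weights — deliberately scoped to the phenotype problem.
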
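# Methods

## Clinical problem and model

Clinically relevant postoperative pancreatic fistula (CR-POPF, ISGPS grade
B/C) is the most dangerous complication of pancreaticoduodenectomy. The risk
is dominated by gland texture: a soft pancreas with a non-dilated main
pancreatic duct (MPD) inside thick parenchyma leaks; a hard, fibrotic gland
with a dilated duct does not. `crpopf` implements a purely preoperative risk
model built on this anatomy:

1. patients are stratified by preoperative diagnosis — pancreatic ductal
   adenocarcinoma (PDAC) versus everything else — because duct obstruction
   in PDAC produces fibrosis and a hard gland, changing which markers carry
   risk;
2. within each stratum a **discrete Bayes classifier** is applied to
   cut-off-dichotomized markers: the MPD index (duct diameter / parenchymal
   thickness, cut-off 0.3) for PDAC, and the MPD index plus BMI (cut-off
   25 kg/m²) for non-PDAC.

### The discrete Bayes classifier

With k binary markers a patient occupies one of 2^k cells. From training
counts n_{c,cell} the classifier estimates priors P(c) (empirical class
frequencies) and class-conditional cell probabilities

    P(cell | c) = (n_{c,cell} + α) / (n_c + α·2^k),

and predicts the class with maximal posterior P(c)·P(cell|c). This is a
*joint-cell* estimate, not a naive-Bayes factorization: with k ≤ 3 the table
has at most 8 cells, well supported at clinical training sizes, and it can
represent interactions (e.g. the non-PDAC "high index but high BMI" cell). A
naive-Bayes variant (`independent=True`) exists for comparison only.

Numerical choices:

* **Ties predict positive.** The model is built to avoid missing a fistula,
  so an exactly balanced posterior routes the patient to the high-risk arm.
  The decision is computed in cross-multiplied, quotient-free form (products
  of integer counts, exact in double precision), so ties resolve by the rule
  rather than by float round-off — with α = 0 and empirical priors the rule
  provably reduces to comparing raw per-class cell counts.
* **Smoothing default α = 1** (Laplace), so leave-one-out folds never
  produce zero-probability cells; α = 0 gives maximum-likelihood estimates
  and is used in hand-checkable fixtures.
* A cell unseen in training at α = 0 falls back to the prior comparison.

### Marker panel and discretization

Fourteen candidate predictors: age (cut-off 65 y), male sex, BMI (25),
visceral fat area (100 cm²), prognostic nutritional index (45), albumin,
parenchymal thickness, MPD size (3 mm), MPD index (0.3), diabetes,
preoperative biliary drainage, CONUT score (≥ 3), sarcopenia, and the
diagnosis itself (which becomes the stratification variable and is excluded
from stratified selection). A continuous value exactly at its cut-off goes
to the upper bin. Albumin and parenchymal thickness have no published
cut-off; the package uses 3.5 g/dL (the standard hypoalbuminemia threshold)
and 13 mm (the typical parenchymal thickness in such cohorts). Both serve
only as candidate noise markers in every experiment asserted here, so the
choice does not move any reported number. PNI uses the Onodera form
10·albumin + 0.005·lymphocytes; CONUT uses the standard
albumin/lymphocyte/cholesterol bands. Missing values are errors, never
imputed, because the analysis is complete-case.

## Leave-one-out wrapper selection

Markers are not selected individually — a marker useless alone can be
decisive in combination — so the optimal *combination* is found by an
exhaustive search wrapped in a leave-one-out loop: for each held-out
sample, every combination of size 1..k_max is fitted on the remaining N−1
samples and scored by **re-substitution** (classifying those same N−1
samples); one combination is selected per fold, and the most frequently
selected combination across the N folds wins. The held-out sample never
influences its fold's selection. Two per-fold criteria are provided:
maximal sensitivity subject to specificity ≥ 50% (default; if no
combination meets the floor the fold falls back to maximal F1, logged), and
maximal F1.

Design choices where the procedure was genuinely open:

* **Ties** — everywhere: fewer markers first, then lexicographic marker
  names. This makes the whole procedure deterministic.
* **Sizes** — `leave_one_out_selection` searches sizes 1..k_max in a single
  tally (so one call can return a single-marker winner in one stratum and a
  pair in another), while `per_size_report` repeats the selection once per
  size, the way size-by-size report tables are constructed.
* **Optimism** — selection uses re-substitution scores by construction;
  `loo_heldout_performance` reports the honest held-out performance of the
  winner so the optimism is visible.
* **Implementation** — within one combination, a fold's sub-training table
  is the full count table minus one sample, so the fitted classifier
  depends only on the held-out sample's (label, cell) pair. Folds are
  grouped accordingly: at most 2·2^k distinct evaluations per combination
  instead of N, with bitwise-identical results (a test checks equivalence
  against the direct refit-every-fold route).

The budget is small: N = 180, sizes 1–3 over 14 markers is 469 combinations
per fold, and the grouped evaluation completes in well under a second.

## Performance metrics

Sensitivity, specificity, PPV, NPV from the 2×2 confusion matrix (positive
class = CR-POPF); F1 as the harmonic mean of PPV and sensitivity. A metric
with a zero denominator is reported as undefined (`None`), never as 0.
Report tables round half-up to whole percents but always keep the raw
ratios; two published validation figures (non-PDAC specificity 61/114 =
53.5% and PPV 98/151 = 64.9%) appear truncated rather than rounded in the
source tables, so the raw ratios are the authoritative values here.

## Synthetic cohorts

No patient-level data are public, so the generator builds cohorts with the
statistical structure the analysis assumes, and it is the basis of every
stochastic test.

**What it emulates.** Marker marginals match the published cohort
composition (median BMI ≈ 22.3, MPD index ≈ 0.33, albumin ≈ 4.0,
PNI ≈ 47.7, parenchymal thickness ≈ 13 mm, ≈ 59% male, 47% PDAC);
dependent fields are generated consistently (MPD index is always the ratio
of the sampled duct size and thickness, rejection-sampled onto the
configured side of the 0.3 cut-off; weight derives from sampled BMI and
height). The outcome is drawn from the *discretized* risk cell —
P(CR-POPF | stratum, cell) — with risk planted on low MPD index in PDAC and
on low MPD index / high BMI in non-PDAC, matching the soft-pancreas
interpretation of the model.

**Default (training-like) configuration.** Stratum prevalences were
back-calculated from the published training operating points (PDAC:
sensitivity 87/specificity 81/PPV 50 imply stratum prevalence ≈ 0.22;
non-PDAC: 84/57/63 imply ≈ 0.47), and cell risks were then chosen as round
numbers whose implied Bayes-optimal operating points land on those targets:
PDAC P(low index) = 0.34 with cell risks 0.56/0.04 (implied 87.8/80.9);
non-PDAC P(low index) = 0.46, P(BMI ≥ 25) = 0.30 with cell risks 0.57,
0.85, 0.20, 0.56 (implied 83.8/56.8); overall prevalence 0.350, inside the
observed 33–36% band. `implied_operating_points` computes these exactly
from any configuration. Because the published operating points force the
mean positive-cell risk to ≈ 0.63, several cells sit within 0.1 of the 0.5
decision boundary; convergence experiments therefore fit on large cohorts
(n = 20 000), where a learned cell flipping against its configured
direction is a > 5σ event.

**Strongly separated (recovery) configuration.** The planted-model recovery
experiment asks whether the selection procedure re-discovers the planted
markers, so its configuration is an identifiability stress test with cell
risks 0.9 vs 0.05 and three deliberate departures from the training-like
cohort: (a) occupancies u = v = 0.33, which keeps the risk of every
*single-marker projection* of the planted non-PDAC pair (≈ 0.33) well below
the decision boundary — no subset of the pair is informative on its own —
while maximizing the case/control count gap in marginal cells; (b)
parenchymal thickness is sampled nearly constant, so the MPD index's own
components (duct size, thickness), which are deterministically coupled to
it, cannot act as a two-marker proxy for the planted index bin; (c) noise
dichotomies sit near 50/50, so no noise marker produces near-empty
sub-cells that could capture stray cases by chance. The diagnosis split
(30% PDAC) favours the stratum with the harder, two-marker recovery.
Measured over 300 replicates at n = 200, selection recovers {MPD index} in
the PDAC-like stratum in 99.3% and {MPD index, BMI} in the non-PDAC-like
stratum in 98.3% of replicates; the packaged experiment uses 50 replicates.
Recovery searches sizes 1..2, matching the planted combination sizes.

**What passing tests do not show.** The generator plants the outcome on the
discretized cells, so the discrete Bayes classifier is the exactly correct
model there — real data offer no such guarantee, carry measurement error
and inter-observer variation in the radiological markers, correlations
between "noise" markers and outcome, and missingness. Recovery and
convergence results therefore validate the *pipeline* (that the procedure
finds a recoverable signal and that its estimates converge to the truth it
was given), not the clinical transportability of the published cut-offs.

## Problem sizes and runtime

Defaults keep everything on one CPU in seconds to a few minutes: recovery
uses 50 replicates of n = 200; calibration and end-to-end convergence use
n = 20 000 with agreement asserted at 3 binomial standard errors; the
classifier-vs-brute-force equivalence sweep uses ≥ 200 random instances
with k ≤ 3, n ≤ 50.

## Known limitations

* The final model's marker sets and cut-offs are fixed to the published
  architecture when fitting; the discovery pathway (`discover_model`)
  reruns selection first and refuses to build the fixed architecture if
  selection disagrees.
* Whether the published training-set tables report re-substitution or
  held-out estimates is ambiguous in the source; both are computed, and
  neither is asserted against the training tables (which are not
  reproducible without the original cohort).
* The two validation-table figures noted above (53, 64) cannot be
  reproduced under half-up rounding; the package reports the raw ratios and
  documents both renderings.
* VFA and sarcopenia are optional fields (not every centre records CT body
  composition); records missing a marker required by an analysis raise an
  error naming it.
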
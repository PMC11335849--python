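# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `acoforms`. It is written for users who need to judge what
the package computes and what its tests do and do not establish.

## Measurement model

All items are dichotomous and follow the unidimensional two-parameter
logistic (2PL) model,

    P(X_ij = 1 | θ_j) = σ(a_i (θ_j − b_i)),    σ(z) = 1 / (1 + e^{−z}),

with discrimination `a_i > 0`, difficulty `b_i` and latent ability
`θ ~ N(0, 1)`. The logistic metric uses no 1.7 scaling constant; all
internal quantities (curves, information, DTF) are self-consistent on this
metric. Polytomous items, guessing (3PL), multidimensionality and missing
responses are out of scope.

### Estimation

Item parameters are estimated by marginal maximum likelihood. The latent
ability is integrated on a fixed quadrature grid — by default 61 equally
spaced nodes on [−6, 6] with standard-normal density weights renormalized
to sum to one — and an EM algorithm alternates between posterior expected
counts per node (E-step) and per-item damped Newton ascent of the expected
complete-data log-likelihood in the (a, a·(−b)) parametrization (M-step).
Because the M-step never accepts a downhill move (step halving, and the
stability-box projection falls back to the previous point if clipping would
cost likelihood), every cycle is a generalized EM step and the marginal
log-likelihood is non-decreasing — asserted in the test suite.

Plain EM crawls on flat likelihoods, so cycles are accelerated by a
safeguarded squared-extrapolation scheme (SQUAREM family): two EM steps,
a quadratic extrapolation, one stabilizing EM step, with fallback to the
unaccelerated double step whenever the extrapolated point does not improve
the likelihood. The ascent guarantee is preserved.

Numerical choices:

- bounds `a ∈ (0.05, 8)`, `b ∈ (−8, 8)` prevent divergence on
  quasi-degenerate items; hitting a bound raises a warning;
- convergence when the maximum absolute parameter change falls below 1e-4
  **or** the per-cycle log-likelihood gain falls below 1e-6. The second
  criterion matters for quasi-unidentified configurations (e.g., one strong
  item among weak ones), where parameters drift along a ridge at
  numerically constant likelihood; every downstream quantity is stable
  there. Cap: 500 EM-map evaluations, after which the fit is flagged
  non-converged and the candidate solution receives pheromone zero;
- items observed in only one response category abort estimation with an
  error naming the item;
- starting values: unit discriminations and normal-ogive difficulties from
  the observed proportions; searches warm-start group fits from the pooled
  solution.

### Scores, reliability, curves

EAP ability scores are posterior means on the same grid; EAP reliability is
`var(EAP) / (var(EAP) + mean(SE²))` with the sample variance (ddof 1).
The test characteristic curve is `TCC(θ) = Σ_i P_i(θ)` (expected raw
score), the information function `TIF(θ) = Σ_i a_i² P_i(1−P_i)`. Form
similarity is measured by the squared differences between curves summed
over all unordered form pairs and all grid nodes. These square sums are
**grid-relative**: a profile therefore records the grid it was calibrated
on, and evaluation with a different grid is a hard error.

## Model fit: M2 and derived indices

First- and second-order margins (item proportions and pairwise joint
proportions; s = k + k(k−1)/2 statistics) are compared with their
model-implied values via the limited-information quadratic form weighted
through an orthonormal complement of the margin Jacobian. This weighting
makes the statistic asymptotically chi-square with s − 2k degrees of
freedom for any root-n-consistent estimator, which the suite verifies
empirically (mean M2 ≈ df over 200 true-model replications). The
moment-covariance matrix and Jacobian are computed analytically by
quadrature (up to fourth-order model moments). A singular weighting matrix
raises an error rather than being ridged, so poor conditioning is visible
instead of silently distorting calibrated thresholds.

Derived indices follow the conventional chi-square algebra:

- `RMSEA = sqrt(max(M2 − df, 0) / (df (n − 1)))`;
- `CFI = 1 − max(M2 − df, 0) / max(M2 − df, M2_0 − df_0, 0)` with the
  independence model (free proportions, zero association) as baseline,
  evaluated with the same margin machinery.

The analytic degrees-of-freedom helpers for categorical simple-structure
CFA (thresholds + polychoric correlations as sample statistics) are
provided for checking published model comparisons; fitting such CFAs is
out of scope.

## Differential test functioning

For a two-level grouping, the form is calibrated separately per group and
the TCC gap is integrated over the focal ability density:

    sDTF = Σ_q [TCC_ref(θ_q) − TCC_foc(θ_q)] w_q,
    uDTF = Σ_q |TCC_ref(θ_q) − TCC_foc(θ_q)| w_q,

both in raw score points, with `uDTF ≥ |sDTF|` by construction.

**Identification.** Two variants are provided, and the distinction
matters:

- *Default (observable gap):* both groups keep a fixed N(0, 1) latent
  distribution with all item parameters free. This deliberately confounds
  true group impact with DIF — the quantity is the expected score gap an
  administrator would observe, which is the operational target for
  fairness-driven assembly. Its sampling noise therefore includes the
  groups' ability-sampling difference (≈ sqrt(2/n) in latent units, scaled
  by the TCC slope), which dominates for moderate n.
- *Anchored:* user-named anchor items have their focal parameters fixed to
  the reference estimates while the focal latent mean/SD are estimated
  (EM updates them from posterior moments). This separates DIF from
  impact; with no DIF planted, anchored sDTF is centred on zero with much
  smaller spread, and the fairness-calibration test applies its 0.15-point
  bound to this variant while checking the observable-gap variant for
  unbiasedness.

The reference group is the first level of the group factor by default and
configurable.

## The optimization function

Raw criteria are mapped to (0, 1) by logistic transforms centred at
thresholds (φ = 0.5 exactly at the threshold; numerically stable via
`expit` for extreme arguments). Components use worst-form decisive rules
(min CFI, max RMSEA, min reliability, max |sDTF|, max uDTF), CFI/RMSEA are
merged 3:1 and sDTF/uDTF 1:1 because each pair measures one facet of
quality, and the overall pheromone is the equally weighted mean of the five
components. All weights, thresholds, slopes and the number of parallel
forms live in an editable profile (JSON); the shipped default carries
thresholds .97/.02/.63/202/62/0.13/0.29 and slopes 100/100/100/0.025/0.08/
25/25. The signed DTF enters via its magnitude: a signed maximum would
reward large negative bias. A form that fails estimation collapses the
whole candidate to φ_overall = 0 rather than raising.

## Threshold calibration

Thresholds are calibrated by drawing many random coverage-respecting
disjoint triples (uniform per domain, items assigned to forms in draw
order), fully fitting and scoring each, and taking the favorable-tail
percentile per criterion — 5th for minimize, 95th for maximize, linear
interpolation between order statistics. By construction ~5% of random
triples beat each single threshold (verified at 500 replications, ±3
points), so clearing all of them at once is rare under random assembly —
which is precisely the gradient the search exploits. Failed replications
are dropped with a logged count. Redundancy between criteria is reported
as a correlation matrix but not acted on automatically: merging decisions
are judgment calls expressed through profile weights. Slope diagnostics
report, for candidate slopes, the share of random models whose φ clears
given cut levels.

## The ACO engine

Pheromone is kept per (form, item) cell — not per item — so the search can
learn which items co-occur well on a form, which matters for TCC/TIF
matching. Sampling proceeds domain by domain: each form in turn draws one
still-available item with probability proportional to its own pheromone
row, so coverage and disjointness hold by construction. Each iteration:

1. `n_ants` candidate triples are sampled and evaluated (evaluations are
   memoized by canonical triple, and per-form results are cached, since
   ants increasingly resample good material);
2. if the best ant strictly beats the incumbent, it becomes the new best
   and deposits `deposit_scale · φ_overall` on its cells (ties keep the
   incumbent, preserving reproducible strict-improvement semantics);
3. all cells evaporate by a fixed fraction (floored at 1e-12 to preserve
   positivity).

Stopping: all component pheromones ≥ 0.5 (every criterion past its
threshold), or `patience` iterations without improvement, or `max_iter`.
Defaults: 50 ants, evaporation 0.05, deposit scale 1, patience 30,
max_iter 300. The planted-recovery harness uses a more intensifying
setting (12 ants, evaporation 0.08, deposit 2.5, patience 12) chosen for
reliable convergence on small banks within a short budget. A
`random_search_baseline` draws uniform triples at the same
evaluation-budget accounting for efficacy comparisons.

Because all criteria are symmetric across forms, triples are canonicalized
(forms sorted by smallest item id) for memoization and reporting; the
best-so-far φ_overall is monotone non-decreasing by construction.

## Synthetic data

The generator emulates the intended study conditions: a bank of 12 domains
× 10 items with a ~ logNormal(0, 0.25) and b ~ N(0, 1), two groups
(reference listed first) of several hundred examinees each with
θ ~ N(0, 1), and optional focal-group DIF (additive on b, multiplicative
on a) planted on a named item subset. `plant_dominant_triple` rebuilds a
bank so a known disjoint triple is near-optimal (uniformly high
discrimination, domain-matched difficulties, zero DIF, against a weakly
discriminating high-DIF background) for search-recovery testing; pilot
analysis showed the background contrast must stay moderate (planted a 1.8
vs background 0.4 with large DIF produces genuinely Heywood-unstable
forms), so the fixture uses background a 0.6 and DIF 0.6.

What the generator does *not* emulate: real response phenomena such as
guessing, speededness, local dependence, missingness, or multidimensional
knowledge structure. Passing tests therefore establish internal
correctness and search efficacy under the 2PL, not robustness to
violations of it.

## Problem sizes used in the checked results

Analytic identities run at full size. Simulation-backed checks run at
reduced but statistically meaningful scales, chosen so the whole suite
completes comfortably on one CPU: M2 calibration at 200 replications
(k = 8, n = 1,000); fairness calibration at 100 replications (12 items,
n = 1,000 per group); planted-triple recovery on a 36-item bank with 600
examinees over 10 seeded paired runs; threshold self-consistency at 500
replications on a 24-item bank. The acceptance script's end-to-end run
uses the full 120-item bank with 800 examinees, 150 calibration triples
and a ~12-iteration-patience search.

## Known limitations

- Unanchored DTF mixes impact and DIF by design; use anchors when the
  distinction matters.
- M2 needs k ≥ 4 items per form for positive df; very small samples can
  make the weighting matrix singular (reported as an error).
- EM point estimates only: no standard errors for item parameters.
- The pheromone search is a heuristic: it provides no optimality
  certificate, and its hyperparameters trade run time against the risk of
  premature convergence.
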
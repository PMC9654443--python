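# Methods

## The screening procedure

The pipeline treats a cross-sectional cohort as a pseudo-time-series:
participants are sorted by their CES-D depression total (stable sort,
participant-id tie-break) and the sorted sequence of seven standardized
subscale scores — positive coping (PC), negative coping (NC), positive
affect (PA), negative affect (NA), life satisfaction (LS), cognitive
reappraisal (CR), expression suppression (ES) — is modelled by a
homogeneous hidden Markov model with multivariate-Gaussian emissions
x|s=k ~ N(mu_k, Sigma_k). Because the axis is ordered by depressive
severity, a sticky Markov chain along it segments the cohort into
contiguous severity regimes that are defined only by the *indirect*
measures; CES enters through the ordering, never as an emission.

After decoding (posterior argmax by default; Viterbi optional), states are
relabelled by the mean CES of their decoded members, ascending:
nonrisk < medium < risk. For each integer CES value the set of decoded
states among its participants is computed; maximal contiguous runs of
values owned by exactly one state are that state's **exclusive covered
ranges**, with gaps (unoccupied CES values) bridged only when flanked by
exclusive values of the same state — the risk range typically spans sparse
high totals. The inner boundaries of the nonrisk and risk exclusive ranges
are the screening thresholds. A medium state with no exclusive range is a
legal outcome, not an error. New respondents are screened by standardizing
their seven scores with the training statistics and taking the
single-observation posterior under the chain's stationary distribution.

Assumptions worth stating plainly: the "sequence" is an ordering artifact,
not time, so the transition matrix expresses how latent patterns change
*across severity*, not within a person; observations are one per
participant; and the homogeneous-HMM reading is used throughout (state
distribution independent of position given the previous state).

## Estimation and numerical choices

* **EM.** Baum–Welch from a k-means partition (per-restart random state),
  uniform initial distribution, sticky initial transitions (self-transition
  0.9), 10 restarts by default, convergence at relative log-likelihood
  change < 1e-6 or 500 iterations. The restart with the highest final
  log-likelihood wins. The forward–backward pass keeps emission densities
  in the log domain, shifts each step by its maximum, and renormalises
  alpha/beta per step (the standard scaling scheme), so the computation is
  exact and underflow-free for sequences up to ~1e5; the log-likelihood is
  the sum of the log scaling factors plus the shifts. Verified against
  exhaustive path enumeration to 1e-10 and against an independent HMM
  implementation.
* **Covariances.** Full 7x7 per state, symmetrised each M-step and ridged
  with cov_reg*I (default 1e-6 * trace(cov(X))/d) to survive near-singular
  within-state scatter and zero-variance columns (which additionally
  warn).
* **Ties and determinism.** Every argmax (decoding, screening) breaks ties
  toward the lower state index; every stochastic component (generator, EM
  restarts, baselines) is seeded, so all outputs are bit-reproducible.
* **Model-order choice.** `select_k` fits a grid of K with a shared seed
  policy and reports AIC/BIC with parameter count
  (K-1) + K(K-1) + Kd + Kd(d+1)/2. The pipeline default is K=3
  (nonrisk/medium/risk), the configuration of interest for screening.
* **Degenerate decodes.** If a decoded state is empty the fit escalates
  once to 30 restarts before accepting the degenerate solution with a
  warning.

## Statistics layer

Cutoff grouping uses strict inequalities (high: CES > 20, low: CES < 10;
scores 10–20 belong to neither). Pearson correlations carry two-sided
p-values from the t transform (n-2 df) and magnitude bands (|r| < 0.3 low,
0.3–0.6 medium). The CES regression is ordinary least squares with
intercept; t statistics and 95% CIs are reported on the raw scale while
betas are standardized (coefficient * sd_x/sd_y); VIF_j = 1/(1 - R_j^2)
from auxiliary regressions, tolerance = 1/VIF (the identity is asserted to
1e-12, and VIF is cross-checked against the inverse-correlation-matrix
diagonal). Two-sample t-tests accept raw vectors or (mean, sd, n)
summaries; `auto` selects Welch (Satterthwaite df) when a two-sided F-test
of variance equality rejects at the 5% level, else the pooled test with
df = n1+n2-2 — the mixture of dfs this produces matches mainstream
statistics-software output. Cronbach's alpha uses sample (ddof=1)
variances, as do all z-scores.

## Synthetic cohort generator

The generator is the package's ground truth, emulating the structure the
analysis assumes: latent state k drawn from state weights, the 7-vector
from N(mu_k, Sigma_k) in z-units, and the CES total drawn **uniformly from
a per-state integer interval**. Intervals, not Gaussians, are used for
CES|state precisely so that exclusive-range recovery has a knowable answer:
with intervals [0,9]/[8,22]/[21,60] and overlap 2, the true exclusive
ranges are [0,7] and [23,60] by construction.

Reference study conditions (the defaults, chosen once): n = 1128
participants; K = 3; state weights (0.21, 0.49, 0.30), set so the expected
exclusive-tail group sizes are ~188 (nonrisk) and ~319 (risk); z-profiles
in which the risk state sits ~1.5 SD below the nonrisk state on PA and
~1.6 SD on NA while PC/NC/LS/CR/ES differ by at most ~0.5 SD — the
qualitative pattern in which *both* affect scales are depressed in the risk
state; uniform within-state correlation 0.15. A single root seed is split
via `SeedSequence.spawn` into four independent streams (states, features,
CES totals, items/validity), so enabling item-level output never perturbs
the participant-level draws.

Item-level generation inverts the scoring maps: each subscale target is
converted to a raw-scale total using fixed anchors (published whole-cohort
means/SDs of the scales), clipped to the legal range, rounded, and spread
across items by uniformly incrementing items below their maximum. Sums
(CES, PA, NA, LS, CR, ES) round-trip exactly through scoring; mean-scored
subscales (PC, NC) round-trip to within half an item unit divided by the
item count. The generator does **not** model socio-demographics, response
styles, reverse-keyed wording effects, or missingness — so passing tests
show the pipeline recovers the assumed latent structure, not that real
questionnaire data satisfies those assumptions.

An optional validity channel emits per-participant "polygraph" mistake
counts; the exclusion rule removes participants with more than 4 mistakes
out of 10 (strict inequality: exactly 4 is retained).

## Baseline comparison

k-means, Gaussian mixture (no transitions), Ward agglomerative and spectral
clustering run on the identical standardized features with shared K and
seed, and are scored by the same exclusive-range extraction code path as
the HMM. The **separation score** — participants inside any
cluster-exclusive CES range divided by cohort size — is this package's own
operationalisation of an "effective division of the CES score" and is
labelled as such in reports. Under the reference conditions the mixture
baseline scores near zero while the HMM exceeds 0.8; the test suite's
ordering ablation confirms the advantage vanishes when the sequence is
shuffled, i.e. it is carried by the severity ordering, not by the emission
model.

## Problem sizes used in validation

The shipped tests and the acceptance script validate at the reference
cohort size n = 1128 with 3 EM restarts per fit; threshold recovery is
replicated over 20 seeds (success = both inner boundaries within +-2 CES
points of the generator's 7/23, observed rate >= 0.95); parameter recovery
uses a 2-state, T = 2000 sequence with 5-sigma mean separation; exhaustive
enumeration oracles cover all K <= 3, T <= 8 instances. These sizes were
chosen as the smallest at which the stochastic properties are stable.

## Known limitations

* The sorted-axis trick makes the transition matrix uninterpretable as
  within-person dynamics; the package makes no longitudinal claims.
* Exclusive ranges cannot extend beyond the observed CES extremes, and
  boundary totals adjacent to the shared band (e.g. 8 and 22 when the
  exclusive ranges are [0,7] and [23,60]) are intentionally reported as
  outside the exclusive intervals; closed intervals are reported and
  boundary interpretation is left to the user.
* Screening a new respondent uses the stationary distribution as the state
  prior, which is the natural choice for a single observation but ignores
  where on the severity axis the respondent would fall.
* No claim of clinical diagnostic validity is made anywhere; thresholds
  are statistical summaries of a fitted model.
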
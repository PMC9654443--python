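# depscreen

Indirect depression-risk screening for questionnaire cohorts.

Universal depression screening in students usually measures distress
directly (e.g. with the CES-D), but stigma makes at-risk respondents
under-report on exactly that instrument. `depscreen` implements an indirect
alternative: it takes seven *low face-validity* subscale measures — positive
and negative coping (WCQ), positive and negative affect (PANAS), life
satisfaction, cognitive reappraisal and expression suppression (ERQ) — and
uses the ordering of participants by their CES-D total to learn latent
mental-pattern states from the indirect measures alone.

## Model

Participants are sorted by CES-D total into a pseudo-sequence
$x_1, \dots, x_T$ (each $x_i \in \mathbb{R}^7$ the standardized subscale
vector), treated as the axis of a hidden Markov model with $K$ latent
states $s_i$ and Gaussian emissions:

$$x_i \mid s_i = k \;\sim\; \mathcal{N}(\mu_k, \Sigma_k), \qquad
  P(s_i = k \mid s_{i-1} = j) = A_{jk}.$$

Parameters are estimated by maximum-likelihood Baum–Welch EM (log-space
forward–backward, k-means initialisation, random restarts); states are
decoded by the posterior argmax (Viterbi optional) and relabelled by the
mean CES of their members (ascending: *nonrisk* < *medium* < *risk*). Each
state's **exclusive covered range** — the maximal CES intervals occupied by
that state and no other — yields the screening thresholds: a new respondent
whose indirect profile is classified into the risk state is flagged without
ever being asked a depression item.

The package also provides the surrounding analysis layers: questionnaire
scoring with a validity-item exclusion rule and Cronbach's α, CES cutoff
grouping, Pearson correlations, OLS regression with VIF/tolerance
diagnostics, pooled/Welch t-tests (from raw data or printed summary
statistics), a baseline-clustering comparison (k-means, Gaussian mixture,
Ward, spectral) scored with the identical range extractor, and a synthetic
cohort generator with known latent ground truth for validation.

## Worked example

Screen the packaged demo cohort (1128 synthetic participants, 3 states)
end to end:

```bash
depscreen screen --out-dir run/
cat run/thresholds.csv
```

```
state,label,ces_lo,ces_hi,n
2,nonrisk,0,7,207
1,medium,10,21,426
0,risk,23,60,340
```

Reading: decoded state 2 exclusively covers CES totals 0–7 (207
participants — the nonrisk group) and state 0 exclusively covers 23–60 (340
participants — the risk group); totals 8–22 are shared between states, so a
CES in that band is not assigned by threshold alone. The generator's ground
truth for this cohort is exclusive ranges [0, 7] and [23, 60], both
recovered exactly.

`run/baseline_comparison.csv` scores every method by the *separation
score* — the fraction of participants inside any cluster-exclusive CES
range (a metric defined by this package):

```
method,separation,low_tail_purity,high_tail_purity
hmm,0.863,1.000,1.000
kmeans,0.004,0.783,0.575
gmm,0.015,0.721,0.761
agglomerative,0.005,0.504,0.726
spectral,0.004,0.721,0.522
```

No transition-free clusterer of the same features produces an effective
division of the CES score; the HMM's advantage comes from the sorted axis
(shuffling the sequence removes it, as the test suite verifies).

Two-sample statistics can be recomputed directly from printed summaries,
e.g. the risk-vs-nonrisk CES contrast (M=31.185, SD=7.31, n=319 vs M=3.83,
SD=2.27, n=188):

```bash
depscreen ttest-summary --m1 31.185 --sd1 7.31 --n1 319 --m2 3.83 --sd2 2.27 --n2 188
# t=61.960 df=411.83 p=7.402e-211 CI95=[26.487, 28.223] variant=welch
```

(`variant=auto` picks Welch here because an F-test rejects variance
equality.)

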
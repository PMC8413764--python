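# Methods

This note records the models, estimators, and design choices behind
`dynstates`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Windowed connectivity model

Each subject contributes a T×C matrix of network component time courses
(C = 5 by default: aDMN, pDMN, LCEN, RCEN, SN; T = 180 volumes at
TR = 2 s, of which the first 10 are discarded, leaving 170). Dynamic
connectivity is modeled as piecewise covariance stationarity: within a
window the C channels are treated as draws from a fixed covariance, and
states are recurring covariance configurations.

**Taper.** The window weight vector is a width-W rectangle (W = 30 TRs =
60 s) convolved with a Gaussian of σ = 3 TRs (support truncated at ±4σ),
cut back to the central W samples and normalized to peak 1. With step 1
the pipeline emits ⌊(T−W)/step⌋ windows — 140 for T = 170 — leaving a
margin for the Gaussian-smeared tail at the scan end; the inclusive
T−W+1 convention is available behind a flag.

**Estimator.** Per window, the taper-weighted sample covariance (weights
normalized to sum 1, weighted demeaning) is standardized to correlation.
A sparse precision matrix is then estimated by the graphical LASSO at
penalty λ and inverted back to a correlation. As λ→0 this reproduces the
taper-weighted Pearson correlation (tested to 1e-5); the solver's
convergence tolerance is scaled down with λ so the limit is actually
attained. Default λ = 0.1; an optional per-subject selection maximizes the
unregularized Gaussian log-likelihood over a 10-point logarithmic grid in
[0.01, 1]. Off-diagonals are Fisher z-transformed (z = arctanh r, clipped
at |r| = 1 − 1e-7).

**Confound residualization.** For every (window, pair) cell, an
across-subject linear model on [intercept, age, sex] replaces values by
residual + intercept. Covariates are **centered** before fitting. This
matters: with raw covariates the removed component is β·age ≈ β·33 rather
than β·(age − mean), so every subject's 140×10 z vector acquires a large,
nearly parallel offset along the fitted slope pattern. Correlation-distance
clustering is extremely sensitive to such shared components — in testing it
degraded planted-state recovery from r ≈ 0.95 to r ≈ 0.3 — while centering
removes only the covariate-deviation effect and leaves the geometry intact.

## State clustering

All subjects' windowed z vectors (P = C(C−1)/2 = 10 dimensions) are pooled
and clustered by k-means under the correlation distance
d(a,b) = 1 − Pearson(a,b), which is sensitive to the connectivity pattern
irrespective of overall magnitude. The procedure is two-stage: many
randomly initialized Lloyd runs (500 by default; replicate r draws its RNG
from (seed, r), so the best objective is non-increasing in the replicate
count) keep the lowest total within-cluster distance; then every window is
re-assigned to its nearest centroid and final centroids are reported as
element-wise medians of the assigned windows. Within iterations the
working centroid is the arithmetic mean of member vectors (common dFNC
practice); the median is used only for reporting. Empty clusters are
re-seeded at the point farthest from its centroid. States are relabeled in
descending pooled occupancy, ties broken by first occurrence, so "state 1"
is reproducibly the most visited state.

**Choosing k (elbow).** For each candidate k the cluster validity index is
(total within-cluster distance) / (size-weighted distance of centroids to
the element-wise grand median). This curve is positive, decreasing, and
convex in practice. The selected k is the point of maximum deviation
*below the chord* joining the curve's endpoints — the standard knee-point
construction. A raw discrete second difference was considered and
rejected: on convex decreasing curves the 2→3 drop always dominates, so
that rule degenerates to the smallest interior k regardless of the true
structure (it recovered a planted k = 4 in 1/10 cohorts, versus 9/10 for
the chord rule). If no point falls below the chord the curve has no elbow
and the smallest k whose relative drop falls under 10% is returned with a
warning.

## Temporal properties and statistics

From each subject's window-level state vector: fractional windows per
state (percent; unvisited states get 0), mean dwell time (mean run length
in windows; 0 when unvisited, so subjects who never enter a state still
contribute), and the number of transitions (runs − 1). These satisfy exact
conservation laws (fractions sum to 100; run-count × mean-dwell sums to
the vector length) which are property-tested.

Group comparisons use the Mann–Whitney U test with midranks and the
tie-corrected normal approximation. The z statistic is the plain
(U − n₁n₂/2)/σ with the sign convention that a first group ranking below
expectation is negative (matching how such tables are printed). The
two-sided p applies a 1/2 continuity correction: U is a lattice statistic,
and without the correction the normal approximation deviates from the
exact permutation p by up to 0.07 at n = m = 6 (0.016 with it). The nine
temporal tests (4 fractions, 4 dwells, transitions) form a single
Benjamini–Hochberg FDR family, mirroring the conventional table layout;
FC-strength t-tests are corrected within state across the 10 pairs, with
subjects lacking a state excluded pairwise. Partial correlations
residualize both variables on [intercept, age, sex, education] and refer
r√(df/(1−r²)) to a t distribution with df = n − q − 2. The sex-ratio
chi-square uses no continuity correction.

## Synthetic cohort generator

The generator emulates the study design the pipeline expects, and its
defaults are the conditions under which the validation suite runs.

- **States.** n_states = 4 covariance matrices sampled as Wishart draws
  standardized to correlation form (unit variances) with a small diagonal
  ridge (0.02·C) and a |r| ≤ 0.95 guard, rejection-sampled until all
  pairwise correlation distances between off-diagonal vectors are ≥ 0.4
  (the same metric the clustering uses, so planted separation is
  meaningful to the estimator). The light ridge keeps the off-diagonal
  structure strong (mean |r| ≈ 0.35–0.4), consistent with the highly
  structured states reported in this literature; weakly structured states
  are dominated by within-window estimation noise (SE ≈ 0.25 per pair at
  W = 30 after 0.15 Hz filtering) and are not a regime any windowed
  method can resolve.
- **Dynamics.** Each subject follows a hidden Markov chain started from
  its kernel's stationary distribution. Controls: stay probability 0.965,
  uniform switching (mean regime ≈ 29 TRs, ≈ 6 switches per scan).
  Patients: stay 0.994 in state 1 and 0.988 elsewhere, with 70% of exits
  from other states landing in state 1 (state-1 stationary occupancy
  ≈ 0.52, mean state-1 regime ≈ 167 TRs, ≈ 1.5 switches per scan). Regime
  durations are deliberately long relative to the 30-TR window: windows
  straddling a regime switch carry mixed covariance and are the dominant
  error source, so recovery-style validation requires the quasi-stationary
  regime the estimator assumes. The planted group effects (patients:
  higher state-1 occupancy and dwell, fewer transitions) point in the
  clinically reported direction but are stronger than typical clinical
  effect sizes, so that recovery is detectable at the reduced cohort
  sizes the test suite can afford.
- **Emission.** Row t is a zero-mean multivariate normal draw with the
  covariance of the active state; switching is instantaneous (no
  hemodynamic smoothing across boundaries — the analysis only assumes
  piecewise covariance structure, and band-limiting is applied by the prep
  chain). Because all channels pass through the same linear filters,
  within-state correlation structure is preserved exactly by the prep
  stage; filtering costs effective per-window sample size instead.
- **Nuisance.** Per channel: random polynomial trends (orders 1–3,
  amplitudes 0.5/0.3/0.2 in signal-SD units), random-walk motion
  parameters leaked into the signal (gain 0.3), and spikes (per-volume
  rate 0.01, amplitude 5–9 robust SDs, one random channel per spiked
  volume). These are the artifact classes the prep chain removes.
- **Covariates and scores.** Age ~ truncated normal (33, 8) on [19, 46];
  sex ~ Bernoulli(0.5); education ~ truncated normal (11.5, 3.1) on
  [5, 22]. SDMT = 20 + 2.2·(true transitions) + N(0, 8); TMT-A = 40 +
  1.0·(true state-1 dwell) + N(0, 14): positive metric-score links with
  correlations ≈ 0.5–0.6 at the design sample size.
- **Ground truth.** The per-subject hidden sequence (full 180 volumes) and
  its exact temporal properties — computed by the same metrics module the
  pipeline uses, so truth-consistency is an identity, not an estimate —
  are stored alongside the data. The whole generator is a pure function of
  its configuration, including the seed (one master seed fans out to
  states, subjects, and stages via independent spawned streams).

### What the generator does and does not emulate

It reproduces the pipeline-relevant structure of multi-subject dFC data:
recurring covariance regimes, group-dependent dynamics, realistic nuisance,
covariates, and metric-linked scores. It does not model hemodynamics,
spatially correlated scanner noise, ICA back-reconstruction leakage between
components, non-Markovian regime durations, or heavy-tailed BOLD noise.
Passing the validation suite therefore demonstrates that the pipeline
recovers planted structure under its own modeling assumptions — it does not
certify performance on real scans, where window-length sensitivity and
slow-switching assumptions remain open questions in the field.

## Numerical choices and edge cases

- Near-singular window covariances get a relative ridge (1e-8·trace/C)
  with a warning; if the glasso coordinate-descent solver still fails
  (correlations at ±1), the window is retried under escalating ridge
  jitter (1e-6 → 1e-2) before an error naming the window is raised.
- Despiking flags |x − median| > 3.5 · 1.4826 · MAD (the Gaussian
  consistency factor makes the threshold ≈ 3.5σ); MAD = 0 flags nothing;
  more than half flagged is an error; repairs come from a cubic spline fit
  through clean samples only. The 3.5 multiplier is a common despiking
  convention and is configurable.
- Motion derivatives are backward differences with the first sample 0;
  rank-deficient nuisance designs fall back to the pseudo-inverse with a
  warning.
- The low-pass filter is a 5th-order zero-phase Butterworth
  (forward-backward). The prep chain is idempotent on passband content;
  re-running it keeps nibbling at the transition band (~9% full-band RMS
  on broadband input), which is inherent to any finite-order filter.
- Fisher z clips at |r| = 1 − 1e-7; inputs beyond |r| = 1 + 1e-12 are
  rejected.
- Constant vectors are rejected by the correlation distance; transiently
  degenerate centroids inside Lloyd iterations are given unit distance to
  everything rather than an undefined correlation.

## Problem sizes used in the validation suite

The test suite runs the full pipeline at reduced but structurally faithful
sizes, chosen as the smallest cohorts at which each question is
statistically meaningful: state-count and recovery checks use 20-subject
cohorts (2800 pooled windows) with 20–30 clustering restarts; the
qualitative group-difference replication uses 50 subjects per group over
20 generator seeds; type-I error control of the nine-test family uses 500
null cohorts at the full 66 + 66 design driven directly by the hidden
state sequences (the statistical layer consumes temporal metrics, which
the sequences determine exactly). The acceptance script runs one full
66 + 66 imaging-pipeline analysis with 100 clustering restarts.

## Known limitations

- The latent dynamics are first-order Markov with geometric dwell times;
  empirical state-switch timing in patient populations is not
  characterized by this model.
- Window-level metrics are attenuated versions of the latent ones: windows
  spanning regime boundaries smooth occupancy and swallow short regimes,
  so estimated transition counts sit below latent switch counts. Group
  contrasts survive, but absolute metric values should not be compared
  across window lengths.
- With five components the precision matrix is small; the graphical LASSO
  is used for fidelity to standard dFNC practice, not because sparsity is
  informative at C = 5.
- The elbow criterion, like all internal validity indices, can prefer a
  neighboring k when planted states sit near the minimum separation floor.
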
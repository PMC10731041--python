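# Methods

`dfncstates` implements a dynamic functional network connectivity (dFNC)
state analysis for resting-state fMRI component time courses, together
with a synthetic-cohort generator used to validate every stage by
recovery of planted ground truth.  This note records the models, the
parameters that matter, the numerical choices, and the limits of what
the synthetic validation can show.

## The analysis model

The input to the analysis is, per subject, a T×C matrix of
independent-component (IC) time courses sampled every TR seconds
(defaults: T = 230 retained TRs after discarding 10 equilibration frames
from a 240-frame acquisition, C = 27 components in seven functional
networks, TR = 2.5 s).  The pipeline assumes the spatial decomposition
(group ICA) has already been performed upstream; only time courses enter.

**Postprocessing.**  Each component is despiked, linearly detrended and
low-pass filtered.  Despiking fits a least-absolute-deviations straight
line per component (iteratively reweighted least squares), estimates the
residual scale σ̂ = 1.4826·MAD, and compresses residuals beyond c1·σ̂ to

    sign(r)·σ̂·(c1 + (c2 − c1)·tanh((|r|/σ̂ − c1)/(c2 − c1)))

with c1 = 2.5, c2 = 4.0, so spike amplitudes are smoothly bounded by
c2·σ̂ while all in-band samples pass through untouched.  (This is the
classic tanh compression map; note it is intentionally *not* idempotent —
a reapplication moves previously compressed samples slightly, which is a
property of the map itself.)  The low-pass is a 5th-order zero-phase
Butterworth at 0.15 Hz applied forward–backward after linear detrending;
the detrend supplies the low end of the effective band-pass, and no
explicit high-pass corner is applied (the convention of the standard
dFNC toolboxes).

**Motion QC.**  Frame displacement is Power's FD: the sum of absolute
frame-to-frame translation differences plus rotation differences
converted to arc length on a 50 mm sphere (radius configurable).
Subjects are excluded when mean FD > 0.5 mm, any |translation| > 3 mm,
or any |rotation| > 3°; all thresholds are strict inequalities, so a
subject sitting exactly on a limit is kept.  The rotation unit of motion
files is a required configuration choice, never guessed.

**Component screening.**  Candidate ICs are scored on a Welch spectrum
(Hann window, segments of min(T, 128) samples, 50 % overlap): the ratio
of integrated power below 0.10 Hz to the 0.15–0.25 Hz band, and the
spectral dynamic range (peak power minus the post-peak minimum).
Components are kept when the ratio is ≥ 4 and the dynamic range is
≥ 2.5 % of total integrated power.  These two thresholds are
reproducible defaults for criteria that, in the original selection
procedure, were combined with spatial-map criteria that require the
spatial decomposition and are out of scope here; the classification rule
uses the scale-invariant *relative* dynamic range so decisions do not
depend on signal units.  Note that at TR = 2.5 s the Nyquist frequency
(0.2 Hz) truncates the high band to 0.15–0.2 Hz, which raises the
flat-spectrum baseline of the ratio from 1 to about 2; the default
threshold of 4 sits above both.

**Windowed connectivity.**  The sliding window is a rectangle of W = 18
TRs (45 s at TR 2.5 s) convolved with a Gaussian of σ = 3 TRs
(truncated at ±4σ), renormalized to sum 1, slid in steps of 1 TR.
Within each window the correlation is a *weighted* Pearson correlation
with the taper as observation weights — invariant to affine rescaling
of the signals — followed by the Fisher z transform with |r| clamped at
1 − 1e−12.  The number of windows is floor((T − W)/step): start indices
run over 0..T−W−1, which yields 212 windows for T = 230 — the count the
standard toolbox produces (one fewer than the natural T − W + 1
enumeration; we match the established convention).  Windowed matrices
are clustered on z rather than r because Euclidean distances on z are
variance-stabilized; `fisher_z=False` exposes the raw-correlation
alternative.

**States.**  All subjects' windowed matrices are pooled, vectorized to
their C(C−1)/2 upper triangles, and clustered with k-means (Euclidean
distance, k-means++ starts, best of 100 replicates by inertia,
deterministic given the seed).  Ties in assignment resolve to the
lowest state id.  States keep fit order; occurrence percentages are
reported, and any matching to reference templates (Hungarian algorithm
on centroid correlations) lives in the validation utilities, not the
pipeline — downstream statistics are invariant to state numbering.
Clustering is single-stage over all windows by default; an optional
two-stage exemplar initialization (replicated k-means on each subject's
high-variance windows, then one full-data fit from those centroids) is
available via `exemplar_init=True`.

**Elbow.**  For k = 2..10 (20 replicates per k) the criterion is the
within-cluster/between-cluster dispersion ratio WSS/BSS.  The selected k
is the maximum-curvature (kneedle) point: both axes min-max normalized,
k chosen to maximize the perpendicular distance to the chord joining the
curve endpoints.  Two refinements were needed to make this rule sound:
(i) the curve used for selection is the between/within ratio anchored at
its exact k = 1 value of zero (WSS(1) = TSS), because otherwise the
smallest searched k is a chord endpoint and could never be selected even
when it is the true cluster count; (ii) the selection is flagged "weak
elbow" when no point departs from the chord by more than 1e−3 of the
normalized range — a genuinely near-linear curve carries no elbow
information.  A structureless single-Gaussian dataset produces a smooth
*convex* (≈1/k) curve, not a linear one, and is therefore not flagged;
interpreting a selected k always requires looking at the curve.

**Temporal metrics.**  Per subject: fractional time (percent of windows
per state; sums to 100), mean dwell time (mean run length in consecutive
windows per state, reported both in windows and in seconds = windows ×
TR × step; unvisited states get 0 by default, switchable to missing),
and the number of transitions (count of consecutive-window label
changes).  Per-state connectivity strength is the mean z matrix over a
subject's windows in that state; subjects that never visit a state are
excluded from that state's group contrast.

**Statistics.**  Groups are defined from the Epworth Sleepiness Scale:
ESS ≥ 10 → EDS, ≤ 3 → non-EDS, 4–9 excluded.  Continuous metrics use a
two-sample t test when both groups pass Shapiro–Wilk (α = 0.05) and
Levene's variance test (α = 0.05), otherwise a Mann–Whitney U test; the
chosen test is recorded.  The FDR family for the temporal metrics is all
nine metric×state tests jointly (4 fractional + 4 dwell + transitions),
adjusted by Benjamini–Hochberg; a per-metric family option exists.
Edgewise state-strength contrasts use t tests for all 351 edges with
BH-FDR within each state.  Categorical variables use Pearson chi-squared
without continuity correction (Yates optional).  Metric–ESS association
is a partial Spearman correlation: both variables rank-transformed,
ranks residualized on the raw covariates (age, sex as 0/1) by least
squares, Pearson correlation of residuals tested with the t
approximation at n − 2 − #covariates degrees of freedom.  Because the
covariates enter untransformed, a strongly nonlinear covariate–rank
relation leaves a small residual association; this is a property of the
rank-residualization estimator.

## The synthetic cohort

The generator emulates a two-group resting-state study: 16 EDS-like and
41 non-EDS subjects, 27 components in seven networks (SMN 7, VIS 6,
DMN 6, CEN 5, BG 1, CB 1, AUD 1), 230 TRs at 2.5 s.  Each subject's
hidden state sequence evolves at TR resolution (windowing later blurs
the boundaries, which keeps recovery honest) under a group-specific
Markov chain; at each TR the C signals are drawn from a zero-mean
Gaussian with the current state's template correlation matrix scaled by
`noise_sd²` (default 1).

**Templates.**  Four planted states with network-block structure:
(I) DMN and VIS strongly positive within-network (0.65) with DMN–VIS
anticorrelation (−0.45); (II) weak sparse connectivity (0.10
within-network); (III) DMN-dominant (0.65) with DMN–CEN coupling (0.35)
and DMN/CEN–SMN anticorrelation; (IV) a sensorimotor–visual state — SMN
and VIS strong within (0.65) and between (0.50), both anticorrelated
(−0.35) with DMN/CEN/BG/CB, and BG–CB positive (0.50).  Hand-built
blocks can be indefinite, so every template passes through a
nearest-correlation repair (eigenvalue clipping at 1e−8, rescale to unit
diagonal).  The block values are generator constants recorded in the
cohort manifest; they were chosen so the four signatures are mutually
distinct (pairwise upper-triangle correlations ≤ 0.66) — the generator's
job is to plant states the clustering stage can in principle recover,
and near-duplicate templates would test nothing.

**Dynamics.**  Group transition matrices come from
P = (1 − a)·I + a·1πᵀ with a = 1/`dwell_scale_tr` (default 12 TRs):
the chain holds with probability 1 − a and otherwise redraws from the
target occupancy π, which makes π the exact stationary distribution and
gives geometric dwell times with mean `dwell_scale`/(1 − π_i).  A
construction with an independent dwell mean per state *and* an arbitrary
exact stationary distribution does not exist in general (detailed
balance constrains the pair), so the single dwell scale is the honest
knob; explicit transition matrices can be supplied instead.  Default
occupancies: non-EDS (0.16, 0.47, 0.27, 0.10), EDS-like
(0.10, 0.38, 0.24, 0.28) — the EDS-like group's mass on state IV is
elevated enough for the fractional-time contrast to be detectable at
n = 16 vs 41, which is the generator's stated purpose; the sizes of
these effects are generator parameters, not empirical claims.

**Covariates.**  ESS = intercept + slope·occupancy(state IV) + noise
(defaults 0, 40, 1.5), rounded and clipped into the group's admissible
band ([10, 24] EDS-like, [0, 3] non-EDS-like) so that the ESS grouping
rule reproduces the planted groups exactly; a continuous link alone
cannot cross the excluded 4–9 band consistently.  Age ~ N(63, 8²)
clipped to [35, 90]; sex Bernoulli(0.63 male).  One RNG stream is split
per subject by counter (seed, subject index), so cohorts are
reproducible bit for bit and a subject's data does not change when the
cohort grows.

**What the generator does not emulate.**  No hemodynamic response or
temporal autocorrelation (signals are white within state), no scanner
drift, no physiological noise spectra, no spatial maps, no motion
artifacts coupled to the signals.  Recovery results on this cohort
demonstrate that the pipeline's arithmetic and inference are correct
under the stated switching-covariance model; they do not certify
performance on real fMRI, where slower mixing, autocorrelation and
non-Gaussian artifacts reduce the effective sample size per window.

## Numerical choices and conventions

- Fisher clamp |r| ≤ 1 − 1e−12 keeps z finite for collinear pairs;
  constant components yield zero connectivity plus a warning rather than
  NaN.
- Windows with zero weighted variance set affected correlations to 0
  with a warning.
- Windowed Fisher-z estimates from ~13 effective samples (tapered 18-TR
  window) carry a positive small-sample bias of roughly r/(2(n_eff − 1))
  plus an atanh-convexity term — about +0.05 at r = 0.65.  Group-mean
  state-strength recovery is accurate to ±0.05 at moderate planted
  correlations (r ≤ 0.5) and the bias mechanism, not an implementation
  error, dominates beyond that.
- k-means determinism: a fixed `random_state` fixes the replicate
  stream; the best-of-replicates choice is by inertia.
- Degenerate two-group comparisons (zero variance in both groups)
  return p = 1 with a flag instead of erroring.
- The elbow stage in the default test-scale configuration uses the full
  57-subject cohort (12 084 windows × 351 features, k = 2..10, 20
  replicates per k), which completes in a few minutes on one CPU; the
  state fit proper uses 100 replicates.

## Known limitations

- The despike trend is a robust straight line, not the Fourier-plus-
  polynomial curve of the classic volume-based implementation; the
  contract (bounded spike amplitude, untouched in-band samples) is the
  same, the trend model is simpler.
- Spatial-map component criteria (gray-matter peak location, artifact
  overlap) are out of scope; network labels are supplied by
  configuration.
- The elbow criterion is a heuristic; with overlapping states or heavy
  window blurring the curve flattens and the weak-elbow flag plus the
  curve itself should be inspected, not just the selected k.
- No regularized (graphical-lasso) covariance option for short windows;
  estimates at W = 18 are noisy per window by design, and the state
  averaging is what stabilizes them.
- The edgewise FDR family is per-state by default (pooling across states
  is configurable); with few subjects visiting a rare state the per-edge
  t tests lose power and the state may be skipped entirely.
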
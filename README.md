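# dfncstates

Dynamic functional network connectivity (dFNC) state analysis for
resting-state fMRI component time courses: tapered sliding-window
connectivity, k-means connectivity states with elbow-based model
selection, per-subject temporal state metrics, and FDR-controlled group
statistics — plus a Markov-switching synthetic cohort generator that
plants known states so every stage is verifiable by recovery.

## Who this is for

Researchers analysing time-varying connectivity between independent
components (ICs) extracted from resting-state fMRI — for example
comparing patients with and without excessive daytime sleepiness (EDS,
Epworth Sleepiness Scale ESS ≥ 10) on how often and how long their
brains occupy recurring connectivity configurations.  The package takes
per-subject T×C component time-course matrices (TSV) plus a metadata
table; the upstream spatial decomposition (group ICA) is out of scope.

## The method

For each subject, component time courses are despiked, detrended and
low-pass filtered (0.15 Hz), then windowed with a tapered sliding
window: a rectangle of W = 18 TRs (45 s at TR = 2.5 s) convolved with a
Gaussian (σ = 3 TRs), stepped 1 TR, giving N_w = ⌊(T − W)/step⌋ windows
(212 for T = 230).  Each window yields a weighted Pearson correlation
matrix among the C components, Fisher z-transformed:

    z_ij = atanh( cov_w(x_i, x_j) / sqrt(cov_w(x_i,x_i) · cov_w(x_j,x_j)) )

with the taper as observation weights.  All subjects' windows are pooled
and clustered with k-means (Euclidean distance on the vectorized upper
triangle, best of 100 k-means++ replicates); k is chosen by the elbow
(maximum-curvature) criterion on the within-/between-cluster dispersion
ratio over k = 2..10.  Per subject and state the pipeline reports
fractional time (% of windows), mean dwell time (mean consecutive-window
run length) and the number of transitions, compares them between groups
(t or Mann–Whitney U, auto-selected; Benjamini–Hochberg FDR over the
nine metric×state tests), contrasts per-state edgewise strength (t tests,
FDR across the C(C−1)/2 edges within each state), and correlates metrics
with ESS by partial Spearman correlation adjusted for age and sex.

Details, defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Generate the default synthetic cohort (57 subjects — 16 EDS-like vs 41
non-EDS — 27 components in 7 networks, 230 TRs at 2.5 s, four planted
connectivity states) and run the full pipeline:

```sh
dfnc run --synth --seed 7 --out demo_run
```

prints

```
k = 4 states; occurrence: 14.4%, 12.6%, 25.2%, 47.8%
report: demo_run/report.md
```

Four states were fitted (numbering is fit order, not importance); the
rare 12.6 % state is the planted sensorimotor–visual state whose
occupancy was elevated in the EDS-like group.  `demo_run/metric_tests.tsv`
then contains, among the nine group contrasts:

```
variable        test          statistic  p            q
frac_time_s2    mann-whitney  557.5      3.75e-05     0.00034
dwell_s2        mann-whitney  521.5      5.12e-04     0.0023
```

— the EDS-like group spends a significantly larger fraction of time in
that state and dwells in it longer (q < 0.05 after BH-FDR), and
`demo_run/ess_correlations.tsv` shows its fractional time correlating
positively with ESS after adjusting for age and sex
(ρ = 0.78, p = 1.7e-12).  The report collects centroid heatmaps with
occurrence percentages, the strongest 5 % of edges per state by network
pair, and group boxplots.

The same stages are available as a library of sklearn-style estimators
(`TimecoursePreprocessor`, `SpectralComponentSelector`,
`SlidingWindowFNC`, `ConnectivityStateKMeans`) and plain functions
(`windowed_fnc`, `cluster_states`, `elbow_select`, `fractional_time`,
`mean_dwell_time`, `n_transitions`, `compare_groups`, `fdr_adjust`,
`partial_spearman`, ...):

```python
from dfncstates import build_cohort, default_cohort_spec, windowed_fnc, cluster_states

series, meta, truth = build_cohort(default_cohort_spec(seed=7))
windows = {s.subject_id: windowed_fnc(s) for s in series}
model = cluster_states(windows, k=4, n_replicates=100, random_state=7)
print(model.occurrence_percent)
```

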
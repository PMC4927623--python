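# Methods

This note documents the models, conventions and numerical choices behind
`emgprofile`, in the spirit of a statistical software methods appendix.

## Signal model and processing chain

Raw sEMG is treated as a zero-mean stochastic process sampled at a fixed
rate (1 kHz in the emulated field protocol). Amplitudes stay in
arbitrary instrument units throughout the raw layer; every reported
quantity is a ratio to the subject's fMVC, so gains and units cancel.
The I/O layer never filters, detrends or rescales — an optional
zero-phase Butterworth band-pass (default edges 20–450 Hz when enabled)
exists for noisy field recordings but is off by default, because the
reported metrics are defined on the signal as recorded.

**RMS envelope.** Moving-window RMS with a 0.1-s window and 0.05-s step.
0.1 s is the conventional smoothing for occupational sEMG amplitude
estimation, and the 0.05-s step gives five envelope samples per minimum
rest gap (0.25 s), fine enough to resolve it. The k-th value covers
samples `[kS, kS+W)`; the trailing partial window is discarded, never
padded, so an envelope has `floor((N−W)/S) + 1` values.

**Calibration.** The fMVC denominator is the middle-3-s RMS of the
best of ≥ 3 maximal trials. "Middle" is the centered window with a
floor-based start index on odd remainders. The maximum across trials
(not the mean) is used, matching MVC convention; the mean is available
as a config option. The 30-s baseline RMS is recorded and reported but
not subtracted by default — a flag enables envelope baseline
subtraction floored at zero. Fewer than three trials logs a warning and
proceeds; all-zero trials are a hard error because normalization is
then impossible.

**APDF.** Empirical quantiles of the normalized envelope with linear
interpolation between order statistics — the most common convention,
pinned so outputs are bit-reproducible.

**%MR.** Maximal runs of consecutive envelope values at or below
0.5 %fMVC (inclusive, since the criterion is a *maximum* threshold); a
run of n values spans `n × step` seconds and counts when that span
reaches 0.25 s. Run boundaries are whole envelope steps — no sub-step
interpolation — so the error per bout edge is bounded by one step
(0.05 s). Together with windows that straddle a bout boundary (and thus
mix in active samples), this biases %MR low by roughly `window/bout`
relative; for 1.5-s bouts that is about one percentage point, visible in
the recovery checks and well inside their tolerance.

**Exposure flags.** Strict inequalities: a load exactly at a limit is
permissible, because "should not exceed X" leaves X itself allowed.
Categories are judged on p10 (static, 2/5 %MVC), p50 (median, 10/14)
and p90 (peak, 50/70).

## Random-block ANOVA

The design is a split-plot: group (dairy location) varies between
subjects, muscle within subjects, and each subject is a block with one
value per muscle. With complete within-subject data the expected-mean-
squares decomposition gives exact F-tests:

* `F_group = MS_group / MS_subject(group)` with `(G−1, N−G)` df,
* `F_muscle` and `F_group×muscle` against the residual
  (subject × muscle) mean square with `(N−G)(m−1)` denominator df.

Subjects missing any muscle are dropped listwise for that metric, with
the count reported. Sums of squares are computed in closed form
(numpy); the muscle and interaction terms equal the hierarchical
model-comparison (Type-II) sums of squares, which the test suite
cross-checks against statsmodels OLS fits and the group term against a
one-way ANOVA on subject means. A zero-variance stratum (e.g. a
constant dataset) raises a model-fit error rather than producing
spurious significance. Variance components are method-of-moments:
`σ²_subject = max((MS_subj − MS_err)/m, 0)`.

**Simple main effects.** For each muscle, the group contrast of cell
means (which are the least-squares estimates for complete data). The
contrast variance pools both strata, `S² = (MS_subj + (m−1)MS_err)/m`,
with Satterthwaite degrees of freedom for the linear combination. The
Tukey adjustment uses the studentized range over the full family of
`G × m` cell means (Tukey–Kramer), the standard post-hoc treatment of a
significant interaction; with k = 10 means the adjusted p is never
below the unadjusted p, and relabeling the groups negates every delta
while leaving p-values unchanged. The large-herd group is listed first
by reporting convention (first appearance in the manifest).

## Synthetic-data generator

The carrier is Gaussian white noise band-passed to 20–450 Hz (4th-order
zero-phase Butterworth) — the standard surface-EMG bandwidth under a
1 kHz sampling rate. A task schedule (ordered segments with target
%MVC amplitudes) modulates it; each segment's slice is rescaled so its
realized RMS equals the target exactly, which makes the ground truth
analytic: mean envelope is the duration-weighted mean amplitude, APDF
quantiles come from the duration-weighted step distribution (midpoint
convention at step boundaries), and the scheduled rest fraction applies
the same ≤ 0.5 %fMVC / ≥ 0.25 s rule as the %MR metric, so recovery
tests are well-posed. Segment transitions are instantaneous; ramps
would blur the rest-bout boundaries the %MR checks rely on.

Calibration sets mirror the field protocol: a 30-s baseline at a low
resting level (0.2 %MVC-equivalent) and three 5-s trials at 100 %MVC.
Randomness is organized as one master seed from which per-subject /
per-recording child streams are derived via `SeedSequence(master,
spawn_key=path)`, so cohorts are bit-reproducible and streams
independent.

**Cohort defaults are the study conditions**: 26 large-herd and 39
small-herd subjects, five muscles, 3600-s work recordings, group ×
muscle mean %fMVC levels set to the published model estimates
(e.g. biceps brachii 19.32 vs 6.85 %fMVC), rest fractions 0.13 vs 0.05
matching the reported %MR contrast, between-subject SD 6 %fMVC (the
middle of the published per-muscle SDs), and 1.5-s rest bouts with a
small (SD 0.02) per-subject scatter of the rest share so %MR varies
between subjects as it does in the field. Per-subject levels are group
truth plus Normal scatter, floored at zero; the active amplitude is
`level / (1 − rest fraction)` so the duration-weighted mean equals the
subject's level.

What the generator does *not* emulate: motor-unit physiology,
electrode lift/motion artifacts, cross-talk between muscles,
non-stationary fatigue drift, and heteroscedastic measurement noise.
Passing recovery tests therefore demonstrates the correctness of the
processing chain and the statistical machinery under the stated
amplitude model, not robustness to real-world signal pathologies.

## Problem sizes in tests and the acceptance script

Monte-Carlo calibration of the interaction test runs at the metric
level (values drawn directly from the split-plot model), which is where
the test's operating characteristics live: 500 null and 200
effect replicates of the 2 × 20 × 5 design. Signal-level checks use 20
ten-minute recordings for parameter recovery, and cohort-level
end-to-end checks use 6–8 subjects per group with 30–60-s recordings —
scaled-down but structurally identical versions of the default cohort,
chosen to keep the suite quick to iterate on. Recovery tolerances
(±2 %MR points, 5 % relative on p50 and fMVC) cover the documented
envelope edge bias plus sampling variability at these sizes.

Two-level task schedules are used for median-recovery checks so the
median falls inside an amplitude level; when the median sits exactly at
a cluster edge, the window-RMS sampling distribution (≈ 7.6 % relative
SD at 0.1-s windows over a 430-Hz band) dominates the comparison and
the check would measure the sampling distribution rather than the
pipeline.

## Known limitations

* The ANOVA requires complete within-subject data after listwise
  dropping; heavily unbalanced missingness patterns are out of scope
  (a mixed-model REML fit would be the upgrade path).
* Denominator df are the classical containment values plus a
  Satterthwaite combination for simple effects; other df methods
  (Kenward–Roger) will give slightly different p-values in small
  samples.
* %MR is computed on the RMS envelope; pipelines that smooth amplitude
  differently (e.g. low-pass rectified EMG) will report slightly
  different rest shares near the threshold.
* The exposure flags summarize group-mean profiles in the report;
  per-subject screening is available through the library API.
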
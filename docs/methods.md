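# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic data emulate, and where the design was genuinely
open.

## The biomarkers

For a delineated beat series (R-peak times `t_k`, preceding interval
`RR_k`, `QT_k` from QRS onset to T end, `Tpe_k` from T apex to T end, all in
ms):

- **QTc, Tpec** — Fridericia correction `I / (RR/1000)^(1/3)` by default,
  Bazett `I / (RR/1000)^(1/2)` as the common alternative. A subject's value
  is the mean of per-beat corrected values over valid beats (median
  switchable); the mean was chosen as the lower-variance choice when the
  cleaning stage has already removed outliers.
- **Rate memory and t90** — repolarization intervals track a weighted
  average of RR history, not the instantaneous RR:

      z_k = sum_i w_i RR_{k-i},  w_i >= 0,  sum w_i = 1
      y_k = a z_k + b + noise

  with FIR weights over a 300 s history window (beat-indexed; the beat-time
  grid maps lags to seconds via the record's mean RR). `t90`, the time to
  complete 90 % of adaptation after an abrupt rate change, is read off the
  weight profile: the filter's step response equals the cumulative weight
  sum, so t90 is the interpolated lag time where `cumsum(w)` first reaches
  0.90. A delta filter gives t90 = 0; an exponential profile with time
  constant tau gives tau·ln 10.
- **DRest** — the dispersion-of-restitution index, operationally the change
  in Tpe per unit change of RR once rate memory is removed. With
  free-running RR the two-point ratio generalizes to the slope of `Tpe_k`
  against the memory-compensated surrogate `z_k`, fitted by Theil–Sen
  (median of pairwise slopes; OLS switchable) over all valid beats, with a
  95 % CI from a seeded bootstrap over beats (1000 resamples; inside
  resamples of records longer than 500 beats the pairwise median is
  computed over 8000 random pairs to keep the loop linear-time). One scalar
  per subject, over the subject's observed RR range; at least ~100 joint
  valid beats and a >= 50 ms surrogate-RR span are required for an
  unflagged estimate — in practice 10–15 min of recording containing
  sustained heart-rate changes.

## Fitting the memory filter

Lagged RR regressors are heavily collinear (piecewise rate levels plus
AR(1) short-term variability), which makes unrestricted FIR deconvolution
ill-conditioned. The default estimator therefore works in a physiological
cone: the weight profile is a nonnegative mixture of exponential decays
(25 log-spaced time constants between 2 and 250 s) plus an instantaneous
delta atom, each atom normalized to unit sum. Because the stationary curve
`g` is linear, the joint problem in (weights, a, b) reduces to a single
nonnegative least-squares fit (intercept removed by centering), with a
global optimum and no iteration.

A refinement stage then fits a single *continuous-time* exponential — the
surrogate computed by the exact recursive filter
`z_k = e^{-RR_k/tau} z_{k-1} + (1 - e^{-RR_k/tau}) RR_k` with tau found by
1-D bounded search — and is adopted whenever it fits the data at least as
well as the mixture. This matters because a beat-lag FIR is time-invariant
in beat index while physiological memory runs in continuous time; on data
whose memory really is one exponential the refinement recovers the
generator exactly (the closed loop is then exact to optimizer precision).

The free-profile alternative (`basis="free"`) keeps the unrestricted
simplex weights: alternating least squares between `g` (OLS) and the
weights (projected-gradient / FISTA on the probability simplex, warm
started), with an optional second-difference roughness penalty
(`reg_lambda`, default 1e-3 relative to the data term). It is retained for
model-free exploration; its t90 estimates are noticeably noisier.

Degenerate inputs — a 1-min-smoothed RR range under 50 ms, or a target that
does not increase with filtered RR — yield a flagged model with undefined
t90 rather than an exception.

## Delineation

QRS detection: band-pass (5–25 Hz), derivative, squaring, 120 ms
moving-window integration, adaptive threshold at 20 % of the 99th feature
percentile, 200 ms refractory, anchors snapped to the band-passed extremum.
QRS onset: backward search from the maximal upstroke for the last point
where |dV/dt| drops below 5.5 % of the beat's maximal slope — on a
Gaussian-shaped R wave this crossing sits 3 sigma before the apex (the
visual foot); the crossing is interpolated to sub-sample precision. T apex:
extremum of the 20 Hz low-pass-filtered T window
`[R + 80 ms, R + min(600 ms, 0.7 RR)]` (the cap avoids the next P wave at
fast rates), refined parabolically. T end: tangent method — the steepest
tangent on the descending limb intersected with the isoelectric baseline
(median of the 40 ms before QRS onset). The tangent convention was chosen
because it dominates the Tpe literature and needs no trained model; the
same routine delineates the simulated pseudo-ECGs, keeping clinical and
in-silico Tpe definitions identical. Beats failing any search keep their
slot with `valid=False`; intervals are never interpolated. Cleaning flags
RR outside [300, 2500] ms, QT/Tpe beyond 5 running MADs of a 60-beat
window, and ectopic-adjacent patterns (>30 % RR swing with compensation).

## Synthetic data

The generators emulate the statistical structure the estimators assume:
RR as piecewise levels (a step every ~5 min, alternating ±5–10 % swings, so
sustained rate changes are guaranteed) plus AR(1) variability (rho = 0.8,
sd 15 ms) and optional respiratory modulation; Tpe as
`tpe0 + DRest_true (z - 1000) + noise` with z from the continuous-time
exponential filter (tau = t90_true/ln 10, warmed up at the baseline rate);
QT as `QTc_true (z/1000)^(1/3) + noise`, exactly Fridericia-invariant at
stationarity. Defaults: t90_true = 80 s (middle of the published healthy
bands; small enough that the 300 s estimation window truncates a negligible
tail of the memory kernel), noise 2 ms, 30-min records.

Waveforms are Gaussian-lobe beats (P, R, and a T whose sigma is Tpe/2, so
the tangent-method end lands at QRS onset + QT by construction; ground-truth
onset is 3 sigma before the R apex) sampled at 180 Hz with optional white
noise and baseline wander. They exercise the delineator's landmark logic,
not real morphology: no Q/S waves, notched or biphasic T, U waves,
ectopy or muscle artefact — so passing delineation tests demonstrates
landmark accuracy and noise tolerance, not clinical-grade robustness.

Cohorts draw healthy DRest uniformly over 0.025–0.058 and torsadogenic over
0.18–0.22; healthy QTc scales uniformly over 376–467 ms, while the three
patient QTc/Tpe scales cycle through the reported patient values (548/436/
480 ms, jittered ±3 ms) so that the key qualitative feature — one patient's
QTc inside the healthy range, hence no complete QTc separation — holds by
construction rather than by lucky draw. t90 draws: healthy 90–200 s,
patients 251–292 s. All generators are deterministic under a single seed.

## The in-silico arm

A 1D monodomain cable stands in for a transmural slice: 100 nodes,
dx 0.15 mm (15 mm), 25 % endocardial / 35 % midmyocardial / 40 % epicardial
in series, ten Tusscher–Panfilov (2006) membrane dynamics with the published cell-type parameters, stimulated at
the endocardial end (-52 pA/pF, 1 ms, 3 nodes). Numerics: operator
splitting, forward-Euler voltage and concentrations, Rush–Larsen gates,
explicit diffusion with no-flux ends, dt 0.02 ms. The diffusion coefficient
(0.10 mm²/ms) was set to put the transmural conduction velocity at
~59 cm/s, the middle of the 40–70 cm/s target range. The pseudo-ECG is the
standard unipolar far-field integral over the strand with the electrode
20 mm beyond the epicardial end; its T wave is delineated with the same
tangent routine as the clinical module. IKr block is a single multiplier on
the IKr maximal conductance (0.5 = IC50 dose of a class III agent); no
other channel effects of sotalol (IKs, beta-blockade) are represented.

The dynamic restitution protocol paces each stationary cycle length
independently from rest (full profile: 50 pre-beats, RR 500–1500 ms step
100; fast profile: 10 pre-beats, step 250 — the profile used by the test
suite and the acceptance script, with results understood as scaled-down),
measures per-node APD90 (max-dV/dt activation to interpolated 90 %
repolarization) and pseudo-ECG Tpe on the final beat, and differentiates on
the RR grid (centered differences, one-sided at the ends; linear
interpolation of the derivative between grid points). Both dispersion
readouts are reported: the ECG-side `DRest(RR) = dTpe/dRR` and the
tissue-side `alpha1 - alpha2` (max minus min per-node restitution slope);
across the grid the two are rank-correlated > 0.8, which is the mechanistic
link the ECG index relies on.

Known small effects worth stating plainly: per-node APD90 is monotone in RR
only up to ~0.5 ms — timing interpolation is good to ~0.1 ms, 10-beat
pacing leaves ~0.1–0.3 ms transients, and under IKr block the restitution
curve genuinely plateaus and dips a few tenths of a ms between 1250 and
1500 ms (a deep-plateau property of the cell model). In this 1D geometry a
homogeneous strand still shows a ~7 ms end-to-end APD90 gradient (stimulus
electrotonus, sealed ends, and the repolarization wake that scales with
activation delay); "interior" homogeneity claims therefore refer to the
central half. And the *amplitude* of the T wave is not a monotone readout
of dispersion here — the homogeneous strand's monotone repolarization
gradient integrates to a larger peak than the partially cancelling
endo/M/epi profile — whereas T-wave *width* (Tpe) is: heterogeneity and
extra M fraction both widen it.

## Statistics

Percentiles are linear-interpolation ("type 7"). The exact Mann–Whitney
test enumerates label assignments (ties handled by half-counts) when
`C(n_a+n_b, n_a) <= 1e6`; tie-free designs use the exact null recurrence;
larger tied designs fall back to the tie-corrected normal approximation.
Two-sided exact p = 2·min(one-sided), capped at 1. Welch's t uses
Satterthwaite degrees of freedom; the degenerate zero-variance/equal-means
case returns p = 1. Single-observation separation is reported in sample
standard deviations of the reference group.

## Problem sizes and tolerances used by the test suite

Recovery suites use 30–40 min synthetic records, 10–28 subjects, 20
replicates; the strand suites use the fast profile (100 nodes, 10
pre-beats, 5 RR levels). The cell kernel is cross-checked against an
independently written right-hand side integrated by LSODA (identical
pacing, APD90 within 5 ms; observed agreement ~0.4 ms). Halving dt changes
single-cell APD90 by well under 2 ms. Closed-loop noise-free DRest recovery
is exact to 4 decimals; with 2 ms noise the median relative slope error is
~2 %, and t90 is recovered within 15 % in ~90 % of seeded replicates.

## Limitations

Real 12-lead morphology (Q/S waves, biphasic T, U waves), atrial activity
and ectopy are out of scope of the waveform generator; the delineator's
tangent T-end is one of several conventions and differs from wavelet-based
delineators by a few ms systematically; the 1D strand cannot represent
apico-basal or anterior-posterior gradients, and no arrhythmia initiation
is simulated; sotalol pharmacokinetics and multichannel pharmacology are
not modeled — IKr block stands in for the IC50 dose.
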
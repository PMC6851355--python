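# Methods

This note documents the models, estimators and numerical choices behind
`spinaltone`, and what the synthetic-data engine does and does not
emulate.

## Voltage-clamp generator

A recording is `baseline + I_tonic + Σ event kernels + white Gaussian
noise`, sampled at 20 kHz (the acquisition rate of the recordings the
package targets).

- **Event kernel.** Difference of exponentials
  `A·(e^(−t/τ_d) − e^(−t/τ_r))` normalized to peak amplitude `A`, with
  τ_r = 0.7 ms by default — fast enough that the decay fit is unaffected
  at 20 kHz. Decay constants are drawn per class: glycinergic
  N(6.2, 2.2) ms, GABAergic N(42, 6) ms (only the 42 ms mean is an
  empirical anchor; the 6 ms spread is this package's choice), AMPA
  N(2.5, 0.8) ms. Co-release ("mixed") events are the sum of one
  glycine-kernel and one GABA-kernel component, weighted 0.5/0.5 by
  default; a single-exponential fit of that composite lands at ≈26 ms,
  inside the 16.8–35.7 ms intermediate band.
- **Polarity and amplitudes.** Event polarity follows the driving force
  at the hold: chloride events recorded at 0 mV (the EPSC reversal) are
  outward, AMPA events at −70 mV (the IPSC reversal) inward. Drawn
  amplitudes (default N(20, 5) pA) are expressed at the standard 70 mV
  driving force and scaled by (V_hold − E_rev)/70.
- **Event rate.** The IPSC preset plants 5 Hz of events total, split
  0.34/0.25/0.41 across glycinergic/GABAergic/mixed — a realistic
  spontaneous rate for these cells. At 5 Hz roughly a quarter of events
  start within the decay window of their predecessor, which is the main
  driver of classification error (below).
- **Tonic current.** A per-class chloride conductance with reversal
  −70 mV; its current at the hold is `g·(V_hold − E_tonic)`. The preset
  shares are chosen so the glycine and GABA tonic currents at 0 mV are
  10.25 and 22.5 pA.
- **Pharmacology as parameter transforms.** Strychnine zeroes the
  glycinergic rate, the glycine component of mixed events (halving their
  amplitude) and the glycine tonic share; bicuculline is the GABA
  mirror; CNQX/NBQX multiply the AMPA rate by 0.1 (90% block), with CNQX
  adding an 11.5 pA depolarizing (inward) baseline shift and NBQX none;
  GRP adds a depolarizing shift only for responsive cells.

## Event detection

The trace is smoothed over 0.5 ms, a slowly varying baseline (per-second
block medians, interpolated) is subtracted, and peaks of the
polarity-rectified signal are kept when both their height and their
prominence exceed `threshold_k` (default 4) times the robust noise sd
(1.4826 × MAD of the high-pass residual of the raw trace), with a 5 ms
minimum separation. The prominence requirement is what stops noise
wiggles riding a slow GABAergic tail from registering as events, while a
genuine event on a tail keeps prominence ≈ its own amplitude. Onsets are
the last 5%-of-rise crossing before the peak; for events that ride a
predecessor's tail the crossing is referenced to the local inter-peak
valley and anchored at the sharp mid-rise crossing, because a plain
back-walk would descend the predecessor's decay. Detection is invariant
to constant baseline shifts by construction.

## Decay fitting and overlap decomposition

Each event is fitted with `A·e^(−t/τ)` from its peak to the first
crossing of 10% of the peak or 5× the initial τ guess (1/e crossing),
whichever comes first, capped at 500 ms. Two numerical points matter:

- Crossing times are measured on a 3 ms-smoothed reference with a
  sustained-crossing rule (the signal must stay below the level for
  1 ms). On the raw 20 kHz signal the *first* noisy dip below a level
  occurs far before the underlying decay reaches it, which silently
  shortens every window and biases τ low.
- Fits over more than 600 samples are bin-averaged to ~400 points; an
  exponential spanning tens of ms does not need 50 µs resolution, and
  the least-squares cost drops an order of magnitude.

Overlaps are decomposed in two passes: pass 1 fits in onset order,
subtracting the running tail of the previous event and truncating at the
next onset; pass 2 refits every event over its full window with the
fitted components of all neighbours subtracted and their rise phases
masked (bridged by interpolation for window purposes). Fits with τ at a
parameter bound or amplitude far above the observed peak are degenerate
residues of imperfect subtraction and are marked unclassified, as are
windows shorter than three samples.

**Known limitation.** Two slow decays that start within ~15 ms of each
other are not identifiable with single-exponential components; the fast
(glycinergic) class therefore inflates by ~2–3 percentage points at the
5 Hz preset rate (measured ≈36% against a planted 34%), within the
±5-point recovery band the package tests. Joint cluster fitting was
evaluated and does not help in exactly those configurations.

## Holding current and tonic shifts

The holding current of an epoch (≥5 s) is the mean of a Gaussian fitted
to the dominant peak of the epoch's all-points histogram
(Freedman–Diaconis bins; fit region = contiguous bins above 20% of the
mode, widened to at least five bins). Synaptic events occupy the
histogram tail and barely move the peak; with 2 pA noise the estimator
recovers planted offsets well within the 0.5 pA tolerance the tests assert. If fewer than half the samples
lie within ±3 sd of the fitted peak the estimate is flagged with a
warning rather than silently returned. A tonic current is the magnitude
of the (signed) holding-current difference between the post- and
pre-antagonist epochs; sequential shifts are additive by construction.

## LIF cell and excitability

Exponential-Euler integration at the trace sample rate is exact for
piecewise-constant input and unconditionally stable; an integration step
longer than the membrane time constant is rejected. Spikes are
threshold/reset events; the spike sample is written at +20 mV so that
the −20 mV upward-crossing criterion used on recorded voltage traces
sees simulated spikes too. The `study_cell` preset is *derived*, not
tuned: control (911.9 MΩ) and blocked (2920 MΩ) input resistances fix
g_L = 0.342 nS and g_tonic = 0.754 nS; the control resting potential
(−56.96 mV) and rheobase (39.8 pA) fix V_th = −20.67 mV; the rheobase
difference (32.4 pA) fixes E_tonic = −63.63 mV via the closed form
Δrheobase = g_tonic·(V_th − E_tonic); E_L = −42.27 mV follows, and the
blocked rheobase (7.4 pA) is then automatic. C = 22 pF gives a ~20 ms
control membrane time constant. The rheobase search ascends linearly in
1 pA steps with 500 ms pulses, as the recording protocol did; when the
analytic rheobase falls exactly on the grid the threshold is approached
only asymptotically and the search returns one increment above —
returned values always lie within one increment above the analytic
value. Input resistance uses the mean of the last 20% of a subthreshold
pulse (≫ membrane time constant) against the pre-step baseline.

Group comparisons use the two-tailed Student's t-test (equal variances)
for electrophysiological measures and the Mann-Whitney U test for ΔF/F
cohorts, via scipy.

## Calcium imaging

Fluorescence is linear superposition of per-spike GCaMP6f transients
(rise 50 ms, decay 1000 ms) on a constant F0, sampled at 2 Hz. The
per-spike ΔF/F amplitude (1.15%) is calibrated so a ~19-spike burst
inside a 500 ms pulse reads ~17.5% on the frame grid — the high-current
end of the calibration pairing. The calibration cell preset uses a long
(20 ms) refractory period as a stand-in for spike-frequency adaptation
so that spike counts at 30/80 pA land near the calibration pairing
rather than at the raw LIF f–I rate; the calibration protocol is 8
steps, 10–80 pA, 500 ms pulses, 1000 ms intervals.

Analysis choices: F0 is the pre-drug minute for drug runs and the first
30 s for control runs; peaks must exceed the threshold *strictly*
(signals "lower than" the threshold are noise, so equality is excluded);
peak separation defaults to 2 s (four frames — GCaMP6f decays over
seconds); repeated bursting = ≥3 suprathreshold peaks within any sliding
300 s window (control recordings are 5 min, drug recordings 15 min, so a
sliding window generalizes the rule to both); the 3.5% criterion applies
to peak height above baseline, not prominence. A peak before drug
arrival flags the cell spontaneously active and removes it from the
responder set. Reaction time is measured from drug arrival in the
chamber (1 min into the recording) to the first suprathreshold peak.
The cohort generator draws responder latencies from a truncated normal
with mean 5.8 min and sd 4 min, which reproduces a cohort-level s.e.m.
of ~0.8 min at n = 25 responders.

## Single-cell prevalence

Normalization scales every cell to the median of the pre-normalization
per-cell totals, then applies log1p (scanpy's `normalize_total` +
`log1p`, the same operations the original processing used); all-zero
cells are dropped with a warning. Population selection keeps cells with
the selector gene's normalized expression strictly above 0.01. The
source describes the prevalence rule once as "> 0.01" and once as
"< 0.01"; the ">" direction is implemented (the "<" reading would call
a gene "expressed" where it is absent) and the direction is exposed in
the pipeline config. Whether the 0.01 threshold applies before or after
the log is also ambiguous in the source; post-log is implemented — at
this magnitude log1p(x) ≈ x, so the choice is immaterial in practice,
and it is configurable. Gene symbols match exactly first, then
case-insensitively.

The count-matrix generator plants per-gene prevalence as a Bernoulli
expression mask; expressed entries are `1 + Poisson(depth·(µ−1))` with
lognormal per-cell depth factors, so an expressed gene survives
median-depth normalization well above the 0.01 threshold and planted
prevalences are recovered to binomial accuracy. It does not model
gene–gene correlation, dropout gradients, doublets or batch structure —
recovery tests validate the prevalence arithmetic, not robustness to
those real-data features. Likewise the trace generators use white noise
and stationary baselines: passing tests demonstrate correct estimator
behaviour under the stated model, not immunity to drift, seal
instability or imaging artifacts.

## Problem sizes

The bundled tests run recordings of 30–400 s at 20 kHz, cohorts of ~74
ROIs and matrices up to 24,384×1,545 (sparse); the acceptance script
measures the kinetic mixture on five ~2000-event recordings (400 s
each). These sizes give multinomial/binomial sampling error comfortably
inside the stated tolerance bands.

## Reproducibility

Every generator takes an explicit seed (numpy `default_rng`; sequences
spawn per-epoch sub-seeds deterministically); there is no hidden global
state, and identical (config, seed) pairs produce byte-identical report
numerics.
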
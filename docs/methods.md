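# Methods

This note documents the models and procedures implemented in
`hippoephys`, the assumptions behind them, the parameters that matter,
and the places where a genuinely open design choice was made.

## Synthetic sessions and what they do (not) emulate

The generator produces the statistical structure the analyses assume,
with a complete ground-truth record so every stage can be validated by
parameter recovery.

The LFP is a sum of

- **theta**: `−A_θ(t)·cos(2π f_θ t)` with `f_θ` = 7 Hz by default
  (anywhere in 5–12 Hz is accepted). The minus-cosine form puts the
  waveform troughs at phase 0°/360° and the peak at 180°, matching the
  trough convention used by the phase analyses. Amplitude is
  state-dependent: 1.0 a.u. while moving, 0.1 at rest.
- **delta**: a 3 Hz component that is large at rest (0.6 a.u.) and small
  during movement (0.05), standing in for the large irregular activity
  of immobility. Without it the theta/delta ratio would stay above
  threshold at rest and the epoch detector would have nothing to reject.
- **gamma**: 60 Hz (mid-gamma) carried only during movement, with
  amplitude `(1 + d·cos(φ_θ − φ_c)) / (1 + d)`: phase-amplitude coupling
  of depth `d ∈ [0, 1]` at coupling phase `φ_c` (default 180°, i.e. the
  theta peak).
- **ripples**: at rest only, Poisson events (0.2/s) of Gaussian-windowed
  150 Hz bursts, 60 ms long.
- **background**: Gaussian noise spectrally shaped to 1/f (exponent 1.0,
  RMS 0.2 a.u.).

Movement and rest alternate as labeled 10-s states (or follow the trial
structure in full sessions); the true state intervals are part of the
ground truth, since no speed threshold for "movement" is assumed
anywhere.

Spike trains are inhomogeneous Poisson processes with intensity

    λ(t) = r₀ · exp(κ·cos(φ_θ(t) − μ)) / I₀(κ) · g(x(t)),

where the von Mises factor has unit mean over uniform phase (so the
long-run rate stays r₀), and `g` is a Gaussian place-field gain on the
corridor fraction (default peak gain 5 at width σ = 0.1). The expected
mean resultant length of the spike phases is the Bessel ratio
I₁(κ)/I₀(κ), which is the oracle for all phase-locking calibration
tests. Complex-spike units expand each parent event into a burst of 2–4
spikes at a fixed 5 ms intra-burst interval with probability 0.5;
interneurons never burst. The generator's theta phase is the analytic
phase of the theta oscillator, never re-estimated from the signal, so
recovery tests keep the generator and the analyzers independent.

Virtual-corridor sessions consist of constant-speed runs (20 cm/s with
15% per-trial jitter) down a 2-m corridor, each followed by a 3-s reward
lock at the corridor end and a teleport back to the start.

What the generator does **not** emulate: biophysical membrane dynamics,
waveform shape and spike sorting (units arrive as clean event lists),
theta asymmetry and sequences/phase precession, multi-channel probe
geometry, behavioral variability beyond speed jitter, and non-stationary
drift. Passing tests therefore demonstrate that the analyses recover the
parameters of this statistical model — not that they are robust to every
failure mode of real recordings.

## Preprocessing

DC shifts are removed by subtracting a centered 0.3-s sliding-window
mean (edges use shrunken windows). Note the operator is not a
projection: a second application is only exactly neutral on trend-like
content; on oscillatory content it re-applies the boxcar's sinc ripple
(≤ a few percent in the theta band).

Downsampling (default to 1.25 kHz) low-passes at 0.4× the target rate
(8th-order Butterworth, forward-backward) before decimation. All
band-pass filtering is zero-phase (4th-order Butterworth,
forward-backward): trough times and therefore assigned spike phases are
never shifted by the filter. The filter family is a design choice — only
the bands are inherited from the protocol — made for phase fidelity.

## Theta epochs, theta peak, ripples

Theta epochs use non-overlapping 2-s windows (the simplest reading of
"in 2-s windows"); adjacent supra-threshold windows merge. The peak
frequency interpolates the Welch spectrum with a cubic spline anchored
one bin beyond each band edge, so the spline never extrapolates inside
the searched range.

Ripple detection computes an RMS envelope in 10-ms sliding windows of
the 130–230 Hz band. Events are where the envelope exceeds mean + 3 SD;
the 3 SD core must last ≥ 20 ms (cores closer than 20 ms merge), and
boundaries then extend outward to the crossing of mean + 1 SD, pulled
back by half the envelope window per side to compensate the smoothing's
spread. Only the 3 SD rule is inherited; the boundary rule, minimum
duration and merge gap are this package's (configurable) choices.
Requiring the minimum duration of the *core* keeps the false-positive
rate on pure 1/f noise below 1 event/min at default settings. Per-event
frequency comes from mean trough-to-trough intervals inside the event —
robust for 4–10-cycle events, unlike a spectral peak on ~60 ms of data —
and `n_cycles` is the trough-interval count.

## Masked EMD and Hilbert-Huang attributes

Sifting subtracts the mean of cubic-spline envelopes through maxima and
minima (edge extrema mirrored beyond the record) until either 15 inner
iterations or a relative squared envelope-mean below 1e-8. Each IMF is
extracted with a mask sinusoid added before sifting and subtracted
afterwards, averaged over 4 mask phases (0°, 90°, 180°, 270°). The mask
amplitude is 2× the SD of the current residual — large enough to own the
extrema (preventing mode mixing), small enough not to swamp the signal;
this is common masked-sift practice, as no amplitude is prescribed by
the protocol. Because each residual is defined by subtraction,
completeness (ΣIMF + residual = input) holds to floating-point error by
construction, and the suite verifies ≤ 1e-6 relative RMS.

The Normalized-Hilbert Transform divides the IMF by the interpolated
envelope of its absolute-value maxima until the carrier has unit
amplitude, takes the phase from the analytic signal of the carrier
(shifted by 180° into the trough convention), and the instantaneous
frequency as the phase derivative, median-smoothed over 3 samples. Two
numerical guards matter: the normalization envelope uses **PCHIP**
(shape-preserving) interpolation rather than a cubic spline, which can
overshoot between extrema and produce isolated amplitude spikes of
several orders of magnitude; and the envelope is floored at 1e-3 of the
IMF's global peak so division stays bounded where a component is locally
silent (e.g. gamma during rest).

IMF summaries are amplitude-weighted means of instantaneous frequency
over movement epochs (whether weighting should be amplitude-based was an
open choice; unweighted means would let silent, noise-dominated stretches
vote). IMF1 is excluded from summaries by default as noise-dominated.
The comodulogram uses 24 phase bins of 15° (the bin width was open;
24 divides 360° evenly and matches the reporting granularity of 20°-bin
phase histograms), requires at least 10 theta cycles, and trims 0.5 s at
each epoch edge, where sifting and the Hilbert transform are least
reliable — without the trim, state-transition transients that always
fall at the same theta phase (state periods are integer multiples of the
theta period) masquerade as coupling.

## Unit classification and rate maps

The CS (complex-spike) criteria quantify "a prominent peak between 3 and
8 ms followed by a relatively fast decay" as: argmax of the 1-ms-binned
autocorrelogram over 2–20 ms inside [3, 8] ms; mean 3–8 ms count ≥ 2×
the 40–50 ms baseline; mean 12–20 ms count ≤ 0.5× the 3–8 ms peak. The
two ratios are free parameters of this package (no numbers exist to
inherit); at these defaults the classifier reaches ≥ 0.9 sensitivity and
specificity on generator units, and a regular 8-ms pacemaker is
correctly rejected by the decay criterion. With fewer than 50 pairs the
flag is indeterminate (`None`). The putative-pyramidal-cell filter's
"event autocorrelogram value below 10 ms" is ambiguous in its source; it
is implemented as the autocorrelogram mode, noted here as an assumption.

Rate maps are occupancy-based (spikes per second actually spent in each
bin) because running speed varies along the corridor; the first trial of
each session is excluded by default. Σ(rate × occupancy) over included
bins equals the included spike count (conservation, tested).

## Permutation test and FDR

The shuffle unit is the 18 (occupancy, count) bin pairs within every
trial — occupancy travels with its counts, so surrogates remain valid
rates. P-values are one-sided ("significantly higher") with the add-one
estimator, so the smallest attainable p is 1/(n_perm + 1). The engine is
validated against exhaustive enumeration of all within-trial
permutations on a 3-bin toy map. The FDR family is one unit's 18 bins,
Benjamini–Hochberg at q = 0.05 (family, method variant and level were
open; BH at 0.05 is the field default), and only the 15 spatial bins
count toward the place-cell call. Missing bins (e.g. a trial without a
reward lock) are excluded pairwise from the across-trial average.

## Circular statistics

Spike phase is linear interpolation between successive troughs (strict
local minima of the zero-phase filtered trace; plateaus resolve to
midpoints) within theta epochs; spikes outside epochs or outside an
epoch's first/last trough are dropped and counted. The Rayleigh p-value
uses the standard finite-n approximation
`p ≈ exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))` with R = n·r; it matches an
independent implementation (pingouin) to 6 significant digits and its
empirical type-I error under uniform phases is 0.05 ± 0.01. Minimum
spike counts for inclusion are dataset-derived quantities kept as
configurable presets ({cs: 72, non_cs: 241} and {cs: 45, non_cs: 168});
exclusion is strict "fewer than". The circular SD is √(−2 ln R̄) with R̄
computed over unit-level mean phases, clipped at R̄ = 1 so identical
angles give exactly 0.

## Group statistics and behavior scores

The t test is pooled-variance (df = n₁ + n₂ − 2), not Welch, matching
the degrees of freedom convention of the summaries it recomputes; it is
exactly recomputable from printed mean ± SD ± n. Mann-Whitney reports
both U orientations (published U values do not fix one); p is exact by
enumeration for n₁·n₂ ≤ 400 without ties, else normal approximation with
tie correction, and fully tied samples return p = 1. Behavior scores:
discrimination ratio t_novel/(t_novel + t_other) (chance 0.5),
alternation score (fraction of choice runs entering the non-forced arm;
chance 0.5), analytic chance level 100/m % for an m-option choice
(33.3% for a three-arm maze goal arm).

## Problem sizes and tolerances

Simulation-based checks use sizes chosen to give stable statistics at
desk scale: 100-s LFPs for PAC recovery (10 seeds), ≥ 1000 spikes for
κ→r calibration (tolerance 0.05 on r), 10,000 replicates of n = 100 for
Rayleigh calibration (0.05 ± 0.01), 500 null units at 1,000 permutations
for place-cell type-I control (the production default stays 10,000
permutations), 20 injected ripples at 4× envelope SNR for
recall/precision ≥ 0.9, and 100 units (50/50) for CS classification.
Derandomized seeds are fixed in the tests; binomial checks use
2-SE slack around their nominal rates.

## Known limitations

- EMD mode allocation follows the mask ladder; oscillations between two
  mask frequencies (e.g. 25–32 Hz) can split across adjacent IMFs.
- Instantaneous frequency is unreliable within ~0.5 s of record and
  epoch edges; summaries and comodulograms trim those samples rather
  than model them.
- The trough-interpolated phase assumes at least two detectable troughs
  per epoch and degrades gracefully (spikes dropped and counted) when
  theta is weak.
- The generator's two-state movement model and constant theta frequency
  are idealizations; speed-continuous theta-amplitude coupling is not
  modeled.
- Group comparisons cover t/U/D statistics only; hierarchical designs
  (linear mixed models) are out of scope.
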
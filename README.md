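# hippoephys

Analysis of hippocampal-formation in vivo electrophysiology: theta and
sharp-wave-ripple detection in local field potentials (LFPs), masked
empirical-mode-decomposition (EMD) Hilbert-Huang phase-amplitude
coupling, complex-spike unit classification, place-cell permutation
testing on a virtual linear corridor, and spike-phase circular
statistics — together with a synthetic session generator that makes
every stage verifiable by parameter recovery.

It is written for systems neuroscientists who analyze rodent
extracellular recordings (glass electrode or silicon probe) together
with behavior, and who want each analysis step to be tested against
ground truth rather than trusted by eye.

## What it computes

**Rhythms.** Theta epochs are windows where the RMS ratio of theta
(5–12 Hz) to delta (2–4 Hz) exceeds 2 in 2-s windows. The theta peak is
read from a cubic-spline-interpolated Welch spectrum (Hanning, 2048-point
FFT at 1.25 kHz, ≈0.61 Hz bins) and averaged within running-speed bins
(4–6 and 6–10 cm/s). Ripples are 130–230 Hz events whose RMS envelope
exceeds mean + 3 SD, with per-event frequency from trough-to-trough
intervals.

**Hilbert-Huang spectra.** Masked EMD with masks
(350, 200, 70, 40, 30, 7, 1) Hz / f_s splits the LFP into intrinsic mode
functions (theta ≈ IMF6, slow/mid/fast gamma ≈ IMF4/3/2). The
Normalized-Hilbert Transform gives instantaneous amplitude a(t),
frequency f(t) and phase φ(t) per IMF; binning gamma amplitude by theta
phase (troughs at 0°/360°, peak at 180°) yields the phase-amplitude
comodulogram.

**Units.** Units below 0.1 Hz are excluded. Complex-spike (CS) bursting
cells are recognized by an autocorrelogram peak in 3–8 ms with fast
decay. Firing rates are mapped onto 18 bins per trial (15 spatial bins
along the corridor + three 1-s bins at the reward lock). Spatial
modulation is tested by shuffling the 18 (occupancy, count) pairs within
every trial (10,000 surrogates), with one-sided add-one p-values,
Benjamini–Hochberg FDR across a unit's bins, and a place-cell call when
any spatial bin survives.

**Phase coupling.** Spike theta phase is linearly interpolated between
successive troughs of the 5–12 Hz filtered trace. Coupling is the mean
resultant vector r·e^{iμ} = Σe^{iφ_j}/n, tested with the Rayleigh
statistic Z = nr² (finite-n p-approximation); population spread is the
circular SD √(−2 ln R̄).

**Group statistics.** Pooled-variance unpaired t (recomputable from
printed mean ± SD summaries), Mann-Whitney U (both orientations),
two-sample Kolmogorov-Smirnov D, novelty discrimination ratios,
alternation scores and analytic chance levels.

## Worked example

```python
import numpy as np
from hippoephys.synthetic_data import SessionConfig, UnitConfig, gen_session
from hippoephys.lfp_rhythms import detect_theta_epochs
from hippoephys.units import session_rate_map, autocorrelogram, classify_cs
from hippoephys.place_cells import place_cell_test
from hippoephys.theta_coupling import assign_theta_phase, rayleigh

cfg = SessionConfig(
    n_trials=21, seed=42,
    units=[UnitConfig(unit_class="cs_pyramidal", base_rate=2.0, kappa=1.0,
                      mu_deg=180.0, field_center=0.4, field_gain=5.0, seed=0)],
)
sig, trains, behavior, truth = gen_session(cfg)
unit = trains[0]
print(f"session: {sig.duration:.0f} s, {len(unit)} spikes")

epochs = detect_theta_epochs(sig)
print(f"theta epochs: {len(epochs)} covering {sum(b-a for a,b in epochs):.0f} s")
print(f"complex-spike unit: {classify_cs(autocorrelogram(unit))}")

rm = session_rate_map(unit, behavior)
res = place_cell_test(rm, n_perm=10_000, seed=1)
print(f"place cell: {res.is_place_cell}, significant spatial bins:",
      np.flatnonzero(res.rejected[:15]).tolist())
print(f"true field bin: {truth.units.field_bin.iloc[0]}")

pa = assign_theta_phase(unit, sig, epochs)
cr = rayleigh(pa.phases_deg)
print(f"theta coupling: r={cr.r:.2f}, mean phase={cr.mean_phase_deg:.0f} deg, "
      f"Rayleigh p={cr.rayleigh_p:.2e} (n={cr.n_spikes})")
```

Output:

```
session: 278 s, 1900 spikes
theta epochs: 21 covering 206 s
complex-spike unit: True
place cell: True, significant spatial bins: [4, 5, 6, 7]
true field bin: 6
theta coupling: r=0.47, mean phase=184 deg, Rayleigh p=2.29e-167 (n=1625)
```

The generated unit had a Gaussian place field centered at corridor
fraction 0.4 (true bin 6 of 15) and von Mises phase locking at
μ = 180°, κ = 1 (expected r = I₁(1)/I₀(1) ≈ 0.45). The pipeline flags
the unit as a bursting place cell, localizes the field to bins 4–7, and
recovers the preferred phase within 4° — the burst spikes push the
measured r slightly above the single-spike expectation.

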
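"""Masked empirical mode decomposition and Hilbert-Huang attributes.

EMD decomposes a non-linear, non-stationary trace into intrinsic mode
functions (IMFs) by iteratively subtracting the mean of cubic-spline
envelopes through the extrema ("sifting"). Plain sifting suffers from
mode mixing when oscillations come and go; the masked variant adds a
known sinusoid (the mask) before sifting and subtracts it afterwards,
averaging over four mask phases (0, 90, 180, 270 deg) so the mask itself
cancels. One IMF is produced per mask frequency, fastest first; the
defaults (350, 200, 70, 40, 30, 7, 1) Hz at a 1250 Hz record place theta
at IMF6, slow gamma at IMF4, mid gamma at IMF3 and fast gamma at IMF2.

The residual at each level is defined by subtraction, so the IMFs plus
final residual reconstruct the input exactly (completeness holds to
floating-point error by construction).

Instantaneous attributes use the Normalized-Hilbert Transform: the IMF is
iteratively divided by the spline envelope of its absolute extrema until
it has unit amplitude, the phase comes from the analytic signal of that
unit-amplitude carrier, and the amplitude is the accumulated envelope.
Phases follow the trough convention throughout: 0/360 deg are troughs,
180 deg is the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, PchipInterpolator

from .types import ContinuousSignal

DEFAULT_MASKS_HZ = (350.0, 200.0, 70.0, 40.0, 30.0, 7.0, 1.0)
MASK_PHASES = (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi)


@dataclass
class ImfSet:
    """Ordered IMFs (index 0 = fastest) plus residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    fs: float
    masks_hz: tuple[float, ...]

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residual


@dataclass
class InstAttributes:
    """Instantaneous amplitude (a.u.), frequency (Hz) and phase (rad).

    ``phase`` is wrapped to [0, 2*pi) in the trough convention (0 at the
    trough, pi at the peak).
    """

    amplitude: np.ndarray
    frequency: np.ndarray
    phase: np.ndarray
    fs: float


@dataclass
class Comodulogram:
    """Mean amplitude per (theta-phase bin x IMF) plus a theta-frequency row."""

    amplitude: np.ndarray  # shape (n_imfs, n_bins)
    theta_frequency: np.ndarray  # shape (n_bins,)
    bin_edges_deg: np.ndarray  # length n_bins + 1
    theta_imf_index: int


# ---------------------------------------------------------------- sifting

def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus -> midpoints)."""
    maxima, _ = sps.find_peaks(x)
    minima, _ = sps.find_peaks(-x)
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, edges mirrored.

    The two outermost extrema are reflected beyond each end so the spline
    is anchored outside the record, the standard remedy for envelope
    divergence at the edges.
    """
    n = len(x)
    if len(idx) < 2:
        raise ValueError("need at least 2 extrema for an envelope")
    k = min(2, len(idx))
    left_i = -idx[:k][::-1]
    left_v = x[idx[:k][::-1]]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = x[idx[-k:][::-1]]
    xi = np.concatenate((left_i, idx, right_i))
    vi = np.concatenate((left_v, x[idx], right_v))
    keep = np.concatenate(([True], np.diff(xi) > 0))
    spline = CubicSpline(xi[keep], vi[keep])
    return spline(np.arange(n))


def _sift_one(x: np.ndarray, max_iters: int = 15, rsd_tol: float = 1e-8) -> np.ndarray:
    """Extract the fastest local mode by envelope-mean subtraction.

    Stops after ``max_iters`` inner iterations or when the relative
    squared deviation of the envelope mean drops below ``rsd_tol``,
    whichever comes first.
    """
    h = x.astype(float).copy()
    for _ in range(max_iters):
        maxima, minima = _extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            break
        mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
        denom = np.sum(h ** 2)
        if denom == 0:
            break
        rsd = np.sum(mean_env ** 2) / denom
        h = h - mean_env
        if rsd < rsd_tol:
            break
    return h


def masked_sift(
    sig: ContinuousSignal,
    mask_freqs: tuple[float, ...] = DEFAULT_MASKS_HZ,
    mask_amp_factor: float = 2.0,
) -> ImfSet:
    """Masked EMD: one IMF per mask frequency, fastest first.

    At each level the mask amplitude is ``mask_amp_factor`` times the
    standard deviation of the current residual — large enough to dominate
    the extrema (preventing mode mixing) without swamping the recovered
    component, which is obtained by subtracting the mask and averaging
    over the four mask phases.
    """
    if any(b >= a for a, b in zip(mask_freqs, mask_freqs[1:])):
        raise ValueError("mask frequencies must be strictly decreasing")
    x = np.asarray(sig.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    t = np.arange(len(x)) / sig.fs
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for f in mask_freqs:
        amp = mask_amp_factor * np.std(residual)
        if amp == 0:
            imfs.append(np.zeros_like(residual))
            continue
        acc = np.zeros_like(residual)
        for ph in MASK_PHASES:
            mask = amp * np.cos(2 * np.pi * f * t + ph)
            acc += _sift_one(residual + mask) - mask
        imf = acc / len(MASK_PHASES)
        imfs.append(imf)
        residual = residual - imf
    return ImfSet(imfs=imfs, residual=residual, fs=sig.fs, masks_hz=tuple(mask_freqs))


# ------------------------------------------------------- instantaneous nht

def _abs_envelope(x: np.ndarray) -> np.ndarray:
    """Spline through the maxima of |x|, floored so that division by the
    envelope stays bounded where the component is locally silent."""
    peak = np.max(np.abs(x)) if len(x) else 0.0
    idx, _ = sps.find_peaks(np.abs(x))
    if len(idx) < 2:
        return np.full(len(x), max(peak, 1e-12))
    n = len(x)
    ax = np.abs(x)
    k = min(2, len(idx))
    xi = np.concatenate((-idx[:k][::-1], idx, 2 * (n - 1) - idx[-k:][::-1]))
    vi = np.concatenate((ax[idx[:k][::-1]], ax[idx], ax[idx[-k:][::-1]]))
    keep = np.concatenate(([True], np.diff(xi) > 0))
    # PCHIP is shape-preserving: no overshoot between extrema, so the
    # envelope stays positive and bounded where cubic splines would spike
    env = PchipInterpolator(xi[keep], vi[keep])(np.arange(n))
    return np.maximum(env, 1e-3 * peak)


def hilbert_nht(imf: np.ndarray, fs: float, max_norm_iters: int = 5) -> InstAttributes:
    """Normalized-Hilbert instantaneous amplitude, frequency and phase.

    The IMF is repeatedly divided by the spline envelope of |IMF| extrema
    until its magnitude is within 1e-3 of unity; the phase is then the
    angle of the analytic signal of this unit carrier (shifted by 180 deg
    into the trough convention), and the instantaneous frequency is the
    phase derivative scaled to Hz and median-smoothed over 3 samples.
    """
    x = np.asarray(imf, dtype=float)
    n = len(x)
    if n == 0 or np.allclose(x, 0):
        nanv = np.full(n, np.nan)
        return InstAttributes(np.zeros(n), nanv, nanv, fs)
    carrier = x.copy()
    amplitude = np.ones(n)
    for _ in range(max_norm_iters):
        env = _abs_envelope(carrier)
        amplitude *= env
        carrier = carrier / env
        if np.max(np.abs(carrier)) <= 1 + 1e-3:
            break
    carrier = np.clip(carrier, -1.0, 1.0)
    analytic = sps.hilbert(carrier)
    # angle(analytic)=0 at the waveform peak; add pi so troughs sit at 0
    phase_unwrapped = np.unwrap(np.angle(analytic)) + np.pi
    freq = np.gradient(phase_unwrapped) * fs / (2 * np.pi)
    freq = sps.medfilt(freq, kernel_size=3)
    return InstAttributes(
        amplitude=amplitude,
        frequency=freq,
        phase=phase_unwrapped % (2 * np.pi),
        fs=fs,
    )


def frequency_transform(imfset: ImfSet) -> list[InstAttributes]:
    """NHT attributes for every IMF of a decomposition."""
    return [hilbert_nht(imf, imfset.fs) for imf in imfset.imfs]


# --------------------------------------------------------------- summaries

def _epoch_mask(
    n: int, fs: float, epochs: list[tuple[float, float]], trim_s: float = 0.0
) -> np.ndarray:
    """Sample mask for epochs, optionally shrunk by ``trim_s`` per edge.

    Trimming discards the samples nearest the epoch boundaries, where
    sifting and the Hilbert transform are least reliable.
    """
    mask = np.zeros(n, dtype=bool)
    for a, b in epochs:
        if b - a <= 2 * trim_s:
            continue
        mask[max(int((a + trim_s) * fs), 0) : min(int((b - trim_s) * fs), n)] = True
    return mask


def imf_summary(
    attrs: list[InstAttributes],
    epochs: list[tuple[float, float]],
    exclude_imf1: bool = True,
    density_grid: np.ndarray | None = None,
) -> dict:
    """Per-IMF amplitude-weighted mean frequency and frequency PDF.

    IMF1 is excluded from summaries by default since in recordings it is
    dominated by noise. Mean instantaneous frequency is amplitude-weighted
    over the supplied (movement) epochs.
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    if not attrs:
        raise ValueError("no attributes supplied")
    n = len(attrs[0].amplitude)
    fs = attrs[0].fs
    mask = _epoch_mask(n, fs, epochs)
    if not mask.any():
        raise ValueError("epochs do not overlap the record")
    if density_grid is None:
        density_grid = np.linspace(0, fs / 2, 256)
    means: dict[int, float] = {}
    pdfs: dict[int, np.ndarray] = {}
    for i, at in enumerate(attrs):
        if exclude_imf1 and i == 0:
            continue
        f = at.frequency[mask]
        a = at.amplitude[mask]
        ok = np.isfinite(f)
        f, a = f[ok], a[ok]
        if len(f) == 0 or np.sum(a) == 0:
            means[i + 1] = float("nan")
            pdfs[i + 1] = np.zeros(len(density_grid) - 1)
            continue
        means[i + 1] = float(np.sum(f * a) / np.sum(a))
        hist, _ = np.histogram(f, bins=density_grid, weights=a, density=True)
        pdfs[i + 1] = hist
    return {"mean_freq_hz": means, "freq_pdf": pdfs, "pdf_bins_hz": density_grid}


def pac_comodulogram(
    attrs: list[InstAttributes],
    theta_imf_index: int,
    epochs: list[tuple[float, float]],
    n_phase_bins: int = 24,
    edge_trim_s: float = 0.5,
) -> Comodulogram:
    """Theta-phase-binned mean amplitudes (phase-amplitude coupling).

    For each of ``n_phase_bins`` equal bins of the theta IMF's
    instantaneous phase (trough convention), the mean instantaneous
    amplitude of every IMF and the mean theta instantaneous frequency are
    computed over the supplied movement epochs. ``theta_imf_index`` is
    zero-based into ``attrs``.
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    theta = attrs[theta_imf_index]
    n = len(theta.phase)
    mask = _epoch_mask(n, theta.fs, epochs, trim_s=edge_trim_s)
    phase = theta.phase[mask]
    if len(phase) == 0:
        raise ValueError("epochs do not overlap the record")
    # number of theta cycles covered, from accumulated phase advance
    dur = mask.sum() / theta.fs
    f_ok = theta.frequency[mask]
    n_cycles = np.nanmedian(f_ok) * dur
    if not np.isfinite(n_cycles) or n_cycles < 10:
        raise ValueError("fewer than 10 theta cycles in the supplied epochs")
    edges = np.linspace(0, 2 * np.pi, n_phase_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_phase_bins - 1)
    amp = np.zeros((len(attrs), n_phase_bins))
    tf = np.zeros(n_phase_bins)
    for b in range(n_phase_bins):
        sel = which == b
        if not sel.any():
            amp[:, b] = np.nan
            tf[b] = np.nan
            continue
        for i, at in enumerate(attrs):
            amp[i, b] = np.mean(at.amplitude[mask][sel])
        tf[b] = np.nanmean(theta.frequency[mask][sel])
    return Comodulogram(
        amplitude=amp,
        theta_frequency=tf,
        bin_edges_deg=np.rad2deg(edges),
        theta_imf_index=theta_imf_index,
    )


def pac_peak_phase_deg(com: Comodulogram, imf_index: int) -> float:
    """Center of the phase bin with maximal amplitude for one IMF row."""
    row = com.amplitude[imf_index]
    b = int(np.nanargmax(row))
    return float(0.5 * (com.bin_edges_deg[b] + com.bin_edges_deg[b + 1]))
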
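"""Theta-epoch detection, theta peak frequency, speed binning and ripples.

Theta epochs are defined by the RMS power ratio of theta (5-12 Hz) over
delta (2-4 Hz) exceeding 2 in non-overlapping 2-s windows; adjacent
supra-threshold windows merge into contiguous epochs. The theta peak is
read from a cubic-spline-interpolated Welch spectrum (Hanning window,
2048-point FFT, ~0.61 Hz bin spacing at 1250 Hz). Ripples are 130-230 Hz
events whose sliding-window RMS envelope exceeds mean + 3 SD; boundaries
extend to the envelope's return to mean + 1 SD, and per-event frequency
comes from trough-to-trough intervals rather than a spectral peak, which
is robust for 4-10-cycle events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .signal_io import bandpass
from .types import ContinuousSignal

THETA_BAND = (5.0, 12.0)
DELTA_BAND = (2.0, 4.0)
RIPPLE_BAND = (130.0, 230.0)


@dataclass
class RippleEvent:
    start_s: float
    end_s: float
    peak_s: float
    ripple_freq: float  # Hz, from intra-event cycle intervals
    duration_ms: float
    n_cycles: int


def detect_theta_epochs(
    sig: ContinuousSignal,
    window_s: float = 2.0,
    ratio_threshold: float = 2.0,
) -> list[tuple[float, float]]:
    """Theta epochs from the theta/delta RMS ratio in fixed windows.

    Returns sorted, non-overlapping (start_s, end_s) intervals relative to
    the signal's own time base.
    """
    n_win = int(round(window_s * sig.fs))
    if n_win > len(sig.samples):
        raise ValueError("signal shorter than one window")
    theta = bandpass(sig, *THETA_BAND).samples
    delta = bandpass(sig, *DELTA_BAND).samples
    n_full = len(sig.samples) // n_win
    epochs: list[tuple[float, float]] = []
    for k in range(n_full):
        sl = slice(k * n_win, (k + 1) * n_win)
        rms_t = np.sqrt(np.mean(theta[sl] ** 2))
        rms_d = np.sqrt(np.mean(delta[sl] ** 2))
        if rms_d == 0 and rms_t == 0:
            continue
        ratio = np.inf if rms_d == 0 else rms_t / rms_d
        if ratio > ratio_threshold:
            start = sig.t0 + k * window_s
            if epochs and np.isclose(epochs[-1][1], start):
                epochs[-1] = (epochs[-1][0], start + window_s)
            else:
                epochs.append((start, start + window_s))
    return epochs


def theta_peak_frequency(
    sig: ContinuousSignal,
    epochs: list[tuple[float, float]],
    nfft: int = 2048,
    band: tuple[float, float] = THETA_BAND,
) -> float:
    """Peak frequency of the spline-interpolated theta-band Welch spectrum."""
    if not epochs:
        raise ValueError("no epochs supplied")
    segs = []
    for a, b in epochs:
        i0 = int(round((a - sig.t0) * sig.fs))
        i1 = int(round((b - sig.t0) * sig.fs))
        segs.append(sig.samples[i0:i1])
    total = sum(len(s) for s in segs)
    if total < nfft:
        raise ValueError("epochs shorter than one FFT window")
    psds = []
    for s in segs:
        if len(s) < nfft:
            continue
        f, p = sps.welch(s, fs=sig.fs, window="hann", nperseg=nfft, noverlap=nfft // 2)
        psds.append(p)
    if not psds:
        # epochs individually short but jointly long enough: concatenate
        f, p = sps.welch(
            np.concatenate(segs), fs=sig.fs, window="hann", nperseg=nfft
        )
        psds = [p]
    psd = np.mean(psds, axis=0)
    # include one bin beyond each band edge so the spline is anchored and
    # never extrapolates inside the searched range
    in_band = (f >= band[0] - 2 * (f[1] - f[0])) & (f <= band[1] + 2 * (f[1] - f[0]))
    spline = CubicSpline(f[in_band], psd[in_band])
    fine = np.linspace(band[0], band[1], 2001)
    return float(fine[np.argmax(spline(fine))])


SPEED_BINS = {"4-6": (4.0, 6.0), "6-10": (6.0, 10.0)}  # cm/s


def bin_theta_by_speed(
    peak_freqs: np.ndarray,
    mean_speeds: np.ndarray,
    bins: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Average per-epoch theta peaks into running-speed bins.

    Default bins are low (4-6 cm/s) and high (6-10 cm/s) speeds; epochs
    outside every bin are dropped. Empty bins are simply absent from the
    returned mapping.
    """
    bins = SPEED_BINS if bins is None else bins
    peak_freqs = np.asarray(peak_freqs, dtype=float)
    mean_speeds = np.asarray(mean_speeds, dtype=float)
    out: dict[str, float] = {}
    for label, (lo, hi) in bins.items():
        sel = (mean_speeds >= lo) & (mean_speeds < hi)
        if sel.any():
            out[label] = float(np.mean(peak_freqs[sel]))
    return out


def detect_ripples(
    sig: ContinuousSignal,
    epochs: list[tuple[float, float]] | None = None,
    threshold_sd: float = 3.0,
    boundary_sd: float = 1.0,
    envelope_window_s: float = 0.010,
    min_duration_s: float = 0.020,
    merge_gap_s: float = 0.020,
) -> list[RippleEvent]:
    """Detect 130-230 Hz ripple events by an RMS-envelope threshold.

    The envelope statistics (mean, SD) are computed over ``epochs`` when
    given (typically rest periods), else over the whole record. Events are
    where the envelope exceeds mean + ``threshold_sd``*SD, with boundaries
    extended outward to the crossing of mean + ``boundary_sd``*SD. Events
    shorter than ``min_duration_s`` are discarded; events separated by
    less than ``merge_gap_s`` are merged.
    """
    if sig.fs < 2 * RIPPLE_BAND[1]:
        raise ValueError("sampling rate too low for the 130-230 Hz band")
    filt = bandpass(sig, *RIPPLE_BAND).samples
    n_env = max(int(round(envelope_window_s * sig.fs)), 1)
    env = np.sqrt(uniform_filter1d(filt ** 2, n_env))

    if epochs is not None:
        mask = np.zeros(len(env), dtype=bool)
        for a, b in epochs:
            i0 = max(int(round((a - sig.t0) * sig.fs)), 0)
            i1 = min(int(round((b - sig.t0) * sig.fs)), len(env))
            mask[i0:i1] = True
        if not mask.any():
            return []
        ref = env[mask]
    else:
        ref = env
    mu, sd = float(np.mean(ref)), float(np.std(ref))
    if sd == 0:
        return []
    hi_th, lo_th = mu + threshold_sd * sd, mu + boundary_sd * sd

    above = env > hi_th
    if not above.any():
        return []
    # core intervals from the high threshold
    starts = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8)))) == 1)
    ends = np.flatnonzero(np.diff(np.concatenate((above.view(np.int8), [0]))) == -1)

    # merge nearby cores, then require the minimum duration of the core
    # itself (before boundary extension) so brief noise crossings never
    # qualify by extension alone
    cores: list[list[int]] = []
    gap = int(merge_gap_s * sig.fs)
    for s, e in zip(starts, ends):
        if cores and s <= cores[-1][1] + gap:
            cores[-1][1] = max(cores[-1][1], int(e))
        else:
            cores.append([int(s), int(e)])
    min_n = int(min_duration_s * sig.fs)
    cores = [c for c in cores if c[1] - c[0] + 1 >= min_n]

    below = env <= lo_th
    events: list[list[int]] = []
    for s, e in cores:
        # extend to the boundary threshold, then pull each side back by half
        # the envelope window: the rms smoothing spreads the event's support
        # by that much on either side
        left = np.flatnonzero(below[:s])
        s_ext = int(left[-1]) + 1 if len(left) else 0
        right = np.flatnonzero(below[e:])
        e_ext = e + int(right[0]) - 1 if len(right) else len(env) - 1
        s_ext = min(s_ext + n_env // 2, int(s))
        e_ext = max(e_ext - n_env // 2, int(e))
        if events and s_ext <= events[-1][1] + gap:
            events[-1][1] = max(events[-1][1], e_ext)
        else:
            events.append([s_ext, e_ext])

    out: list[RippleEvent] = []
    for s, e in events:
        dur = (e - s + 1) / sig.fs
        seg = filt[s : e + 1]
        troughs, _ = sps.find_peaks(-seg)
        peak_i = s + int(np.argmax(env[s : e + 1]))
        if len(troughs) >= 2:
            cycle_len = (troughs[-1] - troughs[0]) / (len(troughs) - 1) / sig.fs
            freq = 1.0 / cycle_len
            n_cycles = len(troughs) - 1
        else:
            freq = float("nan")
            n_cycles = 0
        out.append(
            RippleEvent(
                start_s=sig.t0 + s / sig.fs,
                end_s=sig.t0 + (e + 1) / sig.fs,
                peak_s=sig.t0 + peak_i / sig.fs,
                ripple_freq=freq,
                duration_ms=dur * 1000.0,
                n_cycles=n_cycles,
            )
        )
    return out
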
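"""Signal preprocessing and file round-trips.

Preprocessing mirrors the acquisition chain used for the recordings: DC
shifts removed with a 0.3 s sliding-window moving average, downsampling
to 1.25 kHz with anti-alias filtering, and zero-phase band-pass filtering
(forward-backward 4th-order Butterworth) so spike/phase timing is never
shifted by the filter.

On disk, signals are a ``.npy`` array payload next to a JSON sidecar
carrying fs/t0/channel_id; events and spike trains are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import EVENT_TYPES, ContinuousSignal, SpikeTrain

DEFAULT_TARGET_FS = 1250.0  # Hz, the analysis rate for wide-band recordings


# ---------------------------------------------------------------- filtering

def remove_dc(sig: ContinuousSignal, window_s: float = 0.3) -> ContinuousSignal:
    """Remove slow DC shifts with a centered sliding-window mean.

    Each sample has the mean of the surrounding ``window_s`` seconds
    subtracted; at the edges the window shrinks symmetrically so the
    output keeps the input length.
    """
    n = len(sig.samples)
    win = int(round(window_s * sig.fs))
    if win < 3:
        raise ValueError("window must span at least 3 samples")
    if win > n:
        raise ValueError("DC window longer than the signal")
    half = win // 2
    # cumulative-sum sliding mean with shrunken edge windows
    c = np.concatenate(([0.0], np.cumsum(sig.samples)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    means = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    return ContinuousSignal(sig.samples - means, sig.fs, sig.t0, sig.channel_id)


def downsample(
    sig: ContinuousSignal, target_fs: float = DEFAULT_TARGET_FS
) -> ContinuousSignal:
    """Anti-alias low-pass at 0.4*target_fs, then decimate/resample.

    Integer rate ratios use polyphase decimation; non-integer ratios fall
    back to Fourier resampling after the same anti-alias filter.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > sig.fs:
        raise ValueError("target_fs exceeds the input rate")
    if target_fs == sig.fs:
        return ContinuousSignal(sig.samples.copy(), sig.fs, sig.t0, sig.channel_id)
    sos = sps.butter(8, 0.4 * target_fs, btype="low", fs=sig.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.samples)
    ratio = sig.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:: int(round(ratio))]
    else:
        n_out = int(round(len(sig.samples) * target_fs / sig.fs))
        out = sps.resample(filtered, n_out)
    return ContinuousSignal(out, target_fs, sig.t0, sig.channel_id)


def bandpass(sig: ContinuousSignal, lo: float, hi: float, order: int = 4) -> ContinuousSignal:
    """Zero-phase band-pass (forward-backward Butterworth)."""
    nyq = sig.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz invalid for fs={sig.fs} Hz")
    sos = sps.butter(order, [lo, hi], btype="band", fs=sig.fs, output="sos")
    return ContinuousSignal(
        sps.sosfiltfilt(sos, sig.samples), sig.fs, sig.t0, sig.channel_id
    )


# ------------------------------------------------------------------- files

def write_signal(sig: ContinuousSignal, path: str | Path) -> None:
    """Write array payload (.npy) plus JSON sidecar (.json)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), sig.samples)
    meta = {"fs": sig.fs, "t0": sig.t0, "channel_id": sig.channel_id}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_signal(path: str | Path) -> ContinuousSignal:
    path = Path(path)
    samples = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ContinuousSignal(samples, meta["fs"], meta["t0"], meta["channel_id"])


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False, float_format="%.5f")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "event_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"event file missing columns {required - set(df.columns)}")
    bad = set(df["event_type"]) - EVENT_TYPES
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    for etype, grp in df.groupby("event_type"):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            row = grp.index[np.argmax(np.diff(t) < 0) + 1]
            raise ValueError(f"non-monotonic {etype} times at row {row}")
    return df


def write_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    """Spike trains as CSV (unit_id, time_s) at 1e-5 s precision."""
    rows = [
        (tr.unit_id, f"{t:.5f}") for tr in trains for t in tr.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    if list(df.columns) != ["unit_id", "time_s"]:
        raise ValueError("spike CSV must have header unit_id,time_s")
    out = []
    for uid, grp in df.groupby("unit_id", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            row = grp.index[int(np.argmax(np.diff(t) < 0)) + 1]
            raise ValueError(f"non-monotonic spike times for {uid} at row {row}")
        out.append(SpikeTrain(t, unit_id=str(uid)))
    return out
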
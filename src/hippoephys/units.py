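"""Unit quality filtering, complex-spike classification and rate maps.

Complex-spike (CS) bursting pyramidal cells are recognized from the spike
time autocorrelogram: a prominent peak between 3 and 8 ms followed by a
relatively fast decay. "Prominent" and "fast" are quantified here (the
field's verbal criteria leave the thresholds open): the 1-ms-binned
autocorrelogram's argmax over 2-20 ms must fall in [3, 8] ms, the mean
count at 3-8 ms must be at least twice the 40-50 ms baseline, and the
mean count at 12-20 ms must have dropped to half the 3-8 ms peak. All
three thresholds are configurable.

Rate maps follow the virtual-corridor protocol: each run is split into 15
equal spatial bins followed by three 1-s temporal bins covering the
reward lock at the corridor end; rates are occupancy-based (spikes per
second actually spent in the bin) since running speed varies along the
corridor. The first trial of a session is excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SessionBehavior, SpikeTrain

N_SPATIAL_BINS = 15
N_TEMPORAL_BINS = 3
N_BINS = N_SPATIAL_BINS + N_TEMPORAL_BINS


@dataclass
class Autocorrelogram:
    counts: np.ndarray  # pairs per positive-lag bin
    bin_ms: float
    max_lag_ms: float

    @property
    def lags_ms(self) -> np.ndarray:
        """Bin centers in ms."""
        return (np.arange(len(self.counts)) + 0.5) * self.bin_ms


@dataclass
class UnitMetrics:
    unit_id: str
    n_spikes: int
    mean_rate_hz: float
    is_cs: bool | None = None  # None = indeterminate
    rate_rest_hz: float | None = None
    rate_move_hz: float | None = None


@dataclass
class RateMap18:
    """Per-trial and trial-averaged rates over 15 spatial + 3 temporal bins."""

    per_trial: np.ndarray  # (n_trials, 18), NaN where a bin is missing
    occupancy: np.ndarray  # (n_trials, 18) seconds
    counts: np.ndarray     # (n_trials, 18) spike counts
    trial_ids: np.ndarray

    @property
    def trial_mean(self) -> np.ndarray:
        return np.nanmean(self.per_trial, axis=0)


# ----------------------------------------------------------------- quality

def qc_filter(
    trains: list[SpikeTrain], session_duration_s: float, min_rate_hz: float = 0.1
) -> tuple[list[SpikeTrain], list[str]]:
    """Drop units whose overall rate is below ``min_rate_hz`` (strict <).

    Returns the retained trains and the ids of the removed units.
    """
    if session_duration_s <= 0:
        raise ValueError("session duration must be positive")
    kept, removed = [], []
    for tr in trains:
        rate = len(tr) / session_duration_s
        if rate < min_rate_hz:
            removed.append(tr.unit_id)
        else:
            kept.append(tr)
    return kept, removed


# --------------------------------------------------------- autocorrelogram

def autocorrelogram(
    train: SpikeTrain, bin_ms: float = 1.0, max_lag_ms: float = 50.0
) -> Autocorrelogram:
    """Histogram of ordered spike-time differences in (0, max_lag_ms].

    Only positive lags are used (the construction is symmetric) and
    zero-lag self-pairs are excluded.
    """
    t = train.times
    if len(t) < 2:
        raise ValueError("autocorrelogram needs at least 2 spikes")
    max_lag = max_lag_ms / 1000.0
    n_bins = int(round(max_lag_ms / bin_ms))
    counts = np.zeros(n_bins)
    # sorted times: sliding window of partners within max_lag
    j = 0
    for i in range(len(t)):
        j = max(j, i + 1)
        while j < len(t) and t[j] - t[i] <= max_lag:
            j += 1
        lags = t[i + 1 : j] - t[i]
        lags = lags[lags > 0]
        if len(lags):
            idx = np.minimum((lags * 1000.0 / bin_ms).astype(int), n_bins - 1)
            np.add.at(counts, idx, 1)
    return Autocorrelogram(counts=counts, bin_ms=bin_ms, max_lag_ms=max_lag_ms)


def classify_cs(
    acg: Autocorrelogram,
    peak_window_ms: tuple[float, float] = (3.0, 8.0),
    search_window_ms: tuple[float, float] = (2.0, 20.0),
    prominence_ratio: float = 2.0,
    decay_ratio: float = 0.5,
    min_pairs: int = 50,
) -> bool | None:
    """Flag complex-spike bursting from the autocorrelogram shape.

    Returns ``None`` (indeterminate) with fewer than ``min_pairs`` pairs.
    CS requires (a) the argmax over ``search_window_ms`` to fall inside
    ``peak_window_ms``, (b) the 3-8 ms mean to exceed ``prominence_ratio``
    times the 40-50 ms baseline, and (c) the 12-20 ms mean to have fallen
    below ``decay_ratio`` times the 3-8 ms peak.
    """
    if acg.counts.sum() < min_pairs:
        return None
    lags = acg.lags_ms

    def window_mean(lo: float, hi: float) -> float:
        sel = (lags >= lo) & (lags < hi)
        return float(np.mean(acg.counts[sel])) if sel.any() else 0.0

    search = (lags >= search_window_ms[0]) & (lags < search_window_ms[1])
    if not search.any():
        return None
    argmax_lag = lags[search][int(np.argmax(acg.counts[search]))]
    in_peak = peak_window_ms[0] <= argmax_lag <= peak_window_ms[1]

    peak_mean = window_mean(*peak_window_ms)
    baseline = window_mean(40.0, 50.0)
    prominent = peak_mean >= prominence_ratio * max(baseline, 1e-12)

    sel_peak = (lags >= peak_window_ms[0]) & (lags < peak_window_ms[1])
    peak_count = float(np.max(acg.counts[sel_peak])) if sel_peak.any() else 0.0
    decayed = window_mean(12.0, 20.0) <= decay_ratio * peak_count

    return bool(in_peak and prominent and decayed)


def acg_mode_ms(acg: Autocorrelogram) -> float:
    """Lag (ms) of the autocorrelogram's maximum count."""
    return float(acg.lags_ms[int(np.argmax(acg.counts))])


def putative_pc_filter(
    mean_rate_hz: float,
    spike_width_ms: float,
    acg_mode_ms_value: float,
    max_rate_hz: float = 3.0,
    min_width_ms: float = 0.5,
    max_acg_mode_ms: float = 10.0,
) -> bool:
    """Putative pyramidal cell: low rate, wide spike, early-burst ACG.

    True iff rate < 3 Hz, spike width at 90% of peak amplitude > 0.5 ms,
    and the autocorrelogram mode < 10 ms.
    """
    return bool(
        mean_rate_hz < max_rate_hz
        and spike_width_ms > min_width_ms
        and acg_mode_ms_value < max_acg_mode_ms
    )


# --------------------------------------------------------------- rate maps

def session_rate_map(
    train: SpikeTrain,
    behavior: SessionBehavior,
    exclude_first_trial: bool = True,
) -> RateMap18:
    """Spikes per second over 15 spatial + 3 temporal (1-s reward) bins.

    Spatial bins cover the run from corridor start to end; the three 1-s
    temporal bins start at the reward lock. Trials without a reward lock
    get NaN temporal bins. Occupancy comes from the behavior trace's
    sample spacing.
    """
    trials = behavior.trials
    if exclude_first_trial:
        trials = trials.iloc[1:]
    if len(trials) == 0:
        raise ValueError("no trials left after exclusion")
    dt = float(np.median(np.diff(behavior.t)))
    L = behavior.corridor_length
    n_tr = len(trials)
    occ = np.zeros((n_tr, N_BINS))
    cnt = np.zeros((n_tr, N_BINS))
    for row_i, (_, tr) in enumerate(trials.iterrows()):
        run_sel = (behavior.t >= tr.start_s) & (behavior.t < tr.lock_start_s)
        pos = behavior.position[run_sel]
        sbin = np.clip((pos / L * N_SPATIAL_BINS).astype(int), 0, N_SPATIAL_BINS - 1)
        np.add.at(occ[row_i], sbin, dt)
        sp_sel = (train.times >= tr.start_s) & (train.times < tr.lock_start_s)
        sp_pos = np.interp(train.times[sp_sel], behavior.t, behavior.position)
        sp_bin = np.clip((sp_pos / L * N_SPATIAL_BINS).astype(int), 0, N_SPATIAL_BINS - 1)
        np.add.at(cnt[row_i], sp_bin, 1)
        has_lock = np.isfinite(tr.lock_start_s) and np.isfinite(tr.lock_end_s)
        for k in range(N_TEMPORAL_BINS):
            b = N_SPATIAL_BINS + k
            if not has_lock:
                occ[row_i, b] = np.nan
                cnt[row_i, b] = np.nan
                continue
            a0 = tr.lock_start_s + k
            a1 = min(a0 + 1.0, tr.lock_end_s)
            occ[row_i, b] = max(a1 - a0, 0.0)
            cnt[row_i, b] = np.sum((train.times >= a0) & (train.times < a1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occ > 0, cnt / occ, np.nan)
    return RateMap18(
        per_trial=rates,
        occupancy=occ,
        counts=cnt,
        trial_ids=trials["trial"].to_numpy(),
    )


# -------------------------------------------------------------- state rates

def state_rates(
    train: SpikeTrain,
    move_intervals: list[tuple[float, float]],
    rest_intervals: list[tuple[float, float]],
) -> tuple[float, float]:
    """(rate_rest, rate_move) in Hz over labeled state epochs."""

    def _rate(intervals: list[tuple[float, float]]) -> float:
        total = sum(b - a for a, b in intervals)
        if total <= 0:
            return float("nan")
        n = sum(
            int(np.sum((train.times >= a) & (train.times < b))) for a, b in intervals
        )
        return n / total

    return _rate(rest_intervals), _rate(move_intervals)
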
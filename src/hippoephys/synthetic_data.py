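"""Synthetic LFP, spike-train and behavior generator with ground truth.

The generator emulates the statistical structure the analyses assume:

* theta (5-12 Hz) whose amplitude is high during movement and low at rest,
* a nested gamma oscillation whose amplitude is modulated at a set theta
  phase (phase-amplitude coupling with controllable depth),
* sharp-wave-ripple-like bursts during rest,
* 1/f ("pink") background noise,
* spike trains that are inhomogeneous Poisson processes with von Mises
  theta-phase locking, Gaussian place fields on a linearized virtual
  corridor, and complex-spike bursting,
* jet-ball style corridor behavior: repeated runs down a virtual corridor,
  each followed by a 3-s reward lock and a teleport back to the start.

Every generated object is accompanied by a :class:`GroundTruth` record so
analyses can be validated by parameter recovery. Theta phase in the ground
truth is the analytic phase of the theta oscillator (trough = 0 deg /
360 deg, peak = 180 deg), never re-estimated from the signal, so recovery
tests stay independent of the analyzers they check.

Movement and rest alternate as labeled states (default 10 s move /
10 s rest) rather than via a speed threshold; the true state intervals are
part of the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from .types import ContinuousSignal, SessionBehavior, SpikeTrain


# ----------------------------------------------------------------- configs

@dataclass
class LfpConfig:
    """Parameters of the synthetic LFP. Amplitudes are a.u."""

    duration_s: float = 120.0
    fs: float = 1250.0
    theta_freq: float = 7.0          # Hz, must lie in the 5-12 Hz theta band
    theta_amp_move: float = 1.0
    theta_amp_rest: float = 0.1
    delta_freq: float = 3.0          # Hz, large irregular activity at rest
    delta_amp_rest: float = 0.6
    delta_amp_move: float = 0.05
    gamma_freq: float = 60.0         # Hz (mid-gamma)
    gamma_amp: float = 0.3
    pac_phase_deg: float = 180.0     # theta phase of max gamma amplitude
    pac_depth: float = 0.8           # 0 = no coupling, 1 = full modulation
    ripple_freq: float = 150.0       # Hz
    ripple_rate_rest: float = 0.2    # events/s during rest
    ripple_duration_ms: float = 60.0
    ripple_amp: float = 1.0
    noise_exponent: float = 1.0      # 1/f slope of the background
    noise_amp: float = 0.2           # RMS of the background noise
    state_period_s: float = 10.0     # move/rest alternation half-period
    start_state: str = "move"
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (5.0 <= self.theta_freq <= 12.0):
            raise ValueError("theta_freq must lie within the 5-12 Hz band")
        if not (0.0 <= self.pac_depth <= 1.0):
            raise ValueError("pac_depth must be in [0, 1]")
        if self.fs < 4 * self.gamma_freq:
            raise ValueError("fs must be at least 4x gamma_freq")
        if self.start_state not in ("move", "rest"):
            raise ValueError("start_state must be 'move' or 'rest'")


@dataclass
class UnitConfig:
    """Parameters of one synthetic unit.

    The expected mean vector length of the spike phases is the modified
    Bessel ratio I1(kappa)/I0(kappa). Interneurons never burst.
    """

    unit_class: str = "cs_pyramidal"  # or "interneuron"
    base_rate: float = 2.0            # Hz, mean rate absent a place field
    mu_deg: float = 180.0             # preferred theta phase
    kappa: float = 1.0                # von Mises concentration
    field_center: float | None = None  # corridor fraction in [0, 1]
    field_width: float = 0.1           # Gaussian sigma, corridor fraction
    field_gain: float = 5.0            # peak rate multiplier at the center
    burst_prob: float = 0.5            # probability an event becomes a burst
    burst_isi_ms: float = 5.0
    spike_width_ms: float = 0.7        # waveform width metadata (at 90% peak)
    seed: int = 0

    def validate(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.unit_class not in ("cs_pyramidal", "interneuron"):
            raise ValueError(f"unknown unit class {self.unit_class!r}")
        if self.unit_class == "interneuron" and self.burst_prob != 0:
            raise ValueError("interneurons must have burst_prob = 0")
        if self.field_center is not None and not (0 <= self.field_center <= 1):
            raise ValueError("field_center must be a corridor fraction in [0,1]")
        if not (0 <= self.burst_prob <= 1):
            raise ValueError("burst_prob must be in [0, 1]")

    @property
    def expected_r(self) -> float:
        """Expected mean vector length I1(kappa)/I0(kappa)."""
        return float(i1(self.kappa) / i0(self.kappa))


@dataclass
class SessionConfig:
    """Virtual-corridor session layout."""

    n_trials: int = 20
    corridor_length: float = 2.0   # m
    run_speed_cms: float = 20.0    # cm/s mean running speed
    speed_jitter: float = 0.15     # fractional speed variability per trial
    lock_s: float = 3.0            # reward lock at the corridor end
    fs_behavior: float = 50.0      # Hz of the behavior traces
    units: list[UnitConfig] = field(default_factory=list)
    lfp: LfpConfig = field(default_factory=LfpConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.corridor_length <= 0:
            raise ValueError("corridor length must be positive")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if not self.units:
            raise ValueError("need at least one unit")


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    theta_phase_deg: np.ndarray | None = None   # analytic phase per sample
    fs: float | None = None
    move_intervals: list[tuple[float, float]] = field(default_factory=list)
    rest_intervals: list[tuple[float, float]] = field(default_factory=list)
    ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pac_phase_deg: float | None = None
    units: pd.DataFrame | None = None  # per-unit true rate, mu, kappa, r, field bin
    seed: int | None = None


# --------------------------------------------------------------------- lfp

def _pink_noise(n: int, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to a 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n)
    return out * (rms / np.std(out))


def _state_intervals(cfg: LfpConfig) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    move, rest = [], []
    t = 0.0
    state = cfg.start_state
    while t < cfg.duration_s:
        end = min(t + cfg.state_period_s, cfg.duration_s)
        (move if state == "move" else rest).append((t, end))
        state = "rest" if state == "move" else "move"
        t = end
    return move, rest


def _interval_mask(intervals: list[tuple[float, float]], t: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(t), dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def gen_lfp(cfg: LfpConfig) -> tuple[ContinuousSignal, GroundTruth]:
    """Generate a synthetic LFP with theta, PAC-nested gamma and ripples.

    The theta waveform is ``-cos(phase)`` so phase 0/360 deg falls on the
    troughs and 180 deg on the peak, matching the phase convention of the
    downstream trough-interpolation analysis. Gamma rides on theta during
    movement only; large irregular delta activity and ripple bursts occur
    only at rest. Movement and rest alternate as labeled states.
    """
    cfg.validate()
    move_iv, rest_iv = _state_intervals(cfg)
    return _gen_lfp_with_states(cfg, move_iv, rest_iv)


# ------------------------------------------------------------------ spikes

def gen_spike_train(
    cfg: UnitConfig,
    phase_deg: np.ndarray,
    fs: float,
    behavior: SessionBehavior | None = None,
    t0: float = 0.0,
) -> SpikeTrain:
    """Sample an inhomogeneous Poisson spike train with phase locking.

    Intensity: ``base_rate * exp(kappa*cos(phase - mu)) / I0(kappa)``
    times a Gaussian place-field gain when a field is configured. The von
    Mises factor has unit mean over uniform phase, so the long-run rate
    stays ``base_rate`` absent a field. Each event becomes a burst of 2-4
    spikes (fixed intra-burst ISI) with probability ``burst_prob``; burst
    spikes inherit the parent event's phase in expectation because the
    burst is triggered by a single parent event.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = len(phase_deg)
    if cfg.base_rate == 0 or n == 0:
        return SpikeTrain(np.empty(0), unit_id="synthetic",
                          spike_width_ms=cfg.spike_width_ms)
    t = t0 + np.arange(n) / fs
    mu = np.deg2rad(cfg.mu_deg)
    lam = cfg.base_rate * np.exp(cfg.kappa * np.cos(np.deg2rad(phase_deg) - mu)) / i0(cfg.kappa)
    if cfg.field_center is not None and behavior is not None:
        frac = np.interp(t, behavior.t, behavior.position) / behavior.corridor_length
        gain = 1.0 + (cfg.field_gain - 1.0) * np.exp(
            -((frac - cfg.field_center) ** 2) / (2 * cfg.field_width ** 2)
        )
        lam = lam * gain
    p = lam / fs
    events = t[rng.random(n) < p]

    if cfg.burst_prob > 0 and len(events):
        is_burst = rng.random(len(events)) < cfg.burst_prob
        extra_n = rng.integers(1, 4, size=len(events))  # 1-3 extra => 2-4 spikes
        isi = cfg.burst_isi_ms / 1000.0
        spikes = [events]
        for k in range(1, 4):
            sel = is_burst & (extra_n >= k)
            spikes.append(events[sel] + k * isi)
        times = np.sort(np.concatenate(spikes))
    else:
        times = events
    return SpikeTrain(times, unit_id="synthetic", spike_width_ms=cfg.spike_width_ms)


# ----------------------------------------------------------------- session

def gen_session(
    cfg: SessionConfig,
) -> tuple[ContinuousSignal, list[SpikeTrain], SessionBehavior, GroundTruth]:
    """Generate a full virtual-corridor session.

    Trials are runs 0 -> corridor_length at a per-trial jittered speed,
    each followed by a 3-s reward lock at the corridor end and a teleport
    back to the start. The LFP, behavior traces and all spike trains share
    one time base; movement states of the LFP coincide with the runs and
    rest states with the locks.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    fsb = cfg.fs_behavior
    seg_t, seg_pos, seg_speed = [], [], []
    trials, events = [], []
    move_iv, rest_iv = [], []
    t_cursor = 0.0
    for k in range(cfg.n_trials):
        speed = cfg.run_speed_cms * (1 + cfg.speed_jitter * rng.standard_normal())
        speed = max(speed, 2.0)  # cm/s floor
        run_dur = cfg.corridor_length * 100.0 / speed
        n_run = max(int(round(run_dur * fsb)), 2)
        tt = t_cursor + np.arange(n_run) / fsb
        seg_t.append(tt)
        seg_pos.append(np.linspace(0, cfg.corridor_length, n_run, endpoint=False))
        seg_speed.append(np.full(n_run, speed))
        events.append((t_cursor, "trial_start", k))
        move_iv.append((t_cursor, t_cursor + n_run / fsb))
        t_lock = t_cursor + n_run / fsb
        n_lock = int(round(cfg.lock_s * fsb))
        tt = t_lock + np.arange(n_lock) / fsb
        seg_t.append(tt)
        seg_pos.append(np.full(n_lock, cfg.corridor_length))
        seg_speed.append(np.zeros(n_lock))
        events.append((t_lock, "lock_start", k))
        events.append((t_lock, "reward", k))
        events.append((t_lock + cfg.lock_s, "lock_end", k))
        events.append((t_lock + cfg.lock_s, "teleport", k))
        rest_iv.append((t_lock, t_lock + cfg.lock_s))
        trials.append((k, t_cursor, t_lock, t_lock + cfg.lock_s))
        t_cursor = t_lock + cfg.lock_s

    behavior = SessionBehavior(
        t=np.concatenate(seg_t),
        position=np.concatenate(seg_pos),
        speed=np.concatenate(seg_speed),
        corridor_length=cfg.corridor_length,
        trials=pd.DataFrame(
            trials, columns=["trial", "start_s", "lock_start_s", "lock_end_s"]
        ),
        events=pd.DataFrame(events, columns=["time_s", "event_type", "value"]),
    )

    lfp_cfg = LfpConfig(**{**cfg.lfp.__dict__})
    lfp_cfg.duration_s = t_cursor
    lfp_cfg.seed = int(rng.integers(2 ** 31))
    # session movement/rest follows the trial structure, not the default
    # alternation
    sig, truth = _gen_lfp_with_states(lfp_cfg, move_iv, rest_iv)

    n_bins = 15
    unit_rows, trains = [], []
    for j, ucfg in enumerate(cfg.units):
        ucfg = UnitConfig(**{**ucfg.__dict__})
        ucfg.seed = int(rng.integers(2 ** 31))
        tr = gen_spike_train(ucfg, truth.theta_phase_deg, lfp_cfg.fs, behavior)
        tr.unit_id = f"u{j:03d}"
        trains.append(tr)
        field_bin = (
            int(min(ucfg.field_center * n_bins, n_bins - 1))
            if ucfg.field_center is not None
            else -1
        )
        unit_rows.append(
            {
                "unit_id": tr.unit_id,
                "unit_class": ucfg.unit_class,
                "base_rate": ucfg.base_rate,
                "mu_deg": ucfg.mu_deg,
                "kappa": ucfg.kappa,
                "expected_r": ucfg.expected_r,
                "field_bin": field_bin,
            }
        )
    truth.units = pd.DataFrame(unit_rows)
    truth.seed = cfg.seed
    return sig, trains, behavior, truth


def _gen_lfp_with_states(
    cfg: LfpConfig,
    move_iv: list[tuple[float, float]],
    rest_iv: list[tuple[float, float]],
) -> tuple[ContinuousSignal, GroundTruth]:
    """gen_lfp with externally supplied move/rest intervals."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    if n == 0:
        raise ValueError("empty duration")
    t = np.arange(n) / cfg.fs
    move_mask = _interval_mask(move_iv, t)

    phase = 2 * np.pi * cfg.theta_freq * t  # radians; trough at phase 0
    theta_amp = np.where(move_mask, cfg.theta_amp_move, cfg.theta_amp_rest)
    theta = theta_amp * -np.cos(phase)
    delta_amp = np.where(move_mask, cfg.delta_amp_move, cfg.delta_amp_rest)
    delta = delta_amp * np.cos(2 * np.pi * cfg.delta_freq * t)
    # gamma envelope peaks where the theta phase (deg) equals pac_phase_deg
    env = (1 + cfg.pac_depth * np.cos(phase - np.deg2rad(cfg.pac_phase_deg))) / (
        1 + cfg.pac_depth
    )
    gamma = cfg.gamma_amp * env * np.sin(2 * np.pi * cfg.gamma_freq * t)
    gamma[~move_mask] = 0.0
    sig = theta + delta + gamma + _pink_noise(n, cfg.noise_exponent, cfg.noise_amp, rng)

    ripple_times = []
    half = cfg.ripple_duration_ms / 2000.0
    for a, b in rest_iv:
        n_ev = rng.poisson(cfg.ripple_rate_rest * (b - a))
        for center in np.sort(rng.uniform(a + half, max(b - half, a + half), n_ev)):
            i0_, i1_ = max(int((center - half) * cfg.fs), 0), min(int((center + half) * cfg.fs), n)
            tt = t[i0_:i1_] - center
            burst = cfg.ripple_amp * np.exp(-(tt ** 2) / (2 * (half / 2) ** 2))
            sig[i0_:i1_] += burst * np.sin(2 * np.pi * cfg.ripple_freq * tt)
            ripple_times.append(center)

    truth = GroundTruth(
        theta_phase_deg=np.rad2deg(phase) % 360.0,
        fs=cfg.fs,
        move_intervals=list(move_iv),
        rest_intervals=list(rest_iv),
        ripple_times=np.asarray(ripple_times),
        pac_phase_deg=cfg.pac_phase_deg,
        seed=cfg.seed,
    )
    return ContinuousSignal(sig, cfg.fs, 0.0, "synthetic"), truth
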
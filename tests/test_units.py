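"""Unit QC, autocorrelograms, CS classification, rate maps, state rates."""

import numpy as np
import pytest

from hippoephys.synthetic_data import SessionConfig, UnitConfig, gen_session
from hippoephys.types import SpikeTrain
from hippoephys.units import (
    acg_mode_ms,
    autocorrelogram,
    classify_cs,
    putative_pc_filter,
    qc_filter,
    session_rate_map,
    state_rates,
)


class TestQcFilter:
    def test_threshold_is_strict_less_than(self):
        slow = SpikeTrain(np.linspace(0, 99, 5), "slow")       # 0.05 Hz
        at_threshold = SpikeTrain(np.linspace(0, 99, 10), "at")  # 0.1 Hz
        kept, removed = qc_filter([slow, at_threshold], 100.0)
        assert removed == ["slow"]
        assert [t.unit_id for t in kept] == ["at"]

    def test_empty_session_errors(self):
        with pytest.raises(ValueError):
            qc_filter([], 0.0)


class TestAutocorrelogram:
    def test_regular_train_has_no_short_lags(self):
        tr = SpikeTrain(np.arange(0, 10, 0.1))  # 100 ms regular
        acg = autocorrelogram(tr)
        assert acg.counts.sum() == 0  # nothing within 50 ms

    def test_burst_lag_enumeration(self):
        """3-spike bursts at 5 ms ISI: every burst contributes lags
        5, 5, 10 ms; sparse bursts add nothing else below 50 ms."""
        starts = np.arange(0, 10, 0.5)
        times = np.sort(np.concatenate([starts, starts + 0.005, starts + 0.010]))
        acg = autocorrelogram(SpikeTrain(times))
        n_bursts = len(starts)
        # floating-point lags straddle the 5/10 ms bin edges
        assert acg.counts[4:6].sum() == 2 * n_bursts
        assert acg.counts[9:11].sum() == n_bursts
        assert acg.counts.sum() == 3 * n_bursts

    def test_single_spike_errors(self):
        with pytest.raises(ValueError):
            autocorrelogram(SpikeTrain(np.array([1.0])))


class TestClassifyCs:
    def test_poisson_train_is_not_cs(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 100, 2000))  # ~20 Hz Poisson, flat acg
        assert classify_cs(autocorrelogram(SpikeTrain(times))) is False

    def test_pacemaker_8ms_fails_decay(self):
        # regular 8 ms firing: peaks at 8, 16, 24 ... no decay after the peak
        tr = SpikeTrain(np.arange(0, 4, 0.008))
        assert classify_cs(autocorrelogram(tr)) is False

    def test_bursty_synthetic_train_is_cs(self):
        rng = np.random.default_rng(1)
        events = np.sort(rng.uniform(0, 200, 400))
        extra = [events, events + 0.005, events[: len(events) // 2] + 0.010]
        tr = SpikeTrain(np.sort(np.concatenate(extra)))
        assert classify_cs(autocorrelogram(tr)) is True

    def test_insufficient_pairs_indeterminate(self):
        tr = SpikeTrain(np.array([0.0, 0.005, 0.010]))
        assert classify_cs(autocorrelogram(tr)) is None


class TestPutativePc:
    @pytest.mark.parametrize(
        "rate,width,mode,expected",
        [
            (1.0, 0.6, 5.0, True),
            (4.0, 0.6, 5.0, False),   # too fast overall
            (1.0, 0.3, 5.0, False),   # narrow spike
            (1.0, 0.6, 12.0, False),  # late acg mode
        ],
    )
    def test_criteria(self, rate, width, mode, expected):
        assert putative_pc_filter(rate, width, mode) is expected


@pytest.fixture(scope="module")
def field_session():
    cfg = SessionConfig(
        n_trials=51,
        seed=9,
        units=[
            UnitConfig(
                unit_class="cs_pyramidal", base_rate=5.0, kappa=0.0,
                field_center=0.5, field_width=0.05, field_gain=5.0,
                burst_prob=0.0, seed=1,
            ),
            UnitConfig(
                unit_class="interneuron", base_rate=5.0, kappa=0.0,
                burst_prob=0.0, seed=2,
            ),
        ],
    )
    return gen_session(cfg)


class TestRateMap:
    def test_homogeneous_unit_flat_map(self, field_session):
        _, trains, beh, _ = field_session
        rm = session_rate_map(trains[1], beh)
        se = np.sqrt(5.0 / np.nansum(rm.occupancy, axis=0))
        assert np.all(np.abs(rm.trial_mean - 5.0) < 3.5 * se)

    def test_field_at_center_maps_to_middle_bin(self, field_session):
        _, trains, beh, truth = field_session
        rm = session_rate_map(trains[0], beh)
        assert int(np.argmax(rm.trial_mean[:15])) == truth.units.field_bin.iloc[0] == 7

    def test_conservation_rate_times_occupancy(self, field_session):
        """Sum over bins of rate x occupancy equals the included spike count."""
        _, trains, beh, _ = field_session
        rm = session_rate_map(trains[0], beh)
        recon = np.nansum(rm.per_trial * rm.occupancy)
        t_first_end = beh.trials.lock_start_s.iloc[0]
        included = np.sum(
            (trains[0].times >= beh.trials.start_s.iloc[1])
            & (trains[0].times < beh.trials.lock_start_s.iloc[-1] + 3.0)
        )
        assert abs(recon - np.nansum(rm.counts)) < 1e-9
        assert np.nansum(rm.counts) <= included

    def test_first_trial_excluded_by_default(self, field_session):
        _, trains, beh, _ = field_session
        rm = session_rate_map(trains[0], beh)
        assert len(rm.trial_ids) == len(beh.trials) - 1
        assert 0 not in rm.trial_ids

    def test_no_spikes_all_zero(self, field_session):
        _, _, beh, _ = field_session
        rm = session_rate_map(SpikeTrain(np.empty(0)), beh)
        assert np.nansum(rm.per_trial) == 0


class TestStateRates:
    def test_uniform_train_equal_rates(self):
        tr = SpikeTrain(np.arange(0, 100, 0.1))
        move = [(0.0, 10.0), (20.0, 30.0)]
        rest = [(10.0, 20.0), (30.0, 40.0)]
        r_rest, r_move = state_rates(tr, move, rest)
        assert r_rest == pytest.approx(r_move, abs=0.11)

    def test_move_only_spikes(self):
        tr = SpikeTrain(np.arange(0.0, 10.0, 0.01))
        r_rest, r_move = state_rates(tr, [(0.0, 10.0)], [(10.0, 20.0)])
        assert r_rest == 0.0
        assert r_move == pytest.approx(100.0, rel=0.01)

    def test_generator_state_rates_recovered(self, default_lfp):
        from hippoephys.synthetic_data import UnitConfig, gen_spike_train

        sig, truth = default_lfp
        cfg = UnitConfig(
            unit_class="interneuron", base_rate=8.0, kappa=0.0,
            burst_prob=0.0, seed=4,
        )
        tr = gen_spike_train(cfg, truth.theta_phase_deg, truth.fs)
        r_rest, r_move = state_rates(tr, truth.move_intervals, truth.rest_intervals)
        for r in (r_rest, r_move):
            se = np.sqrt(8.0 * 50.0) / 50.0
            assert abs(r - 8.0) < 3 * se
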
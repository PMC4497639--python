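"""DIN variants: afferent integration, branch dynamics, phenotypes, tuning."""

import numpy as np
import pytest

import dinsim as ds
from dinsim.din_models import afferent_drive, din_branch, integrate_afferent_input, preset
from dinsim.errors import InvalidParameterError
from dinsim.hair_afferents import (
    ActivationTrace,
    Afferent,
    AfferentParams,
    AfferentPopulationResponse,
    SpikeTrain,
)
from dinsim.stimulus import JointAngleTrace


def _synthetic_population(dorsal_trains, ventral_trains, n_steps, dt=0.001):
    """Population response with fabricated spike trains (for integration oracles)."""
    trace = JointAngleTrace(np.zeros(n_steps), dt=dt)
    params = AfferentParams()
    afferents = []
    for side, trains in (("dorsal", dorsal_trains), ("ventral", ventral_trains)):
        for i, st in enumerate(trains):
            act = ActivationTrace(np.zeros(n_steps), dt=dt)
            afferents.append(Afferent(side, i, i * 2.5, act, st))
    return AfferentPopulationResponse(afferents, trace, params)


class TestIntegrateAfferentInput:
    def test_no_spikes_gives_zero_trace(self):
        empty = [SpikeTrain(np.array([]), 1.0, 0.001) for _ in range(3)]
        pop = _synthetic_population(empty, empty, 1000)
        out = integrate_afferent_input(pop, 1.0, 1.0)
        assert np.all(out.values == 0.0)

    def test_zero_weight_silences_a_row(self):
        dorsal = [SpikeTrain(np.arange(0.05, 0.9, 0.01), 1.0, 0.001)]
        ventral = [SpikeTrain(np.array([]), 1.0, 0.001)]
        pop = _synthetic_population(dorsal, ventral, 1000)
        assert np.all(integrate_afferent_input(pop, 0.0, 1.0).values == 0.0)
        assert integrate_afferent_input(pop, 1.0, 0.0).values.max() > 0

    def test_steady_rate_oracle(self):
        """k afferents at rate r -> mean input ~ k*r*dt/(1-exp(-dt/tau)) ~ k*r*tau."""
        rng = np.random.default_rng(0)
        k, rate, dur, dt, tau = 10, 100.0, 60.0, 0.001, 0.005
        n = int(dur / dt)
        trains = []
        for _ in range(k):
            idx = np.flatnonzero(rng.random(n) < rate * dt)
            trains.append(SpikeTrain.from_indices(idx, dt, dur))
        pop = _synthetic_population(trains, [], n)
        out = integrate_afferent_input(pop, 1.0, 0.0, lpf1_tau=tau)
        exact = k * rate * dt / (1 - np.exp(-dt / tau))  # = 5.52, ~ k*r*tau
        assert out.values[1000:].mean() == pytest.approx(exact, rel=0.02)
        assert out.values[1000:].mean() == pytest.approx(k * rate * tau, rel=0.15)


class TestDinBranch:
    def _const_input(self, value, n=4000):
        return ActivationTrace(np.full(n, value), dt=0.001)

    def test_direct_branch_scales_by_norm(self):
        out = din_branch(self._const_input(8.0), preset("SP_d"))
        assert np.allclose(out.values, 2.0)  # norm 4

    def test_bandpass_kills_dc_leaving_offset(self):
        out = din_branch(self._const_input(5.0), preset("ON"))
        assert np.allclose(out.values[-100:], -0.2, atol=1e-6)

    def test_off_baseline_is_one_for_zero_input(self):
        out = din_branch(self._const_input(0.0), preset("OFF"))
        assert np.allclose(out.values, 1.0)

    def test_rectification_modes_on_a_falling_input(self):
        x = np.concatenate([np.full(2000, 5.0), np.zeros(2000)])
        inp = ActivationTrace(x, dt=0.001)
        raw = din_branch(inp, preset("ExDP"))        # rectify none
        rect = din_branch(inp, preset("ON", rmax=100.0))  # rectify abs
        drop = slice(2050, 2300)
        assert raw.values[drop].min() < -0.3          # negative transient
        assert np.allclose(rect.values[drop] + 0.2,
                           -(raw.values[drop] + 0.2), atol=1e-9)

    def test_off_gain_is_half_of_on(self):
        """Identical input: 1 - act_OFF == (act_ON + 0.2) / 2 (norm 40 vs 20)."""
        x = np.concatenate([np.zeros(500), np.linspace(0, 8, 2000), np.full(1500, 8.0)])
        inp = ActivationTrace(x, dt=0.001)
        on = din_branch(inp, preset("ON"))
        off = din_branch(inp, preset("OFF"))
        assert np.allclose(1.0 - off.values, (on.values + 0.2) / 2.0, atol=1e-9)

    def test_unknown_rectify_rejected(self):
        with pytest.raises(InvalidParameterError):
            ds.DINParams("bad", rectify="square")


def _interval_rates_for(resp, labels, steady_margin=0.5):
    """(ramp rate, steady-hold rate) with the post-ramp transient excluded."""
    n = labels.labels.size
    counts = resp.spikes.counts(n)
    ramp = labels.mask("ramp_up", "ramp_down")
    idx = np.arange(n)
    last_ramp = np.maximum.accumulate(np.where(ramp, idx, -n))
    steady = (~ramp) & ((idx - last_ramp) * labels.dt > steady_margin)
    ramp_rate = counts[ramp].sum() / (ramp.sum() * labels.dt)
    steady_rate = counts[steady].sum() / (steady.sum() * labels.dt)
    return ramp_rate, steady_rate


class TestPhenotypes:
    """Spike-pattern signatures of the four DIN classes (40 deg/s staircase)."""

    def test_sp_dorsal_fires_tonically_in_dorsal_range(self, staircase40, afferent_field40):
        trace, labels = staircase40
        resp = ds.simulate_din(afferent_field40, preset("SP_d"), rng=1)
        angles = trace.angle[resp.spikes.indices]
        assert resp.spikes.n_spikes > 5
        assert np.mean(angles >= 0) >= 0.95
        dorsal_hold = labels.mask("hold_dorsal")
        rate_dorsal = resp.spikes.counts(trace.n)[dorsal_hold].sum() / (
            dorsal_hold.sum() * trace.dt)
        assert rate_dorsal > 5.0  # tonic firing while held dorsally

    def test_on_fires_on_all_ramps_and_rests_in_steady_holds(self, staircase40, afferent_field40):
        trace, labels = staircase40
        resp = ds.simulate_din(afferent_field40, preset("ON"), rng=2)
        counts = resp.spikes.counts(trace.n)
        for lab, _, a, b in labels.runs:
            if lab.startswith("ramp"):
                assert counts[a:b].sum() > 0
        ramp_rate, steady_rate = _interval_rates_for(resp, labels)
        assert steady_rate < 0.05 * ramp_rate

    def test_exdp_fires_only_moving_away_from_rest(self, staircase40, afferent_field40):
        trace, labels = staircase40
        resp = ds.simulate_din(afferent_field40, preset("ExDP"), rng=3)
        counts = resp.spikes.counts(trace.n)
        away = (labels.mask("ramp_up", half="upper")
                | labels.mask("ramp_down", half="lower"))
        toward = labels.mask("ramp_up", half="lower") | labels.mask("ramp_down", half="upper")
        assert counts[away].sum() >= 20
        assert counts[toward].sum() <= 0.05 * counts[away].sum()

    def test_dp_dorsal_confined_to_dorsal_range(self, staircase40, afferent_field40):
        trace, labels = staircase40
        resp = ds.simulate_din(afferent_field40, preset("DP_d"), rng=4)
        angles = trace.angle[resp.spikes.indices]
        assert resp.spikes.n_spikes > 10
        assert np.mean(angles >= 0) >= 0.95

    def test_off_rest_rate_is_offset_times_rmax(self):
        """act = 1 at rest -> 30 Hz; checked over 60 s within 3 SE."""
        trace = ds.JointAngleTrace(np.zeros(60_000))
        pop = ds.simulate_hair_fields(trace, rng=5, generate_spikes=False)
        resp = ds.simulate_din(pop, preset("OFF"), rng=6)
        p = 0.03
        se = np.sqrt(p * (1 - p) / 60_000) / 0.001
        assert abs(resp.spikes.mean_rate() - 30.0) < 3 * se

    def test_mirrored_stimulus_swapped_weights_identical(self):
        """DP_d on the staircase == DP_v on the negated staircase (same seeds)."""
        trace = ds.build_staircase(40.0)
        mirrored = ds.JointAngleTrace(-trace.angle, dt=trace.dt)
        rows = ds.default_rows()
        pop_a = ds.simulate_hair_fields(trace, rows=rows, generate_spikes=False)
        pop_b = ds.simulate_hair_fields(mirrored, rows=rows[::-1], generate_spikes=False)
        a = ds.simulate_din(pop_a, preset("DP_d"), rng=7)
        b = ds.simulate_din(pop_b, preset("DP_v"), rng=7)
        assert np.array_equal(a.spikes.spike_times, b.spikes.spike_times)


class TestVelocityTuning:
    def test_on_increases_off_decreases(self):
        velocities = (12.0, 50.0, 150.0, 400.0)
        on = ds.velocity_tuning(preset("ON"), velocities, n_sweeps=4, rng=8)
        off = ds.velocity_tuning(preset("OFF"), velocities, n_sweeps=4, rng=9)
        assert on.rate_hz.is_monotonic_increasing
        assert off.rate_hz.is_monotonic_decreasing
        assert off.rate_hz.iloc[0] > 25.0  # near the 30-Hz baseline at 12 deg/s

    def test_velocity_range_is_validated(self):
        with pytest.raises(InvalidParameterError):
            ds.velocity_tuning(preset("ON"), velocities=(0.5, 100.0), rng=0)

    def test_random_preset_ignores_stimulus(self):
        vt = ds.velocity_tuning(preset("RANDOM"), velocities=(12.0, 400.0),
                                n_sweeps=4, rng=10)
        # constant activation 0.2 * Rmax 100 -> ~20 Hz at any velocity
        assert np.allclose(vt.rate_hz, 20.0, atol=5.0)
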
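"""Hair deflection, lead-lag activation and the noisy spike generator."""

import numpy as np
import pytest

import dinsim as ds
from dinsim.errors import GridMismatchError, InvalidParameterError
from dinsim.hair_afferents import (
    AfferentParams,
    HairRowConfig,
    deflect_hairs,
    expected_rate,
    generate_spike_train,
    lead_lag_activation,
)


class TestDeflectHairs:
    def test_rest_deflects_nothing(self):
        trace = ds.JointAngleTrace(np.zeros(100))
        for side in ("dorsal", "ventral"):
            assert np.all(deflect_hairs(trace, HairRowConfig(side)) == 0.0)

    def test_opposite_side_silent(self):
        trace = ds.JointAngleTrace(np.full(100, 50.0))
        assert np.all(deflect_hairs(trace, HairRowConfig("ventral")) == 0.0)

    def test_linear_mapping_with_onset_spacing(self):
        trace = ds.JointAngleTrace(np.full(10, 50.0))
        defl = deflect_hairs(trace, HairRowConfig("dorsal"))
        assert defl[-1, 0] == pytest.approx(2.5)   # onset 47.5 deg
        assert defl[0, 0] == pytest.approx(50.0)   # onset 0 deg, saturated
        assert np.all(np.diff(defl[:, 0]) == pytest.approx(-2.5))

    def test_saturation_cap(self):
        trace = ds.JointAngleTrace(np.full(10, 50.0))
        defl = deflect_hairs(trace, HairRowConfig("dorsal", max_deflection=20.0))
        assert defl[:, 0].max() == pytest.approx(20.0)


class TestLeadLagActivation:
    def test_zero_deflection_rests_below_threshold(self):
        act = lead_lag_activation(np.zeros(200), AfferentParams())
        assert np.allclose(act.values, -0.35)

    def test_sustained_deflection_steady_state(self):
        # act -> (lpf_weight * theta - offset) / norm = (2*50 - 35)/100
        defl = np.full(3000, 50.0)
        act = lead_lag_activation(defl, AfferentParams())
        assert act.values[-1] == pytest.approx(0.65, rel=1e-6)

    def test_ramp_highpass_contribution(self):
        # discrete steady ramp response of the high-pass: v*dt*(1-a)/a
        p = AfferentParams()
        v = 100.0
        defl = np.clip(v * (np.arange(5000) * p.dt), 0.0, None)
        act = lead_lag_activation(defl, p)
        a = 1 - np.exp(-p.dt / p.hpf_tau)
        lag = v * p.dt * (1 - a) / a  # steady high-pass output on a ramp
        # total activation = low-pass part (with its own small lag) + hp part
        a_l = 1 - np.exp(-p.dt / p.lpf_tau)
        lag_l = v * p.dt * (1 - a_l) / a_l
        expected = (p.lpf_weight * (defl[-1] - lag_l) + p.hpf_weight * lag
                    - p.offset) / p.norm
        assert act.values[-1] == pytest.approx(expected, rel=1e-6)
        # ~ hpf_weight * hpf_tau * v / norm = 0.60 in the continuous limit
        assert p.hpf_weight * lag / p.norm == pytest.approx(0.60, rel=0.05)

    def test_grid_mismatch_raises(self):
        with pytest.raises(GridMismatchError):
            lead_lag_activation(np.zeros(10), AfferentParams(), dt=0.002)


class TestSpikeGenerator:
    def test_nonpositive_activation_is_silent(self):
        st = generate_spike_train(np.full(5000, -0.1), rmax=300, dt=0.001, rng=0)
        assert st.n_spikes == 0

    def test_rate_matches_bernoulli_expectation_without_refractory(self):
        # act = 1, Rmax = 300 -> p = 0.3/step -> 300 Hz
        n = 60_000
        st = generate_spike_train(np.ones(n), rmax=300, dt=0.001, refractory=0.0, rng=1)
        p = 0.3
        se = np.sqrt(p * (1 - p) / n) / 0.001
        assert abs(st.mean_rate() - 300.0) < 3 * se

    def test_rate_matches_renewal_expectation_with_refractory(self):
        # expected rate 1/(3 ms + dt/0.3) ~ 157.9 Hz
        n = 60_000
        st = generate_spike_train(np.ones(n), rmax=300, dt=0.001, refractory=0.003, rng=2)
        expect = 1.0 / (0.003 + 0.001 / 0.3)
        isi = np.diff(st.spike_times)
        se = isi.std() / np.sqrt(isi.size) * expect ** 2  # delta method on mean ISI
        assert abs(st.mean_rate() - expect) < 3 * se
        assert np.all(isi >= 0.003)

    def test_probability_capped_at_one(self):
        # act*dt*rmax > 1 must spike every step when refractory is off
        st = generate_spike_train(np.full(100, 50.0), rmax=300, dt=0.001,
                                  refractory=0.0, rng=3)
        assert st.n_spikes == 100

    def test_max_rate_bounded_by_refractory(self):
        st = generate_spike_train(np.full(10_000, 50.0), rmax=300, dt=0.001,
                                  refractory=0.003, rng=4)
        assert st.mean_rate() <= 1.0 / (0.003 + 0.001) + 1e-9

    def test_seed_determinism(self):
        act = np.random.default_rng(5).uniform(0, 1, 2000)
        a = generate_spike_train(act, rmax=300, dt=0.001, refractory=0.003, rng=42)
        b = generate_spike_train(act, rmax=300, dt=0.001, refractory=0.003, rng=42)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_expected_rate_limits(self):
        assert expected_rate(np.array([1.0]), 300, 0.001, 0.003)[0] == pytest.approx(
            1 / (0.003 + 0.001 / 0.3))
        assert expected_rate(np.array([-1.0]), 300, 0.001, 0.003)[0] == 0.0


class TestHairFieldSimulation:
    def test_rest_holds_are_silent(self, staircase40):
        trace, labels = staircase40
        pop = ds.simulate_hair_fields(trace, rng=7)
        rest = labels.mask("hold_rest")
        for a in pop.afferents:
            assert rest[a.spikes.indices].sum() == 0

    def test_mirror_symmetry_bit_exact(self):
        """Negated stimulus + swapped rows -> identical swapped spike trains."""
        trace = ds.build_staircase(100.0)
        mirrored = ds.JointAngleTrace(-trace.angle, dt=trace.dt)
        rows = ds.default_rows()
        pop_a = ds.simulate_hair_fields(trace, rows=rows, rng=11)
        pop_b = ds.simulate_hair_fields(mirrored, rows=rows[::-1], rng=11)
        for a, b in zip(pop_a.afferents, pop_b.afferents):
            assert a.side != b.side and a.index == b.index
            assert np.array_equal(a.spikes.spike_times, b.spikes.spike_times)

    def test_cascaded_recruitment_during_ramp(self, staircase40):
        """Proximal hairs start firing before distal hairs on the upper ramp."""
        trace, labels = staircase40
        pop = ds.simulate_hair_fields(trace, rng=13)
        up_upper = labels.mask("ramp_up", half="upper")
        start = np.flatnonzero(up_upper)[0] * trace.dt
        firsts = []
        for a in pop.row("dorsal"):
            t = a.spikes.spike_times
            t = t[t >= start]
            if t.size:
                firsts.append((a.onset, t[0]))
        onsets, times = zip(*firsts)
        assert len(firsts) >= 10
        assert np.corrcoef(onsets, times)[0, 1] > 0.95

    @pytest.mark.parametrize("velocity", [25.0, 90.0, 250.0])
    def test_phasic_peak_exceeds_sustained(self, velocity):
        """Deflect-and-return: peak activation during the ramp >= sustained level."""
        from dinsim.hair_afferents import deflect_hairs_single
        p = AfferentParams()
        trace = ds.build_single_hair_protocol(25.0, velocity, dt=p.dt)
        act = lead_lag_activation(deflect_hairs_single(trace), p)
        slope = np.gradient(trace.angle, p.dt)
        ramp_up = slope > 0.5
        hold = (np.abs(slope) < 0.5) & (trace.angle > 12.5)
        sustained = act.values[hold][-200:].mean()
        assert act.values[ramp_up].max() >= sustained


    def test_distal_hairs_fire_less(self, staircase40):
        trace, _ = staircase40
        pop = ds.simulate_hair_fields(trace, rng=19)
        dorsal = pop.row("dorsal")
        assert dorsal[0].spikes.n_spikes > dorsal[-1].spikes.n_spikes


class TestSingleSensillumTuning:
    def test_tuning_tables(self):
        amp, vel = ds.single_sensillum_tuning(
            amplitudes=(0.0, 10.0, 25.0), velocities=(25.0, 150.0), n_reps=4, rng=23)
        assert amp.sustained_rate_hz.iloc[0] == 0.0          # no deflection, no spikes
        assert amp.sustained_rate_hz.is_monotonic_increasing
        assert vel.peak_rate_hz.iloc[1] > vel.peak_rate_hz.iloc[0]

    def test_empty_sweep_raises(self):
        with pytest.raises(InvalidParameterError):
            ds.single_sensillum_tuning(amplitudes=(), rng=0)
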
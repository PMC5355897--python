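"""Unit and property tests for the membrane, adaptation and synapse rules."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lifnet.core import (
    ClampPolicy,
    InvalidStepError,
    NeuronParameters,
    NeuronState,
    NumericalBlowUpError,
    SynapseParameters,
    adaptation_current,
    clamp_voltage,
    decay_adaptation,
    decay_synaptic_current,
    leak_current,
    lif_firing_rate,
    step_neuron,
)


class TestLeakCurrent:
    @pytest.mark.parametrize(
        "dV, Rm, expected",
        [
            (0.0, 1.0e8, 0.0),  # zero at rest
            (0.010, 1.0e8, -1.0e-10),  # hand evaluation of -(V-Vr)/Rm
            (-0.010, 1.0e8, 1.0e-10),  # antisymmetric about rest
        ],
    )
    def test_values(self, dV, Rm, expected):
        params = NeuronParameters(Rm=Rm)
        assert leak_current(params.Vr + dV, params) == pytest.approx(expected, rel=1e-12)

    @given(dV=st.floats(-0.05, 0.05))
    def test_antisymmetry(self, dV):
        params = NeuronParameters()
        assert leak_current(params.Vr + dV, params) == pytest.approx(
            -leak_current(params.Vr - dV, params), rel=1e-9, abs=1e-30
        )


class TestAdaptationCurrent:
    def test_zero_conductance(self, default_neuron):
        assert adaptation_current(0.0, -0.055, default_neuron) == 0.0

    def test_vanishes_at_rest(self, default_neuron):
        assert adaptation_current(1e-8, default_neuron.Vr, default_neuron) == 0.0

    def test_hand_value(self, default_neuron):
        # g = 1e-8 S at 20 mV above rest -> 2e-10 A
        I = adaptation_current(1e-8, default_neuron.Vr + 0.02, default_neuron)
        assert I == pytest.approx(2e-10, rel=1e-12)


class TestDecays:
    def test_adaptation_fixed_point(self):
        p = NeuronParameters(adaptive=True, tau_adapt=1e-2)
        assert decay_adaptation(0.0, 1e-4, p) == 0.0

    def test_adaptation_euler_step(self):
        p = NeuronParameters(adaptive=True, tau_adapt=1e-2)
        assert decay_adaptation(1e-8, 1e-4, p) == pytest.approx(0.99e-8, rel=1e-12)

    def test_adaptation_invalid_step(self):
        p = NeuronParameters(adaptive=True, tau_adapt=1e-3)
        with pytest.raises(InvalidStepError):
            decay_adaptation(1e-8, 2e-3, p)

    def test_adaptation_converges_to_exponential(self):
        # stepping over one time constant approaches g0 / e as dt -> 0
        p = NeuronParameters(adaptive=True, tau_adapt=0.01)
        n = 10000
        g = 1e-8
        for _ in range(n):
            g = decay_adaptation(g, p.tau_adapt / n, p)
        assert g == pytest.approx(1e-8 * math.exp(-1.0), rel=1e-3)

    def test_synaptic_fixed_point_and_step(self):
        syn = SynapseParameters(tau_syn=1e-3)
        assert decay_synaptic_current(0.0, 1e-4, syn) == 0.0
        assert decay_synaptic_current(1e-9, 1e-4, syn) == pytest.approx(
            0.9e-9, rel=1e-12
        )

    def test_synaptic_invalid_step(self):
        syn = SynapseParameters(tau_syn=1e-3)
        with pytest.raises(InvalidStepError):
            decay_synaptic_current(1e-9, 1e-3, syn)

    def test_synaptic_kernel_converges(self):
        # a single increment stepped over tau_syn approaches peak / e
        syn = SynapseParameters(peak_current=1e-9, tau_syn=0.01)
        n = 10000
        s = syn.peak_current
        for _ in range(n):
            s = decay_synaptic_current(s, syn.tau_syn / n, syn)
        assert s == pytest.approx(1e-9 * math.exp(-1.0), rel=1e-3)


class TestClamp:
    def test_interior_point(self):
        assert clamp_voltage(-0.070, ClampPolicy()) == -0.070

    def test_upper_limit(self):
        assert clamp_voltage(0.100, ClampPolicy()) == 0.060

    def test_disabled_is_identity(self):
        assert clamp_voltage(-0.200, ClampPolicy(enabled=False)) == -0.200

    @given(V=st.floats(-10.0, 10.0))
    def test_always_within_bounds(self, V):
        c = ClampPolicy()
        assert c.v_min <= clamp_voltage(V, c) <= c.v_max


class TestStepNeuron:
    def test_rest_is_fixed_point(self, default_neuron, clamp):
        state = NeuronState(V=default_neuron.Vr)
        for dt in (1e-5, 1e-4, 1e-3):
            new, fired = step_neuron(state, default_neuron, 0.0, 0.0, dt, clamp)
            assert new.V == default_neuron.Vr
            assert not fired

    def test_forced_fire_resets_and_starts_refractory(self, default_neuron, clamp):
        state = NeuronState(V=default_neuron.Vthres - 1e-4)
        new, fired = step_neuron(state, default_neuron, 0.0, 1e-8, 1e-4, clamp)
        assert fired
        assert new.V == default_neuron.Vreset
        assert new.refractory_remaining == default_neuron.tau_r
        assert new.V_observed >= default_neuron.Vthres

    def test_refractory_holds_at_reset(self, default_neuron, clamp):
        state = NeuronState(V=default_neuron.Vreset, refractory_remaining=1e-3)
        new, fired = step_neuron(state, default_neuron, 0.0, 1e-8, 1e-4, clamp)
        assert not fired
        assert new.V == default_neuron.Vreset
        assert new.refractory_remaining == pytest.approx(9e-4)

    def test_rc_charging_reaches_steady_state(self, default_neuron, clamp):
        # constant subthreshold current: V -> Vr + Rm*I within 1% after 5 tau_m
        I = 1.0e-10  # 10 mV asymptote, below the 15 mV threshold gap
        V_inf = default_neuron.Vr + default_neuron.Rm * I
        dt = default_neuron.tau_m / 1000
        state = NeuronState(V=default_neuron.Vr)
        for _ in range(5000):  # 5 tau_m
            state, fired = step_neuron(state, default_neuron, 0.0, I, dt, clamp)
            assert not fired
        assert abs(state.V - V_inf) < 0.01 * abs(V_inf - default_neuron.Vr)

    def test_euler_is_first_order(self, default_neuron, no_clamp):
        # halving dt at least halves the max deviation from the closed form
        I = 1.0e-10
        p = default_neuron
        V_inf = p.Vr + p.Rm * I

        def max_deviation(dt, t_end=0.3):
            n = int(round(t_end / dt))
            state = NeuronState(V=p.Vr)
            worst = 0.0
            for k in range(1, n + 1):
                state, _ = step_neuron(state, p, 0.0, I, dt, no_clamp)
                exact = V_inf + (p.Vr - V_inf) * math.exp(-k * dt / p.tau_m)
                worst = max(worst, abs(state.V - exact))
            return worst

        dev = max_deviation(2e-3)
        dev_half = max_deviation(1e-3)
        assert dev_half <= 0.55 * dev

    def test_blow_up_detected(self, default_neuron, no_clamp):
        state = NeuronState(V=default_neuron.Vr)
        with pytest.raises(NumericalBlowUpError):
            step_neuron(state, default_neuron, 0.0, 1e308, 1e300, no_clamp)


def _simulate_spike_times(params, I, dt, duration, clamp=ClampPolicy()):
    state = NeuronState(V=params.Vr)
    spikes = []
    n = int(round(duration / dt))
    for k in range(1, n + 1):
        state, fired = step_neuron(state, params, 0.0, I, dt, clamp)
        if fired:
            spikes.append(k * dt)
    return spikes


class TestFiringProperties:
    def test_analytic_fI_rate(self, default_neuron):
        # simulated steady rate within 2% of the closed-form ISI formula
        I = 2.5e-10  # V_inf 25 mV above rest, threshold gap 15 mV
        dt = default_neuron.tau_m / 1000
        spikes = _simulate_spike_times(default_neuron, I, dt, 2.0)
        assert len(spikes) > 5
        rate = (len(spikes) - 1) / (spikes[-1] - spikes[0])
        expected = lif_firing_rate(default_neuron, I)
        assert rate == pytest.approx(expected, rel=0.02)

    def test_fI_rate_zero_below_rheobase(self, default_neuron):
        assert lif_firing_rate(default_neuron, 1.0e-10) == 0.0

    def test_refractory_floor(self, default_neuron):
        dt = 1e-4
        spikes = _simulate_spike_times(default_neuron, 5e-10, dt, 1.0)
        isis = np.diff(spikes)
        assert np.all(isis >= default_neuron.tau_r + dt - 1e-12)

    def test_adaptation_lengthens_isis(self):
        # under sustained drive, successive ISIs of an adaptive cell grow
        p = NeuronParameters(adaptive=True)
        spikes = _simulate_spike_times(p, 3e-10, 1e-4, 2.0)
        isis = np.diff(spikes)
        assert len(isis) >= 5
        assert np.all(np.diff(isis) >= -1e-12)  # non-decreasing
        assert isis[0] < isis[4]


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"Cm": 0.0},
            {"Rm": -1.0},
            {"Vreset": -0.050, "Vthres": -0.065},
            {"tau_r": -1e-3},
            {"adaptive": True, "tau_adapt": 0.0},
        ],
    )
    def test_invalid_neuron_parameters(self, kwargs):
        with pytest.raises(ValueError):
            NeuronParameters(**kwargs)

    def test_invalid_synapse_and_clamp(self):
        with pytest.raises(ValueError):
            SynapseParameters(tau_syn=0.0)
        with pytest.raises(ValueError):
            SynapseParameters(peak_current=-1e-9)
        with pytest.raises(ValueError):
            ClampPolicy(v_min=0.1, v_max=-0.1)
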
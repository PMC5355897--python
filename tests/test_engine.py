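"""Engine tests: stepping order, event delivery, determinism, recordings."""

import numpy as np
import pytest

from lifnet.core import (
    ClampPolicy,
    NeuronParameters,
    NeuronState,
    Polarity,
    SynapseParameters,
    lif_firing_rate,
    step_neuron,
)
from lifnet.engine import Simulation, SimulationConfig, run
from lifnet.network import Network, NetworkError
from lifnet.stimulators import CurrentSourceParams, EventSchedule, GeneratorParams


def _dc_neuron_net(amplitude, neuron=NeuronParameters()):
    net = Network()
    dc = net.add("dc_source", CurrentSourceParams(amplitude=amplitude))
    cell = net.add("neuron", neuron)
    net.connect(dc, cell)
    return net, cell


class TestNetworkConstruction:
    def test_add_and_count(self):
        net = Network()
        net.add("neuron")
        assert len(net.nodes) == 1 and len(net.edges) == 0

    def test_duplicate_label_rejected(self):
        net = Network()
        net.add("neuron", label="A")
        with pytest.raises(NetworkError, match="duplicate"):
            net.add("neuron", label="A")

    def test_unknown_kind_rejected(self):
        net = Network()
        with pytest.raises(NetworkError, match="unknown node kind"):
            net.add("astrocyte")

    def test_sensor_cannot_drive(self):
        net = Network()
        meter = net.add("voltmeter")
        cell = net.add("neuron")
        with pytest.raises(NetworkError, match="sensors cannot drive"):
            net.connect(meter, cell)

    def test_unknown_endpoint(self):
        net = Network()
        cell = net.add("neuron")
        with pytest.raises(NetworkError, match="unknown node id"):
            net.connect(cell, 99)

    def test_stimulator_to_sensor_rejected(self):
        net = Network()
        dc = net.add("dc_source")
        meter = net.add("voltmeter")
        with pytest.raises(NetworkError):
            net.connect(dc, meter)

    def test_self_loop_rejected_by_default(self):
        net = Network()
        cell = net.add("neuron")
        with pytest.raises(NetworkError, match="self-loop"):
            net.connect(cell, cell)
        permissive = Network(allow_self_loops=True)
        c2 = permissive.add("neuron")
        permissive.connect(c2, c2)  # allowed when opted in


class TestRun:
    def test_empty_network_is_noop(self):
        rec = run(Network(), SimulationConfig(duration=0.01))
        assert len(rec.times) == 101
        assert rec.voltages == {} and rec.spikes == {}

    def test_resting_neuron_unchanged(self):
        net = Network()
        cell = net.add("neuron")
        rec = run(net, SimulationConfig(duration=0.05))
        assert np.all(rec.voltages[cell] == NeuronParameters().Vr)
        assert rec.spikes[cell] == []

    def test_trace_length_includes_t0(self):
        net = Network()
        net.add("neuron")
        dt = 1e-4
        rec = run(net, SimulationConfig(duration=10 * dt, dt=dt))
        assert len(rec.times) == 11
        assert rec.times[0] == 0.0

    def test_determinism_same_seed(self):
        def build():
            net = Network()
            gen = net.add("poisson_generator", GeneratorParams(rate=200.0))
            cell = net.add("neuron")
            net.connect(gen, cell)
            return net, cell

        cfg = SimulationConfig(duration=0.5, seed=42)
        net1, c1 = build()
        net2, c2 = build()
        rec1, rec2 = run(net1, cfg), run(net2, cfg)
        assert np.array_equal(rec1.voltages[c1], rec2.voltages[c2])
        assert rec1.spikes[c1] == rec2.spikes[c2]

    def test_spike_count_matches_analytic_fI(self):
        I = 2.5e-10
        net, cell = _dc_neuron_net(I)
        duration = 2.0
        rec = run(net, SimulationConfig(duration=duration))
        expected = lif_firing_rate(NeuronParameters(), I) * duration
        assert abs(rec.spike_count(cell) - expected) <= 1


class TestEventDelivery:
    def test_fire_effects_arrive_next_step(self):
        # a presynaptic fire at step k first moves the target at step k+1
        net = Network()
        touch = net.add("event_source", EventSchedule((0.01,)))
        a = net.add("neuron", label="A")
        b = net.add("neuron", label="B")
        net.connect(touch, a)
        net.connect(a, b, SynapseParameters(peak_current=1e-10, delay=0.0))
        dt = 1e-4
        rec = run(net, SimulationConfig(duration=0.1, dt=dt))
        assert rec.spikes[a], "A must fire"
        k_fire = int(round(rec.spikes[a][0] / dt))
        Vr = NeuronParameters().Vr
        assert rec.voltages[b][k_fire] == Vr
        assert rec.voltages[b][k_fire + 1] != Vr

    def test_delay_shifts_onset_by_whole_steps(self):
        def onset_step(delay):
            net = Network()
            touch = net.add("event_source", EventSchedule((0.01,)))
            a = net.add("neuron")
            b = net.add("neuron")
            net.connect(touch, a)
            net.connect(a, b, SynapseParameters(peak_current=1e-10, delay=delay))
            rec = run(net, SimulationConfig(duration=0.1, dt=1e-4))
            Vr = NeuronParameters().Vr
            return int(np.flatnonzero(rec.voltages[b] != Vr)[0])

        base = onset_step(0.0)
        assert onset_step(5e-4) == base + 4  # offset 5 steps instead of 1
        assert onset_step(2e-3) == base + 19

    def test_dc_source_never_enqueues_events(self):
        net, cell = _dc_neuron_net(1e-10)
        sim = Simulation(net, SimulationConfig(duration=1.0))
        sim.run()
        assert sim.pending == {}
        dc_id = net.node_ids("dc_source")[0]
        assert dc_id not in sim.spike_steps

    def test_generator_polarity_negates_deflection(self):
        def deflection(polarity):
            net = Network()
            gen = net.add("regular_generator", GeneratorParams(rate=20.0, polarity=polarity))
            cell = net.add("neuron")
            net.connect(gen, cell, SynapseParameters(peak_current=1e-10))
            cfg = SimulationConfig(duration=0.3, clamp=ClampPolicy(enabled=False))
            rec = run(net, cfg)
            return rec.voltages[cell] - NeuronParameters().Vr

        exc = deflection(Polarity.EXCITATORY)
        inh = deflection(Polarity.INHIBITORY)
        assert np.allclose(exc, -inh, atol=1e-15)
        assert np.max(np.abs(exc)) > 0


class TestLinearityAndIsolation:
    def test_subthreshold_superposition(self):
        # with clamping off, deflections from two sources add linearly
        def trace(amplitudes):
            net = Network()
            cell = net.add("neuron")
            for amp in amplitudes:
                src = net.add("dc_source", CurrentSourceParams(amplitude=amp))
                net.connect(src, cell)
            cfg = SimulationConfig(duration=0.2, clamp=ClampPolicy(enabled=False))
            return run(net, cfg).voltages[cell]

        Vr = NeuronParameters().Vr
        # cell node id differs between builds, so compare deflections
        d1 = trace([4e-11]) - Vr
        d2 = trace([6e-11]) - Vr
        d12 = trace([4e-11, 6e-11]) - Vr
        assert np.allclose(d12, d1 + d2, atol=1e-12)

    def test_graph_isolation(self):
        def build(with_isolated):
            net = Network()
            dc = net.add("dc_source", CurrentSourceParams(amplitude=1e-10))
            cell = net.add("neuron")
            net.connect(dc, cell)
            if with_isolated:
                gen = net.add("poisson_generator", GeneratorParams(rate=500.0))
                other = net.add("neuron")
                net.connect(gen, other)
            return net, cell

        cfg = SimulationConfig(duration=0.2, seed=9)
        net1, c1 = build(False)
        net2, c2 = build(True)
        assert np.array_equal(
            run(net1, cfg).voltages[c1], run(net2, cfg).voltages[c2]
        )

    def test_engine_matches_pure_stepper(self):
        # dual route: the vectorized engine reproduces step_neuron exactly
        I = 2.0e-10
        net, cell = _dc_neuron_net(I)
        dt = 1e-4
        cfg = SimulationConfig(duration=0.5, dt=dt)
        rec = run(net, cfg)
        p = NeuronParameters()
        state = NeuronState(V=p.Vr)
        for k in range(1, int(0.5 / dt) + 1):
            state, _ = step_neuron(state, p, 0.0, I, dt, cfg.clamp)
            assert rec.voltages[cell][k] == pytest.approx(state.V_observed, abs=1e-15)

    def test_blow_up_names_offending_neuron(self):
        net, cell = _dc_neuron_net(1e308)
        with pytest.raises(ArithmeticError, match=str(cell)):
            run(net, SimulationConfig(duration=0.01, clamp=ClampPolicy(enabled=False)))


class TestRecordedVoltageShape:
    def test_spiking_trace_is_sawtooth_with_separate_spike_events(self):
        net, cell = _dc_neuron_net(2.5e-10)
        rec = run(net, SimulationConfig(duration=1.0))
        p = NeuronParameters()
        v = rec.voltages[cell]
        # trace rises just to threshold (one Euler step of overshoot at most)
        assert v.max() >= p.Vthres
        assert v.max() < p.Vthres + 1e-3
        assert v.min() >= p.Vreset
        assert len(rec.spikes[cell]) > 5

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=1e-5, dt=1e-4)
        with pytest.raises(ValueError):
            SimulationConfig(duration=1.0, dt=0.0)
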
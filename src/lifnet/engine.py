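"""The graph engine: advances a whole network one fixed time step at a time,
routes fire events through delayed edges, and collects recordings.

Update order within a step (fixed and documented):

1. deliver spike events that fall due this step as synaptic increments;
2. decay every edge's synaptic current one Euler step;
3. evaluate stimulators (current sources at the step's start time, spike
   sources over the step's time bin);
4. integrate all neurons with their summed synaptic and injected currents;
5. enqueue new fires with a per-edge delivery offset of
   max(1, round(delay/dt)) steps — effects always land in a *later* step;
6. update sensors.

Determinism: a single global random stream seeded from the configuration,
consumed in ascending node-id order, makes identical (network, config) pairs
produce bit-identical recordings.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .core import (
    ClampPolicy,
    InvalidStepError,
    NumericalBlowUpError,
    DEFAULT_DT,
)
from .network import (
    CURRENT_SOURCE_KINDS,
    Network,
    SENSOR_KINDS,
    SPIKE_SOURCE_KINDS,
)
from .receptive_fields import field_response
from .sensors import rate_trace
from .stimulators import ac_current, dc_current

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "RecordingSet", "Simulation", "run"]


@dataclass(frozen=True)
class SimulationConfig:
    """Batch-run configuration (replaces interactive playback controls)."""

    duration: float = 1.0
    dt: float = DEFAULT_DT
    seed: int = 0
    clamp: ClampPolicy = field(default_factory=ClampPolicy)
    record: Union[str, tuple] = "all"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")


@dataclass
class RecordingSet:
    """All traces collected by a run, on a shared time grid.

    ``times`` has n_steps + 1 entries (the t = 0 sample is recorded before
    the first step).  ``voltages`` maps each neuron id to its trace;
    ``spikes`` maps each neuron and spike-source id to its (strictly
    increasing) spike times; ``rates`` maps each firing-rate-meter id to its
    population-rate trace (Hz).
    """

    times: np.ndarray
    voltages: dict
    spikes: dict
    rates: dict
    labels: dict

    def spike_count(self, nid: int) -> int:
        return len(self.spikes.get(nid, ()))

    def mean_rate(self, nid: int) -> float:
        """Spike count divided by run duration (Hz)."""
        span = float(self.times[-1]) if len(self.times) else 0.0
        return self.spike_count(nid) / span if span > 0 else 0.0


class Simulation:
    """A compiled, steppable simulation of one network.

    The network is flattened into numpy arrays at construction; ``step``
    advances one dt, ``run`` executes the configured duration and returns the
    :class:`RecordingSet`.
    """

    def __init__(self, net: Network, cfg: SimulationConfig) -> None:
        self.net = net
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        dt = cfg.dt
        self.n_steps = int(math.ceil(cfg.duration / dt))
        self.k = 0  # completed steps

        # --- neurons --------------------------------------------------------
        self.neuron_ids = net.node_ids("neuron")
        idx = {nid: i for i, nid in enumerate(self.neuron_ids)}
        n = len(self.neuron_ids)
        get = lambda attr: np.array(
            [getattr(net.nodes[i].params, attr) for i in self.neuron_ids], dtype=float
        )
        self.Cm, self.Rm = get("Cm"), get("Rm")
        self.Vrest, self.Vreset, self.Vthres = get("Vr"), get("Vreset"), get("Vthres")
        self.adaptive = np.array(
            [net.nodes[i].params.adaptive for i in self.neuron_ids], dtype=bool
        )
        self.tau_adapt, self.dg_adapt = get("tau_adapt"), get("delta_g_adapt")
        if np.any(self.adaptive & (self.tau_adapt <= dt)):
            raise InvalidStepError("dt must be smaller than every tau_adapt")
        safe_tau = np.where(self.adaptive, self.tau_adapt, 1.0)
        self.g_decay = np.where(self.adaptive, 1.0 - dt / safe_tau, 1.0)
        self.refr_steps_full = np.array(
            [int(round(net.nodes[i].params.tau_r / dt)) for i in self.neuron_ids]
        )
        self.V = self.Vrest.copy()
        self.V_obs = self.V.copy()
        self.g_adapt = np.zeros(n)
        self.refr = np.zeros(n, dtype=int)

        # --- edges ----------------------------------------------------------
        syn_dst, syn_amp, syn_decay, syn_delay = [], [], [], []
        self.syn_out: dict[int, list[int]] = {}  # firing node id -> edge indices
        self.inj_edges = []  # (source id, neuron index)
        self.sensor_targets: dict[int, list[int]] = {}  # sensor id -> neuron ids
        for e in net.edges:
            src_kind = net.nodes[e.source].kind
            dst_kind = net.nodes[e.target].kind
            if dst_kind in SENSOR_KINDS:
                self.sensor_targets.setdefault(e.target, []).append(e.source)
            elif src_kind in CURRENT_SOURCE_KINDS:
                self.inj_edges.append((e.source, idx[e.target]))
            else:  # spike-carrying synapse
                syn = e.synapse
                if syn.tau_syn <= dt:
                    raise InvalidStepError(
                        f"dt ({dt}) must be smaller than tau_syn ({syn.tau_syn})"
                    )
                eidx = len(syn_dst)
                syn_dst.append(idx[e.target])
                syn_amp.append(net.polarity_of(e.source).sign * syn.peak_current)
                syn_decay.append(1.0 - dt / syn.tau_syn)
                syn_delay.append(max(1, int(round(syn.delay / dt))))
                self.syn_out.setdefault(e.source, []).append(eidx)
        self.syn_dst = np.array(syn_dst, dtype=int)
        self.syn_amp = np.array(syn_amp, dtype=float)
        self.syn_decay = np.array(syn_decay, dtype=float)
        self.syn_delay = np.array(syn_delay, dtype=int)
        self.s = np.zeros(len(syn_dst))
        self.pending: dict[int, list[int]] = {}

        # --- stimulators ----------------------------------------------------
        inj_map: dict[int, list[int]] = {}
        for src, tgt in self.inj_edges:
            inj_map.setdefault(src, []).append(tgt)
        self.current_sources = [
            (nid, net.nodes[nid].kind, net.nodes[nid].params, inj_map.get(nid, []))
            for nid in net.node_ids(*CURRENT_SOURCE_KINDS)
        ]
        self.regular = [
            [nid, net.nodes[nid].params.rate, 0.0]
            for nid in net.node_ids("regular_generator")
        ]
        # an activation at time ta lands in the step whose bin (t_{k-1}, t_k]
        # contains it: k = ceil(ta/dt), robust to grid round-off
        self.event_steps = {
            nid: {
                int(math.ceil(ta / dt - 1e-9))
                for ta in net.nodes[nid].params.activation_times
            }
            for nid in net.node_ids("event_source")
        }
        # stochastic sources draw one uniform each per step, in id order
        stoch: list[tuple[int, float]] = []
        for nid in net.node_ids("poisson_generator"):
            p = net.nodes[nid].params.rate * dt
            if p > 1.0:
                raise ValueError(
                    f"poisson generator {nid}: rate*dt = {p:.3g} exceeds 1"
                )
            if p > 0.1:
                warnings.warn(
                    f"poisson generator {nid}: rate*dt = {p:.3g} > 0.1; "
                    "the per-step Bernoulli approximation is biased",
                    stacklevel=2,
                )
            stoch.append((nid, p))
        for nid in net.node_ids("visual_input"):
            vp = net.nodes[nid].params
            resp = field_response(vp.kernel, vp.image)
            stoch.append((nid, min(1.0, max(0.0, resp) * vp.gain * dt)))
        self.stochastic = sorted(stoch)

        # --- recordings -----------------------------------------------------
        self.times = np.arange(self.n_steps + 1) * dt
        self.v_trace = np.empty((n, self.n_steps + 1))
        self.v_trace[:, 0] = self.V_obs
        self.spike_steps: dict[int, list[int]] = {
            nid: [] for nid in self.neuron_ids
        }
        for nid in net.node_ids(*SPIKE_SOURCE_KINDS):
            self.spike_steps[nid] = []
        for sid, targets in self.sensor_targets.items():
            if not targets:  # pragma: no cover - connect() prevents this
                logger.warning("sensor %d is not connected to any neuron", sid)
        for sid in net.node_ids(*SENSOR_KINDS):
            if sid not in self.sensor_targets:
                logger.warning("sensor %d is not connected to any neuron", sid)

    # -----------------------------------------------------------------------

    def step(self) -> np.ndarray:
        """Advance the whole network by one dt; returns the fired neuron mask."""
        dt = self.cfg.dt
        self.k += 1
        k = self.k
        t_prev = (k - 1) * dt

        # 1. deliver due spike events
        for eidx in self.pending.pop(k, ()):
            self.s[eidx] += self.syn_amp[eidx]
        # 2. decay all synaptic currents
        self.s *= self.syn_decay

        # 3. stimulators
        I_inj = np.zeros(len(self.neuron_ids))
        for nid, kind, params, targets in self.current_sources:
            value = (
                ac_current(params, t_prev)
                if kind == "ac_source"
                else dc_current(params, t_prev)
            )
            for tgt in targets:
                I_inj[tgt] += value
        fired_sources: list[int] = []
        for rec in self.regular:
            nid, rate, elapsed = rec
            elapsed += dt
            if rate > 0 and elapsed > 1.0 / rate:
                fired_sources.append(nid)
                elapsed = 0.0
            rec[2] = elapsed
        for nid, steps in self.event_steps.items():
            if k in steps:
                fired_sources.append(nid)
        if self.stochastic:
            draws = self.rng.random(len(self.stochastic))
            for (nid, p), u in zip(self.stochastic, draws):
                if u < p:
                    fired_sources.append(nid)

        # 4. integrate neurons
        I_syn = (
            np.bincount(self.syn_dst, weights=self.s, minlength=len(self.neuron_ids))
            if len(self.s)
            else np.zeros(len(self.neuron_ids))
        )
        I_leak = -(self.V - self.Vrest) / self.Rm
        I_adapt = self.g_adapt * (self.V - self.Vrest)
        with np.errstate(over="ignore", invalid="ignore"):
            V_new = self.V + (dt / self.Cm) * (I_leak + I_syn + I_inj - I_adapt)
        clamp = self.cfg.clamp
        if clamp.enabled:
            np.clip(V_new, clamp.v_min, clamp.v_max, out=V_new)
        if not np.all(np.isfinite(V_new)):
            bad = int(np.flatnonzero(~np.isfinite(V_new))[0])
            raise NumericalBlowUpError(
                f"membrane potential of neuron {self.neuron_ids[bad]} became "
                "non-finite; check dt against the smallest time constant"
            )
        self.g_adapt *= self.g_decay
        in_refr = self.refr > 0
        V_new[in_refr] = self.Vreset[in_refr]
        fired = (~in_refr) & (V_new >= self.Vthres)
        self.V_obs = V_new.copy()
        V_new[fired] = self.Vreset[fired]
        self.V = V_new
        self.refr[in_refr] -= 1
        self.refr[fired] = self.refr_steps_full[fired]
        self.g_adapt[fired & self.adaptive] += self.dg_adapt[fired & self.adaptive]

        # 5. enqueue new fires (sources and neurons, ascending node id)
        firing_ids = sorted(
            fired_sources + [self.neuron_ids[i] for i in np.flatnonzero(fired)]
        )
        for nid in firing_ids:
            self.spike_steps[nid].append(k)
            for eidx in self.syn_out.get(nid, ()):
                self.pending.setdefault(k + int(self.syn_delay[eidx]), []).append(eidx)

        # 6. sensors (voltage rows; rate traces are assembled post-run)
        self.v_trace[:, k] = self.V_obs
        return fired

    def run(self) -> RecordingSet:
        while self.k < self.n_steps:
            self.step()
        return self.recordings()

    def recordings(self) -> RecordingSet:
        dt = self.cfg.dt
        spikes = {
            nid: [k * dt for k in steps] for nid, steps in self.spike_steps.items()
        }
        voltages = {
            nid: self.v_trace[i, : self.k + 1].copy()
            for i, nid in enumerate(self.neuron_ids)
        }
        labels = {
            nid: spec.label for nid, spec in self.net.nodes.items() if spec.label
        }
        rec = RecordingSet(
            times=self.times[: self.k + 1].copy(),
            voltages=voltages,
            spikes=spikes,
            rates={},
            labels=labels,
        )
        wanted = self.cfg.record
        for sid in self.net.node_ids("firing_rate_meter"):
            if wanted != "all" and sid not in wanted:
                continue
            targets = self.sensor_targets.get(sid)
            if not targets:
                continue
            sigma = self.net.nodes[sid].params.sigma_w
            rec.rates[sid] = rate_trace(
                [spikes[t] for t in targets], sigma, rec.times
            )
        return rec


def run(net: Network, cfg: SimulationConfig) -> RecordingSet:
    """Simulate ``net`` for ``cfg.duration`` from t = 0 and collect recordings.

    Deterministic given ``cfg.seed``: the same network and configuration
    produce bit-identical results.
    """
    return Simulation(net, cfg).run()
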
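# lifnet

A headless, scriptable simulator for small neural circuits built from leaky
integrate-and-fire (LIF) neurons, current-based synapses, stimulators and
recording devices. It is aimed at teaching and prototyping: the kind of
plug-and-play circuit one would sketch on a whiteboard — a touch-driven
inhibition gate, a feedback-inhibition gain controller, a
direction-selective array — can be built in a few lines of Python or loaded
from a JSON file, simulated deterministically, and probed with voltmeters,
spike detectors and firing-rate meters.

## The model

Each cell is a point neuron whose membrane potential `V` integrates currents
like an RC circuit:

```
C_m dV/dt = I_leak + I_syn + I_inj − I_adapt
I_leak    = −(V − V_r) / R_m,        τ_m = R_m C_m
```

When `V` reaches the threshold `V_thres` the cell fires, `V` is reset to
`V_reset` and pinned there for an absolute refractory period `τ_r`.
Optionally, a spike-frequency adaptation conductance `g_adapt` grows by
`Δg_adapt` at every spike, decays with time constant `τ_adapt`, and feeds the
hyperpolarizing current `I_adapt = g_adapt (V − V_r)`, so a sustained input
produces progressively longer inter-spike intervals.

Synapses are current-based: a presynaptic spike adds a signed jump `±Ī_syn`
to a per-edge current that decays exponentially with `τ_syn` (successive
spikes superpose linearly); the sign comes from the presynaptic cell's
excitatory/inhibitory polarity. Because current-based synapses impose no
intrinsic voltage bound, the membrane is clamped by default to
[−90, +60] mV, the K⁺ and Na⁺ reversal potentials (the clamp can be widened
or disabled).

Circuits can be driven by DC and sine-wave (AC) current sources, regular
(metronome) and Poisson spike generators, scheduled event sources (a
headless stand-in for touch input), and visual-input spike generators with
edge, difference-of-Gaussians or Gabor receptive fields applied to a
grayscale image. Integration is forward Euler at a fixed step
(default 0.1 ms); every stochastic element draws from one seeded stream, so
a run is exactly reproducible.

## Worked example

The direction-selective circuit: a row of touch-driven input cells project
to relay cells and to inhibitory cells; each inhibitory cell suppresses the
relay cell immediately to its right, so only a right-to-left sweep of
touches reaches the output cell.

```
$ lifnet demo fig9
direction_selectivity: output spikes: right-to-left 2, left-to-right 0, DSI 1.00 (0.34 s)
OK
```

The output cell fires twice for the preferred sweep and never for the null
sweep, a direction-selectivity index (preferred − null)/(preferred + null)
of 1.0 — complete null-direction suppression. The feedback-inhibition
circuit shows gain control the same way:

```
$ lifnet demo fig8
feedback_inhibition: rates (Hz): input 14.00, output 3.50, output without feedback 13.50 (0.91 s)
OK
```

With the inhibitory feedback loop intact the output fires at a quarter of
the input rate; cutting the loop restores it. Networks round-trip through
JSON and simulate from the command line:

```
$ lifnet motif direction_selectivity --save ds.json
direction_selectivity: 17 nodes (4 event_source, 13 neuron), 19 edges
saved to ds.json
$ lifnet validate ds.json
valid: 17 nodes (4 event_source, 13 neuron), 19 edges
$ lifnet run ds.json --duration 0.8 --out-dir out
...
wrote out/voltages.csv, out/spikes.csv, out/rates.csv
```

The same experiments are available as library calls
(`lifnet.motifs.run_direction_selectivity()` etc.), and arbitrary networks
are assembled with `Network.add` / `Network.connect` and executed with
`lifnet.run(net, SimulationConfig(...))`.

## Layout

- `src/lifnet/core.py` — membrane, adaptation, synapse and clamp update rules
- `src/lifnet/engine.py` — the stepping engine, event queue, recordings
- `src/lifnet/network.py` — the node/edge container and validation
- `src/lifnet/stimulators.py` — DC/AC sources, regular/Poisson/event generators
- `src/lifnet/receptive_fields.py` — edge/DoG/Gabor kernels and spike encoding
- `src/lifnet/sensors.py` — voltmeter rows, rasters, Gaussian rate meter, CSV
- `src/lifnet/netio.py` — versioned JSON format (+ JSON-Schema in `schemas/`)
- `src/lifnet/motifs.py`, `src/lifnet/cli.py` — reference circuits and the CLI
- `docs/methods.md` — modeling choices, defaults, and limitations
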
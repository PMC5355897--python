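# Methods

## Model

Neurons are leaky integrate-and-fire point cells: `C_m dV/dt = I_leak +
I_syn + I_inj − I_adapt` with `I_leak = −(V − V_r)/R_m`, hard threshold
`V_thres`, reset to `V_reset`, and an absolute refractory period `τ_r`
during which `V` is pinned to `V_reset` and membrane integration is
suspended (synaptic and adaptation state variables keep decaying).
Spike-frequency adaptation, when enabled, is a conductance `g_adapt` that
decays as `dg/dt = −g/τ_adapt`, is incremented by `Δg_adapt` at each spike,
and contributes `I_adapt = g_adapt (V − V_r)`. This term is *subtracted* in
the membrane equation: for a depolarized membrane it always opposes firing,
which is the defining property of an adaptation current; writing it with an
explicit minus sign keeps `g_adapt` and `Δg_adapt` nonnegative.

Synapses are current-based. Each edge carries a single current state
variable: a presynaptic spike adds the signed peak `±Ī_syn` and the state
decays exponentially with `τ_syn`. Successive spikes therefore superpose
linearly (the kernel convolution of the spike train), rather than resetting
the current to its peak; superposition preserves the linearity of the
subthreshold dynamics and is the standard convention for exponential
current-based synapses. The sign is a property of the *presynaptic* node —
cells and generators are excitatory or inhibitory — while the edge stores
only a nonnegative magnitude.

Because current-based synapses place no intrinsic bound on the membrane
potential, a clamp to [−90, +60] mV (the K⁺ and Na⁺ reversal potentials) is
applied after every integration step by default; it can be widened or
disabled per run.

## Numerics

Integration is forward Euler with a fixed step, default `dt = 1e-4 s`. The
scheme is first order (the test suite verifies that halving `dt` at least
halves the deviation from the closed-form subthreshold trajectory), and a
step is rejected up front if `dt` is not smaller than every `τ_syn` and
`τ_adapt` in the network (Euler stability). A non-finite membrane value
raises immediately, naming the offending node.

The engine's update order within one step is fixed: (1) deliver spike
events falling due as synaptic increments; (2) decay all edge currents; (3)
evaluate stimulators — current sources at the step's start time, spike
sources over the step's time bin; (4) integrate all neurons with summed
currents; (5) enqueue new fires with a per-edge delivery offset of
`max(1, round(delay/dt))` steps; (6) record sensors. The floor of one step
makes every synaptic effect strictly causal: a fire at step *k* first moves
any target at step *k+1*. Transmission delays are rounded to whole steps.
Simultaneous fires are processed in ascending node-id order — with the
one-step latency this has no observable effect, but it pins down
determinism.

Recording: the `t = 0` state is sampled before the first step, so a run of
*n* steps yields *n+1* samples. On a firing step the voltmeter records the
(clamped) threshold-crossing value reached *before* the reset — the trace
rises to threshold the way the membrane actually did — while the dynamical
state continues from `V_reset`; spikes themselves are recorded as event
times, never as voltage excursions. One consequence is that under a
saturating current the recorded maximum is the clamp ceiling exactly.

Randomness: one `numpy` generator seeded from the run configuration,
consumed in ascending node-id order (one uniform per stochastic node per
step), gives bit-identical repeats of any (network, config) pair.

## Defaults

| parameter | default | rationale |
|---|---|---|
| `R_m` | 1.0e8 Ω | canonical teaching value for a small cell |
| `C_m` | 1.0e-9 F | gives τ_m = 100 ms, a slow, visually legible membrane |
| `V_r`, `V_reset` | −65 mV | typical resting potential; reset at rest |
| `V_thres` | −50 mV | 15 mV threshold gap |
| `τ_r` | 2 ms | typical absolute refractory period |
| `Ī_syn` | 1.0e-9 A | one EPSP ≈ 7.7 mV peak: a few convergent inputs needed to fire |
| `τ_syn` | 10 ms | fast excitatory synapse scale |
| `Δg_adapt`, `τ_adapt` | 1.0e-9 S, 250 ms | visible ISI lengthening within ~10 spikes |
| clamp | [−90, +60] mV, enabled | ionic reversal potentials |
| `dt` | 0.1 ms | ≪ every default time constant; τ_m/1000 |

All defaults are overridable per node/edge and in the JSON format. The
threshold-demo circuit uses an artificial resting potential of 0 mV
(`V_r = V_reset = 0`, `V_thres = +15 mV`) so its traces read directly as
depolarization, as in classic textbook figures.

## Stimulators

DC and AC sources inject straight into `I_inj` and never enter the spike
event queue. The AC source is `A sin(2πft)` with phase 0 and no offset. The
regular generator accumulates elapsed time and fires when it exceeds `1/rate`,
then resets the accumulator to zero — the realized period is quantized up to
the next whole step, so a 10 Hz generator at `dt = 0.1 ms` emits 9–10 spikes
per second. The irregular generator is the per-step Bernoulli construction
of a homogeneous Poisson process (`p = rate·dt`, independent across steps);
the bias relative to exact exponential waiting times is O(rate·dt), a
warning is issued above `rate·dt = 0.1` and an error above 1. Touch input is
modeled as a pre-declared schedule of activation times; each activation
makes the event source fire once (activations within one step coalesce), and
the default event-source synapse is strong (10 nA) but brief (τ_syn = 2 ms)
so a single activation fires a resting default cell exactly once — the kick
has decayed away by the end of the target's refractory period.

## Receptive fields

The visual-input node applies a spatial kernel to a grayscale frame and
emits spikes. Responses are instantaneous — no temporal kernel — and the
response is the pixel-count-normalized inner product, so gains transfer
across grid sizes. Kernels:

- **edge**: +1/−1 half-planes split by a rotatable boundary through the grid
  center. On even-sized grids the ON and OFF areas are exactly equal (zero
  sum); on odd sizes they differ by one pixel row.
- **difference of Gaussians**: both Gaussians are normalized to unit
  discrete sum before subtraction, giving a balanced surround (zero response
  to uniform light); OFF-center is the exact negation of ON-center.
- **Gabor**: oriented Gaussian envelope times cosine carrier with the five
  standard parameters (orientation, σx, σy, wavelength, phase). Its uniform
  response is only approximately zero (≈1e-3 for the default σ = 3 px,
  λ = 6 px on a 21×21 grid).

Spike conversion is half-wave-rectified Bernoulli: fire probability
`min(1, max(0, response)·gain·dt)`, matching the Poisson generator's
construction. Frames are static for a run; time-varying stimuli are
expressed as scheduled event sources instead.

## Sensors

The firing-rate meter sums a unit-mass Gaussian (width `σ_w`) at each spike
time and averages over connected cells, so a regular f Hz train reads f Hz
and N identical cells read the same as one. The kernel is truncated at
±5σ_w (neglected mass < 1e-6). `rate_min`/`rate_max` are display bounds
only; stored values are never clipped. Spike detectors report rows of event
times restricted to a trailing window; voltmeters report labeled rows.

## File format

Documents have exactly four top-level keys — `fileFormatVersion` (= 3),
`nodes`, `edges`, `workspace` — with snake_case SI-unit properties per node,
defaults filling anything omitted, and free-form workspace metadata
preserved opaquely. Serialization is canonical (sorted keys, two-space
indent), so save → load → save is byte-identical, and a loaded network
simulates bit-identically to its source. Versions other than 3 are rejected
outright rather than guessed at. A JSON-Schema document ships in
`lifnet/schemas/`; validation is performed by explicit checks in `netio`
(clearer errors, no schema-library dependency). No byte compatibility with
any external file format is claimed. Visual-input frames are embedded as
nested float arrays, which is only sensible for the small grids this tool
targets.

## Reference circuits

The circuit topologies are fixed; all synaptic magnitudes and drive currents
were calibrated once by simulation to meet each circuit's behavioral
contract with margin, and are committed as named constants in
`lifnet.motifs` (the contracts themselves are locked in by tests, including
robustness of the spike counts to halving `dt`):

- **threshold demo**: drives of 0.1/0.2/0.3 nA against a 15 mV threshold
  gap give 0/14/28 spikes in 2 s.
- **summation**: one 1 nA EPSP peaks ≈ 7.7 mV (subthreshold); three
  synchronous inputs peak ≈ 23 mV and fire the output.
- **touch inhibition**: the inhibitory cell's slow synapse (3 nA, 50 ms)
  holds C below threshold when activated 20 ms before the excitatory path.
- **feedback inhibition**: a 0.3 nA DC drive yields a 14 Hz input rate; the
  Output→B→A loop cuts the output to 3.5 Hz, and removing the B→A edge
  restores 13.5 Hz.
- **direction selectivity** (4 columns, 0.1 s sweep interval): each
  inhibitory cell projects a strong, slow synapse (4 nA, 120 ms) one column
  rightward, arriving a full interval before the excitation it vetoes in the
  null direction; relay→output EPSPs (1.6 nA ≈ 12 mV) are individually
  subthreshold but summate across the sweep in the preferred direction. The
  default build yields 2 preferred-direction output spikes, 0 in the null
  direction — a direction-selectivity index of exactly 1.

## Problem sizes

The test suite and the reproduction script use second-scale runs at
`dt = 0.1 ms` (10⁴–2·10⁴ steps per simulation) for all circuit experiments,
and 100 s × 5 seeds of vectorized draws for Poisson statistics; the whole
suite completes in well under a minute on one core.

## Limitations

- Current-based synapses only; no conductance-based synapses, plasticity,
  or richer neuron models (Izhikevich, AdEx, Hodgkin–Huxley).
- Forward Euler, fixed step: accuracy is first order in `dt`, and spike
  times are quantized to the grid.
- The Bernoulli Poisson construction slightly underestimates rate variance
  at coarse `dt` (ISI CV ≈ √(1 − rate·dt)).
- Visual input is purely spatial and static per run.
- The generators and scheduled events are idealized stand-ins for recorded
  stimuli: passing the circuit contracts here demonstrates the mechanisms
  (summation, gating, gain control, direction selectivity) under clean,
  noise-free inputs, not performance on physiological spike trains.
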
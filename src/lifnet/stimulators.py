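"""Neuron activators: DC/AC current sources, regular and Poisson spike
generators, and a scheduled event source (headless stand-in for touch input).

Current sources inject directly into the membrane equation's I_inj and never
enter the spike event queue.  Spike generators fire like neurons and are
delivered through ordinary current-based synapse edges.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import Polarity

__all__ = [
    "CurrentSourceParams",
    "GeneratorParams",
    "EventSchedule",
    "dc_current",
    "ac_current",
    "regular_generator_step",
    "poisson_generator_step",
    "poisson_spike_train",
    "event_source_step",
]


@dataclass(frozen=True)
class CurrentSourceParams:
    """Amplitude (ampere) and, for AC, sine frequency (Hz; 0 means DC)."""

    amplitude: float = 2.0e-10
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be nonnegative")


@dataclass(frozen=True)
class GeneratorParams:
    """Spike-generator configuration plus the regular generator's phase state.

    ``time_since_fire`` accumulates simulated time for the regular generator;
    the Poisson generator ignores it.
    """

    rate: float = 10.0
    polarity: Polarity = Polarity.EXCITATORY
    time_since_fire: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")
        if isinstance(self.polarity, str) and not isinstance(self.polarity, Polarity):
            object.__setattr__(self, "polarity", Polarity(self.polarity))


@dataclass(frozen=True)
class EventSchedule:
    """Pre-declared activation times (second) for a touch-like event source."""

    activation_times: tuple = ()
    polarity: Polarity = Polarity.EXCITATORY

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.activation_times)
        if any(t < 0 for t in times):
            raise ValueError("activation times must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("activation times must be strictly increasing")
        object.__setattr__(self, "activation_times", times)
        if isinstance(self.polarity, str) and not isinstance(self.polarity, Polarity):
            object.__setattr__(self, "polarity", Polarity(self.polarity))


def dc_current(params: CurrentSourceParams, t: float) -> float:
    """Constant injected current, independent of time (ampere)."""
    return params.amplitude


def ac_current(params: CurrentSourceParams, t: float) -> float:
    """Sine-wave injected current amplitude*sin(2*pi*f*t) (ampere)."""
    return params.amplitude * math.sin(2.0 * math.pi * params.frequency * t)


def regular_generator_step(state: GeneratorParams, dt: float) -> tuple[GeneratorParams, bool]:
    """Advance the metronome-like generator by ``dt``.

    Accumulates time since the last fire and fires when it exceeds the period
    1/rate, then resets the accumulator to zero (so the realized period is
    quantized up to the next whole step).  ``rate == 0`` never fires.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    elapsed = state.time_since_fire + dt
    if state.rate > 0 and elapsed > 1.0 / state.rate:
        return replace(state, time_since_fire=0.0), True
    return replace(state, time_since_fire=elapsed), False


def poisson_generator_step(params: GeneratorParams, dt: float, rng: np.random.Generator) -> bool:
    """One Bernoulli trial of the homogeneous Poisson process: fire with
    probability rate*dt, independently across steps."""
    p = params.rate * dt
    if p > 1.0:
        raise ValueError(
            f"rate*dt = {p:.3g} exceeds 1; reduce dt or the rate"
        )
    if p > 0.1:
        warnings.warn(
            f"rate*dt = {p:.3g} > 0.1: the per-step Bernoulli approximation "
            "of the Poisson process is biased at this resolution",
            stacklevel=2,
        )
    return bool(rng.random() < p)


def poisson_spike_train(
    rate: float, duration: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Bernoulli-per-step Poisson train; returns spike times (s).

    Equivalent to calling :func:`poisson_generator_step` once per step, with
    spike times placed at the end of the firing step.
    """
    p = rate * dt
    if p > 1.0:
        raise ValueError(f"rate*dt = {p:.3g} exceeds 1; reduce dt or the rate")
    n_steps = int(math.ceil(duration / dt))
    fired = rng.random(n_steps) < p
    return (np.flatnonzero(fired) + 1) * dt


def event_source_step(schedule: EventSchedule, t: float, dt: float) -> bool:
    """True iff some scheduled activation lies in the half-open bin (t-dt, t].

    Multiple activations inside one bin coalesce into a single fire.
    """
    times = schedule.activation_times
    lo = bisect.bisect_right(times, t - dt)
    hi = bisect.bisect_right(times, t)
    return hi > lo
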
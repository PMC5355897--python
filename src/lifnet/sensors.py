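"""Measurement items: voltmeter rows, spike-detector rasters, and the
Gaussian-window firing-rate meter, plus CSV writers and optional plots.

Spikes are recorded as event times, never as voltage excursions; the voltage
trace of a firing cell rises to threshold and drops back to the reset value
(any vertical "spike line" is purely a rendering choice).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "RateMeterParams",
    "gaussian_rate",
    "rate_trace",
    "spike_raster",
    "voltage_rows",
    "write_voltages_csv",
    "write_spikes_csv",
    "write_rates_csv",
    "plot_voltages",
]

#: The Gaussian window is truncated at +/- this many sigma; the neglected
#: tail mass is < 1e-6 of a unit-mass spike kernel.
TRUNCATION_SIGMA = 5.0


@dataclass(frozen=True)
class RateMeterParams:
    """Gaussian rate-meter configuration.

    ``sigma_w`` is the smoothing window width (second).  ``rate_min`` and
    ``rate_max`` are display bounds only — stored values are never clipped.
    """

    sigma_w: float = 0.1
    rate_min: float = 0.0
    rate_max: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be positive")
        if self.rate_min >= self.rate_max:
            raise ValueError("rate_min must be below rate_max")


def gaussian_rate(
    spike_trains: Sequence[Sequence[float]], sigma_w: float, t: float
) -> float:
    """Population firing rate at time ``t`` (Hz).

    Each spike contributes a unit-mass Gaussian of width ``sigma_w``; trains
    are averaged (not summed), so N identical trains read the same as one.
    """
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    if len(spike_trains) == 0:
        raise ValueError("rate meter is not connected to any spike train")
    norm = 1.0 / (math.sqrt(2.0 * math.pi) * sigma_w)
    cutoff = TRUNCATION_SIGMA * sigma_w
    total = 0.0
    for train in spike_trains:
        for ts in train:
            d = t - ts
            if abs(d) <= cutoff:
                total += norm * math.exp(-(d * d) / (2.0 * sigma_w * sigma_w))
    return total / len(spike_trains)


def rate_trace(
    spike_trains: Sequence[Sequence[float]], sigma_w: float, times: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`gaussian_rate` over a whole time grid."""
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    if len(spike_trains) == 0:
        raise ValueError("rate meter is not connected to any spike train")
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    norm = 1.0 / (math.sqrt(2.0 * math.pi) * sigma_w)
    cutoff = TRUNCATION_SIGMA * sigma_w
    inv_two_s2 = 1.0 / (2.0 * sigma_w * sigma_w)
    for train in spike_trains:
        for ts in train:
            lo = np.searchsorted(times, ts - cutoff, side="left")
            hi = np.searchsorted(times, ts + cutoff, side="right")
            if hi > lo:
                d = times[lo:hi] - ts
                out[lo:hi] += norm * np.exp(-d * d * inv_two_s2)
    return out / len(spike_trains)


def _label_for(recordings, node_id):
    label = recordings.labels.get(node_id)
    return label if label else str(node_id)


def spike_raster(recordings, ids: Sequence[int], window: Optional[float] = None):
    """Rows of spike times (trailing ``window`` seconds), in the given order.

    Returns a list of (label, times) pairs; the label is the node's label
    when present, otherwise its id.
    """
    rows = []
    t_end = float(recordings.times[-1]) if len(recordings.times) else 0.0
    for nid in ids:
        if nid not in recordings.spikes:
            raise KeyError(f"no spike recording for node {nid}")
        times = recordings.spikes[nid]
        if window is not None:
            times = [t for t in times if t > t_end - window]
        rows.append((_label_for(recordings, nid), list(times)))
    return rows


def voltage_rows(recordings, ids: Sequence[int]):
    """Rows of voltage series, one per requested node, labels attached."""
    rows = []
    for nid in ids:
        if nid not in recordings.voltages:
            raise KeyError(f"no voltage recording for node {nid}")
        rows.append((_label_for(recordings, nid), recordings.voltages[nid]))
    return rows


# --- CSV writers -----------------------------------------------------------


def write_voltages_csv(recordings, path) -> None:
    """One wide CSV: time column plus one voltage column per recorded node."""
    ids = sorted(recordings.voltages)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + [_label_for(recordings, i) for i in ids])
        for k, t in enumerate(recordings.times):
            w.writerow([f"{t:.6g}"] + [repr(float(recordings.voltages[i][k])) for i in ids])


def write_spikes_csv(recordings, path) -> None:
    """Two-column CSV of (node_id, spike_time), ordered by time then id."""
    events = []
    for nid, train in recordings.spikes.items():
        events.extend((t, nid) for t in train)
    events.sort()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "time_s"])
        for t, nid in events:
            w.writerow([nid, f"{t:.6g}"])


def write_rates_csv(recordings, path) -> None:
    """Time column plus one rate column (Hz) per firing-rate meter."""
    ids = sorted(recordings.rates)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + [_label_for(recordings, i) for i in ids])
        for k, t in enumerate(recordings.times):
            w.writerow([f"{t:.6g}"] + [repr(float(recordings.rates[i][k])) for i in ids])


def plot_voltages(recordings, ids: Sequence[int], path, spike_lines: bool = True) -> None:
    """Save stacked voltage-trace rows (mV) as a PNG; optional vertical
    markers at spike times, drawn for illustration only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = voltage_rows(recordings, ids)
    fig, axes = plt.subplots(len(rows), 1, sharex=True, squeeze=False, figsize=(8, 2 * len(rows)))
    for ax, (label, series), nid in zip(axes[:, 0], rows, ids):
        ax.plot(recordings.times, np.asarray(series) * 1e3, lw=0.8)
        if spike_lines:
            for ts in recordings.spikes.get(nid, []):
                ax.axvline(ts, color="k", lw=0.6, alpha=0.6)
        ax.set_ylabel(f"{label}\nV (mV)")
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
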
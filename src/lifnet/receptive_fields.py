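"""Visual-input encoding: parametric spatial receptive-field kernels and the
conversion of instantaneous image responses into spikes.

Three kernel families are provided, mirroring classic receptive fields along
the early visual pathway:

* ``edge`` — two adjacent rectangular ON (+1) and OFF (-1) half-planes at an
  adjustable orientation (an idealized edge detector).
* ``dog`` — circular center-surround as a difference of two Gaussians, the
  receptive field type of retinal ganglion and LGN cells; ON- or OFF-center.
* ``gabor`` — oriented Gaussian envelope times a cosine carrier, the
  orientation-selective receptive field of primary visual cortex.

Responses are purely instantaneous (no temporal kernel): the response at time
t depends only on the frame shown at t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ReceptiveFieldKernel",
    "VisualStimulus",
    "make_edge_kernel",
    "make_dog_kernel",
    "make_gabor_kernel",
    "field_response",
    "encode_response",
    "load_image",
    "grating",
    "uniform_stimulus",
    "step_edge_stimulus",
]


def _centered_grid(H: int, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates with the origin at the grid center.

    x increases rightward (columns), y increases upward (toward row 0).
    """
    ys = (H - 1) / 2.0 - np.arange(H)
    xs = np.arange(W) - (W - 1) / 2.0
    return np.meshgrid(xs, ys)  # x[H,W], y[H,W]


@dataclass(frozen=True)
class ReceptiveFieldKernel:
    """Signed spatial weight grid plus the parameters that generated it."""

    kind: str  # "edge" | "dog" | "gabor"
    grid: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("kernel grid must be 2-D")
        if not np.all(np.isfinite(g)):
            raise ValueError("kernel grid must be finite")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class VisualStimulus:
    """A grayscale frame with intensities in [0, 1]."""

    image: np.ndarray

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("stimulus must be a 2-D grayscale image")
        if img.size and (img.min() < -1e-9 or img.max() > 1 + 1e-9):
            raise ValueError("stimulus intensities must lie in [0, 1]")
        object.__setattr__(self, "image", img)


def make_edge_kernel(H: int, W: int, orientation: float = 0.0) -> ReceptiveFieldKernel:
    """Rectangular edge detector: +1 on the ON half-plane, -1 on the OFF.

    ``orientation`` rotates the ON/OFF boundary; at 0 the ON region is the
    top half.  Rotating by pi swaps ON and OFF.
    """
    if H < 2 or W < 2:
        raise ValueError("edge kernel needs H, W >= 2")
    x, y = _centered_grid(H, W)
    # signed distance along the rotated "up" axis; >= 0 is the ON side
    d = y * np.cos(orientation) - x * np.sin(orientation)
    grid = np.where(d >= 0, 1.0, -1.0)
    return ReceptiveFieldKernel("edge", grid, {"orientation": float(orientation)})


def make_dog_kernel(
    H: int,
    W: int,
    sigma_center: float,
    sigma_surround: float,
    on_center: bool = True,
) -> ReceptiveFieldKernel:
    """Center-surround kernel: difference of two unit-sum Gaussians.

    Both Gaussians are normalized to unit discrete sum, so the kernel sums to
    (numerically) zero — a balanced surround with no response to uniform
    illumination.  The OFF-center kernel is the elementwise negation of the
    ON-center one.
    """
    if not sigma_center < sigma_surround:
        raise ValueError(
            f"sigma_center ({sigma_center}) must be smaller than "
            f"sigma_surround ({sigma_surround})"
        )
    x, y = _centered_grid(H, W)
    r2 = x * x + y * y

    def unit_gaussian(sigma: float) -> np.ndarray:
        g = np.exp(-r2 / (2.0 * sigma * sigma))
        return g / g.sum()

    grid = unit_gaussian(sigma_center) - unit_gaussian(sigma_surround)
    if not on_center:
        grid = -grid
    return ReceptiveFieldKernel(
        "dog",
        grid,
        {
            "sigma_center": float(sigma_center),
            "sigma_surround": float(sigma_surround),
            "on_center": bool(on_center),
        },
    )


def make_gabor_kernel(
    H: int,
    W: int,
    orientation: float = 0.0,
    sigma_x: float = 3.0,
    sigma_y: float = 3.0,
    wavelength: float = 6.0,
    phase: float = 0.0,
) -> ReceptiveFieldKernel:
    """Oriented Gabor kernel: Gaussian envelope times cosine carrier.

    w(x, y) = exp(-x'^2/2sx^2 - y'^2/2sy^2) * cos(2 pi x'/lambda + phase)
    with (x', y') the pixel coordinates rotated by ``orientation`` about the
    grid center.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    x, y = _centered_grid(H, W)
    xr = x * np.cos(orientation) + y * np.sin(orientation)
    yr = -x * np.sin(orientation) + y * np.cos(orientation)
    envelope = np.exp(-(xr**2) / (2 * sigma_x**2) - (yr**2) / (2 * sigma_y**2))
    carrier = np.cos(2.0 * np.pi * xr / wavelength + phase)
    return ReceptiveFieldKernel(
        "gabor",
        envelope * carrier,
        {
            "orientation": float(orientation),
            "sigma_x": float(sigma_x),
            "sigma_y": float(sigma_y),
            "wavelength": float(wavelength),
            "phase": float(phase),
        },
    )


_KERNEL_FACTORIES = {
    "edge": lambda H, W, p: make_edge_kernel(H, W, p.get("orientation", 0.0)),
    "dog": lambda H, W, p: make_dog_kernel(
        H, W, p["sigma_center"], p["sigma_surround"], p.get("on_center", True)
    ),
    "gabor": lambda H, W, p: make_gabor_kernel(
        H,
        W,
        p.get("orientation", 0.0),
        p.get("sigma_x", 3.0),
        p.get("sigma_y", 3.0),
        p.get("wavelength", 6.0),
        p.get("phase", 0.0),
    ),
}


def make_kernel(kind: str, H: int, W: int, params: Optional[dict] = None) -> ReceptiveFieldKernel:
    """Build a kernel by kind name from a parameter dict (used by netio)."""
    try:
        factory = _KERNEL_FACTORIES[kind]
    except KeyError:
        raise ValueError(f"unknown receptive-field kind: {kind!r}") from None
    return factory(H, W, params or {})


def field_response(kernel: ReceptiveFieldKernel, stim: VisualStimulus) -> float:
    """Instantaneous response: mean over pixels of weight * intensity.

    Normalizing by pixel count keeps gains transferable across grid sizes.
    """
    if kernel.grid.shape != stim.image.shape:
        raise ValueError(
            f"kernel shape {kernel.grid.shape} != stimulus shape {stim.image.shape}"
        )
    return float(np.sum(kernel.grid * stim.image) / kernel.grid.size)


def encode_response(
    response: float, gain: float, dt: float, rng: np.random.Generator
) -> bool:
    """Half-wave-rectified Bernoulli spike conversion.

    Fires with probability min(1, max(0, response) * gain * dt); negative
    responses never fire.  ``gain`` is in Hz per unit response.
    """
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    p = min(1.0, max(0.0, response) * gain * dt)
    return bool(rng.random() < p)


# --- stimulus helpers ------------------------------------------------------


def load_image(path) -> VisualStimulus:
    """Load a grayscale PNG (or any PIL-readable image) scaled into [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return VisualStimulus(arr)


def uniform_stimulus(H: int, W: int, intensity: float = 0.5) -> VisualStimulus:
    """Spatially uniform frame."""
    return VisualStimulus(np.full((H, W), float(intensity)))


def step_edge_stimulus(H: int, W: int, bright_top: bool = True) -> VisualStimulus:
    """Horizontal luminance step: bright half and dark half."""
    img = np.zeros((H, W))
    img[: H // 2, :] = 1.0
    if not bright_top:
        img = 1.0 - img
    return VisualStimulus(img)


def grating(
    H: int, W: int, orientation: float, wavelength: float, phase: float = 0.0
) -> VisualStimulus:
    """Sinusoidal luminance grating in [0, 1] at the given orientation."""
    x, y = _centered_grid(H, W)
    xr = x * np.cos(orientation) + y * np.sin(orientation)
    img = 0.5 + 0.5 * np.cos(2.0 * np.pi * xr / wavelength + phase)
    return VisualStimulus(img)
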
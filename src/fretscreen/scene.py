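"""Optical scene model: a trapped worm head with one fluorescent neuron.

The virtual instrument renders the labelled neuron as a 2-D Gaussian spot on
top of worm-body fluorescence and a constant camera offset.  Defocus widens
the spot linearly with distance from the true focal plane while conserving
its integrated intensity (energy-preserving blur), which makes any
sharpness- or correlation-based focus metric unimodal in z.

Channel split: the donor and acceptor images share identical geometry; a
per-channel scale factor (the donor/acceptor partition of the current FRET
ratio, times the photobleaching envelope) multiplies the fluorescent signal.
The camera offset is unpartitioned and common to both channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .regions import Rect

__all__ = [
    "SceneParams",
    "BleachModel",
    "NoiseConfig",
    "render_frame",
    "make_template",
    "EXPRESSION_SCALE",
]

# brightness multiplier per expression class (dim / normal / bright worms)
EXPRESSION_SCALE = {"dim": 0.2, "normal": 1.0, "bright": 4.0}


@dataclass(frozen=True)
class BleachModel:
    """Per-channel exponential photobleaching rates (1/s, >= 0)."""

    lambda_donor: float = 0.004
    lambda_acceptor: float = 0.0015

    def __post_init__(self) -> None:
        if self.lambda_donor < 0 or self.lambda_acceptor < 0:
            raise ValueError("bleach rates must be >= 0")

    def factors(self, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        return np.exp(-self.lambda_donor * t), np.exp(-self.lambda_acceptor * t)


@dataclass(frozen=True)
class NoiseConfig:
    """Camera noise: Poisson shot noise on expected counts + Gaussian read noise."""

    enabled: bool = True
    poisson: bool = True
    read_noise_sd: float = 3.0


@dataclass(frozen=True)
class SceneParams:
    """Geometry and photometry of one trapped worm.

    The image is a top-down view of the trap channel; the worm body is a
    horizontal band across the frame, the head pointing left when loaded
    head-first.  Distances are in pixels unless suffixed ``_um``.
    """

    width: int = 160
    height: int = 100
    pixel_size_um: float = 0.4
    neuron_x: float = 28.0
    neuron_y: float = 50.0
    z_true_um: float = 50.0
    amp_total: float = 3000.0       # donor+acceptor peak counts at focus
    sigma0_px: float = 2.0          # spot width at focus
    defocus_px_per_um: float = 0.25 # width growth per um of defocus
    body_level: float = 80.0        # worm-body fluorescence counts
    body_rows: tuple[int, int] = (35, 65)
    camera_offset: float = 100.0
    orientation: str = "head_first"   # head_first | tail_first
    viability: str = "alive"          # alive | dead
    expression: str = "normal"        # dim | normal | bright
    z_range_um: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.sigma0_px <= 0 or self.defocus_px_per_um < 0:
            raise ValueError("spot widths must be positive")
        if self.amp_total < 0 or self.body_level < 0 or self.camera_offset < 0:
            raise ValueError("brightness must be >= 0")
        if not (self.z_range_um[0] <= self.z_true_um <= self.z_range_um[1]):
            raise ValueError(
                f"z_true_um={self.z_true_um} outside configured z range {self.z_range_um}"
            )
        if self.orientation not in ("head_first", "tail_first"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.expression not in EXPRESSION_SCALE:
            raise ValueError(f"unknown expression class {self.expression!r}")

    # --- default analysis regions tied to the trap geometry -----------------

    def head_region(self) -> Rect:
        return Rect(4, 28, self.width // 2 - 16, 72)

    def tail_region(self) -> Rect:
        return Rect(self.width // 2 + 16, 28, self.width - 4, 72)

    def background_region(self) -> Rect:
        return Rect(4, 4, 36, 24)   # above the body band

    def entry_region(self) -> Rect:
        return Rect(self.width - 30, 38, self.width - 4, 62)

    def body_mask(self) -> np.ndarray:
        mask = np.zeros((self.height, self.width), dtype=float)
        mask[self.body_rows[0] : self.body_rows[1], :] = 1.0
        return mask

    def amplitude(self) -> float:
        return self.amp_total * EXPRESSION_SCALE[self.expression]

    def flipped(self) -> "SceneParams":
        """Same worm loaded tail-first: the neuron mirrors to the far side."""
        return replace(self, neuron_x=self.width - 1 - self.neuron_x, orientation="tail_first")


def _gaussian_spot(
    shape: tuple[int, int], x0: float, y0: float, sigma: float, amp: float
) -> np.ndarray:
    h, w = shape
    y = np.arange(h, dtype=float)[:, None]
    x = np.arange(w, dtype=float)[None, :]
    return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma * sigma))


def render_frame(
    scene: SceneParams,
    z_offset_um: float,
    bleach_factor: tuple[float, float] = (1.0, 1.0),
    channel_scale: tuple[float, float] = (1.0, 1.0),
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one donor/acceptor frame pair.

    Parameters
    ----------
    z_offset_um : distance of the imaging plane from the neuron's true focus.
    bleach_factor : per-channel photobleach envelope (donor, acceptor).
    channel_scale : per-channel partition of the fluorescent signal, e.g.
        ``(1/(1+R), R/(1+R))`` for FRET ratio ``R``.
    noise : ``NoiseConfig``; ``None`` or ``enabled=False`` renders noise-free.
    rng : required when noise is enabled (reproducibility).

    Returns
    -------
    (donor, acceptor) float64 images of shape (height, width).
    """
    sigma = scene.sigma0_px + scene.defocus_px_per_um * abs(z_offset_um)
    if sigma <= 0:
        raise ValueError("non-positive spot width")
    amp = scene.amplitude() * (scene.sigma0_px / sigma) ** 2
    signal = scene.body_mask() * scene.body_level
    if scene.amplitude() > 0:
        signal = signal + _gaussian_spot(
            (scene.height, scene.width), scene.neuron_x, scene.neuron_y, sigma, amp
        )

    out = []
    for c in range(2):
        expected = scene.camera_offset + bleach_factor[c] * channel_scale[c] * signal
        if noise is not None and noise.enabled:
            if rng is None:
                raise ValueError("rng required when noise is enabled")
            img = expected.astype(float)
            if noise.poisson:
                img = rng.poisson(np.clip(expected, 0, None)).astype(float)
            if noise.read_noise_sd > 0:
                img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
            expected = np.clip(img, 0, None)
        out.append(expected)
    return out[0], out[1]


def make_template(sigma_px: float = 2.0, size: int = 17, amp: float = 1000.0) -> np.ndarray:
    """Synthesize an in-focus neuron template: a centred Gaussian spot.

    Stands in for the operator-drawn template box around a focused neuron.
    Correlation matching is intensity-normalized, so ``amp`` is arbitrary.
    """
    if size % 2 == 0:
        raise ValueError("template size must be odd")
    c = size // 2
    return _gaussian_spot((size, size), c, c, sigma_px, amp)
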
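"""Computer-vision layer: locate the labelled neuron and reject unusable worms.

Responsibilities mirror the acquisition software of an automated worm-trap
imager: recognize that a worm entered the trap, decide head-to-tail
orientation from the position of the fluorescently labelled neuron, sweep z
to bring the neuron into focus, and flag worms that are too dim or too
bright to quantify.

Template matching uses zero-normalized cross-correlation (ZNCC): patches are
mean-subtracted and norm-divided, so scores live on a fixed [-1, 1] scale
that is invariant to additive offsets and multiplicative gain — this is what
makes a single correlation threshold (default 0.5) meaningful across worms
of different brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage import filters, measure

from .regions import Rect
from .stacks import ChannelStack

__all__ = [
    "NeuronTemplate",
    "DetectionConfig",
    "DetectionResult",
    "detect_entry",
    "match_template_ncc",
    "autofocus_z",
    "detect_neuron_edge",
    "classify_orientation",
    "qc_brightness",
]

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class NeuronTemplate:
    """A small acceptor-channel patch around a focused neuron."""

    patch: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.patch, dtype=float)
        if p.ndim != 2:
            raise ValueError("template must be a 2-D patch")
        if np.ptp(p) == 0:
            raise ValueError("constant-valued template has no correlation structure")
        object.__setattr__(self, "patch", p)


@dataclass
class DetectionConfig:
    """Tunable parameters of the detection layer.

    ``corr_threshold`` is the ZNCC score below which a plane does not count
    as containing the neuron; if every plane of a z sweep falls below it the
    worm is rejected as ``neuron_not_found``.  The threshold is exposed
    because it must be adapted to the age (hence brightness and shape) of
    the imaged cohort.
    """

    entry_threshold: float = 50.0          # counts above background
    corr_threshold: float = 0.5            # ZNCC in [0, 1]
    mode: str = "template"                 # template | edge
    z_range_um: tuple[float, float] = (0.0, 100.0)
    brightness_bounds: tuple[float, float] = (500.0, 2500.0)  # ROI mean counts
    match_channel: str = "acceptor"
    min_blob_px: int = 4
    max_blob_px: int = 1000
    track_radius_px: int = 5
    track_score_floor: float = 0.2
    roi_radius_px: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("correlation threshold must lie in [0, 1]")
        if self.mode not in ("template", "edge"):
            raise ValueError(f"unknown detection mode {self.mode!r}")
        lo, hi = self.brightness_bounds
        if lo >= hi:
            raise ValueError("brightness bounds must be ordered low < high")


@dataclass
class DetectionResult:
    """Outcome of entry/orientation/autofocus for one worm."""

    status: str                       # head_loaded | tail_loaded | neuron_not_found | no_worm
    x: int | None = None
    y: int | None = None
    z_index: int | None = None
    scores: np.ndarray | None = None  # best ZNCC per z plane
    brightness_qc: str = "pass"

    def __post_init__(self) -> None:
        if self.status == "head_loaded" and (self.x is None or self.y is None):
            raise ValueError("head_loaded results must carry a neuron position")


def detect_entry(
    frame: np.ndarray, entry_region: Rect, background_region: Rect, threshold: float
) -> bool:
    """True iff the entry region is brighter than background by ``threshold``.

    Emulates the trap-entry cut-off: the worm body's autofluorescence raises
    the mean of the entry window relative to an empty background window.
    """
    if entry_region.overlaps(background_region):
        raise ValueError("entry and background regions must be disjoint")
    frame = np.asarray(frame, dtype=float)
    for r in (entry_region, background_region):
        if not r.inside(frame.shape):
            raise ValueError(f"region {r} outside image {frame.shape}")
    return float(entry_region.crop(frame).mean() - background_region.crop(frame).mean()) > threshold


def _zncc_map(region: np.ndarray, template: np.ndarray) -> np.ndarray:
    """ZNCC score for every admissible template placement inside ``region``.

    Returns an array of shape (H-h+1, W-w+1); windows with (near) zero
    variance score 0 by convention.
    """
    t = np.asarray(template, dtype=float)
    region = np.asarray(region, dtype=float)
    h, w = t.shape
    if region.shape[0] < h or region.shape[1] < w:
        raise ValueError(
            f"template {t.shape} does not fit inside search region {region.shape}"
        )
    t0 = t - t.mean()
    tnorm = float(np.sqrt((t0 * t0).sum()))
    if tnorm * tnorm <= _VAR_TOL:
        raise ValueError("constant-valued template rejected")
    windows = sliding_window_view(region, (h, w))
    wmean = windows.mean(axis=(-2, -1))
    centered = windows - wmean[..., None, None]
    wnorm2 = np.einsum("ijkl,ijkl->ij", centered, centered)
    num = np.einsum("ijkl,kl->ij", centered, t0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = num / (np.sqrt(wnorm2) * tnorm)
    scores[wnorm2 <= _VAR_TOL] = 0.0
    return scores


def match_template_ncc(
    image: np.ndarray,
    template: NeuronTemplate | np.ndarray,
    search_region: Rect | None = None,
) -> tuple[int, int, float]:
    """Best ZNCC match of ``template`` inside ``search_region`` of ``image``.

    Returns ``(x, y, score)`` with (x, y) the centre pixel of the best
    placement in full-image coordinates.  Ties are broken toward the
    smallest (y, then x), which row-major argmax provides.
    """
    patch = template.patch if isinstance(template, NeuronTemplate) else np.asarray(template, float)
    image = np.asarray(image, dtype=float)
    if search_region is None:
        search_region = Rect(0, 0, image.shape[1], image.shape[0])
    if not search_region.inside(image.shape):
        raise ValueError(f"search region {search_region} outside image {image.shape}")
    scores = _zncc_map(search_region.crop(image), patch)
    flat = int(np.argmax(scores))
    iy, ix = np.unravel_index(flat, scores.shape)
    h, w = patch.shape
    x = search_region.x0 + int(ix) + w // 2
    y = search_region.y0 + int(iy) + h // 2
    return x, y, float(scores[iy, ix])


def autofocus_z(
    zstack: ChannelStack,
    template: NeuronTemplate | np.ndarray,
    config: DetectionConfig,
    search_region: Rect | None = None,
) -> DetectionResult:
    """Sweep the z stack, score each plane by its best ZNCC match, pick the focus.

    The chosen plane ``z*`` is the argmax of the per-plane score vector
    (ties resolve to the lowest z).  If every score falls below the
    correlation threshold the worm is rejected as ``neuron_not_found``.
    """
    if zstack.axis != "z":
        raise ValueError("autofocus requires a z stack")
    if zstack.n_frames < 2:
        raise ValueError("autofocus needs at least 2 planes")
    frames = zstack.channel(config.match_channel)
    scores = np.empty(zstack.n_frames)
    positions = []
    for i in range(zstack.n_frames):
        x, y, s = match_template_ncc(frames[i], template, search_region)
        scores[i] = s
        positions.append((x, y))
    if np.all(scores < config.corr_threshold):
        return DetectionResult(status="neuron_not_found", scores=scores)
    z = int(np.argmax(scores))
    x, y = positions[z]
    return DetectionResult(status="head_loaded", x=x, y=y, z_index=z, scores=scores)


def detect_neuron_edge(
    image: np.ndarray, search_region: Rect, config: DetectionConfig
) -> tuple[float, float] | None:
    """Edge-based neuron detection for young, small worms.

    Chain: Sobel gradient magnitude -> Otsu threshold on the region ->
    connected components -> centroid of the component maximizing
    (mean intensity x area) within the configured size bounds.
    Returns full-image (x, y) or ``None`` when nothing qualifies.
    """
    image = np.asarray(image, dtype=float)
    if not search_region.inside(image.shape):
        raise ValueError("search region outside image")
    if search_region.width * search_region.height < config.min_blob_px:
        raise ValueError("search region smaller than the minimum blob size")
    sub = search_region.crop(image)
    grad = filters.sobel(sub)
    if np.ptp(grad) == 0:
        return None
    mask = grad > filters.threshold_otsu(grad)
    labels = measure.label(mask)
    best, best_score = None, -np.inf
    for prop in measure.regionprops(labels, intensity_image=sub):
        if not (config.min_blob_px <= prop.area <= config.max_blob_px):
            continue
        score = prop.intensity_mean * prop.area
        if score > best_score:
            best, best_score = prop, score
    if best is None:
        return None
    cy, cx = best.centroid_weighted
    return search_region.x0 + float(cx), search_region.y0 + float(cy)


def classify_orientation(
    obj: ChannelStack | np.ndarray,
    head_region: Rect,
    tail_region: Rect,
    config: DetectionConfig,
    template: NeuronTemplate | np.ndarray | None = None,
) -> str:
    """Decide loading orientation: ``head`` | ``tail`` | ``none``.

    The configured detector runs in the head-side region first; success
    means the worm loaded head-first.  Otherwise the tail-side region is
    tried; success there means a tail entry (the worm gets flushed).
    ``obj`` is either the z stack (template mode sweeps it per region) or a
    single image.
    """
    if head_region.overlaps(tail_region):
        raise ValueError("head and tail regions must be disjoint")

    def found(region: Rect) -> bool:
        if config.mode == "edge":
            img = obj.channel(config.match_channel).max(axis=0) if isinstance(obj, ChannelStack) else obj
            return detect_neuron_edge(img, region, config) is not None
        if template is None:
            raise ValueError("template mode requires a template")
        if isinstance(obj, ChannelStack):
            return autofocus_z(obj, template, config, region).status == "head_loaded"
        _, _, s = match_template_ncc(obj, template, region)
        return s >= config.corr_threshold

    if found(head_region):
        return "head"
    if found(tail_region):
        return "tail"
    return "none"


def qc_brightness(roi_mean: float, bounds: tuple[float, float]) -> str:
    """Three-way brightness gate on the neuron ROI mean: worms far outside the
    typical expression range do not yield measurable responses."""
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("brightness bounds must be ordered low < high")
    if roi_mean < lo:
        return "too_dim"
    if roi_mean > hi:
        return "too_bright"
    return "pass"
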
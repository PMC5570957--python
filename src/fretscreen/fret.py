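"""FRET calcium-transient quantification.

Turns a recorded dual-channel time series (or a pre-extracted donor/acceptor
intensity pair) into a photobleach-corrected percent-change ratio trace and
two scalar metrics of the stimulus-evoked transient's rising phase:

* **peak** — the maximum percent change of the ratio from its pre-stimulus
  baseline, a proxy for the total calcium entering the cell;
* **slope** — the rate of percent change during the rise (a 10-90% linear
  fit), a proxy for the speed of depolarization.

The ratio is oriented acceptor/donor so that calcium influx *raises* it
(FRET-increase sensors such as TN-XL).  Photobleaching is compensated per
channel with a mono-exponential fit on the pre-stimulus window, because the
two fluorophores bleach at different rates and uncorrected ratios drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionConfig, NeuronTemplate, match_template_ncc
from .kinetics import ResponseKinetics, ideal_ratio
from .regions import Rect
from .stacks import ChannelStack

__all__ = [
    "QuantConfig",
    "FretTrace",
    "TransientMetrics",
    "track_neuron",
    "extract_trace",
    "correct_bleach",
    "percent_change",
    "rising_phase",
    "compute_metrics",
    "quantify_trace",
    "metrics_from_ideal",
]


@dataclass(frozen=True)
class QuantConfig:
    """Windows and thresholds of the quantification stage (times in seconds).

    ``baseline_window`` (percent-change reference) defaults to the final
    10 s of the 40 s pre-stimulation phase, after light-response settling;
    ``bleach_window`` (exponential-fit support) defaults to the whole
    pre-stimulus phase for a steadier rate estimate.
    """

    t_on: float = 40.0
    t_off: float = 70.0
    baseline_window: tuple[float, float] = (30.0, 40.0)
    bleach_window: tuple[float, float] = (0.0, 40.0)
    grace_s: float = 5.0               # peaks may lag stimulus offset
    responder_threshold_pct: float = 2.0
    slope_fractions: tuple[float, float] = (0.1, 0.9)
    smooth_samples: int = 11           # boxcar width for metric extraction
    slope_ref_window_s: float = 2.5    # local-mean window defining the 10/90% thresholds

    def __post_init__(self) -> None:
        if self.baseline_window[1] > self.t_on or self.bleach_window[1] > self.t_on:
            raise ValueError("baseline/bleach windows must precede stimulus onset")
        if self.smooth_samples < 1:
            raise ValueError("smooth_samples must be >= 1")


@dataclass
class FretTrace:
    """Per-frame intensities and derived ratio series for one worm.

    ``donor``/``acceptor`` are background-subtracted ROI means; the
    corrected channels, ratio and percent-change series are filled in by
    :func:`correct_bleach` and :func:`percent_change`.
    """

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    t_on: float
    t_off: float
    frame_ok: np.ndarray = None  # type: ignore[assignment]
    donor_corr: np.ndarray | None = None
    acceptor_corr: np.ndarray | None = None
    ratio: np.ndarray | None = None
    dr_pct: np.ndarray | None = None
    baseline_ratio: float | None = None
    lambda_hat: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.time.shape == self.donor.shape == self.acceptor.shape):
            raise ValueError("time, donor and acceptor must share shape")
        if self.frame_ok is None:
            self.frame_ok = (self.donor > 0) & (self.acceptor > 0)
        bad = ~self.frame_ok
        if bad.any() and "nonpositive_frames" not in self.flags:
            self.flags.append("nonpositive_frames")

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.time >= lo) & (self.time < hi) & self.frame_ok


@dataclass
class TransientMetrics:
    """Scalar summary of one transient's rising phase."""

    baseline_ratio: float
    peak_pct: float
    slope_pct_s: float
    onset_idx: int
    peak_idx: int
    prestim_level: float
    responder: bool
    flags: list[str] = field(default_factory=list)


def _roi_mask(shape: tuple[int, int], x: float, y: float, radius: int) -> np.ndarray:
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    return (xx - x) ** 2 + (yy - y) ** 2 <= radius * radius


def track_neuron(
    series: ChannelStack,
    initial_pos: tuple[int, int],
    config: DetectionConfig,
    template: NeuronTemplate | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Follow the neuron across a recording.

    Per frame, the position is the best ZNCC match of the template within
    ``track_radius_px`` of the previous position; a frame whose best score
    falls below ``track_score_floor`` is flagged and the last good position
    is held (drift between consecutive frames is bounded by the radius).

    Returns ``(positions, lost)``: an (n, 2) array of (x, y) and a boolean
    flag per frame.
    """
    if series.axis != "time":
        raise ValueError("tracking requires a time series")
    if config.track_radius_px < 1:
        raise ValueError("track radius must be >= 1 px")
    frames = series.channel(config.match_channel)
    n, h, w = frames.shape
    if template is None:
        # cut the tracking patch from the first frame at the detected position
        x0, y0 = initial_pos
        r = max(config.roi_radius_px * 2, 6)
        patch = frames[0][
            max(0, y0 - r) : min(h, y0 + r + 1), max(0, x0 - r) : min(w, x0 + r + 1)
        ]
        template = NeuronTemplate(patch, note="cut from frame 0")
    patch = template.patch if isinstance(template, NeuronTemplate) else np.asarray(template, float)
    th, tw = patch.shape
    rad = config.track_radius_px

    positions = np.zeros((n, 2), dtype=int)
    lost = np.zeros(n, dtype=bool)
    px, py = int(initial_pos[0]), int(initial_pos[1])
    for i in range(n):
        x0 = max(0, px - rad - tw // 2)
        y0 = max(0, py - rad - th // 2)
        x1 = min(w, px + rad + tw // 2 + 1)
        y1 = min(h, py + rad + th // 2 + 1)
        x, y, s = match_template_ncc(frames[i], patch, Rect(x0, y0, x1, y1))
        if s < config.track_score_floor:
            lost[i] = True   # hold the last good position
        else:
            px, py = x, y
        positions[i] = (px, py)
    return positions, lost


def extract_trace(
    series: ChannelStack,
    positions: np.ndarray,
    roi_radius: int,
    background_region: Rect,
    t_on: float,
    t_off: float,
) -> FretTrace:
    """ROI means minus the background-region median, per frame and channel."""
    if series.axis != "time":
        raise ValueError("trace extraction requires a time series")
    positions = np.asarray(positions)
    n, h, w = series.donor.shape
    if positions.shape != (n, 2):
        raise ValueError("need one (x, y) position per frame")
    donor = np.empty(n)
    acceptor = np.empty(n)
    for i in range(n):
        x, y = positions[i]
        if not (roi_radius <= x < w - roi_radius and roi_radius <= y < h - roi_radius):
            raise ValueError(f"ROI at frame {i} extends outside the image")
        mask = _roi_mask((h, w), x, y, roi_radius)
        donor[i] = series.donor[i][mask].mean() - np.median(background_region.crop(series.donor[i]))
        acceptor[i] = series.acceptor[i][mask].mean() - np.median(
            background_region.crop(series.acceptor[i])
        )
    return FretTrace(series.times(), donor, acceptor, t_on=t_on, t_off=t_off)


def _fit_bleach(t: np.ndarray, intensity: np.ndarray) -> float | None:
    """Exponential decay rate on a window; linear fallback; None when hopeless."""
    if t.size < 5:
        return None
    if np.all(intensity > 0):
        lam = -np.polyfit(t, np.log(intensity), 1)[0]
        if np.isfinite(lam):
            return float(max(lam, 0.0))
    coeffs = np.polyfit(t, intensity, 1)
    if not np.all(np.isfinite(coeffs)) or coeffs[1] <= 0:
        return None
    return float(max(-coeffs[0] / coeffs[1], 0.0))


def correct_bleach(trace: FretTrace, config: QuantConfig | None = None) -> FretTrace:
    """Divide each channel by its fitted exponential bleach envelope.

    The decay rate is fit by least squares on the pre-stimulus window
    (log-linear fit; rates clipped at >= 0).  A failed exponential fit
    falls back to a linear fit of the envelope; if both fail the trace is
    left uncorrected and flagged.
    """
    config = config or QuantConfig(t_on=trace.t_on, t_off=trace.t_off)
    win = trace.window_mask(*config.bleach_window)
    if win.sum() < 5:
        raise ValueError("bleach window must contain at least 5 usable samples")
    lams = []
    for channel in (trace.donor, trace.acceptor):
        lams.append(_fit_bleach(trace.time[win], channel[win]))
    if any(l is None for l in lams):
        trace.flags.append("bleach_fit_failed")
        trace.donor_corr = trace.donor.copy()
        trace.acceptor_corr = trace.acceptor.copy()
        trace.lambda_hat = None
    else:
        ld, la = lams
        trace.donor_corr = trace.donor * np.exp(ld * trace.time)
        trace.acceptor_corr = trace.acceptor * np.exp(la * trace.time)
        trace.lambda_hat = (ld, la)
    with np.errstate(divide="ignore", invalid="ignore"):
        trace.ratio = np.where(
            trace.frame_ok, trace.acceptor_corr / np.where(trace.frame_ok, trace.donor_corr, 1.0), np.nan
        )
    return trace


def percent_change(trace: FretTrace, config: QuantConfig | None = None) -> FretTrace:
    """Percent change of the corrected ratio from its pre-stimulus baseline."""
    config = config or QuantConfig(t_on=trace.t_on, t_off=trace.t_off)
    if trace.ratio is None:
        raise ValueError("run correct_bleach first")
    win = trace.window_mask(*config.baseline_window)
    if win.sum() < 1:
        raise ValueError("baseline window contains no usable samples")
    b = float(np.nanmean(trace.ratio[win]))
    if b <= 0:
        raise ValueError(f"non-positive baseline ratio {b}")
    trace.baseline_ratio = b
    trace.dr_pct = 100.0 * (trace.ratio - b) / b
    return trace


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    pad = window // 2
    padded = np.pad(x, pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def rising_phase(
    dr_pct: np.ndarray,
    time: np.ndarray,
    t_on: float,
    t_off: float,
    grace_s: float = 5.0,
) -> tuple[int, int]:
    """Locate onset and peak of the rising phase on a percent-change series.

    The peak is the (earliest) argmax on [t_on, t_off + grace]; the onset is
    the last sample before the peak where the series is at or below 10% of
    the peak value (stimulus onset if none).  A flat series maps both
    indices to stimulus onset.
    """
    window = (time >= t_on) & (time <= t_off + grace_s)
    if not window.any():
        raise ValueError("stimulus window lies outside the series")
    on_idx = int(np.argmax(time >= t_on))
    seg = np.where(window, dr_pct, -np.inf)
    peak_idx = int(np.argmax(seg))   # earliest max by argmax semantics
    peak_val = dr_pct[peak_idx]
    if peak_val <= 1e-9:   # flat to numerical precision
        return on_idx, on_idx
    below = np.nonzero(dr_pct[on_idx:peak_idx + 1] <= 0.1 * peak_val)[0]
    onset_idx = on_idx + int(below[-1]) if below.size else on_idx
    return onset_idx, peak_idx


def compute_metrics(trace: FretTrace, config: QuantConfig | None = None) -> TransientMetrics:
    """Peak (% of baseline) and 10-90% rise slope (%/s) of the transient.

    The percent-change series is boxcar-smoothed before extraction; the
    slope is a least-squares line through the samples between the first
    crossings of 10% and 90% of the peak (falling back to the onset-peak
    window when that span holds fewer than 3 samples).  The crossing
    thresholds are referenced to a short local mean of the smoothed series
    ending at the peak rather than to the single maximum sample: the max of
    a noisy series is biased upward, and thresholds anchored to it land in
    the plateau, flattening the fitted slope.
    """
    config = config or QuantConfig(t_on=trace.t_on, t_off=trace.t_off)
    if trace.dr_pct is None:
        raise ValueError("run percent_change first")
    dr = _smooth(np.nan_to_num(trace.dr_pct, nan=0.0), config.smooth_samples)
    onset_idx, peak_idx = rising_phase(dr, trace.time, config.t_on, config.t_off, config.grace_s)
    peak = float(dr[peak_idx])
    prestim = float(np.nanmean(trace.ratio[trace.window_mask(0.0, config.t_on)]))

    if peak <= 1e-9 or peak_idx == onset_idx:   # flat to numerical precision
        return TransientMetrics(
            baseline_ratio=trace.baseline_ratio or np.nan,
            peak_pct=0.0,
            slope_pct_s=0.0,
            onset_idx=onset_idx,
            peak_idx=peak_idx,
            prestim_level=prestim,
            responder=False,
            flags=list(trace.flags),
        )

    lo_frac, hi_frac = config.slope_fractions
    ref_win = (trace.time >= trace.time[peak_idx] - config.slope_ref_window_s) & (
        trace.time <= trace.time[peak_idx]
    )
    peak_ref = float(dr[ref_win].mean()) if ref_win.any() else peak
    seg = dr[onset_idx : peak_idx + 1]
    above_lo = np.nonzero(seg >= lo_frac * peak_ref)[0]
    above_hi = np.nonzero(seg >= hi_frac * peak_ref)[0]
    i10 = onset_idx + int(above_lo[0]) if above_lo.size else onset_idx
    i90 = onset_idx + int(above_hi[0]) if above_hi.size else peak_idx
    if i90 - i10 + 1 < 3:
        i10, i90 = onset_idx, peak_idx
    if i90 > i10:
        slope = float(np.polyfit(trace.time[i10 : i90 + 1], dr[i10 : i90 + 1], 1)[0])
    else:
        slope = 0.0

    return TransientMetrics(
        baseline_ratio=trace.baseline_ratio or np.nan,
        peak_pct=peak,
        slope_pct_s=slope,
        onset_idx=onset_idx,
        peak_idx=peak_idx,
        prestim_level=prestim,
        responder=peak > config.responder_threshold_pct,
        flags=list(trace.flags),
    )


def quantify_trace(trace: FretTrace, config: QuantConfig | None = None) -> TransientMetrics:
    """Full trace pipeline: bleach correction -> percent change -> metrics."""
    config = config or QuantConfig(t_on=trace.t_on, t_off=trace.t_off)
    correct_bleach(trace, config)
    percent_change(trace, config)
    return compute_metrics(trace, config)


def metrics_from_ideal(kinetics: ResponseKinetics, timing, config: QuantConfig | None = None) -> TransientMetrics:
    """The metric estimand: peak and slope measured on the noise-free ideal trace.

    Used as ground truth in recovery experiments — the estimators applied to
    the ideal percent-change series, with no bleach or noise.
    """
    t = timing.times()
    r = ideal_ratio(kinetics, t)
    base = 1000.0
    trace = FretTrace(
        t, base / (1.0 + r), base * r / (1.0 + r), t_on=kinetics.t_on, t_off=kinetics.t_off
    )
    cfg = config or QuantConfig(
        t_on=kinetics.t_on,
        t_off=kinetics.t_off,
        baseline_window=(max(0.0, kinetics.t_on - 10.0), kinetics.t_on),
        bleach_window=(0.0, kinetics.t_on),
    )
    return quantify_trace(trace, cfg)
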
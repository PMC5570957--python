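"""Stimulus-evoked FRET-ratio transient model.

The calcium transient of a sensory neuron responding to a stimulus pulse is
modelled as a piecewise saturating-exponential rise followed by an
exponential relaxation back to baseline:

    R(t) = R0                                          t <  t_on
    R(t) = R0 * (1 + A * (1 - exp(-(t - t_on)/tau_r))) t_on <= t <= t_off
    R(t) = R0 + (R(t_off) - R0) * exp(-(t - t_off)/tau_d)   t > t_off

``R0`` is the resting acceptor/donor ratio, ``A`` the fractional peak
amplitude, ``tau_r``/``tau_d`` the rise/decay time constants, and
``t_on``/``t_off`` the stimulus window.  The series is continuous at both
break points and bounded by ``R0 * (1 + A)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ResponseKinetics", "ideal_ratio", "ideal_peak_pct"]


@dataclass(frozen=True)
class ResponseKinetics:
    """Parameters of one stimulus-locked ratio transient.

    Parameters
    ----------
    r0 : float
        Baseline acceptor/donor ratio (dimensionless, > 0).
    amplitude : float
        Fractional peak amplitude A (>= 0); the ratio saturates at
        ``r0 * (1 + A)`` for a long stimulus.
    tau_rise, tau_decay : float
        Rise and decay time constants in seconds (> 0).
    t_on, t_off : float
        Stimulus onset and offset in seconds (t_off > t_on).
    """

    r0: float = 1.5
    amplitude: float = 0.3
    tau_rise: float = 5.0
    tau_decay: float = 8.0
    t_on: float = 40.0
    t_off: float = 70.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"baseline ratio must be positive, got {self.r0}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError(
                f"time constants must be positive, got tau_rise={self.tau_rise}, "
                f"tau_decay={self.tau_decay}"
            )
        if self.t_off <= self.t_on:
            raise ValueError("stimulus offset must follow onset")

    def with_amplitude(self, amplitude: float) -> "ResponseKinetics":
        return replace(self, amplitude=amplitude)


def ideal_ratio(kinetics: ResponseKinetics, t: np.ndarray) -> np.ndarray:
    """Evaluate the noise-free ratio transient on a time base.

    Parameters
    ----------
    kinetics : ResponseKinetics
    t : array of sample times in seconds, strictly increasing.

    Returns
    -------
    ndarray of the same shape as ``t``.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("timebase must be a non-empty 1-D array")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timebase must be strictly increasing")

    k = kinetics
    r = np.full_like(t, k.r0)
    during = (t >= k.t_on) & (t <= k.t_off)
    r[during] = k.r0 * (1.0 + k.amplitude * (1.0 - np.exp(-(t[during] - k.t_on) / k.tau_rise)))
    after = t > k.t_off
    r_off = k.r0 * (1.0 + k.amplitude * (1.0 - np.exp(-(k.t_off - k.t_on) / k.tau_rise)))
    r[after] = k.r0 + (r_off - k.r0) * np.exp(-(t[after] - k.t_off) / k.tau_decay)
    return r


def ideal_peak_pct(kinetics: ResponseKinetics) -> float:
    """Closed-form peak of the percent-change trace, in % of baseline.

    The ratio maximum is attained at stimulus offset, so the peak of
    ``100 * (R(t) - R0) / R0`` is ``100 * A * (1 - exp(-(t_off - t_on)/tau_r))``.
    """
    k = kinetics
    return 100.0 * k.amplitude * (1.0 - np.exp(-(k.t_off - k.t_on) / k.tau_rise))
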
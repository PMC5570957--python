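"""In-memory container for dual-channel image stacks.

A :class:`ChannelStack` is the unit the (virtual) instrument produces per
worm: a donor and an acceptor image series sharing geometry and acquisition
metadata.  The frame axis is either time (a recording) or z (a focus sweep),
set exactly once at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelStack"]

_AXES = ("time", "z")


@dataclass
class ChannelStack:
    donor: np.ndarray
    acceptor: np.ndarray
    axis: str
    pixel_size_um: float = 0.4
    exposure_ms: float = 80.0
    frame_interval_s: float | None = None
    z_values_um: np.ndarray | None = None
    channels: tuple[str, str] = ("donor", "acceptor")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor)
        self.acceptor = np.asarray(self.acceptor)
        if self.donor.ndim != 3:
            raise ValueError(f"expected (frames, height, width) arrays, got ndim={self.donor.ndim}")
        if self.donor.shape != self.acceptor.shape:
            raise ValueError(
                f"channel shape mismatch: donor {self.donor.shape} vs acceptor {self.acceptor.shape}"
            )
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {self.axis!r}")
        if self.axis == "time":
            if self.frame_interval_s is None or self.frame_interval_s <= 0:
                raise ValueError("time-series stacks need a positive frame_interval_s")
        else:
            if self.z_values_um is None:
                raise ValueError("z stacks need z_values_um")
            self.z_values_um = np.asarray(self.z_values_um, dtype=float)
            if self.z_values_um.size != self.donor.shape[0]:
                raise ValueError("z_values_um length must equal the number of planes")
        if np.issubdtype(self.donor.dtype, np.floating) and (
            np.any(self.donor < 0) or np.any(self.acceptor < 0)
        ):
            # counts are physically non-negative; clip tolerance for read noise
            if min(self.donor.min(), self.acceptor.min()) < -1e-6:
                raise ValueError("pixel counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.donor.shape

    def times(self) -> np.ndarray:
        """Sample times in seconds (time-series stacks only)."""
        if self.axis != "time":
            raise ValueError("times() is only defined for time-series stacks")
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    def channel(self, name: str) -> np.ndarray:
        if name == "donor":
            return self.donor
        if name == "acceptor":
            return self.acceptor
        raise KeyError(name)
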
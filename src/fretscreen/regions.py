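"""Rectangular image regions.

Coordinates are 0-based, ``x`` = column, ``y`` = row, origin at the top-left;
all rectangles are half-open: ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Rect"]


@dataclass(frozen=True)
class Rect:
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"empty or inverted rectangle: {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def crop(self, image: np.ndarray) -> np.ndarray:
        """View of ``image`` restricted to the rectangle."""
        return image[..., self.y0 : self.y1, self.x0 : self.x1]

    def inside(self, shape: tuple[int, int]) -> bool:
        h, w = shape[-2], shape[-1]
        return 0 <= self.x0 and 0 <= self.y0 and self.x1 <= w and self.y1 <= h

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)
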
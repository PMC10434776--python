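"""Shared pixel geometry for the six-module display layout.

The display is divided into six labelled areas of interest (AOIs)
A–F: driving status, navigation, speed, warnings, customizable info and
basic info.  Both the stylized renderer and the synthetic scene
generator place the six module boxes on a 2 x 3 grid scaled to the
canvas, so importance mass can be attributed to modules consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Rect", "AOI_LABELS", "aoi_grid"]

AOI_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [top, bottom) x [left, right)."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def area(self) -> int:
        return self.height * self.width

    def contains(self, row: float, col: float) -> bool:
        return self.top <= row < self.bottom and self.left <= col < self.right

    def mask(self, height: int, width: int) -> np.ndarray:
        m = np.zeros((height, width), dtype=bool)
        m[self.top : self.bottom, self.left : self.right] = True
        return m


def aoi_grid(width: int, height: int, margin_frac: float = 0.06, gap_frac: float = 0.04) -> dict[str, Rect]:
    """Six non-overlapping module boxes on a 2 x 3 grid.

    Margins and inter-box gaps are fractions of the canvas edge, so the
    same relative layout works at any resolution >= 32 x 32.
    """
    if width < 32 or height < 32:
        raise ValueError("canvas must be at least 32 x 32 pixels")
    mx = max(1, int(round(margin_frac * width)))
    my = max(1, int(round(margin_frac * height)))
    gx = max(1, int(round(gap_frac * width)))
    gy = max(1, int(round(gap_frac * height)))
    bw = (width - 2 * mx - 2 * gx) // 3
    bh = (height - 2 * my - gy) // 2
    boxes: dict[str, Rect] = {}
    for i, label in enumerate(AOI_LABELS):
        r, c = divmod(i, 3)
        top = my + r * (bh + gy)
        left = mx + c * (bw + gx)
        boxes[label] = Rect(top, left, top + bh, left + bw)
    return boxes
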
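"""Stylized deterministic rendering of a design, and the attention objective.

The study never specifies how a chromosome becomes an image for the
importance predictor, so this bridge is an artifact construction kept
behind a narrow interface: :func:`render_design` draws a grayscale
schematic of the six-module display for a decoded design, and
:func:`attention_objective` scores a design by the fraction of
predicted importance mass falling inside the module boxes (AOI
coverage).  Rendering is pure: identical design and template give
byte-identical pixels.

Design variables map to visual features as follows: the main color GM
sets the fill intensity of every module (the luminance of its RGB
value); the arrangement GL permutes the modules over the grid
positions (four fixed permutations); the frame shape GF_frame selects
the border style; the font GA selects the line texture of module A;
each binary module variant toggles the texture of its own box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codec import InterfaceDesign
from .errors import DegenerateMapError, HudoptError
from .layout import AOI_LABELS, Rect, aoi_grid

__all__ = ["LayoutTemplate", "default_template", "render_design", "attention_objective", "aoi_coverage"]

# luminance (Rec. 709) of the four main-color options, on [0, 1]
_HEX_COLORS = ("#2979FF", "#FE0000", "#4ADE80", "#F26D21")


def _luminance(hex_color: str) -> float:
    r, g, b = (int(hex_color[i : i + 2], 16) / 255.0 for i in (1, 3, 5))
    return 0.2126 * r + 0.7152 * g + 0.0722 * b


_FILL_LEVELS = tuple(0.25 + 0.5 * _luminance(c) for c in _HEX_COLORS)

# four fixed module-to-position permutations selected by GL
_ARRANGEMENTS = (
    (0, 1, 2, 3, 4, 5),
    (2, 1, 0, 5, 4, 3),
    (3, 4, 5, 0, 1, 2),
    (5, 4, 3, 2, 1, 0),
)


@dataclass(frozen=True)
class LayoutTemplate:
    """Canvas size plus the six labelled AOI rectangles."""

    width: int = 320
    height: int = 160
    boxes: dict[str, Rect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.boxes:
            object.__setattr__(self, "boxes", aoi_grid(self.width, self.height))
        for label, box in self.boxes.items():
            if box.bottom > self.height or box.right > self.width:
                raise HudoptError(f"box {label} exceeds the canvas")
        labels = list(self.boxes)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                ba, bb = self.boxes[a], self.boxes[b]
                if (
                    ba.top < bb.bottom
                    and bb.top < ba.bottom
                    and ba.left < bb.right
                    and bb.left < ba.right
                ):
                    raise HudoptError(f"boxes {a} and {b} overlap")

    def aoi_mask(self) -> np.ndarray:
        mask = np.zeros((self.height, self.width), dtype=bool)
        for box in self.boxes.values():
            mask |= box.mask(self.height, self.width)
        return mask


def default_template(width: int = 320, height: int = 160) -> LayoutTemplate:
    return LayoutTemplate(width, height)


def _draw_border(img: np.ndarray, box: Rect, style: int) -> None:
    t, l, b, r = box.top, box.left, box.bottom, box.right
    if style == 1:  # thin solid
        img[t, l:r] = img[b - 1, l:r] = 1.0
        img[t:b, l] = img[t:b, r - 1] = 1.0
    elif style == 2:  # thick solid
        img[t : t + 2, l:r] = img[b - 2 : b, l:r] = 1.0
        img[t:b, l : l + 2] = img[t:b, r - 2 : r] = 1.0
    elif style == 3:  # dashed
        for j in range(l, r, 6):
            img[t, j : j + 3] = img[b - 1, j : j + 3] = 1.0
        for i in range(t, b, 6):
            img[i : i + 3, l] = img[i : i + 3, r - 1] = 1.0
    else:  # double
        img[t, l:r] = img[b - 1, l:r] = 1.0
        img[t:b, l] = img[t:b, r - 1] = 1.0
        if b - t > 4 and r - l > 4:
            img[t + 2, l + 2 : r - 2] = img[b - 3, l + 2 : r - 2] = 1.0
            img[t + 2 : b - 2, l + 2] = img[t + 2 : b - 2, r - 3] = 1.0


def _texture(img: np.ndarray, box: Rect, kind: str, pitch: int) -> None:
    t, l, b, r = box.top + 2, box.left + 2, box.bottom - 2, box.right - 2
    if t >= b or l >= r:
        return
    if kind == "h":
        for i in range(t, b, pitch):
            img[i, l:r] *= 0.55
    elif kind == "v":
        for j in range(l, r, pitch):
            img[t:b, j] *= 0.55
    elif kind == "dots":
        img[t:b:pitch, l:r:pitch] *= 0.4


def render_design(design: InterfaceDesign, template: LayoutTemplate | None = None) -> np.ndarray:
    """Draw a design as a grayscale matrix in [0, 1] (rows x cols)."""
    template = template or default_template()
    img = np.full((template.height, template.width), 0.08)
    fill = _FILL_LEVELS[design["GM"] - 1]
    perm = _ARRANGEMENTS[design["GL"] - 1]
    labels = [AOI_LABELS[i] for i in perm]  # module occupying each grid position
    positions = [template.boxes[lab] for lab in AOI_LABELS]
    module_box = {lab: positions[pos] for pos, lab in enumerate(labels)}
    for lab in AOI_LABELS:
        box = module_box[lab]
        img[box.top : box.bottom, box.left : box.right] = fill
    # per-module textures: font choice drives module A, binary variants their own box
    _texture(img, module_box["A"], "h", 2 + design["GA"])
    for lab, var_name in (("B", "GB"), ("C", "GC"), ("D", "GD"), ("E", "GE"), ("F", "GF_gear")):
        _texture(img, module_box[lab], "v" if design[var_name] == 1 else "dots", 4)
    for lab in AOI_LABELS:
        _draw_border(img, module_box[lab], design["GF_frame"])
    return np.clip(img, 0.0, 1.0)


def aoi_coverage(importance: np.ndarray, template: LayoutTemplate) -> float:
    """Fraction of importance mass inside the six AOI boxes."""
    importance = np.asarray(importance, dtype=float)
    if importance.shape != (template.height, template.width):
        raise HudoptError("importance map does not match the template canvas")
    total = importance.sum()
    if total <= 0:
        raise DegenerateMapError("zero-mass importance map")
    return float(importance[template.aoi_mask()].sum() / total)


def attention_objective(model, design: InterfaceDesign, template: LayoutTemplate | None = None) -> float:
    """Render the design, predict importance, return AOI coverage in [0, 1]."""
    template = template or default_template()
    image = render_design(design, template)
    pred = model.predict(image[None])[0]
    return aoi_coverage(pred, template)
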
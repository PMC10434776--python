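"""Synthetic data generators with the statistical structure the models assume.

Two generators are provided:

* :func:`make_synthetic_load_dataset` draws valid one-hot chromosomes
  uniformly and scores them with a fixed, documented ground-truth load
  function plus Gaussian rating noise.  It exists so that surrogate
  parameter recovery can be tested against a known truth, which the
  real rating table cannot provide.
* :func:`make_synthetic_scene` emulates an eye-tracking hotspot map
  paired with a stylized display rendering: sparse isotropic Gaussian
  attention blobs centered inside module boxes, normalized to peak 1,
  over a drawing whose box fills reflect where the blobs sit.  The real
  study's heatmap corpus was never deposited; these scenes stand in for
  it at desk scale and are labelled synthetic throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .. import codec
from ..layout import AOI_LABELS, Rect, aoi_grid

__all__ = [
    "SyntheticScene",
    "make_synthetic_load_dataset",
    "make_synthetic_scene",
    "synthetic_truth_function",
]

# Ground-truth load models.  Additive weights per option step, chosen so
# scores span roughly [4, 14] -- the range of the printed rating table.
_BASE = 4.0
_WEIGHTS = {
    "GM": 1.0,
    "GL": 0.8,
    "GF_frame": 0.6,
    "GA": 0.4,
    "GB": 0.5,
    "GC": 0.4,
    "GD": 0.3,
    "GE": 0.2,
    "GF_gear": 0.2,
}
_INTERACTION = 0.8  # added when GM == 2 and GL == 3


def synthetic_truth_function(kind: str = "interaction") -> Callable[[codec.InterfaceDesign], float]:
    """Return the documented ground-truth load function f(design).

    ``linear``: f = 4.0 + sum_g w_g * (option_g - 1).
    ``interaction``: the linear form plus 0.8 when GM=2 and GL=3.
    Both have range within [4, 15].
    """
    if kind not in ("linear", "interaction"):
        raise ValueError(f"unknown truth function {kind!r}")

    def f(design: codec.InterfaceDesign) -> float:
        y = _BASE + sum(w * (design[name] - 1) for name, w in _WEIGHTS.items())
        if kind == "interaction" and design["GM"] == 2 and design["GL"] == 3:
            y += _INTERACTION
        return y

    return f


def sample_valid_codes(n: int, rng: np.random.Generator) -> list[str]:
    """Draw n valid one-hot chromosome strings uniformly over designs."""
    out = []
    for _ in range(n):
        choices = {g.name: int(rng.integers(1, g.arity + 1)) for g in codec.GROUPS}
        out.append(codec.encode(codec.InterfaceDesign(choices)))
    return out


def make_synthetic_load_dataset(
    n: int,
    truth: str = "interaction",
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Sample a (codes, scores) training set from a known load function.

    Returns ``(dataset, truth_fn)`` where ``dataset`` is a
    :class:`~hudopt.datasets.LoadDataset` and ``truth_fn`` the noise-free
    ground truth, so tests can measure recovery error exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    from . import LoadDataset

    rng = np.random.default_rng(seed)
    f = synthetic_truth_function(truth)
    codes = sample_valid_codes(n, rng)
    clean = np.array([f(codec.decode(c)) for c in codes])
    scores = clean + rng.normal(0.0, noise_sd, size=n)
    return LoadDataset(tuple(codes), scores), f


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered layout image with its ground-truth importance map."""

    image: np.ndarray
    importance: np.ndarray
    aoi_boxes: dict[str, Rect]

    def __post_init__(self) -> None:
        if self.image.shape != self.importance.shape:
            raise ValueError("image and importance must share dimensions")


def make_synthetic_scene(
    width: int = 64,
    height: int = 64,
    n_hotspots: int = 2,
    seed: int = 0,
    background: float = 0.05,
) -> SyntheticScene:
    """Generate one synthetic eye-tracking hotspot scene.

    Importance is a normalized sum of isotropic Gaussian blobs, each
    centered uniformly inside a distinct module box (boxes reused once
    all six are taken), over a uniform background floor; after
    normalization the peak is exactly 1.  The image draws the six box
    outlines and fills each box with an intensity that increases with
    the attention weight it received, so the importance map is
    predictable from the image.
    """
    if width < 32 or height < 32:
        raise ValueError("dimensions must be >= 32")
    if n_hotspots < 1:
        raise ValueError("n_hotspots must be >= 1")
    rng = np.random.default_rng(seed)
    boxes = aoi_grid(width, height)
    labels = list(AOI_LABELS)
    chosen: list[str] = []
    while len(chosen) < n_hotspots:
        take = min(n_hotspots - len(chosen), len(labels))
        chosen.extend(rng.choice(labels, size=take, replace=False))
    rows, cols = np.mgrid[0:height, 0:width].astype(float)
    importance = np.full((height, width), background)
    box_weight = {lab: 0.0 for lab in labels}
    for lab in chosen:
        b = boxes[lab]
        cr = rng.uniform(b.top, b.bottom)
        cc = rng.uniform(b.left, b.right)
        sigma = 0.25 * min(b.height, b.width)
        w = rng.uniform(0.5, 1.0)
        importance += w * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2))
        box_weight[lab] = max(box_weight[lab], w)
    importance /= importance.max()

    image = np.full((height, width), 0.08)
    for lab, b in boxes.items():
        image[b.top : b.bottom, b.left : b.right] = 0.15 + 0.7 * box_weight[lab]
        # 1-px outline
        image[b.top, b.left : b.right] = 0.95
        image[b.bottom - 1, b.left : b.right] = 0.95
        image[b.top : b.bottom, b.left] = 0.95
        image[b.top : b.bottom, b.right - 1] = 0.95
    return SyntheticScene(image, importance, boxes)
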
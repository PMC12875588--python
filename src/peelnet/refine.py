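"""Grayscale-deviation bounding-box refinement.

A detection box around a peel specimen often includes a margin of uniform
background.  Because the specimen and the background differ in mean gray
level (by ~40 on the reference acquisition setup), a box corner that sits on
the background has a gray value far from the global image mean.  The
refinement loop therefore shrinks the box inward, one corner pair of
coordinates at a time, until every corner's absolute deviation from the
global mean falls within a threshold tau — at which point the box hugs the
specimen.

Coordinates are 0-based with inclusive corners; a pixel is addressed as
``I(x, y)`` with ``x`` the column and ``y`` the row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrayImage",
    "Box",
    "CornerDeviations",
    "RefinementParams",
    "RefinementResult",
    "to_grayscale",
    "as_gray_image",
    "global_mean",
    "corner_deviations",
    "compute_threshold",
    "refine_box",
]

#: Luma weights used for RGB -> gray conversion (ITU-R BT.601).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

GrayImage = np.ndarray  # 2-D float array, values in [0, 255]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box with inclusive integer corners, 0-based."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self):
        for v in (self.x1, self.y1, self.x2, self.y2):
            if int(v) != v:
                raise ValueError("box coordinates must be integers")

    @property
    def width(self) -> int:
        return self.x2 - self.x1 + 1

    @property
    def height(self) -> int:
        return self.y2 - self.y1 + 1

    @property
    def area(self) -> int:
        return max(self.width, 0) * max(self.height, 0)

    def is_valid(self) -> bool:
        return self.x1 < self.x2 and self.y1 < self.y2

    def within(self, h: int, w: int) -> bool:
        return 0 <= self.x1 and 0 <= self.y1 and self.x2 <= w - 1 and self.y2 <= h - 1

    def contains(self, other: "Box") -> bool:
        return (
            self.x1 <= other.x1
            and self.y1 <= other.y1
            and other.x2 <= self.x2
            and other.y2 <= self.y2
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x1, self.y1, self.x2, self.y2)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two inclusive-corner boxes."""
    ix = max(0, min(a.x2, b.x2) - max(a.x1, b.x1) + 1)
    iy = max(0, min(a.y2, b.y2) - max(a.y1, b.y1) + 1)
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class CornerDeviations:
    """Absolute deviations of the four box-corner gray values from the
    global image mean (top-left, top-right, bottom-left, bottom-right)."""

    tl: float
    tr: float
    bl: float
    br: float

    def max(self) -> float:
        return max(self.tl, self.tr, self.bl, self.br)

    def all_within(self, tau: float) -> bool:
        return self.tl <= tau and self.tr <= tau and self.bl <= tau and self.br <= tau


@dataclass(frozen=True)
class RefinementParams:
    """Shrink step (pixels), deviation threshold tau (gray levels) and an
    iteration cap guarding against non-convergence."""

    step: int = 1
    tau: float = 20.0
    max_iterations: int = 500
    single_update_per_coordinate: bool = False

    def __post_init__(self):
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class RefinementResult:
    box: Box
    iterations: int
    converged: bool


def to_grayscale(image: np.ndarray) -> GrayImage:
    """Convert an (H, W, 3) color image in [0, 255] to a float gray image
    using 0.299/0.587/0.114 luma weights, clamped to [0, 255]."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    r, g, b = LUMA_WEIGHTS
    gray = r * img[..., 0].astype(np.float64) + g * img[..., 1] + b * img[..., 2]
    return np.clip(gray, 0.0, 255.0)


def as_gray_image(image: np.ndarray) -> GrayImage:
    """Accept either a gray (H, W) or color (H, W, 3) array and return a
    validated gray image."""
    img = np.asarray(image)
    if img.ndim == 3:
        return to_grayscale(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D gray or 3-channel color image, got shape {img.shape}")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    img = img.astype(np.float64)
    if not np.all(np.isfinite(img)) or img.min() < 0 or img.max() > 255:
        raise ValueError("gray values must be finite and within [0, 255]")
    return img


def global_mean(image: GrayImage) -> float:
    """Arithmetic mean gray value over all H*W pixels."""
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    return float(img.mean())


def corner_deviations(image: GrayImage, box: Box, mu: float) -> CornerDeviations:
    """Absolute deviation of the gray value at each box corner from ``mu``."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    if not box.within(h, w):
        raise ValueError(f"box {box.as_tuple()} out of bounds for {h}x{w} image")
    return CornerDeviations(
        tl=abs(float(img[box.y1, box.x1]) - mu),
        tr=abs(float(img[box.y1, box.x2]) - mu),
        bl=abs(float(img[box.y2, box.x1]) - mu),
        br=abs(float(img[box.y2, box.x2]) - mu),
    )


def compute_threshold(mu_specimen: float, mu_background: float) -> float:
    """Deviation threshold: half the absolute gray-level gap between the
    specimen and background means.  Symmetric in its arguments; a gap of 40
    gives the operating value tau = 20."""
    return abs(mu_specimen - mu_background) / 2.0


def refine_box(
    image: GrayImage,
    box: Box,
    params: RefinementParams = RefinementParams(),
    mu: float | None = None,
) -> RefinementResult:
    """Iteratively shrink ``box`` until all four corner deviations are within
    ``params.tau``.

    Per iteration the four corner gray values and their deviations from the
    global mean are recomputed; each corner whose deviation exceeds tau pulls
    its two coordinates inward by ``step``.  The four corner updates are
    applied sequentially within one iteration, so a coordinate shared by two
    violating corners moves by ``2*step`` (``single_update_per_coordinate``
    caps it at one step).  The loop stops with ``converged=True`` when no
    corner deviation exceeds tau, or with ``converged=False`` when the box
    would collapse (x1 >= x2 or y1 >= y2) or the iteration cap is reached;
    the last valid box is returned either way, and the result is always
    contained in the input box.
    """
    img = as_gray_image(image)
    h, w = img.shape
    if not box.is_valid() or not box.within(h, w):
        raise ValueError(f"invalid starting box {box.as_tuple()} for {h}x{w} image")
    if mu is None:
        mu = global_mean(img)
    s = params.step
    x1, y1, x2, y2 = box.as_tuple()
    for it in range(params.max_iterations):
        dev = corner_deviations(img, Box(x1, y1, x2, y2), mu)
        if dev.all_within(params.tau):
            return RefinementResult(Box(x1, y1, x2, y2), it, True)
        nx1, ny1, nx2, ny2 = x1, y1, x2, y2
        if params.single_update_per_coordinate:
            if dev.tl > params.tau or dev.bl > params.tau:
                nx1 += s
            if dev.tl > params.tau or dev.tr > params.tau:
                ny1 += s
            if dev.tr > params.tau or dev.br > params.tau:
                nx2 -= s
            if dev.bl > params.tau or dev.br > params.tau:
                ny2 -= s
        else:
            if dev.tl > params.tau:
                nx1 += s
                ny1 += s
            if dev.tr > params.tau:
                nx2 -= s
                ny1 += s
            if dev.bl > params.tau:
                nx1 += s
                ny2 -= s
            if dev.br > params.tau:
                nx2 -= s
                ny2 -= s
        if nx1 >= nx2 or ny1 >= ny2:
            return RefinementResult(Box(x1, y1, x2, y2), it + 1, False)
        x1, y1, x2, y2 = nx1, ny1, nx2, ny2
    return RefinementResult(Box(x1, y1, x2, y2), params.max_iterations, False)
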
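"""Region detection for peel specimens.

Detection is a pluggable contract: any object with a
``propose(image) -> list[RegionDetection]`` method can supply candidate
boxes (e.g. a trained object detector).  The package ships
:class:`ContrastDetector`, a reference detector for the synthetic fixtures:
the specimen is darker than the uniform backdrop, so foreground pixels are
found by thresholding at the gray midpoint between the two populations,
connected components give whole-specimen boxes, and a second threshold
inside each specimen separates the bright inner pith (albedo) core from the
outer exocarp annulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .refine import Box, RefinementParams, RefinementResult, as_gray_image, refine_box

__all__ = [
    "RegionDetection",
    "Detector",
    "ContrastDetector",
    "NoDetectionError",
    "detect_regions",
    "localize_and_refine",
    "LocalizedRegions",
]

EXOCARP = "exocarp"
ALBEDO = "albedo"
WHOLE = "whole"


@dataclass(frozen=True)
class RegionDetection:
    box: Box
    kind: str  # one of {exocarp, albedo, whole}
    confidence: float

    def __post_init__(self):
        if self.kind not in (EXOCARP, ALBEDO, WHOLE):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")


class Detector(Protocol):
    def propose(self, image: np.ndarray) -> list[RegionDetection]: ...


class NoDetectionError(RuntimeError):
    """Raised when a detector returns no usable boxes for an image."""


def _mask_box(mask: np.ndarray) -> Box | None:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    b = Box(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))
    return b if b.is_valid() else None


class ContrastDetector:
    """Reference contrast-based detector for near-uniform backgrounds.

    Parameters
    ----------
    min_area:
        Components smaller than this pixel count are treated as noise.
    min_contrast:
        Minimum gray-level gap between the two Otsu populations for a
        detection to be attempted; flat images yield no detections.
    """

    def __init__(self, min_area: int = 64, min_contrast: float = 10.0):
        self.min_area = min_area
        self.min_contrast = min_contrast

    def propose(self, image: np.ndarray) -> list[RegionDetection]:
        gray = as_gray_image(image)
        if gray.std() < 1e-6:
            return []
        thr = threshold_otsu(gray)
        lo = gray[gray <= thr]
        hi = gray[gray > thr]
        if lo.size == 0 or hi.size == 0 or hi.mean() - lo.mean() < self.min_contrast:
            return []
        # Specimens are darker than the backdrop.
        fg = gray <= thr
        fg = ndimage.binary_fill_holes(fg)
        labels, n = ndimage.label(fg)
        if n == 0:
            return []
        areas = ndimage.sum_labels(np.ones_like(gray), labels, index=np.arange(1, n + 1))
        total = float(fg.sum())
        out: list[RegionDetection] = []
        for lab in np.argsort(areas)[::-1]:
            area = float(areas[lab])
            if area < self.min_area:
                continue
            comp = labels == lab + 1
            wbox = _mask_box(comp)
            if wbox is None:
                continue
            conf = min(1.0, area / max(total, 1.0))
            out.append(RegionDetection(wbox, WHOLE, conf))
            # The exocarp annulus spans the full specimen extent.
            out.append(RegionDetection(wbox, EXOCARP, conf))
            abox = self._albedo_core(gray, comp)
            if abox is not None:
                out.append(RegionDetection(abox, ALBEDO, conf))
        return out

    def _albedo_core(self, gray: np.ndarray, comp: np.ndarray) -> Box | None:
        # Smooth away surface texture before splitting ring from core; the
        # threshold histogram is sampled away from the specimen boundary so
        # the blurred-in backdrop cannot dominate it.
        smooth = ndimage.gaussian_filter(gray, 1.5)
        inner = ndimage.binary_erosion(comp, iterations=4)
        vals = smooth[inner]
        if vals.size < 16 or vals.std() < 1e-6:
            return None
        try:
            inner_thr = threshold_otsu(vals)
        except ValueError:
            return None
        # The core is whichever side of the split owns the specimen centroid:
        # the exocarp ring is an annulus, so its side never contains the
        # center.  This stays valid when a device style inverts the ring/core
        # gray ordering.  Opening detaches residual texture patches in the
        # ring from the core.
        cy, cx = ndimage.center_of_mass(comp)
        cy, cx = int(round(cy)), int(round(cx))
        candidates = []
        for side in (comp & (smooth <= inner_thr), comp & (smooth > inner_thr)):
            side = ndimage.binary_fill_holes(ndimage.binary_opening(side, iterations=3))
            if side.sum() < self.min_area // 4:
                continue
            labels, n = ndimage.label(side)
            lab = labels[cy, cx]
            if lab == 0:
                # Centroid pixel may sit on a texture streak; fall back to
                # the component whose center of mass is nearest the centroid.
                coms = ndimage.center_of_mass(side, labels, index=np.arange(1, n + 1))
                d2 = [(yy - cy) ** 2 + (xx - cx) ** 2 for yy, xx in coms]
                lab = int(np.argmin(d2)) + 1
            blob = labels == lab
            # The core is an interior region, well short of the whole specimen.
            if blob.sum() <= 0.75 * comp.sum():
                candidates.append(blob)
        if not candidates:
            return None
        return _mask_box(min(candidates, key=lambda m: m.sum()))


def detect_regions(image: np.ndarray, detector: Detector) -> list[RegionDetection]:
    """Run a detector and keep only valid in-bounds boxes.

    Raises :class:`NoDetectionError` if nothing usable is returned.
    """
    gray = as_gray_image(image)
    h, w = gray.shape
    dets = [d for d in detector.propose(image) if d.box.is_valid() and d.box.within(h, w)]
    if not dets:
        raise NoDetectionError("detector returned no valid boxes")
    return dets


@dataclass(frozen=True)
class LocalizedRegions:
    """Refined detections plus the crops they enclose."""

    detections: list[RegionDetection]
    refined: list[RefinementResult]
    crops: list[np.ndarray]


def localize_and_refine(
    image: np.ndarray,
    detector: Detector,
    params: RefinementParams = RefinementParams(),
) -> LocalizedRegions:
    """Detect regions, refine every box with the corner-deviation loop, and
    return the refined boxes together with the image crops they select."""
    img = np.asarray(image)
    gray = as_gray_image(img)
    dets = detect_regions(img, detector)
    refined = [refine_box(gray, d.box, params) for d in dets]
    crops = []
    for r in refined:
        b = r.box
        if img.ndim == 3:
            crops.append(img[b.y1 : b.y2 + 1, b.x1 : b.x2 + 1, :])
        else:
            crops.append(img[b.y1 : b.y2 + 1, b.x1 : b.x2 + 1])
    return LocalizedRegions(dets, refined, crops)
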
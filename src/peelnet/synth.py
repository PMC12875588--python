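"""Synthetic peel-specimen image generator.

Real dried-peel photographs are not redistributable, so every stage of the
pipeline is exercised on rendered stand-ins: an elliptical specimen on a
uniform bright backdrop, split into a textured outer exocarp annulus and a
paler fibrous albedo (pith) core.  The generator honors the statistics the
method depends on — a specimen-vs-background gray gap of ~40 (which fixes
the refinement threshold at 20), four appearance classes named by market
price tier, and three device-style photometric domains differing in color
gain, brightness, sharpness and noise.  Every sample carries ground-truth
region boxes derived from the render masks, and the same specimen geometry
is re-rendered under each device so cross-device experiments are paired.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .refine import LUMA_WEIGHTS, Box

__all__ = [
    "ClassProfile",
    "DeviceProfile",
    "PeelSample",
    "DEFAULT_CLASS_PROFILES",
    "DEFAULT_DEVICE_PROFILES",
    "DEFAULT_CLASS_COUNTS",
    "generate_peel_image",
    "apply_device_style",
    "generate_dataset",
    "stratified_split",
    "load_crops",
]

#: Backdrop gray level of the emulated acquisition rig.
BACKGROUND_GRAY = 228.0
#: Default specimen-vs-background gray gap.
DEFAULT_GRAY_GAP = 40.0
#: Default rendered canvas edge, pixels.
DEFAULT_SIZE = 160

_LUMA = np.array(LUMA_WEIGHTS)


def _colorize(luma: float, direction: tuple[float, float, float]) -> np.ndarray:
    """RGB triple with the given hue direction scaled to the target luma."""
    d = np.asarray(direction, dtype=np.float64)
    return luma * d / float(_LUMA @ d)


@dataclass(frozen=True)
class ClassProfile:
    """Appearance recipe for one price-tier class.

    ``exocarp_luma`` sets the outer-ring gray level; ``albedo_contrast`` is
    the signed luma offset of the pith core relative to the ring (negative:
    the pith of aged peel is darker); the hue directions separate classes
    chromatically while the overall specimen-vs-background gray gap is held
    near the configured value.
    """

    label: int
    exocarp_luma: float
    albedo_contrast: float
    exocarp_hue: tuple[float, float, float]
    albedo_hue: tuple[float, float, float]
    texture_amp: float
    texture_sigma: float
    streak_amp: float
    #: Fiber-streak grating: wavelength (px) and orientation (degrees).
    #: Wavelengths are a few pixels so the pattern is crisp in the albedo
    #: patch but aliases away once the whole frame is downscaled.
    streak_wavelength: float = 4.0
    streak_angle: float = 0.0
    luma_jitter: float = 2.0
    axis_jitter: float = 0.015
    #: Per-specimen white-balance jitter (fractional RGB gain range),
    #: emulating shot-to-shot lighting variation within one device.
    color_jitter: float = 0.05


_IDENTITY3 = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class DeviceProfile:
    """Photometric rendering style of one capture device.

    ``color_matrix`` is a row-major 3x3 channel-mixing matrix emulating the
    device ISP's color correction — the component of cross-device shift that
    rotates hue and therefore cannot be removed by per-channel
    normalization.
    """

    device_id: str
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brightness: float = 0.0
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    color_matrix: tuple[float, ...] = _IDENTITY3

    def is_identity(self) -> bool:
        return (
            tuple(self.gain) == (1.0, 1.0, 1.0)
            and self.brightness == 0.0
            and self.blur_sigma == 0.0
            and self.noise_sigma == 0.0
            and tuple(self.color_matrix) == _IDENTITY3
        )


#: Albedo contrast is negative: the pith of aged peel darkens, and keeping
#: the exocarp ring near the specimen-mean gray is what lets corner-deviation
#: refinement stop at the specimen boundary rather than inside it.  All
#: classes share the exocarp hue (dried peel is brown whatever the vintage);
#: class identity lives in the pith — its gray contrast, a subtle hue shift,
#: and the scale/orientation of the fiber streaks — so the discriminative
#: cues are fine-grained and local, as on real specimens.
DEFAULT_CLASS_PROFILES: tuple[ClassProfile, ...] = (
    ClassProfile(190, 178.0, -10.0, (1.15, 0.95, 0.70), (1.045, 0.985, 0.93), 2.0, 1.0, 8.0, 2.8, 0.0, color_jitter=0.06),
    ClassProfile(560, 178.0, -11.5, (1.15, 0.95, 0.70), (1.015, 1.005, 0.92), 3.0, 1.5, 8.0, 2.8, 90.0, color_jitter=0.06),
    ClassProfile(2800, 178.0, -13.0, (1.15, 0.95, 0.70), (0.995, 0.995, 1.00), 4.0, 2.0, 8.0, 4.5, 0.0, color_jitter=0.06),
    ClassProfile(3300, 178.0, -14.5, (1.15, 0.95, 0.70), (1.02, 0.97, 1.00), 5.0, 2.5, 8.0, 4.5, 90.0, color_jitter=0.06),
)

DEFAULT_DEVICE_PROFILES: tuple[DeviceProfile, ...] = (
    DeviceProfile("cam0"),
    DeviceProfile(
        "cam1",
        gain=(1.06, 1.00, 0.94),
        brightness=8.0,
        blur_sigma=0.5,
        noise_sigma=2.0,
        color_matrix=(0.90, 0.10, 0.0, 0.0, 0.90, 0.10, 0.10, 0.0, 0.90),
    ),
    DeviceProfile(
        "cam2",
        gain=(0.94, 0.97, 1.06),
        brightness=-8.0,
        blur_sigma=0.8,
        noise_sigma=3.0,
        color_matrix=(0.90, 0.0, 0.10, 0.10, 0.90, 0.0, 0.0, 0.10, 0.90),
    ),
)

#: Specimens per class in the default emulated dataset (399 total).
DEFAULT_CLASS_COUNTS: dict[int, int] = {190: 120, 560: 105, 2800: 84, 3300: 90}


@dataclass(frozen=True)
class PeelSample:
    image: np.ndarray  # (H, W, 3) uint8
    whole_box: Box
    exocarp_box: Box
    albedo_box: Box
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _mask_box(mask: np.ndarray) -> Box:
    ys, xs = np.nonzero(mask)
    return Box(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))


def generate_peel_image(
    profile: ClassProfile,
    size: int = DEFAULT_SIZE,
    rng: np.random.Generator | None = None,
    gray_gap: float = DEFAULT_GRAY_GAP,
    background_gray: float = BACKGROUND_GRAY,
) -> PeelSample:
    """Render one specimen and return the image with its region boxes.

    The realized specimen-mean gray is calibrated to sit ``gray_gap`` below
    the backdrop (within a few levels after quantization), so corner-deviation
    refinement at tau = gray_gap/2 behaves as on the reference rig.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng() if rng is None else rng

    # Jittered elliptical geometry; the ellipse must fit inside the canvas.
    # The specimen fills >50% of the frame, as on the reference rig, so that
    # a box corner on the backdrop deviates from the global mean by more
    # than gray_gap/2 and corner-deviation refinement can tighten the box.
    a = size * (0.45 + profile.axis_jitter * rng.uniform(-1, 1))  # semi-axis, x
    b = size * (0.41 + profile.axis_jitter * rng.uniform(-1, 1))  # semi-axis, y
    cx = size / 2 + size * 0.005 * rng.uniform(-1, 1)
    cy = size / 2 + size * 0.005 * rng.uniform(-1, 1)
    if cx - a < 1 or cx + a > size - 2 or cy - b < 1 or cy + b > size - 2:
        raise ValueError("ellipse exceeds canvas; reduce axes or jitter")

    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    outer = r2 <= 1.0
    core = r2 <= 0.55**2
    annulus = outer & ~core

    jit = profile.luma_jitter * rng.uniform(-1, 1)
    # Independent pith-contrast jitter: the ring/core gray contrast varies
    # from specimen to specimen on the same order as its class separation.
    jit_core = profile.luma_jitter * rng.uniform(-1, 1)
    exo_rgb = _colorize(profile.exocarp_luma + jit, profile.exocarp_hue)
    alb_rgb = _colorize(
        profile.exocarp_luma + profile.albedo_contrast + jit + jit_core, profile.albedo_hue
    )

    img = np.full((size, size, 3), background_gray, dtype=np.float64)
    img[annulus] = exo_rgb
    img[core] = alb_rgb

    # Exocarp surface texture: band-limited luma noise (oil-gland mottling).
    tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), profile.texture_sigma)
    tex *= profile.texture_amp / max(tex.std(), 1e-9)
    img[annulus] += tex[annulus, None]
    # Albedo fiber streaks: a grating at a class-specific wavelength and
    # orientation, amplitude-modulated by a smooth envelope (fiber bundles).
    lam = profile.streak_wavelength * (1 + 0.08 * rng.uniform(-1, 1))
    theta = np.deg2rad(profile.streak_angle + 8.0 * rng.uniform(-1, 1))
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * (np.cos(theta) * xx + np.sin(theta) * yy) / lam + phase)
    envelope = 1.0 + 0.5 * np.tanh(ndimage.gaussian_filter(rng.standard_normal((size, size)), 6.0) * 3)
    streaks = carrier * envelope
    streaks *= profile.streak_amp / max(streaks.std(), 1e-9)
    img[core] += streaks[core, None]

    # Per-specimen white-balance jitter: a small random RGB cast over the
    # whole frame, as lighting drifts between shots.
    if profile.color_jitter > 0:
        cast = 1.0 + profile.color_jitter * rng.uniform(-1, 1, 3)
        img *= cast[None, None, :]

    # Calibrate the specimen mean gray to background_gray - gray_gap.
    luma = img @ _LUMA
    shift = (background_gray - gray_gap) - float(luma[outer].mean())
    img[outer] += shift
    # Keep the backdrop at its nominal level despite the cast.
    luma = img @ _LUMA
    img[~outer] += background_gray - float(luma[~outer].mean())

    img = np.clip(img, 0, 255).astype(np.uint8)
    return PeelSample(
        image=img,
        whole_box=_mask_box(outer),
        exocarp_box=_mask_box(annulus),
        albedo_box=_mask_box(core),
        masks={"whole": outer, "exocarp": annulus, "albedo": core},
    )


def apply_device_style(
    image: np.ndarray,
    device: DeviceProfile,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Re-render an image under a device's photometric style.

    Pipeline: ISP color-matrix mixing -> per-channel gain -> brightness
    offset -> Gaussian blur -> additive sensor noise, clamped to [0, 255].
    The identity profile returns the input unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) color image")
    m = np.asarray(device.color_matrix, dtype=np.float64).reshape(3, 3)
    out = img @ m.T
    out = out * np.asarray(device.gain)[None, None, :]
    out = out + device.brightness
    if device.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, (device.blur_sigma, device.blur_sigma, 0))
    if device.noise_sigma > 0:
        rng = np.random.default_rng() if rng is None else rng
        out = out + rng.normal(0, device.noise_sigma, out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def _floor_distribute(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer partition of n by fractions: floor each share, then hand the
    remainder to the largest fractional parts (first-listed wins ties)."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


SPLIT_NAMES = ("train", "val", "test")


def stratified_split(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train/val/test splits stratified by class label.

    Splitting is done per specimen (column ``specimen``) when present so a
    specimen lands in the same split under every device; rows otherwise.
    Fractions must sum to 1; rounding is floor-and-distribute, deterministic
    for a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    df = manifest.copy()
    key = "specimen" if "specimen" in df.columns else None
    rng = np.random.default_rng(seed)
    assign: dict = {}
    units = (
        df[[key, "label"]].drop_duplicates().sort_values(key)
        if key
        else df.reset_index()[["index", "label"]].rename(columns={"index": "_row"})
    )
    idcol = key if key else "_row"
    for label in sorted(units["label"].unique()):
        ids = units.loc[units["label"] == label, idcol].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        counts = _floor_distribute(len(ids), tuple(fractions))
        pos = 0
        for split, c in zip(SPLIT_NAMES, counts):
            for i in ids[pos : pos + c]:
                assign[i] = split
            pos += c
    if key:
        df["split"] = df[key].map(assign)
    else:
        df["split"] = [assign[i] for i in range(len(df))]
    return df


_BOX_COLS = {
    "whole": ("wx1", "wy1", "wx2", "wy2"),
    "exocarp": ("ex1", "ey1", "ex2", "ey2"),
    "albedo": ("ax1", "ay1", "ax2", "ay2"),
}


def generate_dataset(
    out_dir: str,
    class_counts: dict[int, int] | None = None,
    devices: tuple[DeviceProfile, ...] = DEFAULT_DEVICE_PROFILES,
    gray_gap: float = DEFAULT_GRAY_GAP,
    seed: int = 0,
    size: int = DEFAULT_SIZE,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    class_profiles: tuple[ClassProfile, ...] = DEFAULT_CLASS_PROFILES,
    write_images: bool = True,
) -> pd.DataFrame:
    """Render the full dataset and write a manifest.

    Each specimen is rendered once and then re-styled under every device
    profile, so ground-truth geometry is identical across devices.  The
    manifest has one row per (specimen, device) with path, label, device,
    split and the three ground-truth boxes; it is also written to
    ``out_dir/manifest.csv``.
    """
    class_counts = dict(DEFAULT_CLASS_COUNTS) if class_counts is None else class_counts
    profs = {p.label: p for p in class_profiles}
    unknown = set(class_counts) - set(profs)
    if unknown:
        raise ValueError(f"no class profile for labels {sorted(unknown)}")
    if any(c < 5 for c in class_counts.values()):
        raise ValueError("need at least 5 specimens per class")
    rng = np.random.default_rng(seed)
    rows = []
    os.makedirs(out_dir, exist_ok=True)
    spec_id = 0
    for label in sorted(class_counts):
        for _ in range(class_counts[label]):
            sample = generate_peel_image(profs[label], size=size, rng=rng, gray_gap=gray_gap)
            for dev in devices:
                styled = apply_device_style(sample.image, dev, rng=rng)
                rel = os.path.join(dev.device_id, f"spec{spec_id:04d}_c{label}.png")
                if write_images:
                    path = os.path.join(out_dir, rel)
                    os.makedirs(os.path.dirname(path), exist_ok=True)
                    Image.fromarray(styled).save(path)
                row = {"path": rel, "label": label, "device": dev.device_id, "specimen": spec_id}
                for kind, cols in _BOX_COLS.items():
                    box = getattr(sample, f"{kind}_box")
                    row.update(dict(zip(cols, box.as_tuple())))
                rows.append(row)
            spec_id += 1
    manifest = stratified_split(pd.DataFrame(rows), fractions, seed=seed)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def manifest_boxes(row: pd.Series) -> dict[str, Box]:
    """Ground-truth boxes stored in one manifest row."""
    return {kind: Box(*(int(row[c]) for c in cols)) for kind, cols in _BOX_COLS.items()}


def _crop_resize(img: np.ndarray, box: Box, size: int) -> np.ndarray:
    crop = img[box.y1 : box.y2 + 1, box.x1 : box.x2 + 1]
    return np.asarray(Image.fromarray(crop).resize((size, size), Image.BILINEAR))


def load_crops(
    manifest: pd.DataFrame,
    root: str,
    size: int = 64,
    device: str | None = None,
    split: str | None = None,
) -> dict[str, np.ndarray]:
    """Load (whole, exocarp, albedo) crops for the selected manifest rows.

    Returns float32 arrays in [0, 1], NCHW, plus integer class indices
    (labels sorted ascending) and the raw labels.
    """
    df = manifest
    if device is not None:
        df = df[df["device"] == device]
    if split is not None:
        df = df[df["split"] == split]
    df = df.reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no manifest rows match the requested selection")
    labels_sorted = sorted(manifest["label"].unique())
    label_to_idx = {l: i for i, l in enumerate(labels_sorted)}
    whole, exo, alb, y = [], [], [], []
    for _, row in df.iterrows():
        img = np.asarray(Image.open(os.path.join(root, row["path"])).convert("RGB"))
        boxes = manifest_boxes(row)
        whole.append(_crop_resize(img, boxes["whole"], size))
        exo.append(_crop_resize(img, boxes["exocarp"], size))
        alb.append(_crop_resize(img, boxes["albedo"], size))
        y.append(label_to_idx[row["label"]])

    def _pack(lst):
        arr = np.stack(lst).astype(np.float32) / 255.0
        return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))

    return {
        "whole": _pack(whole),
        "exocarp": _pack(exo),
        "albedo": _pack(alb),
        "y": np.asarray(y, dtype=np.int64),
        "labels": np.asarray([labels_sorted[i] for i in y]),
        "class_labels": labels_sorted,
    }
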
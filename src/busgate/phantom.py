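"""Synthetic B-mode ultrasound phantoms.

Generates grayscale images that mimic the first-order statistics of breast
ultrasound: a smooth echogenic background carrying multiplicative
gamma-distributed speckle, hypoechoic (darker) lesions with smooth
"benign-like" or lobulated "malignant-like" boundaries, optional posterior
acoustic shadowing, and ordered frame sequences in which a lesion sweeps
through the field of view. These phantoms exercise a segmentation +
classification pipeline end to end; they make no claim to acoustic physics
(no point-spread function, no depth-dependent attenuation).

All randomness flows from an explicit integer seed through
``numpy.random.Generator``; identical spec + seed gives byte-identical
output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "SegSample", "generate_phantom", "generate_dataset",
           "generate_sequence"]

# lesion-class modifiers: benign lesions get smoother boundaries, malignant
# ones more lobulation and slightly lower echogenicity
_BENIGN_IRREGULARITY = 0.5
_MALIGNANT_IRREGULARITY = 2.0
_MALIGNANT_CONTRAST = 0.8


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of the synthetic ultrasound world.

    Parameters
    ----------
    image_height, image_width : int
        Output size in pixels.
    normal_fraction : float in [0, 1]
        Probability that a sample is lesion-free.
    lesion_area_range : (float, float)
        Min/max lesion footprint as a fraction of image area; both in
        (0, 0.5).
    lesion_contrast : float in (0, 1)
        Multiplicative intensity ratio lesion/background (hypoechoic).
    boundary_irregularity : float >= 0
        Amplitude of the radial Fourier perturbation of the lesion
        boundary; 0 gives a smooth ellipse.
    speckle_shape : float > 0
        Shape of the unit-mean gamma law of the multiplicative speckle;
        smaller = noisier.
    distractor_rate : float >= 0
        Mean number (Poisson) of hypoechoic non-lesion structures per
        image — the shadows/vessels/fat-lobule look-alikes that make
        real lesion-free images hard for a segmentation-only model.
        Distractors appear in normal AND abnormal images, are weaker and
        smaller than lesions, and are never part of the mask.
    distractor_contrast : (float, float)
        Min/max multiplicative contrast of distractors (lighter than
        lesions).
    distractor_area_range : (float, float)
        Min/max distractor footprint as a fraction of image area.
    shadow_probability : float in [0, 1]
        Chance of a posterior acoustic shadow band under the lesion.
    seed : int
        Root seed of all randomness.
    """

    image_height: int = 64
    image_width: int = 64
    normal_fraction: float = 0.5
    lesion_area_range: tuple[float, float] = (0.03, 0.12)
    lesion_contrast: float = 0.5
    boundary_irregularity: float = 0.15
    speckle_shape: float = 4.0
    shadow_probability: float = 0.3
    distractor_rate: float = 0.8
    distractor_contrast: tuple[float, float] = (0.60, 0.85)
    distractor_area_range: tuple[float, float] = (0.01, 0.04)
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image_height/image_width must be >= 8")
        if not 0.0 <= self.normal_fraction <= 1.0:
            raise ValueError("normal_fraction must be in [0, 1]")
        lo, hi = self.lesion_area_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(
                "lesion_area_range must satisfy 0 < min <= max < 0.5")
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValueError("lesion_contrast must be in (0, 1)")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be non-negative")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if not 0.0 <= self.shadow_probability <= 1.0:
            raise ValueError("shadow_probability must be in [0, 1]")
        if self.distractor_rate < 0:
            raise ValueError("distractor_rate must be non-negative")
        dlo, dhi = self.distractor_contrast
        if not 0.0 < dlo <= dhi < 1.0:
            raise ValueError("distractor_contrast must be inside (0, 1)")
        alo, ahi = self.distractor_area_range
        if not 0.0 < alo <= ahi < 0.5:
            raise ValueError(
                "distractor_area_range must satisfy 0 < min <= max < 0.5")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SegSample:
    """One image + binary lesion mask + normal/abnormal label."""

    image: np.ndarray            # (H, W) uint8
    mask: np.ndarray             # (H, W) uint8 in {0, 1}
    label: str                   # "normal" | "abnormal"
    patient_id: str = ""
    lesion_class: str = "none"   # "none" | "benign_like" | "malignant_like"
    image_path: str = ""
    mask_path: str = ""

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        has_fg = bool(self.mask.any())
        if (self.label == "normal") == has_fg:
            raise ValueError(
                f"label {self.label!r} inconsistent with mask foreground "
                f"count {int(self.mask.sum())}")


def _lesion_radius_profile(theta: np.ndarray, coeffs: np.ndarray,
                           irregularity: float) -> np.ndarray:
    """Unit radius modulated by a low-order random Fourier series."""
    r = np.ones_like(theta)
    for k, (a, b) in enumerate(coeffs, start=2):
        r += irregularity * (a * np.cos(k * theta) + b * np.sin(k * theta)) / k
    return np.clip(r, 0.2, None)


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator,
                 irregularity: float,
                 center: tuple[float, float] | None = None,
                 geometry: dict | None = None,
                 area_range: tuple[float, float] | None = None
                 ) -> tuple[np.ndarray, dict]:
    """Rasterize one lesion footprint; returns (mask, geometry).

    The footprint is an ellipse with a radial Fourier perturbation; its
    discrete area is bisected into ``lesion_area_range`` so the stated
    area bounds hold for every sample, not just in expectation.
    """
    h, w = spec.image_height, spec.image_width
    lo, hi = area_range if area_range is not None else spec.lesion_area_range
    if geometry is None:
        geometry = {
            "target_frac": float(rng.uniform(lo, hi)),
            "aspect": float(rng.uniform(0.6, 1.0)),
            "angle": float(rng.uniform(0, np.pi)),
            "coeffs": rng.normal(0.0, 1.0, (4, 2)),
        }
        if center is None:
            center = (float(rng.uniform(0.3, 0.7) * h),
                      float(rng.uniform(0.3, 0.7) * w))
        geometry["center"] = center
    center = geometry["center"] if center is None else center
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(geometry["angle"]), np.sin(geometry["angle"])
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / geometry["aspect"]
    theta = np.arctan2(v, u)
    profile = _lesion_radius_profile(theta, geometry["coeffs"], irregularity)
    area = geometry["target_frac"] * h * w
    # ellipse u^2 + v^2 <= r0^2 has raster area ~ pi * r0^2 * aspect
    r0 = np.sqrt(area / (np.pi * geometry["aspect"]))
    rho = np.sqrt(u * u + v * v)

    def mask_at(scale: float) -> np.ndarray:
        return (rho <= scale * r0 * profile).astype(np.uint8)

    s_lo, s_hi = 0.25, 4.0
    m = mask_at(1.0)
    frac = m.sum() / (h * w)
    s = 1.0
    for _ in range(40):
        if lo <= frac <= hi and m.sum() > 0:
            break
        if frac < lo:
            s_lo = s
        else:
            s_hi = s
        s = 0.5 * (s_lo + s_hi)
        m = mask_at(s)
        frac = m.sum() / (h * w)
    geometry["scale"] = s
    return m, geometry


def _draw_distractors(spec: PhantomSpec, rng: np.random.Generator,
                      lesion_mask: np.ndarray | None) -> np.ndarray:
    """Multiplicative darkening field of the non-lesion hypoechoic
    structures; placed to avoid the lesion footprint (if any)."""
    h, w = spec.image_height, spec.image_width
    fieldmap = np.ones((h, w))
    n = int(rng.poisson(spec.distractor_rate))
    if n == 0:
        return fieldmap
    if lesion_mask is not None and lesion_mask.any():
        from scipy.ndimage import binary_dilation
        forbidden = binary_dilation(lesion_mask.astype(bool), iterations=5)
    else:
        forbidden = np.zeros((h, w), dtype=bool)
    for _ in range(n):
        contrast = float(rng.uniform(*spec.distractor_contrast))
        for _attempt in range(8):
            dmask, _ = _lesion_mask(
                spec, rng, spec.boundary_irregularity,
                area_range=spec.distractor_area_range)
            if not (dmask.astype(bool) & forbidden).any():
                break
        else:
            continue
        soft = gaussian_filter(dmask.astype(np.float64), sigma=0.8)
        fieldmap *= 1.0 - (1.0 - contrast) * np.clip(soft, 0.0, 1.0)
    return fieldmap


def _render(spec: PhantomSpec, rng: np.random.Generator,
            mask: np.ndarray | None, contrast: float,
            add_shadow: bool) -> np.ndarray:
    """Compose background field, lesion and distractor darkening, shadow
    and speckle."""
    h, w = spec.image_height, spec.image_width
    base = 0.55 + 0.12 * gaussian_filter(
        rng.normal(0.0, 1.0, (h, w)), sigma=max(h, w) / 8.0)
    base = np.clip(base, 0.25, 0.9)
    base *= _draw_distractors(spec, rng, mask)
    if mask is not None and mask.any():
        soft = gaussian_filter(mask.astype(np.float64), sigma=0.8)
        base *= 1.0 - (1.0 - contrast) * np.clip(soft, 0.0, 1.0)
        if add_shadow:
            cols = np.where(mask.any(axis=0))[0]
            rows = np.where(mask.any(axis=1))[0]
            shadow = np.ones((h, w))
            lesion_bottom = rows[-1]
            fade = np.clip(
                (np.arange(h) - lesion_bottom) / max(h - lesion_bottom, 1),
                0.0, 1.0)
            shadow[:, cols[0]:cols[-1] + 1] = 1.0 - 0.4 * fade[:, None]
            base *= shadow
    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, (h, w))
    img = np.clip(base * speckle, 0.0, 1.0)
    return np.round(img * 255.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec,
                     rng: np.random.Generator | None = None) -> SegSample:
    """Draw one phantom sample (lesion-free with prob. ``normal_fraction``)."""
    spec.validate()
    if rng is None:
        rng = spec.rng()
    if rng.uniform() < spec.normal_fraction:
        img = _render(spec, rng, None, 1.0, False)
        return SegSample(image=img,
                         mask=np.zeros_like(img, dtype=np.uint8),
                         label="normal", lesion_class="none")
    malignant = rng.uniform() < 0.5
    if malignant:
        irregularity = spec.boundary_irregularity * _MALIGNANT_IRREGULARITY
        contrast = spec.lesion_contrast * _MALIGNANT_CONTRAST
        lesion_class = "malignant_like"
    else:
        irregularity = spec.boundary_irregularity * _BENIGN_IRREGULARITY
        contrast = spec.lesion_contrast
        lesion_class = "benign_like"
    mask, _ = _lesion_mask(spec, rng, irregularity)
    add_shadow = rng.uniform() < spec.shadow_probability
    img = _render(spec, rng, mask, contrast, add_shadow)
    return SegSample(image=img, mask=mask, label="abnormal",
                     lesion_class=lesion_class)


def generate_dataset(spec: PhantomSpec, n_images: int, out_dir) -> Path:
    """Write ``n_images`` PNG image/mask pairs plus a CSV manifest.

    Consecutive images are grouped into synthetic patients (1-4 images per
    patient), emulating clinical datasets where one patient contributes
    several views. Returns the manifest path.
    """
    spec.validate()
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = spec.rng()
    rows = []
    patient, left = 0, 0
    for i in range(n_images):
        if left == 0:
            patient += 1
            left = int(rng.integers(1, 5))
        left -= 1
        sample = generate_phantom(spec, rng)
        img_rel = f"images/img_{i:05d}.png"
        mask_rel = f"masks/mask_{i:05d}.png"
        iio.imwrite(out_dir / img_rel, sample.image)
        iio.imwrite(out_dir / mask_rel, sample.mask * np.uint8(255))
        rows.append((img_rel, mask_rel, sample.label, f"P{patient:04d}",
                     sample.lesion_class))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image_path", "mask_path", "label", "patient_id", "lesion_class"])
        writer.writerows(rows)
    return manifest


def generate_sequence(spec: PhantomSpec, n_frames: int,
                      lesion_entry_frame: int, lesion_exit_frame: int,
                      rng: np.random.Generator | None = None
                      ) -> list[SegSample]:
    """Simulate a probe sweep: a lesion enters and leaves the field of view.

    Frames with index < ``lesion_entry_frame`` or >= ``lesion_exit_frame``
    are lesion-free; in between, a fixed lesion shape translates smoothly
    across the image (its center moving left to right), the mask tracking
    it frame by frame.
    """
    spec.validate()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= lesion_entry_frame < lesion_exit_frame <= n_frames:
        raise ValueError(
            "frame indices must satisfy 0 <= entry < exit <= n_frames")
    if rng is None:
        rng = spec.rng()
    irregularity = spec.boundary_irregularity * _BENIGN_IRREGULARITY
    n_abnormal = lesion_exit_frame - lesion_entry_frame
    cy = spec.image_height * float(rng.uniform(0.4, 0.6))
    x_start = spec.image_width * 0.25
    x_end = spec.image_width * 0.75
    _, geometry = _lesion_mask(spec, rng, irregularity,
                               center=(cy, 0.5 * spec.image_width))
    frames = []
    for f in range(n_frames):
        frame_rng = np.random.default_rng([int(spec.seed) % (2 ** 31), f])
        if lesion_entry_frame <= f < lesion_exit_frame:
            t = 0.5 if n_abnormal == 1 else (
                (f - lesion_entry_frame) / (n_abnormal - 1))
            cx = x_start + t * (x_end - x_start)
            geom = dict(geometry, center=(cy, cx))
            mask, _ = _lesion_mask(spec, frame_rng, irregularity,
                                   geometry=geom)
            img = _render(spec, frame_rng, mask, spec.lesion_contrast, False)
            frames.append(SegSample(image=img, mask=mask, label="abnormal",
                                    lesion_class="benign_like",
                                    patient_id="SEQ"))
        else:
            img = _render(spec, frame_rng, None, 1.0, False)
            frames.append(SegSample(
                image=img, mask=np.zeros_like(img, dtype=np.uint8),
                label="normal", lesion_class="none", patient_id="SEQ"))
    return frames
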
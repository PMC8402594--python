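"""Procedural colonoscopy-like image/mask fixtures.

Real colonoscopy frames show a pinkish, textured mucosa with strong radial
vignetting from the endoscope light, occasional specular highlights, and one
or more polyps — rounded protrusions, usually brighter than their
surroundings, varying widely in size and aspect. The generator emulates
those gross photometric features: a low-frequency textured background, a
radial vignette, a few Gaussian specular spots, and 1..k anti-aliased filled
ellipses with a configurable intensity offset. The paired mask is the exact
union of the ellipse interiors.

Every sample is fully determined by (spec.seed, index): the per-sample RNG
is derived through :class:`numpy.random.SeedSequence`, so datasets are
reproducible and order-independent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
from PIL import Image

from .dataio import DatasetManifest, DatasetRecord, SampleRecord, write_mask
from .specs import SyntheticSpec

__all__ = ["generate_sample", "generate_dataset", "ellipse_coverage"]

_BASE_COLOR = np.array([0.62, 0.38, 0.32], dtype=np.float32)  # mucosa tone


def _sample_rng(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed),
                                                         int(index)]))


def _low_frequency_texture(rng, h, w, scale: float) -> np.ndarray:
    """Smooth random field in [-scale, scale] from an upsampled coarse grid."""
    gh, gw = max(h // 16, 2), max(w // 16, 2)
    coarse = rng.uniform(-1.0, 1.0, size=(gh, gw)).astype(np.float32)
    img = Image.fromarray(coarse, mode="F").resize((w, h), Image.BILINEAR)
    return np.asarray(img) * scale


def ellipse_coverage(h: int, w: int, center: Tuple[float, float],
                     axes: Tuple[float, float], theta: float,
                     supersample: int = 2) -> np.ndarray:
    """Fractional pixel coverage of a rotated filled ellipse, estimated by
    regular sub-pixel sampling (anti-aliasing)."""
    s = supersample
    ys = (np.arange(h * s) + 0.5) / s - 0.5
    xs = (np.arange(w * s) + 0.5) / s - 0.5
    dy = ys[:, None] - center[0]
    dx = xs[None, :] - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (dy * ct + dx * st) / axes[0]
    v = (-dy * st + dx * ct) / axes[1]
    inside = (u * u + v * v <= 1.0).astype(np.float32)
    return inside.reshape(h, s, w, s).mean(axis=(1, 3))


def generate_sample(spec: SyntheticSpec, index: int) -> SampleRecord:
    """Render one image/mask pair, fully determined by (spec.seed, index)."""
    rng = _sample_rng(spec, index)
    h, w = spec.resolution
    min_hw = min(h, w)

    base = np.empty((h, w, 3), dtype=np.float32)
    base[:] = _BASE_COLOR
    texture = _low_frequency_texture(rng, h, w,
                                     spec.background_texture_scale)
    base += texture[..., None] * np.array([1.0, 0.8, 0.7], dtype=np.float32)

    # radial vignette centred near the middle of the frame
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / (h / 2)) ** 2 + ((xx - cx) / (w / 2)) ** 2
    base *= (1.0 - spec.vignette_strength * np.clip(r2, 0.0, 1.5) / 1.5
             )[..., None]

    # polyps: bright anti-aliased ellipses; mask = union of interiors
    n_polyps = int(rng.integers(spec.polyps_per_image[0],
                                spec.polyps_per_image[1] + 1))
    coverage = np.zeros((h, w), dtype=np.float32)
    for _ in range(n_polyps):
        a = rng.uniform(*spec.polyp_radius_range) * min_hw
        ecc = rng.uniform(*spec.polyp_eccentricity_range)
        b = a / ecc
        if 2 * a >= min(h, w):
            raise ValueError(
                f"polyp with semi-axis {a:.1f}px cannot fit in a "
                f"{h}x{w} frame")
        theta = rng.uniform(0.0, np.pi)
        pc_y = rng.uniform(a, h - a)
        pc_x = rng.uniform(a, w - a)
        coverage = np.maximum(
            coverage, ellipse_coverage(h, w, (pc_y, pc_x), (a, b), theta))
    mask = (coverage >= 0.5).astype(np.uint8)

    # intensity offset: full configured contrast inside, soft at the rim
    bump = spec.intensity_contrast * coverage
    base += bump[..., None] * np.array([1.0, 0.9, 0.85], dtype=np.float32)

    # specular highlights: small bright Gaussian spots
    for _ in range(spec.specular_highlight_count):
        sy = rng.uniform(0, h)
        sx = rng.uniform(0, w)
        sr = rng.uniform(0.004, 0.012) * min_hw + 1.0
        g = np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * sr * sr)))
        base += 0.5 * g.astype(np.float32)[..., None]

    if spec.noise_std > 0:
        base += rng.normal(0.0, spec.noise_std, size=base.shape
                           ).astype(np.float32)
    image = np.clip(base, 0.0, 1.0)
    return SampleRecord(image=image, mask=mask, native_resolution=(h, w),
                        collection="synthetic")


def generate_dataset(spec: SyntheticSpec, n: int, out_dir) -> DatasetManifest:
    """Write ``n`` image/mask pairs in the standard dataset layout and
    return their manifest. Regeneration with the same spec is byte-identical."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    images_dir = out / "images"
    masks_dir = out / "masks"
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n):
        sample = generate_sample(spec, i)
        img8 = np.clip(np.rint(sample.image * 255.0), 0, 255).astype(np.uint8)
        image_path = images_dir / f"sample_{i:04d}.png"
        mask_path = masks_dir / f"sample_{i:04d}.png"
        Image.fromarray(img8).save(image_path, format="PNG")
        write_mask(sample.mask, mask_path)
        records.append(DatasetRecord(str(image_path), str(mask_path),
                                     "synthetic"))
    return DatasetManifest(records)
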
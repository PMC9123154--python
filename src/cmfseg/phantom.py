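"""Synthetic DCE-MRI case generator.

The study data (paired pre/post-contrast breast MR volumes with expert
lesion masks) are private clinical images, so the pipeline is exercised on
phantoms that emulate their essential physics: a smooth textured background,
one or more ellipsoidal lesions that enhance only in the post-contrast
frame, Rician magnitude noise (whose zero-signal background is exactly the
Rayleigh distribution assumed by the denoiser's threshold model), and a
small in-plane affine misalignment between the pre and post frames.

Defaults are sized so the full pipeline runs in seconds: an (8, 128, 128)
volume, one ellipsoid of radii (3, 10, 12) voxels, enhancement +80 on a
background of 60 with a low-frequency sinusoidal texture of amplitude 10,
Rician sigma 8 (gray range 0-255), misalignment (tx=2.5, ty=-1.5,
theta=0.01 rad).  Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import VolumeImage, BinaryMask
from .registration import compose_affine, apply_affine


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (8, 128, 128)
    # each lesion: (center (z,y,x), radii (rz,ry,rx), enhancement)
    lesions: tuple = (((3.5, 63.5, 63.5), (3.0, 10.0, 12.0), 80.0),)
    background_level: float = 60.0
    texture_amplitude: float = 10.0
    noise_sigma: float = 8.0
    misalignment: dict = field(
        default_factory=lambda: {"tx": 2.5, "ty": -1.5, "theta": 0.01})
    spacing: tuple[float, float, float] = (1.5, 0.6, 0.6)
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        nz, ny, nx = self.shape
        for center, radii, enh in self.lesions:
            if enh <= 0:
                raise ValueError("enhancement must be > 0")
            cz, cy, cx = center
            rz, ry, rx = radii
            if not (0 <= cz - rz and cz + rz <= nz - 1 and
                    0 <= cy - ry and cy + ry <= ny - 1 and
                    0 <= cx - rx and cx + rx <= nx - 1):
                raise ValueError(f"lesion {center}, {radii} outside bounds {self.shape}")


def rician_noise(img: VolumeImage, sigma: float, seed: int) -> VolumeImage:
    """Magnitude of (signal + complex Gaussian noise).

    ``out = sqrt((img + g1)^2 + g2^2)`` with g1, g2 iid N(0, sigma^2);
    sigma = 0 is the identity.  On zero signal the output is Rayleigh(sigma).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    data = np.asarray(img.data, dtype=np.float64)
    if sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, data.shape)
    g2 = rng.normal(0.0, sigma, data.shape)
    out = np.sqrt((data + g1) ** 2 + g2 ** 2)
    return VolumeImage(out, img.spacing, img.intensity_range)


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    """Elliptical 'body' cross-section; outside is air (zero signal)."""
    nz, ny, nx = spec.shape
    _, yy, xx = np.indices(spec.shape, dtype=np.float64)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    return ((yy - cy) / (0.42 * ny)) ** 2 + ((xx - cx) / (0.42 * nx)) ** 2 <= 1.0


def _clean_pre(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    zz, yy, xx = np.indices(spec.shape, dtype=np.float64)
    # low-frequency sinusoidal texture; two incommensurate components so the
    # tissue carries enough structure to drive registration
    a = spec.texture_amplitude
    texture = (0.6 * a * np.sin(2 * np.pi * yy / (ny / 4)) *
               np.cos(2 * np.pi * xx / (nx / 3.2)) +
               0.4 * a * np.sin(2 * np.pi * (xx + 0.7 * yy) / (nx / 2.4)) *
               np.cos(2 * np.pi * (yy - 0.3 * xx) / (ny / 1.7)))
    return np.where(_body_mask(spec), spec.background_level + texture, 0.0)


def _lesion_mask(spec: PhantomSpec) -> np.ndarray:
    zz, yy, xx = np.indices(spec.shape, dtype=np.float64)
    mask = np.zeros(spec.shape, dtype=bool)
    for (cz, cy, cx), (rz, ry, rx), _ in spec.lesions:
        mask |= (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 +
                 ((xx - cx) / rx) ** 2) <= 1.0
    return mask


def generate_case(spec: PhantomSpec | None = None):
    """Build one (pre, post, gt) case.

    ``pre`` = background + texture + Rician noise.  ``post`` applies the
    configured in-plane misalignment to (pre_clean + enhancement inside the
    lesions) and adds independent Rician noise.  ``gt`` is the lesion voxel
    set in pre-frame coordinates.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    pre_clean = _clean_pre(spec)
    gt = _lesion_mask(spec)
    post_clean = pre_clean.copy()
    for (cz, cy, cx), (rz, ry, rx), enh in spec.lesions:
        zz, yy, xx = np.indices(spec.shape, dtype=np.float64)
        inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 +
                  ((xx - cx) / rx) ** 2) <= 1.0
        post_clean = post_clean + enh * inside

    t = compose_affine(**spec.misalignment)
    post_moved = np.stack([apply_affine(post_clean[z], t, "bicubic")
                           for z in range(spec.shape[0])])

    spacing = spec.spacing
    pre = rician_noise(VolumeImage(pre_clean, spacing), spec.noise_sigma,
                       seed=spec.seed * 2 + 1)
    post = rician_noise(VolumeImage(post_moved, spacing), spec.noise_sigma,
                        seed=spec.seed * 2 + 2)
    return pre, post, BinaryMask(gt.astype(np.uint8), spacing)


def clean_components(spec: PhantomSpec | None = None):
    """Noise-free building blocks (pre_clean, post_clean_aligned, gt) for tests."""
    spec = spec or PhantomSpec()
    spec.validate()
    pre_clean = _clean_pre(spec)
    gt = _lesion_mask(spec)
    enh = np.zeros(spec.shape)
    for (cz, cy, cx), (rz, ry, rx), e in spec.lesions:
        zz, yy, xx = np.indices(spec.shape, dtype=np.float64)
        inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 +
                  ((xx - cx) / rx) ** 2) <= 1.0
        enh += e * inside
    return (VolumeImage(pre_clean, spec.spacing),
            VolumeImage(pre_clean + enh, spec.spacing),
            BinaryMask(gt.astype(np.uint8), spec.spacing))
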
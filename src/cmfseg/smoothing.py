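"""Edge-preserving smoothing: pixel-wise adaptive Wiener and bilateral filters.

The adaptive Wiener filter estimates the local mean ``m_f`` and variance
``sigma_f^2`` inside an odd ``(X, Y)`` window and outputs

    out = m_f + (sigma_f^2 - v^2) / sigma_f^2 * (img - m_f)

where ``v^2`` is the noise variance, estimated as the average of
``sigma_f^2`` over the image when not supplied.  Pixels whose local variance
falls below ``v^2`` would get a negative gain; the gain is clamped to
[0, 1] so the filter interpolates between the local mean (flat regions) and
the original intensity (edges).  Local statistics use reflect padding.

The bilateral filter is the standard normalized product of a spatial
Gaussian and an intensity-range Gaussian; for very large ``sigma_range`` it
reduces to plain Gaussian blur.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = 1e-12


def local_statistics(img: np.ndarray, window: tuple[int, int] = (5, 5)):
    """Local mean and variance in an odd (X, Y) window, reflect boundary."""
    img = np.asarray(img, dtype=np.float64)
    wy, wx = int(window[0]), int(window[1])
    if wy % 2 == 0 or wx % 2 == 0 or wy < 1 or wx < 1:
        raise ValueError(f"window must be odd and >= 1 in both axes, got {window}")
    m = ndimage.uniform_filter(img, size=(wy, wx), mode="reflect")
    m2 = ndimage.uniform_filter(img * img, size=(wy, wx), mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    return m, var


def adaptive_wiener(img: np.ndarray, window: tuple[int, int] = (5, 5),
                    v2: float | None = None) -> np.ndarray:
    """Pixel-wise adaptive Wiener filter with gain clamped to [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D slice")
    m, var = local_statistics(img, window)
    if v2 is None:
        v2 = float(var.mean())
    if v2 < 0:
        raise ValueError("noise variance must be nonnegative")
    gain = (var - v2) / np.maximum(var, _EPS)
    gain = np.clip(gain, 0.0, 1.0)
    return m + gain * (img - m)


def bilateral(img: np.ndarray, sigma_spatial: float = 2.0,
              sigma_range: float = 20.0, truncate: float = 3.0) -> np.ndarray:
    """Bilateral filter: normalized spatial x range Gaussian weighting.

    The kernel is truncated at ``truncate * sigma_spatial`` pixels (reflect
    boundary).  Output intensities stay within [min(img), max(img)] because
    the weights are a convex combination.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D slice")
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("sigmas must be positive")
    radius = max(1, int(truncate * sigma_spatial + 0.5))
    # numpy "symmetric" = edge-repeating reflection, same as ndimage "reflect"
    pad = np.pad(img, radius, mode="symmetric")
    h, w = img.shape
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    inv2ss = 1.0 / (2.0 * sigma_spatial ** 2)
    inv2sr = 1.0 / (2.0 * sigma_range ** 2)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            shifted = pad[radius + dy:radius + dy + h,
                          radius + dx:radius + dx + w]
            ws = np.exp(-(dy * dy + dx * dx) * inv2ss)
            wr = np.exp(-((shifted - img) ** 2) * inv2sr)
            weight = ws * wr
            num += weight * shifted
            den += weight
    return num / den


def smooth_volume(data: np.ndarray, *, wiener_window=(5, 5), wiener_v2=None,
                  sigma_spatial: float = 2.0, sigma_range: float = 20.0,
                  stages=("wiener", "bilateral")) -> np.ndarray:
    """Apply the enabled smoothing stages slice by slice (Wiener first)."""
    out = np.asarray(data, dtype=np.float64).copy()
    for z in range(out.shape[0]):
        sl = out[z]
        if "wiener" in stages:
            sl = adaptive_wiener(sl, wiener_window, wiener_v2)
        if "bilateral" in stages:
            sl = bilateral(sl, sigma_spatial, sigma_range)
        out[z] = sl
    return out
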
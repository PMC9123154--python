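"""Affine registration of the post-contrast volume onto the pre-contrast one,
in-plane resampling, and contrast subtraction.

The in-plane transform is the product of four elementary factors,
Translation · Rotation · Shear · Scale::

    A = [[sx*cos(t),  sy*(k*cos(t) - sin(t)),  tx],
         [sx*sin(t),  sy*(k*sin(t) + cos(t)),  ty],
         [0,          0,                        1]]

with translation ``(tx, ty)`` in pixels, clockwise rotation ``theta`` in
radians, shear factor ``k`` and scales ``(sx, sy)``.  Coordinates are
0-based array indices referring to pixel centers; the transform acts about
the image center so that rotation/scale behave as a patient-frame motion.

Registration minimizes mean-squared intensity error over a multiresolution
pyramid (pre/post pairs come from the same scanner, so a mono-modal metric
suffices) with a deterministic derivative-free (Powell) optimizer started at
the identity.  Subtraction clamps negatives to zero so downstream amplitude
statistics stay nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .io_formats import VolumeImage

_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


@dataclass
class AffineTransform2D:
    """Six-parameter in-plane affine transform and its homogeneous matrix."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    k: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([
            [self.sx * c, self.sy * (self.k * c - s), self.tx],
            [self.sx * s, self.sy * (self.k * s + c), self.ty],
            [0.0, 0.0, 1.0],
        ])

    def inverse_matrix(self) -> np.ndarray:
        m = self.matrix
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise np.linalg.LinAlgError("singular affine transform")
        return np.linalg.inv(m)

    def params(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "theta": self.theta,
                "k": self.k, "sx": self.sx, "sy": self.sy}


def compose_affine(tx=0.0, ty=0.0, theta=0.0, k=0.0, sx=1.0, sy=1.0) -> AffineTransform2D:
    """Build the Translation·Rotation·Shear·Scale transform."""
    return AffineTransform2D(float(tx), float(ty), float(theta),
                             float(k), float(sx), float(sy))


def apply_affine(img: np.ndarray, t: AffineTransform2D,
                 interpolation: str = "bicubic") -> np.ndarray:
    """Warp a 2-D slice by ``t`` (inverse mapping, zero fill outside).

    Each output pixel ``p`` pulls intensity from ``A^{-1}(p)``, with the
    transform acting in (x, y) coordinates relative to the image center, so
    a translation ``(tx, ty)`` moves content by ``+tx`` columns and ``+ty``
    rows.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("apply_affine expects a 2-D slice")
    order = _ORDER[interpolation]
    inv = t.inverse_matrix()
    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # ndimage uses (row, col) = (y, x); convert the (x, y) matrix.
    # source = inv @ (p - c) + c
    m_xy = inv[:2, :2]
    b_xy = inv[:2, 2]
    m_rc = np.array([[m_xy[1, 1], m_xy[1, 0]],
                     [m_xy[0, 1], m_xy[0, 0]]])
    center_rc = np.array([cy, cx])
    offset = np.array([b_xy[1], b_xy[0]]) + center_rc - m_rc @ center_rc
    return ndimage.affine_transform(img, m_rc, offset=offset, order=order,
                                    mode="constant", cval=0.0,
                                    prefilter=(order > 1))


def _warp_volume(vol: np.ndarray, t: AffineTransform2D, order: int) -> np.ndarray:
    out = np.empty_like(vol)
    name = {0: "nearest", 1: "bilinear", 3: "bicubic"}[order]
    for z in range(vol.shape[0]):
        out[z] = apply_affine(vol[z], t, name)
    return out


def register_affine(moving: VolumeImage, fixed: VolumeImage, *,
                    levels: int = 3, max_iter: int = 200, tol: float = 1e-4,
                    params: tuple[str, ...] = ("tx", "ty", "theta"),
                    per_slice: bool = False):
    """Recover the in-plane transform aligning ``moving`` onto ``fixed``.

    Mean-squared-error metric, ``levels``-level Gaussian pyramid, Powell
    optimizer (max ``max_iter`` function evaluations per level, parameter
    tolerance ``tol``), identity initialization.  By default one transform
    shared by all slices (rigid patient-shift assumption); ``per_slice=True``
    returns a list of per-slice transforms.

    Returns an :class:`AffineTransform2D` whose ``converged`` flag is False
    when the optimizer exhausted its budget.
    """
    mov, fix = np.asarray(moving.data, float), np.asarray(fixed.data, float)
    if mov.shape != fix.shape:
        raise ValueError("moving and fixed volumes must share a shape")
    if per_slice:
        return [
            _register_stack(mov[z:z + 1], fix[z:z + 1], levels, max_iter, tol, params)
            for z in range(mov.shape[0])
        ]
    return _register_stack(mov, fix, levels, max_iter, tol, params)


_DEFAULTS = {"tx": 0.0, "ty": 0.0, "theta": 0.0, "k": 0.0, "sx": 1.0, "sy": 1.0}


def _register_stack(mov, fix, levels, max_iter, tol, names):
    pyramids = []
    m, f = mov, fix
    for lev in range(levels):
        pyramids.append((m, f))
        if min(m.shape[1:]) <= 16:
            break
        m = ndimage.zoom(ndimage.gaussian_filter(m, (0, 1, 1)), (1, 0.5, 0.5), order=1)
        f = ndimage.zoom(ndimage.gaussian_filter(f, (0, 1, 1)), (1, 0.5, 0.5), order=1)
    # optimization variables are scaled so a unit Powell step is comparable
    # across parameters: ~1 px translation, 0.02 rad rotation, 2% scale/shear
    unit = {"tx": 1.0, "ty": 1.0, "theta": 0.02, "k": 0.02, "sx": 0.02, "sy": 0.02}
    x = np.array([_DEFAULTS[n] / unit[n] for n in names])
    converged = True
    for lev, (m, f) in enumerate(reversed(pyramids)):
        scale = 2.0 ** (len(pyramids) - 1 - lev)

        def cost(x):
            p = dict(_DEFAULTS)
            for n, v in zip(names, x):
                p[n] = v * unit[n]
            # translations live in full-resolution pixels
            p["tx"] /= scale
            p["ty"] /= scale
            if p["sx"] <= 1e-3 or p["sy"] <= 1e-3:
                return np.inf
            t = AffineTransform2D(**p)
            warped = _warp_volume(m, t, order=1)
            # interior crop: keeps zero-filled borders (from the warp and
            # from the acquisition) out of the metric
            my = max(2, int(0.08 * m.shape[1]))
            mx = max(2, int(0.08 * m.shape[2]))
            d = warped[:, my:-my, mx:-mx] - f[:, my:-my, mx:-mx]
            return float(np.mean(d ** 2))

        res = minimize(cost, x, method="Powell",
                       options={"maxiter": max_iter, "xtol": tol, "ftol": tol})
        x = np.asarray(res.x, float).reshape(-1)
        converged = converged and bool(res.success)
    p = dict(_DEFAULTS)
    for n, v in zip(names, x):
        p[n] = float(v) * unit[n]
    t = AffineTransform2D(**p)
    t.converged = converged
    return t


def warp_volume(vol: VolumeImage, t: AffineTransform2D,
                interpolation: str = "bicubic") -> VolumeImage:
    """Apply one in-plane transform to every slice of a volume."""
    out = _warp_volume(np.asarray(vol.data, float), t, _ORDER[interpolation])
    return VolumeImage(out, vol.spacing, vol.intensity_range)


def subtract(post_registered: VolumeImage, pre: VolumeImage) -> VolumeImage:
    """Contrast subtraction ``I_sub = max(I_reg - I_pre, 0)``."""
    a, b = post_registered.data, pre.data
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return VolumeImage(np.maximum(a - b, 0.0), pre.spacing, pre.intensity_range)
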
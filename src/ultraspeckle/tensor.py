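"""Per-pixel intensity Hessian (diffusion tensor) and its eigensystem.

The local diffusion of the intensity field is summarized by the 2x2 Hessian

    H = [[Ixx, Ixy],
         [Ixy, Iyy]],

computed by convolving the image with analytic second-order Gaussian
derivative kernels at scale ``sigma`` (x = column axis, y = row axis).
H is symmetric, so its eigenvalues are real and its eigenvectors orthogonal.
Eigenvalues are ordered by magnitude, |lam1| >= |lam2|: the major
eigenvector points across a 1D structure, the minor eigenvector along it.
Eigenvalues are then normalized by the global maximum magnitude so every
value lies in [-1, 1], which makes the classifier thresholds scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import GrayImage

__all__ = ["TensorField", "hessian_field", "compute_eigensystem",
           "eig2x2_symmetric", "normalize_field"]

DEFAULT_SIGMA = 1.4  # pixels; scale of the Gaussian-derivative kernels
_TRUNCATE = 4.0      # kernel support radius in units of sigma

# Curvatures below this (intensity / pixel^2, on the [0, 255] scale) are
# indistinguishable from convolution roundoff on a flat image.
_ZERO_FIELD_TOL = 1e-9


@dataclass
class TensorField:
    """Hessian entries plus (optionally) the eigensystem, per pixel.

    Eigenvector components are expressed in (x, y) = (column, row) axes.
    ``norm_const`` records the global max |eigenvalue| used to normalize;
    it is 0.0 for an identically-zero field.
    """

    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray
    lam1: np.ndarray | None = None
    lam2: np.ndarray | None = None
    v1x: np.ndarray | None = None
    v1y: np.ndarray | None = None
    v2x: np.ndarray | None = None
    v2y: np.ndarray | None = None
    norm_const: float = field(default=0.0)
    normalized: bool = field(default=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ixx.shape

    def require_eigensystem(self) -> None:
        if self.lam1 is None:
            raise ValueError("eigensystem not computed; call compute_eigensystem")

    def require_normalized(self) -> None:
        self.require_eigensystem()
        if not self.normalized:
            raise ValueError("tensor field not normalized; call normalize_field")


def _gauss_deriv_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative kernel with exact discrete moments.

    Truncation leaves the raw sampled kernels with small moment errors
    (e.g. the second-derivative kernel does not sum exactly to zero, so a
    flat image would acquire a uniform curvature bias).  The kernels are
    therefore corrected so that, under correlation:

      order 0: sum = 1;  order 1: sum = 0, response to I = x is exactly 1;
      order 2: sum = 0, response to I = x^2 is exactly 2.
    """
    radius = int(_TRUNCATE * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-(x**2) / (2.0 * sigma**2))
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = x / sigma**2 * phi  # antisymmetric: sum is 0 already
        return k / np.sum(x * k)
    if order == 2:
        k = (x**2 - sigma**2) / sigma**4 * phi
        k -= k.mean()
        return k * (2.0 / np.sum(x**2 * k))
    raise ValueError(f"unsupported derivative order {order}")


def hessian_field(img: GrayImage, sigma: float = DEFAULT_SIGMA) -> TensorField:
    """Convolve the image with second-order Gaussian-derivative kernels.

    Border handling is mirror reflection; kernels are truncated at 4*sigma
    (relative truncation error below 1e-4).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    px = img.pixels

    def g2(order_y: int, order_x: int) -> np.ndarray:
        out = ndimage.correlate1d(px, _gauss_deriv_kernel(sigma, order_y),
                                  axis=0, mode="mirror")
        return ndimage.correlate1d(out, _gauss_deriv_kernel(sigma, order_x),
                                   axis=1, mode="mirror")

    # axis 0 is y (rows), axis 1 is x (columns)
    return TensorField(ixx=g2(0, 2), ixy=g2(1, 1), iyy=g2(2, 0))


def _eig_arrays(ixx, ixy, iyy):
    """Vectorized closed-form eigendecomposition of symmetric 2x2 fields."""
    mean = 0.5 * (ixx + iyy)
    disc = np.hypot(0.5 * (ixx - iyy), ixy)
    lo = mean - disc  # algebraically smaller eigenvalue
    hi = mean + disc
    # Magnitude ordering; on a magnitude tie with hi != lo the negative
    # eigenvalue (lo) is the major one, which the non-strict comparison gives.
    hi_major = np.abs(hi) > np.abs(lo)
    lam1 = np.where(hi_major, hi, lo)
    lam2 = np.where(hi_major, lo, hi)

    # Minor eigenvector: (ixy, lam2 - ixx) or (lam2 - iyy, ixy), whichever
    # has the larger norm; degenerate (both ~0) falls back to (0, 1).
    ax, ay = np.broadcast_to(ixy, lam2.shape), lam2 - ixx
    bx, by = lam2 - iyy, np.broadcast_to(ixy, lam2.shape)
    na = np.hypot(ax, ay)
    nb = np.hypot(bx, by)
    use_a = na >= nb
    vx = np.where(use_a, ax, bx)
    vy = np.where(use_a, ay, by)
    norm = np.hypot(vx, vy)
    scale = np.hypot(np.abs(ixx) + np.abs(ixy), np.abs(iyy)) + 1.0
    degenerate = norm <= 1e-14 * scale
    vx = np.where(degenerate, 0.0, vx)
    vy = np.where(degenerate, 1.0, vy)
    norm = np.where(degenerate, 1.0, norm)
    v2x, v2y = vx / norm, vy / norm
    # Sign canonicalization: v2x >= 0, and v2y >= 0 when v2x == 0.
    flip2 = (v2x < 0) | ((v2x == 0) & (v2y < 0))
    v2x, v2y = np.where(flip2, -v2x, v2x), np.where(flip2, -v2y, v2y)
    # Major eigenvector is the orthogonal complement, same canonicalization.
    v1x, v1y = -v2y, v2x
    flip1 = (v1x < 0) | ((v1x == 0) & (v1y < 0))
    v1x, v1y = np.where(flip1, -v1x, v1x), np.where(flip1, -v1y, v1y)
    return lam1, lam2, v1x, v1y, v2x, v2y


def eig2x2_symmetric(
    ixx: float, ixy: float, iyy: float
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Closed-form eigendecomposition of [[ixx, ixy], [ixy, iyy]].

    Returns ``(lam1, lam2, v1, v2)`` with |lam1| >= |lam2|, unit orthogonal
    eigenvectors as (x, y) tuples.  On a magnitude tie between distinct
    eigenvalues the negative one is the major eigenvalue.  The zero matrix
    yields lam1 = lam2 = 0 with v1 = (1, 0), v2 = (0, 1) by convention.
    """
    vals = np.array([ixx, ixy, iyy], dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("Hessian entries must be finite")
    lam1, lam2, v1x, v1y, v2x, v2y = _eig_arrays(*vals)
    return (float(lam1), float(lam2),
            (float(v1x), float(v1y)), (float(v2x), float(v2y)))


def compute_eigensystem(tf: TensorField) -> TensorField:
    """Fill in eigenvalues and eigenvectors for every pixel (in place)."""
    tf.lam1, tf.lam2, tf.v1x, tf.v1y, tf.v2x, tf.v2y = _eig_arrays(
        tf.ixx, tf.ixy, tf.iyy
    )
    return tf


def normalize_field(tf: TensorField) -> TensorField:
    """Divide all eigenvalues by the global maximum magnitude (in place).

    After normalization every eigenvalue lies in [-1, 1] and the maximum
    magnitude over the field is exactly 1.  A zero field — including one
    whose responses are only floating-point residue from a flat image — is
    returned unchanged with ``norm_const = 0``, so a featureless image does
    not get roundoff noise blown up to unit eigenvalues.
    """
    tf.require_eigensystem()
    norm_const = float(np.abs(tf.lam1).max())  # |lam1| >= |lam2| pointwise
    if norm_const > _ZERO_FIELD_TOL:
        tf.norm_const = norm_const
        tf.lam1 = tf.lam1 / norm_const
        tf.lam2 = tf.lam2 / norm_const
    else:
        tf.norm_const = 0.0
    tf.normalized = True
    return tf
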
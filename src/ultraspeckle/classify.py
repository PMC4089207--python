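"""Five-type structure classification from the normalized tensor field.

From the normalized eigenvalues (lam1, lam2), |lam1| >= |lam2|, two
responses are formed per pixel:

    T1 = lam1^2 + lam2^2            (feature strength, in [0, 2])
    T2 = (|lam2| + eps) / (|lam1| + eps)   (isotropy ratio, eps guards 0/0)

and from them the linearity and spot measures

    Cl = T1 * (1 - T2),   Cs = T1 * T2        (so Cl + Cs = T1).

The decision rules, applied in order:

  1. T1 <= beta                      -> UNIFORM   (no feature)
  2. T1 > beta, Cl > Cs, lam1 <= 0   -> LINEAR    (bright ridge: local max)
  3. T1 > beta, Cl > Cs, lam1 > 0    -> BOUNDARY  (dark valley: local min)
  4. T1 >= alpha, Cs > Cl            -> SPOT      (isotropic concentration)
  5. otherwise                       -> UNKNOWN

The alpha guard on rule 4 keeps moderately noisy isotropic responses out of
the SPOT class.  A refinement pass then reclassifies SPOT/UNKNOWN pixels
that sit on a tubular structure (e.g. a high-curvature boundary segment
whose echo is weak): each is relabeled after its two neighbors along the
minor eigenvector, so broken curves are merged back together.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np

from .tensor import TensorField

__all__ = ["Structure", "ResponseMaps", "StructureMap", "ClassifierParams",
           "responses", "classify_pixel", "classify_field", "refine",
           "save_typemap"]


class Structure(IntEnum):
    """Per-pixel structure label."""

    UNIFORM = 0
    LINEAR = 1
    BOUNDARY = 2
    SPOT = 3
    UNKNOWN = 4


# Display palette for exported type maps: grey uniform, green linear,
# dark-green boundary, red spot, blue unknown.
_PALETTE = {
    Structure.UNIFORM: (128, 128, 128),
    Structure.LINEAR: (0, 220, 0),
    Structure.BOUNDARY: (0, 110, 0),
    Structure.SPOT: (220, 0, 0),
    Structure.UNKNOWN: (0, 0, 220),
}


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the structure classifier.

    beta: feature-strength threshold below which a pixel is uniform.
    alpha: minimum strength for the spot class (guards against noise).
    epsilon: guard added to numerator and denominator of the T2 ratio.
    refine_iters: number of refinement sweeps over the SPOT/UNKNOWN queue.
    """

    beta: float = 0.12
    alpha: float = 0.45
    epsilon: float = 1e-6
    refine_iters: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < self.alpha < 2.0):
            raise ValueError(
                f"need 0 < beta < alpha < 2, got beta={self.beta}, alpha={self.alpha}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.refine_iters < 0:
            raise ValueError("refine_iters must be >= 0")


@dataclass(frozen=True)
class ResponseMaps:
    t1: np.ndarray
    t2: np.ndarray
    cl: np.ndarray
    cs: np.ndarray


@dataclass(frozen=True)
class StructureMap:
    """2D array of :class:`Structure` labels."""

    labels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def counts(self) -> dict[str, int]:
        """Pixels per structure type (every pixel counted exactly once)."""
        return {
            s.name.lower(): int(np.count_nonzero(self.labels == s))
            for s in Structure
        }


def responses(lam1n, lam2n, epsilon: float = 1e-6):
    """Compute (T1, T2, Cl, Cs) from normalized eigenvalues (vectorizable)."""
    lam1n = np.asarray(lam1n, dtype=np.float64)
    lam2n = np.asarray(lam2n, dtype=np.float64)
    t1 = lam1n**2 + lam2n**2
    t2 = (np.abs(lam2n) + epsilon) / (np.abs(lam1n) + epsilon)
    cl = t1 * (1.0 - t2)
    cs = t1 * t2
    return t1, t2, cl, cs


def _decide(t1, cl, cs, lam1n, params: ClassifierParams):
    return np.select(
        [
            t1 <= params.beta,
            (cl > cs) & (lam1n <= 0),
            cl > cs,
            (t1 >= params.alpha) & (cs > cl),
        ],
        [Structure.UNIFORM, Structure.LINEAR, Structure.BOUNDARY, Structure.SPOT],
        default=Structure.UNKNOWN,
    ).astype(np.uint8)


def classify_pixel(
    t1: float, cl: float, cs: float, lam1n: float,
    params: ClassifierParams | None = None,
) -> Structure:
    """Apply the decision rules to one pixel's responses."""
    params = params or ClassifierParams()
    return Structure(
        int(_decide(np.float64(t1), np.float64(cl), np.float64(cs),
                    np.float64(lam1n), params))
    )


def classify_field(
    tf: TensorField, params: ClassifierParams | None = None
) -> tuple[ResponseMaps, StructureMap]:
    """Classify every pixel of a normalized tensor field."""
    params = params or ClassifierParams()
    tf.require_normalized()
    t1, t2, cl, cs = responses(tf.lam1, tf.lam2, params.epsilon)
    labels = _decide(t1, cl, cs, tf.lam1, params)
    return ResponseMaps(t1, t2, cl, cs), StructureMap(labels)


def refine(
    smap: StructureMap, tf: TensorField, params: ClassifierParams | None = None
) -> StructureMap:
    """Reclassify SPOT/UNKNOWN pixels that adjoin a tubular structure.

    All SPOT and UNKNOWN pixels are queued in raster order.  For each, the
    two adjacent pixels in the positive and negative minor-eigenvector
    direction (nearest-pixel rounding of p +/- v2) are inspected: a LINEAR
    neighbor relabels the pixel LINEAR; otherwise a BOUNDARY neighbor
    relabels it BOUNDARY; otherwise it is kept for the next sweep.
    Relabeling takes effect immediately, so later queue entries see it.
    The sweep is repeated ``refine_iters`` times with a freshly rebuilt
    queue.  Off-image neighbors are ignored; a pixel with a zero minor
    eigenvector is left unchanged.
    """
    params = params or ClassifierParams()
    if smap.shape != tf.shape:
        raise ValueError(f"shape mismatch: map {smap.shape} vs field {tf.shape}")
    tf.require_eigensystem()
    labels = smap.labels.copy()
    nrows, ncols = labels.shape

    def rnd(x: float) -> int:
        # round half away from zero offsets deterministically
        return int(np.floor(x + 0.5))

    for _ in range(params.refine_iters):
        queue = np.argwhere(
            (labels == Structure.SPOT) | (labels == Structure.UNKNOWN)
        )  # raster order
        for r, c in queue:
            vx = tf.v2x[r, c]
            vy = tf.v2y[r, c]
            if vx == 0.0 and vy == 0.0:
                continue
            neighbor_labels = []
            for sign in (1.0, -1.0):
                rr, cc = rnd(r + sign * vy), rnd(c + sign * vx)
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    neighbor_labels.append(labels[rr, cc])
            if Structure.LINEAR in neighbor_labels:
                labels[r, c] = Structure.LINEAR
            elif Structure.BOUNDARY in neighbor_labels:
                labels[r, c] = Structure.BOUNDARY
    return StructureMap(labels)


def save_typemap(smap: StructureMap, path: str | Path) -> None:
    """Export a structure map as an indexed PNG with the display palette."""
    from PIL import Image

    im = Image.fromarray(smap.labels.astype(np.uint8), mode="P")
    palette = [0] * 768
    for s, rgb in _PALETTE.items():
        palette[3 * int(s): 3 * int(s) + 3] = rgb
    im.putpalette(palette)
    im.save(Path(path))
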
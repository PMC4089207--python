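"""Synthetic data, quality metrics, and baseline filters.

This module makes the whole despeckling protocol testable without any
external images: a phantom generator that emulates the tissue structures
the classifier targets (piecewise-uniform regions, bright/dark curvilinear
boundaries with Gaussian cross-section, isolated bright/dark spots), a
multiplicative speckle model, PSNR/SSIM metrics, the plain Gaussian/median
baseline filters, and a benchmark driver that corrupts, filters, and scores.

Speckle model
-------------
Speckle is multiplicative: ``I*(x, y) = I(x, y) * n(x, y)`` with a
Rayleigh-shaped noise field.  A raw Rayleigh variate has its mean and
standard deviation locked together, and a non-unit-mean field would shift
overall brightness, so the field is built as ``n = 1 + sigma * Z`` where Z
is a standardized (zero-mean, unit-variance) Rayleigh variate and ``sigma``
is the target coefficient of variation; n is clipped at 0 and the product
at [0, 255].  For a constant image of level I this gives the closed form
``MSE = (I * sigma)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imgio import GrayImage
from .pipeline import PipelineConfig, despeckle

__all__ = [
    "NoiseSpec", "Ridge", "Spot", "PhantomSpec", "Truth",
    "multiplicative_rayleigh", "make_phantom", "default_phantom_spec",
    "psnr", "ssim", "baseline_gaussian", "baseline_median", "run_benchmark",
]

# ---------------------------------------------------------------------------
# speckle noise


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative speckle: target coefficient of variation and RNG seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


# Rayleigh(scale=1): mean sqrt(pi/2), variance (4 - pi)/2
_RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))
_RAYLEIGH_STD = float(np.sqrt(2.0 - np.pi / 2.0))


def multiplicative_rayleigh(img: GrayImage, spec: NoiseSpec) -> GrayImage:
    """Corrupt an image with multiplicative Rayleigh-shaped speckle."""
    if spec.sigma == 0.0:
        return GrayImage(img.pixels.copy())
    rng = np.random.default_rng(spec.seed)
    raw = rng.rayleigh(scale=1.0, size=img.shape)
    z = (raw - _RAYLEIGH_MEAN) / _RAYLEIGH_STD
    n = np.maximum(1.0 + spec.sigma * z, 0.0)
    return GrayImage(np.clip(img.pixels * n, 0.0, 255.0))


# ---------------------------------------------------------------------------
# phantoms


class Truth(IntEnum):
    """Ground-truth mask labels for phantom pixels."""

    FLAT = 0          # interior of a uniform region
    CREST_BRIGHT = 1  # centerline of a bright ridge (expected LINEAR)
    CREST_DARK = 2    # centerline of a dark curve (expected BOUNDARY)
    SPOT_CENTER = 3   # center pixel of an isolated spot
    DONT_CARE = 4     # near a structure border; excluded from scoring


@dataclass(frozen=True)
class Ridge:
    """A curvilinear structure with Gaussian cross-section.

    points: polyline vertices as (row, col) pairs.
    amplitude: added intensity at the crest (negative = dark curve).
    width: cross-section standard deviation in pixels.
    """

    points: tuple[tuple[float, float], ...]
    amplitude: float
    width: float


@dataclass(frozen=True)
class Spot:
    """An isotropic Gaussian bump: center (row, col), amplitude, radius (std)."""

    center: tuple[float, float]
    amplitude: float
    radius: float


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (256, 256)
    background_levels: tuple[float, ...] = (60.0, 110.0, 160.0)
    ridges: tuple[Ridge, ...] = ()
    spots: tuple[Spot, ...] = ()
    seed: int = 0
    crest_tol: float = 0.6    # max distance (px) from centerline to count as crest
    care_margin: float = 4.0  # don't-care band half-width, in structure widths

    def __post_init__(self) -> None:
        if self.size[0] < 64 or self.size[1] < 64:
            raise ValueError("phantom must be at least 64x64")
        for r in self.ridges:
            if r.width <= 0:
                raise ValueError("ridge width must be positive")
        for s in self.spots:
            if s.radius <= 0:
                raise ValueError("spot radius must be positive")


def _polyline_distance(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Distance from every pixel to a densely resampled polyline."""
    segs = []
    for p, q in zip(points[:-1], points[1:]):
        length = float(np.hypot(*(q - p)))
        n = max(int(np.ceil(length / 0.25)), 1)
        t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
        segs.append(p[None, :] + t * (q - p)[None, :])
    segs.append(points[-1:][:])
    samples = np.concatenate(segs, axis=0)
    tree = cKDTree(samples)
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    dist, _ = tree.query(grid, workers=-1)
    return dist.reshape(shape)


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray]:
    """Render a phantom and its ground-truth mask.

    The background is a set of equal-width vertical bands at the given
    levels.  Ridges and spots are added on top; overlapping structures add
    and the overlap is marked don't-care.  The truth mask (dtype uint8,
    values of :class:`Truth`) marks ridge centerlines, spot centers, and
    flat interiors, with a don't-care band around every structure and
    around the band boundaries.
    """
    nrows, ncols = spec.size
    img = np.zeros((nrows, ncols), dtype=np.float64)
    truth = np.full((nrows, ncols), Truth.FLAT, dtype=np.uint8)

    nbands = len(spec.background_levels)
    edges = np.linspace(0, ncols, nbands + 1).round().astype(int)
    for level, lo, hi in zip(spec.background_levels, edges[:-1], edges[1:]):
        img[:, lo:hi] = level
    # band boundaries are intensity steps: exclude a margin from scoring
    cols = np.arange(ncols)
    for e in edges[1:-1]:
        truth[:, np.abs(cols - e + 0.5) < 8] = Truth.DONT_CARE

    structure_count = np.zeros((nrows, ncols), dtype=np.intp)

    crest_masks: list[tuple[np.ndarray, Truth]] = []
    for ridge in spec.ridges:
        pts = np.asarray(ridge.points, dtype=np.float64)
        dist = _polyline_distance(pts, (nrows, ncols))
        img += ridge.amplitude * np.exp(-(dist**2) / (2.0 * ridge.width**2))
        near = dist < spec.care_margin * ridge.width
        truth[near] = Truth.DONT_CARE
        structure_count += near
        kind = Truth.CREST_BRIGHT if ridge.amplitude > 0 else Truth.CREST_DARK
        crest_masks.append((dist < spec.crest_tol, kind))

    spot_centers: list[tuple[int, int]] = []
    for spot in spec.spots:
        r0, c0 = spot.center
        rr, cc = np.mgrid[0:nrows, 0:ncols]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        img += spot.amplitude * np.exp(-d2 / (2.0 * spot.radius**2))
        near = d2 < (spec.care_margin * spot.radius) ** 2
        truth[near] = Truth.DONT_CARE
        structure_count += near
        spot_centers.append((int(round(r0)), int(round(c0))))

    overlap = structure_count > 1
    for mask, kind in crest_masks:
        truth[mask & ~overlap] = kind
    for r0, c0 in spot_centers:
        if 0 <= r0 < nrows and 0 <= c0 < ncols and not overlap[r0, c0]:
            truth[r0, c0] = Truth.SPOT_CENTER

    return GrayImage(np.clip(img, 0.0, 255.0)), truth


def default_phantom_spec(size: tuple[int, int] = (256, 256),
                         seed: int = 0) -> PhantomSpec:
    """The standard test phantom: three flat bands, two bright ridges, one
    dark curve, and four spots (two bright, two dark).

    Structure strengths are chosen so that, after Gaussian-derivative
    smoothing at the default scale, ridge crests carry the largest Hessian
    eigenvalue magnitudes and spot centers remain well above the spot
    threshold once eigenvalues are normalized.  The seed jitters the curve
    phases only; rendering is otherwise deterministic.
    """
    nrows, ncols = size
    rng = np.random.default_rng(seed)

    def wavy(row: float, amp: float, cycles: float) -> tuple[tuple[float, float], ...]:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        cs = np.linspace(0, ncols - 1, 33)
        rs = row + amp * np.sin(phase + 2.0 * np.pi * cycles * cs / ncols)
        return tuple((float(r), float(c)) for r, c in zip(rs, cs))

    sr = nrows / 256.0
    sc = ncols / 256.0
    ridges = (
        Ridge(points=wavy(60.0 * sr, 5.0, 1.5), amplitude=90.0, width=1.8),
        Ridge(points=wavy(120.0 * sr, 5.0, 2.0), amplitude=90.0, width=1.8),
        Ridge(points=wavy(190.0 * sr, 4.0, 1.0), amplitude=-50.0, width=2.0),
    )
    spots = (
        Spot(center=(35.0 * sr, 40.0 * sc), amplitude=90.0, radius=2.5),
        Spot(center=(38.0 * sr, 210.0 * sc), amplitude=-90.0, radius=2.5),
        Spot(center=(225.0 * sr, 60.0 * sc), amplitude=90.0, radius=2.5),
        Spot(center=(222.0 * sr, 200.0 * sc), amplitude=-90.0, radius=2.5),
    )
    return PhantomSpec(size=size, ridges=ridges, spots=spots, seed=seed)


# ---------------------------------------------------------------------------
# quality metrics


def psnr(a: GrayImage, b: GrayImage) -> float:
    """Peak signal-to-noise ratio in dB, 10*log10(255^2 / MSE).

    Identical images (MSE = 0) are reported as 100 dB.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a.pixels - b.pixels) ** 2))
    if mse == 0.0:
        return 100.0
    return float(10.0 * np.log10(255.0**2 / mse))


_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius int(3.5 * 1.5 + 0.5) = 5  ->  11x11 window
_SSIM_PAD = 5
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03
_SSIM_L = 255.0


def ssim(a: GrayImage, b: GrayImage) -> float:
    """Mean structural similarity with an 11x11 Gaussian window (sigma 1.5).

    The Wang et al. formulation: local means, variances and covariance are
    Gaussian-weighted, constants C1 = (K1 L)^2 and C2 = (K2 L)^2 with
    K1 = 0.01, K2 = 0.03, L = 255.  A border of half the window width is
    excluded from the mean, so the result is independent of padding.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 2 * _SSIM_PAD + 1:
        raise ValueError(f"image smaller than the {2*_SSIM_PAD+1}x"
                         f"{2*_SSIM_PAD+1} SSIM window: {a.shape}")
    x, y = a.pixels, b.pixels

    def filt(z: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(z, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)

    ux, uy = filt(x), filt(y)
    vxx = filt(x * x) - ux * ux
    vyy = filt(y * y) - uy * uy
    vxy = filt(x * y) - ux * uy
    c1 = (_SSIM_K1 * _SSIM_L) ** 2
    c2 = (_SSIM_K2 * _SSIM_L) ** 2
    s = ((2.0 * ux * uy + c1) * (2.0 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vxx + vyy + c2)
    )
    p = _SSIM_PAD
    return float(np.mean(s[p:-p, p:-p]))


# ---------------------------------------------------------------------------
# baseline filters and the benchmark driver


def baseline_gaussian(img: GrayImage, sigma: float = 1.0) -> GrayImage:
    """Plain full-image Gaussian smoothing (the comparison setting)."""
    out = ndimage.gaussian_filter(img.pixels, sigma, mode="mirror", truncate=4.0)
    return GrayImage(np.clip(out, 0.0, 255.0))


def baseline_median(img: GrayImage, size: int = 7) -> GrayImage:
    """Plain full-image median filtering (the comparison setting)."""
    out = ndimage.median_filter(img.pixels, size=size, mode="mirror")
    return GrayImage(out)


_BUILTIN_METHODS: dict[str, Callable[[GrayImage], GrayImage]] = {
    "identity": lambda im: im,
    "gaussian": baseline_gaussian,
    "median": baseline_median,
}


def run_benchmark(
    images: Sequence[tuple[str, GrayImage]],
    sigmas: Sequence[float],
    methods: Sequence[str | tuple[str, Callable[[GrayImage], GrayImage]]],
    passes: int = 3,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Corrupt, filter, and score: one row per (image, sigma, method, pass).

    Methods: ``"proposed"`` (the structure-based pipeline, scored after
    every pass up to ``passes``), ``"gaussian"``, ``"median"``,
    ``"identity"`` (scores the noisy image itself), or ``(name, callable)``
    pairs for external filters.  Columns: image, sigma, method, pass,
    psnr_db, ssim.  The proposed method is evaluated with equalization off
    so outputs stay on the reference intensity scale.
    """
    cfg = (config or PipelineConfig()).replace(equalize_each_pass=False)
    rows = []
    for img_idx, (name, clean) in enumerate(images):
        for sig_idx, sigma in enumerate(sigmas):
            noise_seed = seed + 1000 * img_idx + sig_idx
            noisy = multiplicative_rayleigh(clean, NoiseSpec(sigma, noise_seed))
            for method in methods:
                if isinstance(method, tuple):
                    mname, fn = method
                    filtered = fn(noisy)
                    rows.append((name, sigma, mname, 1,
                                 psnr(clean, filtered), ssim(clean, filtered)))
                elif method == "proposed":
                    current = noisy
                    for p in range(1, passes + 1):
                        current, _ = despeckle(current, cfg.replace(passes=1))
                        rows.append((name, sigma, "proposed", p,
                                     psnr(clean, current), ssim(clean, current)))
                elif method in _BUILTIN_METHODS:
                    filtered = _BUILTIN_METHODS[method](noisy)
                    rows.append((name, sigma, method, 1,
                                 psnr(clean, filtered), ssim(clean, filtered)))
                else:
                    raise ValueError(f"unknown method: {method!r}")
    return pd.DataFrame(
        rows, columns=["image", "sigma", "method", "pass", "psnr_db", "ssim"]
    )
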
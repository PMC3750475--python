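"""Fluorescent spot detection by the multiscale product of wavelet details.

The red channel is decomposed with the undecimated à-trous transform: at
level ``i`` the approximation ``A_{i-1}`` is smoothed separably (rows, then
columns) with the B3-spline kernel ``[1/16, 1/4, 3/8, 1/4, 1/16]`` dilated by
inserting ``2^{i-1} - 1`` zeros between its taps, giving ``A_i``; the detail
is ``W_i = A_{i-1} - A_i`` (bright spots give positive details; the sum of
all details plus ``A_J`` reconstructs the input exactly).  Spot-like
structures persist at every scale, so the pixelwise product ``P_J = prod_i
W_i`` is large only at spots.  Detection keeps pixels whose detail exceeds
``k`` robust noise standard deviations (MAD-based) at every level and where
``P_J > 0``, then removes components smaller than ``min_area``.

An optional pre-step removes green-to-red bleed-through.  Modeling the
measured red image as ``I = R + beta*G`` with the true signal ``R`` sparse,
``beta`` is estimated by least squares (no intercept) and the corrected
signal is ``max(I - beta_hat*G, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask, Raster, ValidationError, ZebregError

__all__ = [
    "ATROUS_KERNEL",
    "WaveletStack",
    "ProductImage",
    "BleedthroughFit",
    "Spot",
    "SpotSet",
    "dilated_kernel",
    "atrous_decompose",
    "multiscale_product",
    "detect_spots",
    "correct_bleedthrough",
]

ATROUS_KERNEL = np.array([1, 4, 6, 4, 1], dtype=np.float64) / 16.0

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class WaveletStack:
    """À-trous decomposition: approximations A_0..A_J and details W_1..W_J."""

    approximations: list[np.ndarray]
    details: list[np.ndarray]
    kernel: np.ndarray

    @property
    def levels(self) -> int:
        return len(self.details)


@dataclass(frozen=True)
class ProductImage:
    """Pixelwise product of the detail images W_1..W_J."""

    pixels: np.ndarray
    levels: int


@dataclass(frozen=True)
class BleedthroughFit:
    """Estimated bleed-through coefficient and the corrected red channel."""

    beta_hat: float
    corrected: Raster


@dataclass(frozen=True)
class Spot:
    centroid: tuple[float, float]
    area: int


@dataclass(frozen=True)
class SpotSet:
    mask: BinaryMask
    spots: list[Spot]

    def __len__(self) -> int:
        return len(self.spots)

    def centroids(self) -> np.ndarray:
        if not self.spots:
            return np.empty((0, 2))
        return np.array([s.centroid for s in self.spots])


def dilated_kernel(level: int, base: np.ndarray = ATROUS_KERNEL) -> np.ndarray:
    """Level-``i`` à-trous kernel: 2^(i-1) - 1 zeros between the base taps."""
    if level < 1:
        raise ValidationError(f"Level must be >= 1, got {level}")
    gap = 2 ** (level - 1) - 1
    out = np.zeros(len(base) + gap * (len(base) - 1))
    out[:: gap + 1] = base
    return out


def atrous_decompose(image: Raster, levels: int = 3) -> WaveletStack:
    """Undecimated à-trous wavelet decomposition with reflective borders."""
    if levels < 1:
        raise ValidationError(f"levels must be >= 1, got {levels}")
    top_kernel = dilated_kernel(levels)
    if min(image.shape) < len(top_kernel):
        raise ValidationError(
            f"Image shape {image.shape} smaller than the level-{levels} kernel "
            f"support ({len(top_kernel)})"
        )
    approximations = [image.pixels.copy()]
    details: list[np.ndarray] = []
    for level in range(1, levels + 1):
        kern = dilated_kernel(level)
        prev = approximations[-1]
        smoothed = ndimage.correlate1d(prev, kern, axis=1, mode="reflect")
        smoothed = ndimage.correlate1d(smoothed, kern, axis=0, mode="reflect")
        approximations.append(smoothed)
        details.append(prev - smoothed)
    return WaveletStack(approximations=approximations, details=details, kernel=ATROUS_KERNEL.copy())


def multiscale_product(stack: WaveletStack) -> ProductImage:
    """P_J(x, y) = product over levels of W_i(x, y)."""
    prod = np.ones_like(stack.details[0])
    for detail in stack.details:
        prod = prod * detail
    return ProductImage(pixels=prod, levels=stack.levels)


def _robust_sigma(detail: np.ndarray) -> float:
    med = np.median(detail)
    return float(np.median(np.abs(detail - med)) / 0.6745)


def detect_spots(
    product: ProductImage,
    stack: WaveletStack,
    k: float = 3.0,
    min_area: int = 4,
) -> SpotSet:
    """Threshold the multiscale product into labeled spots.

    A pixel is a candidate when its detail exceeds ``k`` times the MAD-based
    robust noise sigma at *every* level and the multiscale product is
    positive; 8-connected components smaller than ``min_area`` are dropped.
    An empty result is valid.
    """
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if min_area < 1:
        raise ValidationError(f"min_area must be >= 1, got {min_area}")
    candidates = product.pixels > 0
    for detail in stack.details:
        sigma = _robust_sigma(detail)
        candidates &= detail > k * sigma
    labels, n = ndimage.label(candidates, structure=EIGHT_CONNECTED)
    spots: list[Spot] = []
    keep = np.zeros_like(candidates)
    if n:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        centroids = ndimage.center_of_mass(candidates, labels, index=range(1, n + 1))
        for label, area, centroid in zip(range(1, n + 1), areas, centroids):
            if area >= min_area:
                keep |= labels == label
                spots.append(Spot(centroid=(float(centroid[0]), float(centroid[1])), area=int(area)))
    return SpotSet(mask=BinaryMask(keep), spots=spots)


def correct_bleedthrough(red: Raster, green: Raster) -> BleedthroughFit:
    """Least-squares bleed-through removal: beta_hat = <I, G> / <G, G>.

    The corrected channel is ``max(I - beta_hat*G, 0)``.  The model has no
    intercept; remove any constant background upstream.
    """
    if red.shape != green.shape:
        raise ValidationError(f"Channel shapes differ: {red.shape} vs {green.shape}")
    g = green.pixels
    denom = float(np.sum(g * g))
    if denom == 0.0:
        raise ZebregError("Green channel is identically zero; beta is undefined")
    beta = float(np.sum(red.pixels * g)) / denom
    corrected = np.maximum(red.pixels - beta * g, 0.0)
    return BleedthroughFit(beta_hat=beta, corrected=Raster(corrected))
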
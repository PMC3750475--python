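"""Embryo body segmentation and outline extraction.

The embryo outline is found in four steps: Otsu thresholding of the intensity
histogram, OR-combined with zero-crossing edges of a Laplacian-of-Gaussian
(LoG) filter response (which recovers faint structures such as vasculature
that fall below the global threshold), morphological closing with a disk to
bridge gaps, and selection of the largest connected component.  The outline
is then traced with the Moore-neighbor boundary-following algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask, Contour, Raster, ValidationError, ZebregError

__all__ = [
    "SegmentationParams",
    "DegenerateInputError",
    "NoForegroundError",
    "otsu_threshold",
    "log_kernel",
    "log_edge_mask",
    "disk_closing",
    "trace_boundary",
    "segment_embryo",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class DegenerateInputError(ZebregError):
    """Raised for inputs (e.g. constant images) with no meaningful answer."""


class NoForegroundError(ZebregError):
    """Raised when segmentation finds no foreground at all."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the outline segmentation.

    log_sigma / log_size
        Standard deviation (px) and square support (px, odd) of the LoG
        filter; defaults 2 and 13 suppress noise while keeping edges of fine
        vasculature.
    close_radius
        Radius (px) of the disk structuring element used to close gaps left
        by dim vasculature; default 25.
    edge_min_size
        Edge components smaller than this (px) are treated as speckle and
        discarded before the closing step; real edges (outline, vasculature)
        form long curves, while isolated noise crossings would otherwise be
        welded onto the body by the large closing disk.
    invert
        Negate intensities first; used for DIC images where the embryo is
        dark on a bright background.
    """

    log_sigma: float = 2.0
    log_size: int = 13
    close_radius: int = 25
    edge_min_size: int = 10
    invert: bool = False

    def __post_init__(self) -> None:
        if self.log_size < 3 or self.log_size % 2 == 0:
            raise ValidationError(f"log_size must be odd and >= 3, got {self.log_size}")
        if self.log_sigma <= 0:
            raise ValidationError(f"log_sigma must be > 0, got {self.log_sigma}")
        if self.close_radius < 0:
            raise ValidationError(f"close_radius must be >= 0, got {self.close_radius}")


def otsu_threshold(image: Raster) -> tuple[float, BinaryMask]:
    """Global threshold maximizing between-class variance.

    The histogram uses 256 equal-width bins spanning [min, max] regardless of
    bit depth; the returned threshold is the center of the last bin assigned
    to the background class, and the mask marks pixels strictly above it.
    Raises :class:`DegenerateInputError` on constant images.
    """
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if lo == hi:
        raise DegenerateInputError("Cannot threshold a constant image")
    counts, edges = np.histogram(px, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(np.float64)
    total = counts.sum()

    # Between-class variance for a split after bin k: w0*w1*(mu0-mu1)^2.
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    mu_cum = np.cumsum(counts * centers)
    mu0 = np.divide(mu_cum[:-1], w0, out=np.zeros(255), where=w0 > 0)
    mu1 = np.divide(mu_cum[-1] - mu_cum[:-1], w1, out=np.zeros(255), where=w1 > 0)
    variance = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(variance))
    threshold = float(centers[k])
    return threshold, BinaryMask(px > threshold)


def log_kernel(sigma: float, size: int) -> np.ndarray:
    """Zero-mean Laplacian-of-Gaussian kernel on a ``size`` x ``size`` support."""
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    r2 = x * x + y * y
    gauss = np.exp(-r2 / (2.0 * sigma**2))
    kern = (r2 - 2.0 * sigma**2) / sigma**4 * gauss
    kern -= kern.mean()
    return kern


def log_edge_mask(image: Raster, params: SegmentationParams | None = None) -> BinaryMask:
    """Edges as zero crossings of the LoG-filtered image.

    A pixel is an edge when its LoG response changes sign against a
    4-neighbor and the absolute response difference across that crossing
    exceeds a noise floor.  The floor is the larger of 1e-3 of the image
    dynamic range (suppressing float-noise crossings in noiseless images)
    and 6 robust standard deviations of the neighbor response differences
    (suppressing the dense spurious crossings that sensor noise produces in
    flat regions, while steps of more than ~6 noise sigmas still register).
    Borders are handled by reflection.
    """
    params = params or SegmentationParams()
    px = image.pixels
    if px.shape[0] < params.log_size or px.shape[1] < params.log_size:
        raise ValidationError(
            f"Image shape {px.shape} smaller than LoG kernel size {params.log_size}"
        )
    resp = ndimage.convolve(px, log_kernel(params.log_sigma, params.log_size), mode="reflect")
    diffs = np.concatenate([np.diff(resp, axis=0).ravel(), np.diff(resp, axis=1).ravel()])
    sigma_d = float(np.median(np.abs(diffs - np.median(diffs)))) / 0.6745
    floor = max(1e-3 * (float(px.max()) - float(px.min())), 6.0 * sigma_d)
    # A true zero crossing has both samples bounded away from zero by the
    # local slope; where one sample is essentially zero the "crossing" is a
    # kernel-truncation artifact at the edge of the LoG support.
    tiny = 1e-4 * float(np.max(np.abs(resp))) if resp.any() else 0.0
    edges = np.zeros(px.shape, dtype=bool)
    for axis in (0, 1):
        a = np.take(resp, range(resp.shape[axis] - 1), axis=axis)
        b = np.take(resp, range(1, resp.shape[axis]), axis=axis)
        crossing = (
            (a * b < 0)
            & (np.abs(a - b) > floor)
            & (np.minimum(np.abs(a), np.abs(b)) > tiny)
        )
        # Mark the negative-response side of the crossing: for this LoG sign
        # convention that is the locally brighter pixel, so edges hug the
        # bright structure instead of widening it.
        if axis == 0:
            edges[:-1, :] |= crossing & (a < 0)
            edges[1:, :] |= crossing & (b < 0)
        else:
            edges[:, :-1] |= crossing & (a < 0)
            edges[:, 1:] |= crossing & (b < 0)
    return BinaryMask(edges)


def disk_closing(mask: BinaryMask, radius: int) -> BinaryMask:
    """Morphological closing by a Euclidean disk of the given radius.

    Implemented with two exact Euclidean distance transforms: dilation keeps
    pixels within ``radius`` of the foreground, erosion then keeps pixels
    farther than ``radius`` from the background of the dilated mask.  This is
    the algebraic closing by the discrete disk {d : |d| <= radius}, hence
    extensive and idempotent.
    """
    if radius <= 0:
        return mask
    fg = mask.bool()
    if not fg.any():
        return mask
    pad = radius + 1  # keep a background ring so both transforms see zeros
    p = np.pad(fg, pad)
    dilated = ndimage.distance_transform_edt(~p) <= radius
    closed = ndimage.distance_transform_edt(dilated) > radius
    return BinaryMask(closed[pad:-pad, pad:-pad])


_MOORE_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=np.intp,
)  # clockwise on screen starting North


def trace_boundary(mask: BinaryMask) -> Contour:
    """Moore-neighbor boundary trace of the (single-component) foreground.

    Starts at the topmost-then-leftmost foreground pixel and walks clockwise;
    terminates on re-entering the start pixel from the same direction
    (Jacob's stopping criterion), so spurs traversed in both directions are
    visited correctly.
    """
    fg = mask.bool()
    rows, cols = np.nonzero(fg)
    if len(rows) == 0:
        raise NoForegroundError("Cannot trace the boundary of an empty mask")
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))

    padded = np.zeros((fg.shape[0] + 2, fg.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = fg
    current = (start[0] + 1, start[1] + 1)
    start_p = current

    points: list[tuple[int, int]] = []
    scan_dir = 0  # start pixel is topmost-leftmost, so its North neighbor is bg
    start_exit: int | None = None
    for _ in range(4 * padded.size):
        exit_dir = -1
        for step in range(8):
            d = (scan_dir + step) % 8
            off = _MOORE_OFFSETS[d]
            cand = (current[0] + off[0], current[1] + off[1])
            if padded[cand]:
                exit_dir = d
                break
        if exit_dir < 0:  # isolated pixel: the boundary is the pixel itself
            points.append((current[0] - 1, current[1] - 1))
            break
        if current == start_p:
            if start_exit is None:
                start_exit = exit_dir
            elif exit_dir == start_exit:
                break  # Jacob's criterion: leaving start the same way again
        points.append((current[0] - 1, current[1] - 1))
        current = cand
        scan_dir = (exit_dir + 5) % 8  # resume just past the backtrack pixel
    pts = np.array(points, dtype=np.intp)
    return Contour(pts, closed=True)


def segment_embryo(
    image: Raster, params: SegmentationParams | None = None
) -> tuple[BinaryMask, Contour]:
    """Full outline segmentation: Otsu OR LoG edges, closing, largest component.

    Returns the filled body mask and its closed outer boundary contour.
    """
    params = params or SegmentationParams()
    work = Raster(-image.pixels) if params.invert else image
    _, otsu_mask = otsu_threshold(work)
    edges = log_edge_mask(work, params).bool()
    if params.edge_min_size > 1:
        labels, n = ndimage.label(edges, structure=EIGHT_CONNECTED)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
            small = np.flatnonzero(sizes < params.edge_min_size) + 1
            edges &= ~np.isin(labels, small)
    combined = BinaryMask(otsu_mask.bool() | edges)
    if combined.area == 0:
        raise NoForegroundError("Combined Otsu/edge mask is empty")
    closed = disk_closing(combined, params.close_radius)
    labels, n = ndimage.label(closed.bool(), structure=EIGHT_CONNECTED)
    if n == 0:
        raise NoForegroundError("No connected component found after closing")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    body = ndimage.binary_fill_holes(labels == largest)
    body_mask = BinaryMask(body)
    return body_mask, trace_boundary(body_mask)
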
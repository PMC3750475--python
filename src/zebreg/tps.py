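"""Regularized thin-plate-spline (TPS) fitting and warping.

The transformation ``f`` maps 2D points to 2D points as

    f(x) = a0 + a1*row + a2*col + sum_i w_i U(|x - p_i|),   U(r) = r^2 log r

(one coefficient set per output coordinate, ``U(0) = 0``).  The coefficients
minimize a penalized landmark mismatch

    J(f) = sum_i |q_i - f(p_i)|^2 / sigma_i^2 + lambda * E(f)

where ``E(f) = w^T K w`` (summed over the two output coordinates) is the
bending-energy quadratic form; for the kernel above the physical
bending-energy integral equals ``8*pi*w^T K w``.  The minimizer solves the
bordered linear system

    [K + lambda*diag(sigma_i^2), P; P^T, 0] [w; a] = [q; 0]

with ``K_ij = U(|p_i - p_j|)`` and ``P`` rows ``(1, row_i, col_i)``.  The
side conditions ``sum w_i = 0`` and ``sum w_i p_i = 0`` keep the bending
energy finite; ``lambda -> 0`` gives exact interpolation, ``lambda -> inf``
the weighted least-squares affine fit.  The default ``lambda`` is 300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .io_core import BinaryMask, OrganAtlas, Raster, ZebregError
from .landmarks import LandmarkSet

__all__ = [
    "DEFAULT_LAMBDA",
    "TpsTransform",
    "TpsFitReport",
    "DegenerateLandmarksError",
    "tps_kernel",
    "fit_tps",
    "apply_tps",
    "tps_objective",
    "warp_to_reference",
    "transfer_atlas",
]

DEFAULT_LAMBDA = 300.0
_LAMBDA_FLOOR = 1e-10  # lambda = 0 is solved as this value; keeps one code path


class DegenerateLandmarksError(ZebregError):
    """Raised when source landmarks are collinear/duplicated (singular system)."""


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """Biharmonic spline kernel U(r) = r^2 log r with U(0) = 0."""
    r = np.asarray(r, dtype=np.float64)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass(frozen=True)
class TpsTransform:
    """A fitted TPS map; ``affine`` is (3, 2), ``w`` is (n, 2), one column per
    output coordinate (row, col)."""

    affine: np.ndarray
    w: np.ndarray
    centers: np.ndarray
    lam: float
    sigma: np.ndarray

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_tps(self, points)


@dataclass(frozen=True)
class TpsFitReport:
    """Diagnostics of a TPS fit: bending energy, per-landmark residuals and
    the value of the penalized objective J(f)."""

    bending_energy: float
    residuals: np.ndarray
    objective: float


def _design_matrices(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = tps_kernel(cdist(p, p))
    P = np.column_stack([np.ones(len(p)), p])
    return K, P


def fit_tps(landmarks: LandmarkSet, lam: float = DEFAULT_LAMBDA) -> tuple[TpsTransform, TpsFitReport]:
    """Fit the regularized TPS mapping landmark sources ``p`` onto targets ``q``.

    ``lam >= 0``; zero is handled as a tiny positive floor so interpolation
    and smoothing share one solver.  Raises
    :class:`DegenerateLandmarksError` when the source points are collinear or
    duplicated.
    """
    if lam < 0:
        raise ZebregError(f"lambda must be nonnegative, got {lam}")
    p, q, sigma = landmarks.p, landmarks.q, landmarks.sigma
    n = len(p)
    K, P = _design_matrices(p)
    if np.linalg.matrix_rank(P) < 3:
        raise DegenerateLandmarksError("Source landmarks are collinear; TPS is not solvable")
    lam_eff = max(lam, _LAMBDA_FLOOR)
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K + lam_eff * np.diag(sigma**2)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = q
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateLandmarksError(f"Singular TPS system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise DegenerateLandmarksError("TPS solve produced non-finite coefficients")
    w, a = sol[:n], sol[n:]
    transform = TpsTransform(affine=a, w=w, centers=p.copy(), lam=lam, sigma=sigma.copy())

    bending = float(sum(w[:, d] @ K @ w[:, d] for d in range(2)))
    bending = max(bending, 0.0)  # K is PSD on the side-condition subspace
    fitted = K @ w + P @ a
    residuals = np.linalg.norm(q - fitted, axis=1)
    objective = float(np.sum(residuals**2 / sigma**2) + lam * bending)
    return transform, TpsFitReport(bending_energy=bending, residuals=residuals, objective=objective)


def apply_tps(t: TpsTransform, points: np.ndarray, chunk: int = 65536) -> np.ndarray:
    """Evaluate f at each (row, col) point; chunked to bound memory."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.empty_like(pts)
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        U = tps_kernel(cdist(block, t.centers))
        out[start : start + chunk] = (
            np.column_stack([np.ones(len(block)), block]) @ t.affine + U @ t.w
        )
    return out


def tps_objective(
    landmarks: LandmarkSet, w: np.ndarray, affine: np.ndarray, lam: float
) -> float:
    """J(f) for arbitrary coefficient sets (used to verify minimizer dominance)."""
    K, P = _design_matrices(landmarks.p)
    fitted = K @ w + P @ affine
    res2 = np.sum((landmarks.q - fitted) ** 2, axis=1)
    bending = float(sum(w[:, d] @ K @ w[:, d] for d in range(2)))
    return float(np.sum(res2 / landmarks.sigma**2) + lam * bending)


def _grid_points(shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)


def _snap_to_bounds(coords: np.ndarray, shape: tuple[int, int], tol: float = 1e-6) -> np.ndarray:
    """Snap coordinates within ``tol`` of the image extent onto it.

    map_coordinates treats a coordinate of -1e-15 as fully out of bounds;
    without snapping, an identity transform would zero the first row/column.
    """
    out = coords.copy()
    for d in (0, 1):
        clipped = np.clip(out[:, d], 0.0, shape[d] - 1.0)
        near = np.abs(out[:, d] - clipped) < tol
        out[near, d] = clipped[near]
    return out


def warp_to_reference(
    t: TpsTransform, target_image: Raster, reference_shape: tuple[int, int]
) -> Raster:
    """Resample the target image onto the reference grid.

    ``t`` must be fitted in the reference -> target direction (a backward
    map): each output pixel (r, c) takes the bilinear sample of the target
    image at f(r, c).  Samples outside the target are 0.
    """
    coords = _snap_to_bounds(apply_tps(t, _grid_points(reference_shape)), target_image.shape)
    sampled = ndimage.map_coordinates(
        target_image.pixels, coords.T.reshape(2, *reference_shape), order=1, mode="constant", cval=0.0
    )
    return Raster(sampled)


def transfer_atlas(
    atlas: OrganAtlas, t: TpsTransform, target_shape: tuple[int, int]
) -> dict[str, BinaryMask]:
    """Map every atlas organ mask into the target frame.

    ``t`` must map target coordinates to reference coordinates: each target
    pixel (r, c) takes the nearest-neighbor sample of the organ mask at
    f(r, c).  Organ names are preserved.
    """
    coords = _snap_to_bounds(
        apply_tps(t, _grid_points(target_shape)), atlas.reference.shape
    ).T.reshape(2, *target_shape)
    out: dict[str, BinaryMask] = {}
    for name, mask in atlas.organs.items():
        sampled = ndimage.map_coordinates(mask.pixels, coords, order=0, mode="constant", cval=0)
        out[name] = BinaryMask(sampled)
    return out
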
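"""Axis finding, horizontal alignment and automatic contour landmarks.

Corresponding landmarks for two embryos are generated purely from their
outlines: the head and tail are the contour points separated by the longest
distance, and the remaining landmarks are spread at equal arc-length
intervals along the contour, skipping the tail and yolk regions whose shape
varies too much between individuals to be useful for correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .io_core import BinaryMask, Contour, Raster, ValidationError, ZebregError

__all__ = [
    "AxisEndpoints",
    "LandmarkSet",
    "ExclusionZones",
    "TooManyLandmarksError",
    "CorrespondenceError",
    "find_axis_endpoints",
    "align_horizontal",
    "place_landmarks",
    "correspond",
]

DEFAULT_N_AUTO = 17


class TooManyLandmarksError(ZebregError):
    """Raised when more landmarks are requested than the admissible arc holds."""


class CorrespondenceError(ZebregError):
    """Raised when automatic landmark lists of the two fish cannot be paired."""


@dataclass(frozen=True)
class AxisEndpoints:
    """Head and tail of the embryo: the maximally distant contour point pair."""

    head: tuple[int, int]
    tail: tuple[int, int]

    @property
    def length(self) -> float:
        return float(np.hypot(self.head[0] - self.tail[0], self.head[1] - self.tail[1]))


@dataclass(frozen=True)
class ExclusionZones:
    """Contour arcs (as fractions of total arc length) skipped for landmarks.

    ``tail_fraction`` is centered on the tail endpoint, ``yolk_fraction`` on
    the ventral-most (largest-row) contour point; both default to the values
    used throughout this package (0.15 and 0.10).
    """

    tail_fraction: float = 0.15
    yolk_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name, frac in (("tail_fraction", self.tail_fraction), ("yolk_fraction", self.yolk_fraction)):
            if not 0.0 <= frac < 0.5:
                raise ValidationError(f"{name} must be in [0, 0.5), got {frac}")


@dataclass(frozen=True)
class LandmarkSet:
    """Paired landmarks: target points ``p``, reference points ``q``, weights ``sigma``."""

    p: np.ndarray
    q: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.p, dtype=np.float64))
        q = np.atleast_2d(np.asarray(self.q, dtype=np.float64))
        s = np.asarray(self.sigma, dtype=np.float64).ravel()
        if p.shape != q.shape or p.shape[1] != 2:
            raise ValidationError(f"p and q must both be (n, 2); got {p.shape} and {q.shape}")
        if len(s) != len(p):
            raise ValidationError("sigma must hold one weight per landmark pair")
        if len(p) < 3:
            raise ValidationError(f"Need at least 3 landmark pairs, got {len(p)}")
        if np.any(s <= 0):
            raise ValidationError("Landmark weights sigma must be positive")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "sigma", s)

    @property
    def n(self) -> int:
        return len(self.p)


def find_axis_endpoints(outline: Contour) -> AxisEndpoints:
    """Maximally distant contour point pair, labeled head (wider end) and tail.

    The pair is the exact brute-force maximum over all point pairs; ties are
    broken toward the lexicographically smallest pair so the result is
    deterministic.  The head is the endpoint whose perpendicular contour
    extent, over the nearest 10% of the major axis, is larger.
    """
    pts = outline.points.astype(np.float64)
    if len(pts) < 2:
        raise ValidationError("Need at least 2 contour points to find an axis")
    d = cdist(pts, pts)
    dmax = d.max()
    ii, jj = np.nonzero(d == dmax)
    pairs = sorted(
        tuple(sorted((tuple(outline.points[i]), tuple(outline.points[j]))))
        for i, j in zip(ii, jj)
        if i < j
    )
    a, b = pairs[0]
    a = (int(a[0]), int(a[1]))
    b = (int(b[0]), int(b[1]))

    axis = np.array(b, dtype=np.float64) - np.array(a, dtype=np.float64)
    axis /= np.linalg.norm(axis)
    s = (pts - np.array(a, dtype=np.float64)) @ axis  # 0 at a, |ab| at b
    t = (pts - np.array(a, dtype=np.float64)) @ np.array([-axis[1], axis[0]])
    span = s.max() - s.min()

    def end_width(near_zero: bool) -> float:
        sel = s <= s.min() + 0.1 * span if near_zero else s >= s.max() - 0.1 * span
        if not np.any(sel):
            return 0.0
        return float(t[sel].max() - t[sel].min())

    width_a, width_b = end_width(True), end_width(False)
    if width_a > width_b or (width_a == width_b and a <= b):
        return AxisEndpoints(head=a, tail=b)
    return AxisEndpoints(head=b, tail=a)


def align_horizontal(
    image: Raster, body: BinaryMask, endpoints: AxisEndpoints
) -> tuple[Raster, BinaryMask, float]:
    """Rotate image and body so the head-to-tail axis points right (head left).

    Bilinear interpolation for intensities, nearest-neighbor for the mask;
    the canvas grows to contain the full rotated frame.  Returns the applied
    rotation angle in degrees (the argument passed to the rotation).
    """
    dr = endpoints.tail[0] - endpoints.head[0]
    dc = endpoints.tail[1] - endpoints.head[1]
    # scipy.ndimage.rotate(angle) moves content from the +col axis toward the
    # -row axis (counterclockwise on screen); rotating by the axis angle
    # brings the head->tail direction onto +col.
    angle = float(np.degrees(np.arctan2(dr, dc)))
    rot_img = ndimage.rotate(image.pixels, angle, reshape=True, order=1, mode="constant", cval=0.0)
    rot_body = ndimage.rotate(
        body.pixels.astype(np.uint8), angle, reshape=True, order=0, mode="constant", cval=0
    )
    return Raster(rot_img), BinaryMask(rot_body), angle


def _zone_intervals(center_s: float, fraction: float, total: float) -> list[tuple[float, float]]:
    """Circular interval of length fraction*total centered at center_s, split at wrap."""
    if fraction <= 0:
        return []
    half = fraction * total / 2.0
    lo, hi = center_s - half, center_s + half
    if lo < 0:
        return [(lo % total, total), (0.0, hi)]
    if hi > total:
        return [(lo, total), (0.0, hi % total)]
    return [(lo, hi)]


def place_landmarks(
    outline: Contour,
    endpoints: AxisEndpoints,
    n_auto: int = DEFAULT_N_AUTO,
    zones: ExclusionZones | None = None,
) -> np.ndarray:
    """Place ``n_auto`` landmarks on the contour, equally spaced by arc length.

    The head and tail endpoints are always landmarks; the remaining
    ``n_auto - 2`` are spread at equal arc-length intervals over the
    admissible contour (the contour minus the tail and yolk exclusion arcs,
    which are simply skipped).  The output is ordered by contour traversal
    starting from the head and always contains exactly ``n_auto`` points.
    """
    zones = zones or ExclusionZones()
    if n_auto < 3:
        raise ValidationError(f"n_auto must be >= 3, got {n_auto}")
    pts = outline.points
    n_pts = len(pts)
    if n_pts < 2:
        raise TooManyLandmarksError("Contour too short for landmark placement")

    head_idx = int(np.flatnonzero((pts[:, 0] == endpoints.head[0]) & (pts[:, 1] == endpoints.head[1]))[0])
    pts = np.roll(pts, -head_idx, axis=0)
    steps = Contour(pts, closed=True).arc_steps()
    s = np.concatenate([[0.0], np.cumsum(steps)[:-1]])  # arc position of each point
    total = float(steps.sum())

    tail_idx = int(
        np.flatnonzero((pts[:, 0] == endpoints.tail[0]) & (pts[:, 1] == endpoints.tail[1]))[0]
    )
    # Ventral (yolk) anchor: the bottom of the yolk bulge is locally flat, so
    # the single largest-row pixel jitters between individuals; the median
    # arc position of all near-ventral points is stable.
    near_ventral = np.flatnonzero(pts[:, 0] >= pts[:, 0].max() - 2)
    ventral_s = float(np.median(s[near_ventral]))
    intervals = _zone_intervals(s[tail_idx], zones.tail_fraction, total)
    intervals += _zone_intervals(ventral_s, zones.yolk_fraction, total)

    excluded = np.zeros(n_pts, dtype=bool)
    for lo, hi in intervals:
        excluded |= (s >= lo) & (s <= hi)
    excluded[tail_idx] = True  # the tail endpoint is added explicitly
    excluded[0] = True  # so is the head
    admissible = np.flatnonzero(~excluded)
    if len(admissible) < n_auto - 2:
        raise TooManyLandmarksError(
            f"Admissible contour has {len(admissible)} points; cannot place {n_auto - 2} "
            "interior landmarks"
        )

    # Head and tail split the contour into two sides; interior landmarks are
    # allocated to the sides proportionally to admissible arc length and
    # spaced equally within each, so spacing stays anchored at both ends.
    m = n_auto - 2
    side_of = admissible < tail_idx  # True: head->tail side in traversal order
    chosen: list[int] = []
    len_a = float(steps[admissible[side_of]].sum())
    len_b = float(steps[admissible[~side_of]].sum())

    def spacing_mismatch(k: int) -> float:
        da = len_a / (k + 1) if k >= 0 else np.inf
        db = len_b / (m - k + 1) if m - k >= 0 else np.inf
        return abs(da - db)

    m_a = int(round(m * len_a / (len_a + len_b))) if len_a + len_b > 0 else 0
    m_a = min(max(m_a, 0 if len_a == 0 else 1), m)
    # rounding can leave the two sides with visibly different spacing; nudge
    for cand in (m_a - 1, m_a + 1):
        if 0 <= cand <= m and spacing_mismatch(cand) < spacing_mismatch(m_a):
            m_a = cand
    for side_idx, count in ((admissible[side_of], m_a), (admissible[~side_of], m - m_a)):
        if count == 0:
            continue
        if len(side_idx) < count:
            raise TooManyLandmarksError(
                f"Admissible side has {len(side_idx)} points; cannot place {count} landmarks"
            )
        side_steps = steps[side_idx]
        side_s = np.concatenate([[0.0], np.cumsum(side_steps)[:-1]])
        arc = float(side_steps.sum())
        targets = np.arange(1, count + 1) * arc / (count + 1)
        picks = np.searchsorted(side_s, targets, side="left").clip(max=len(side_idx) - 1)
        chosen.extend(side_idx[picks])

    all_idx = np.concatenate([[0], chosen, [tail_idx]]).astype(np.intp)
    order = np.argsort(s[all_idx], kind="stable")
    landmarks = pts[all_idx[order]]
    if len(np.unique(all_idx)) != n_auto:
        raise TooManyLandmarksError("Landmark placement produced a duplicate point")
    return landmarks


def correspond(
    ref_landmarks: np.ndarray,
    target_landmarks: np.ndarray,
    manual_pairs: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
) -> LandmarkSet:
    """Pair automatic landmarks by index and append manual pairs.

    ``manual_pairs`` entries are ``((target_row, target_col), (ref_row,
    ref_col))``, matching the landmark CSV dialect.  All weights are 1.
    """
    ref = np.atleast_2d(np.asarray(ref_landmarks, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(target_landmarks, dtype=np.float64))
    if len(ref) != len(tgt):
        raise CorrespondenceError(
            f"Automatic landmark counts differ: reference {len(ref)} vs target {len(tgt)}"
        )
    p = [tuple(pt) for pt in tgt]
    q = [tuple(pt) for pt in ref]
    for tgt_pt, ref_pt in manual_pairs or []:
        p.append(tuple(float(v) for v in tgt_pt))
        q.append(tuple(float(v) for v in ref_pt))
    return LandmarkSet(p=np.array(p), q=np.array(q), sigma=np.ones(len(p)))
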
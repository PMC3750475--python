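"""Synthetic zebrafish-embryo phantoms with exhaustive ground truth.

The phantom emulates the features the pipeline depends on: a bright
fish-shaped body (head ellipse, tapering tail, ventral yolk bulge) with
ridge-like vasculature texture on a dark background; seven named organ
regions (brain, eye, otic vesicle, pectoral fin, yolk, ventral and dorsal
somites) spanning small (~300 px) to large (~20000 px) areas; smooth random
inter-individual deformation drawn from a thin-plate-spline family; and a
red channel carrying Gaussian-profile cancer-cell spots plus a linear
bleed-through of the green channel and additive Gaussian noise.

Every output is a deterministic function of the spec's seed, so phantoms
serve both as unit-test fixtures and as the inputs of the end-to-end
registration and spot-quantification experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask, OrganAtlas, Raster, ValidationError, ZebregError
from .landmarks import LandmarkSet
from .tps import TpsTransform, _snap_to_bounds, apply_tps, fit_tps

__all__ = [
    "ORGAN_NAMES",
    "PhantomSpec",
    "PhantomTarget",
    "DeformationTooLargeError",
    "make_reference",
    "make_target",
    "grow_mask",
]

ORGAN_NAMES = (
    "brain",
    "eye",
    "otic_vesicle",
    "pec_fin",
    "yolk",
    "ventral_somites",
    "dorsal_somites",
)


class DeformationTooLargeError(ZebregError):
    """Raised when the random deformation folds (non-positive Jacobian)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic embryo.

    Defaults model a 2-3 dpf embryo imaged at low magnification: body about
    1000 px long on a 600x1200 canvas, body intensity ~120 with additive
    Gaussian noise (sigma 3, i.e. SNR ~40), inter-individual deformation of
    ~10 px amplitude (about 1% of the body length), and 10 injected spots of
    amplitude 150 (50 noise sigmas) with a 2 px Gaussian radius, most of
    them in the yolk where cells are injected.  Bleed-through beta is 0.25.
    """

    canvas: tuple[int, int] = (600, 1200)
    body_intensity: float = 120.0
    texture_amplitude: float = 30.0
    noise_sigma: float = 3.0
    deform_scale: float = 10.0
    n_spots: int = 10
    n_yolk_spots: int = 6
    spot_amplitude: float = 150.0
    spot_sigma: float = 2.0
    min_spot_separation: float = 30.0
    beta: float = 0.25
    seed: int = 0

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PhantomTarget:
    """A deformed individual: channels, true organ masks and spot centers."""

    green: Raster
    red: Raster
    truth_organs: dict[str, BinaryMask]
    truth_spots: np.ndarray  # (n, 2) spot centers, (row, col)
    deformation: TpsTransform  # maps target coords -> reference coords


def _grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)


def _body_mask(shape: tuple[int, int]) -> np.ndarray:
    """Fish silhouette: head/trunk ellipse + tapering tail + yolk bulge.

    The raw union of the three parts is smoothed (Gaussian blur of the
    indicator, re-thresholded at 0.5) so the outline has no sharp concave
    notches at the part junctions — embryo silhouettes are smooth.
    """
    h, w = shape
    sy, sx = h / 600.0, w / 1200.0
    rr, cc = _grids(shape)
    ellipse = ((rr - 300 * sy) / (120 * sy)) ** 2 + ((cc - 400 * sx) / (280 * sx)) ** 2 <= 1.0
    t = np.clip((cc - 500 * sx) / (580 * sx), 0.0, 1.0)
    half = (112.0 * (1 - t) ** 1.2 + 8.0 * t) * sy
    tail = (cc >= 500 * sx) & (cc <= 1080 * sx) & (np.abs(rr - 300 * sy) <= half)
    yolk_bulge = (rr - 395 * sy) ** 2 + (cc - 330 * sx) ** 2 <= (72 * min(sy, sx)) ** 2
    union = ellipse | tail | yolk_bulge
    smooth = ndimage.gaussian_filter((union).astype(np.float64), sigma=6.0 * min(sy, sx))
    return (smooth >= 0.5) | union


def _organ_masks(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    h, w = shape
    sy, sx = h / 600.0, w / 1200.0
    s = min(sy, sx)
    rr, cc = _grids(shape)

    def ellipse(r0: float, c0: float, ra: float, rc: float) -> np.ndarray:
        return ((rr - r0 * sy) / (ra * sy)) ** 2 + ((cc - c0 * sx) / (rc * sx)) ** 2 <= 1.0

    def circle(r0: float, c0: float, radius: float) -> np.ndarray:
        return (rr - r0 * sy) ** 2 + (cc - c0 * sx) ** 2 <= (radius * s) ** 2

    def band(r_lo: float, r_hi: float, c_lo: float, c_hi: float) -> np.ndarray:
        return (
            (rr >= r_lo * sy) & (rr <= r_hi * sy) & (cc >= c_lo * sx) & (cc <= c_hi * sx)
        )

    return {
        "brain": ellipse(255, 240, 40, 65),
        "eye": circle(295, 150, 22),
        "otic_vesicle": circle(255, 330, 10),
        "pec_fin": ellipse(350, 395, 16, 10),
        "yolk": circle(395, 330, 58),
        "ventral_somites": band(305, 350, 430, 830),
        "dorsal_somites": band(250, 295, 430, 830),
    }


def _texture(shape: tuple[int, int]) -> np.ndarray:
    """Smooth ridge-like vasculature pattern in [0, 1]."""
    rr, cc = _grids(shape)
    h, w = shape
    ridges = 0.5 + 0.5 * np.sin(2 * np.pi * cc / (w / 30.0)) * np.sin(2 * np.pi * rr / (h / 20.0))
    veins = 0.5 + 0.5 * np.sin(2 * np.pi * (cc + 0.3 * rr) / (w / 18.0))
    return 0.6 * ridges + 0.4 * veins


def make_reference(spec: PhantomSpec) -> tuple[Raster, OrganAtlas]:
    """Reference embryo: green channel plus the seven-organ atlas."""
    shape = spec.canvas
    body = _body_mask(shape)
    if not body.any():
        raise ValidationError("Phantom body does not fit the canvas")
    # Erode slightly so all organs sit strictly inside the body.

    interior = ndimage.binary_erosion(body, iterations=3)
    organs: dict[str, BinaryMask] = {}
    for name, raw in _organ_masks(shape).items():
        mask = raw & interior
        if not mask.any():
            raise ValidationError(f"Phantom organ {name!r} does not fit inside the body")
        organs[name] = BinaryMask(mask)

    green = np.zeros(shape, dtype=np.float64)
    green[body] = spec.body_intensity + spec.texture_amplitude * _texture(shape)[body]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, 0])
        green = green + rng.normal(0.0, spec.noise_sigma, shape)
    reference = Raster(green)
    return reference, OrganAtlas(reference=reference, organs=organs, stage="2dpf")


def _random_deformation(spec: PhantomSpec) -> TpsTransform:
    """TPS mapping target coords -> reference coords: identity + smooth bumps."""
    h, w = spec.canvas
    sy, sx = h / 600.0, w / 1200.0
    ctrl = np.array(
        [(r * sy, c * sx) for r in (230, 370) for c in (180, 440, 700, 960)],
        dtype=np.float64,
    )
    rng = np.random.default_rng([spec.seed, 1])
    delta = rng.uniform(-spec.deform_scale, spec.deform_scale, ctrl.shape)
    anchors = np.array(
        [(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)], dtype=np.float64
    )
    p = np.vstack([ctrl, anchors])
    q = np.vstack([ctrl + delta, anchors])
    transform, _ = fit_tps(LandmarkSet(p=p, q=q, sigma=np.ones(len(p))), lam=0.0)
    return transform


def _check_invertible(transform: TpsTransform, shape: tuple[int, int]) -> None:
    step = max(4, min(shape) // 64)
    rr, cc = np.mgrid[0 : shape[0] : step, 0 : shape[1] : step].astype(np.float64)
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    eps = 0.5
    f0 = apply_tps(transform, pts)
    fr = apply_tps(transform, pts + [eps, 0.0])
    fc = apply_tps(transform, pts + [0.0, eps])
    jrr, jrc = (fr - f0).T / eps
    jcr, jcc = (fc - f0).T / eps
    det = jrr * jcc - jrc * jcr
    if det.min() <= 0:
        raise DeformationTooLargeError(
            f"Deformation folds (min Jacobian determinant {det.min():.3g}); "
            "reduce deform_scale"
        )


def _sample_spot_centers(
    spec: PhantomSpec, truth_organs: dict[str, BinaryMask], body: np.ndarray
) -> np.ndarray:
    rng = np.random.default_rng([spec.seed, 2])

    margin = int(np.ceil(3 * spec.spot_sigma)) + 2
    yolk = ndimage.binary_erosion(truth_organs["yolk"].bool(), iterations=margin)
    elsewhere = ndimage.binary_erosion(body, iterations=margin) & ~truth_organs["yolk"].bool()
    centers: list[tuple[float, float]] = []
    # separation scales with the canvas so small test phantoms stay feasible
    separation = spec.min_spot_separation * min(
        spec.canvas[0] / 600.0, spec.canvas[1] / 1200.0
    )

    def draw(region: np.ndarray, count: int) -> None:
        coords = np.column_stack(np.nonzero(region)).astype(np.float64)
        if len(coords) == 0:
            raise ValidationError("Phantom spot region is empty")
        # If the region is too small for the requested separation, relax it
        # deterministically rather than fail: crowded spots are realistic.
        sep = separation
        while sep >= 2.0:
            attempts = 0
            remaining = count
            placed: list[tuple[float, float]] = []
            while remaining > 0 and attempts < 5000:
                attempts += 1
                cand = coords[rng.integers(len(coords))]
                if all(
                    np.hypot(*(cand - np.array(c))) >= sep for c in centers + placed
                ):
                    placed.append((float(cand[0]), float(cand[1])))
                    remaining -= 1
            if remaining == 0:
                centers.extend(placed)
                return
            sep *= 0.5
        raise ValidationError("Could not place spots even at minimal separation")

    n_yolk = min(spec.n_yolk_spots, spec.n_spots)
    draw(yolk, n_yolk)
    if spec.n_spots - n_yolk > 0:
        draw(elsewhere, spec.n_spots - n_yolk)
    return np.array(centers)


def render_spots(
    shape: tuple[int, int], centers: np.ndarray, amplitude: float, sigma: float
) -> np.ndarray:
    """Sum of Gaussian profiles at the given (row, col) centers."""
    out = np.zeros(shape, dtype=np.float64)
    if len(centers) == 0:
        return out
    half = int(np.ceil(5 * sigma))
    for r0, c0 in np.atleast_2d(centers):
        r_lo, r_hi = max(0, int(r0) - half), min(shape[0], int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(shape[1], int(c0) + half + 1)
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi].astype(np.float64)
        out[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
        )
    return out


def make_target(
    reference: tuple[Raster, OrganAtlas], spec: PhantomSpec
) -> PhantomTarget:
    """Deform the reference into a new individual and inject red spots.

    The deformation is a seeded TPS displacement field (checked to be
    fold-free); organ masks are carried along as ground truth.  The red
    channel is ``spots + beta * green + noise``.
    """

    green_ref, atlas = reference
    shape = green_ref.shape
    transform = _random_deformation(spec)
    _check_invertible(transform, shape)

    rr, cc = _grids(shape)
    coords = apply_tps(transform, np.column_stack([rr.ravel(), cc.ravel()]))
    coords = _snap_to_bounds(coords, shape).T.reshape(2, *shape)
    green = ndimage.map_coordinates(green_ref.pixels, coords, order=1, mode="constant", cval=0.0)
    rng = np.random.default_rng([spec.seed, 3])
    if spec.noise_sigma > 0:
        green = green + rng.normal(0.0, spec.noise_sigma, shape)

    truth_organs = {
        name: BinaryMask(
            ndimage.map_coordinates(mask.pixels, coords, order=0, mode="constant", cval=0)
        )
        for name, mask in atlas.organs.items()
    }
    body_target = ndimage.map_coordinates(
        _body_mask(shape).astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)

    centers = _sample_spot_centers(spec, truth_organs, body_target)
    red = render_spots(shape, centers, spec.spot_amplitude, spec.spot_sigma)
    red = red + spec.beta * green
    if spec.noise_sigma > 0:
        red = red + rng.normal(0.0, spec.noise_sigma, shape)
    return PhantomTarget(
        green=Raster(green),
        red=Raster(red),
        truth_organs=truth_organs,
        truth_spots=centers,
        deformation=transform,
    )


def grow_mask(mask: BinaryMask, area_factor: float = 1.03) -> BinaryMask:
    """Grow a mask to ~``area_factor`` times its area (Euclidean dilation).

    Emulates reference organ masks drawn slightly larger than the organ
    itself: exactly the requested number of background pixels is added, in
    order of Euclidean distance to the mask (row/col tie-break), so the
    result has area round(area * area_factor) exactly.
    """
    if area_factor < 1.0:
        raise ValidationError(f"area_factor must be >= 1, got {area_factor}")
    fg = mask.bool()
    area = int(fg.sum())
    if area == 0 or area_factor == 1.0:
        return mask

    target = int(round(area * area_factor))
    extra = target - area
    if extra <= 0:
        return mask
    dist = ndimage.distance_transform_edt(~fg)
    rows, cols = np.nonzero(dist > 0)
    order = np.lexsort((cols, rows, dist[rows, cols]))[:extra]
    out = fg.copy()
    out[rows[order], cols[order]] = True
    return BinaryMask(out)
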
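"""Registration validation and per-organ cancer-coverage quantification.

Registration accuracy is scored with the Simpson overlap coefficient,
``|A ∩ B| / min(|A|, |B|)``: 1 when the smaller mask is contained in the
larger, 0 when the masks are disjoint.  Cancer burden per organ is the
fraction of the organ's area covered by detected spots; elongated regions
(ventral/dorsal somites) can be subdivided into equal-width bands along the
anteroposterior axis before quantification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import BinaryMask, ValidationError, ZebregError
from .spots import SpotSet

__all__ = [
    "UndefinedCoefficientError",
    "TooManyBinsError",
    "OverlapReport",
    "simpson",
    "overlap_report",
    "subdivide",
    "coverage",
    "aggregate",
]

COVERAGE_COLUMNS = ["fish", "day", "organ", "organ_area", "spot_area", "fraction"]


class UndefinedCoefficientError(ZebregError):
    """Raised when the Simpson coefficient has no value (empty smaller mask)."""


class TooManyBinsError(ZebregError):
    """Raised when a mask is subdivided into more bands than it has columns."""


class OverlapReport(dict):
    """Mapping organ -> Simpson coefficient, with missing organs tracked.

    Organs whose masks were both empty are listed in ``missing`` and excluded
    from ``mean``.
    """

    def __init__(self, per_organ: dict[str, float], missing: list[str] | None = None):
        super().__init__(per_organ)
        self.missing = list(missing or [])

    @property
    def mean(self) -> float:
        if not self:
            return float("nan")
        return float(np.mean(list(self.values())))


def simpson(a: BinaryMask, b: BinaryMask) -> float:
    """Overlap coefficient |a ∩ b| / min(|a|, |b|)."""
    if a.shape != b.shape:
        raise ValidationError(f"Mask shapes differ: {a.shape} vs {b.shape}")
    area_a, area_b = a.area, b.area
    if area_a == 0 and area_b == 0:
        raise UndefinedCoefficientError("Simpson coefficient undefined for two empty masks")
    if min(area_a, area_b) == 0:
        # One mask vanished (e.g. an organ mapped out of frame): no overlap.
        return 0.0
    inter = int(np.sum(a.bool() & b.bool()))
    return inter / min(area_a, area_b)


def overlap_report(
    registered: dict[str, BinaryMask], truth: dict[str, BinaryMask]
) -> OverlapReport:
    """Per-organ Simpson coefficients of registered vs ground-truth masks."""
    if set(registered) != set(truth):
        raise ValidationError(
            f"Organ name sets differ: {sorted(registered)} vs {sorted(truth)}"
        )
    per_organ: dict[str, float] = {}
    missing: list[str] = []
    for name in registered:
        if registered[name].area == 0 and truth[name].area == 0:
            missing.append(name)
            continue
        per_organ[name] = simpson(registered[name], truth[name])
    return OverlapReport(per_organ, missing)


def subdivide(mask: BinaryMask, n_bins: int) -> list[BinaryMask]:
    """Cut a mask into ``n_bins`` equal-width vertical bands, head to tail.

    Bands span the mask's column extent (the anteroposterior axis of a
    horizontally aligned embryo); the sub-masks are pairwise disjoint and
    their union is the input.
    """
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    if mask.area == 0:
        raise ValidationError("Cannot subdivide an empty mask")
    cols = np.nonzero(mask.pixels.any(axis=0))[0]
    cmin, cmax = int(cols.min()), int(cols.max())
    width = cmax - cmin + 1
    if n_bins > width:
        raise TooManyBinsError(f"Cannot cut a {width}-column extent into {n_bins} bands")
    edges = cmin + np.round(width * np.arange(n_bins + 1) / n_bins).astype(int)
    out: list[BinaryMask] = []
    col_index = np.arange(mask.shape[1])
    for lo, hi in zip(edges[:-1], edges[1:]):
        band = (col_index >= lo) & (col_index < hi)
        out.append(BinaryMask(mask.pixels * band[None, :]))
    return out


def coverage(
    organs: dict[str, BinaryMask], spots: SpotSet, fish_id: str, day: str
) -> pd.DataFrame:
    """One row per organ: spot-covered area fraction of the organ.

    Organs may overlap; a spot pixel then counts in each organ it falls in.
    Empty organs yield a missing (NaN) fraction.
    """
    spot_bool = spots.mask.bool()
    rows = []
    for name, mask in organs.items():
        if mask.shape != spots.mask.shape:
            raise ValidationError(
                f"Organ {name!r} shape {mask.shape} differs from spot mask {spots.mask.shape}"
            )
        organ_area = mask.area
        spot_area = int(np.sum(mask.bool() & spot_bool))
        fraction = spot_area / organ_area if organ_area > 0 else float("nan")
        rows.append((fish_id, day, name, organ_area, spot_area, fraction))
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


def aggregate(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean coverage fraction per (day, organ) across fish, with group sizes.

    Missing (NaN) fractions are excluded from both the mean and the count.
    """
    if not tables:
        raise ValidationError("aggregate needs at least one coverage table")
    combined = pd.concat(tables, ignore_index=True)
    grouped = combined.groupby(["day", "organ"], sort=True)["fraction"].agg(
        mean_fraction="mean", n="count"
    )
    return grouped.reset_index()
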
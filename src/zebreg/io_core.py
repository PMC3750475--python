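"""Shared data types and file I/O for the registration pipeline.

All coordinates throughout the package are ``(row, col)`` with the origin at
the top-left corner and rows increasing downward.  Intensities are kept on
their native scale: an 8-bit image loads with values in 0..255, a 16-bit one
with values in 0..65535.  No rescaling is ever applied on read or write.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "Raster",
    "BinaryMask",
    "Contour",
    "OrganAtlas",
    "ZebregError",
    "UnsupportedFormatError",
    "ValidationError",
    "read_raster",
    "write_raster",
    "read_mask",
    "write_mask",
    "read_landmark_pairs",
    "write_landmark_pairs",
    "read_atlas",
    "write_atlas",
]


class ZebregError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedFormatError(ZebregError):
    """Raised for files whose layout the readers cannot interpret."""


class ValidationError(ZebregError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class Raster:
    """A single-channel 2D image with float intensities in arbitrary units."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"Raster must be 2D, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"Raster must be at least 1x1, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("Raster intensities must all be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 2D mask holding {0, 1}; same shape conventions as :class:`Raster`."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"BinaryMask must be 2D, got shape {px.shape}")
        px = (px != 0).astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


def _check_8_connected(points: np.ndarray, closed: bool) -> None:
    if len(points) < 2:
        return
    diffs = np.abs(np.diff(points, axis=0))
    if closed:
        wrap = np.abs(points[0] - points[-1])[None, :]
        diffs = np.vstack([diffs, wrap])
    steps = diffs.max(axis=1)
    if np.any(steps > 1) or np.any(steps == 0):
        bad = int(np.argmax((steps > 1) | (steps == 0)))
        raise ValidationError(
            f"Contour points {bad} and {bad + 1} are not distinct 8-neighbors"
        )


@dataclass(frozen=True)
class Contour:
    """An ordered trace of boundary pixels; consecutive points are 8-connected."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"Contour points must be (n, 2), got {pts.shape}")
        pts = pts.astype(np.intp)
        if len(pts) == 0:
            raise ValidationError("Contour must contain at least one point")
        if len(pts) > 1:
            _check_8_connected(pts, self.closed)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def arc_steps(self) -> np.ndarray:
        """Euclidean step length from each point to the next (wrapping if closed)."""
        pts = self.points.astype(np.float64)
        if self.closed:
            nxt = np.roll(pts, -1, axis=0)
        else:
            nxt = pts[1:]
            pts = pts[:-1]
        return np.hypot(*(nxt - pts).T)

    def perimeter(self) -> float:
        return float(self.arc_steps().sum())


@dataclass
class OrganAtlas:
    """A reference embryo image with one named binary mask per organ."""

    reference: Raster
    organs: dict[str, BinaryMask] = field(default_factory=dict)
    stage: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, mask in self.organs.items():
            if name in seen:
                raise ValidationError(f"Duplicate organ name {name!r} in atlas")
            seen.add(name)
            if mask.shape != self.reference.shape:
                raise ValidationError(
                    f"Organ {name!r} mask shape {mask.shape} does not match "
                    f"reference shape {self.reference.shape}"
                )

    @property
    def organ_names(self) -> list[str]:
        return list(self.organs)


_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def _load_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path))
        return np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - reraise with path context
        raise ZebregError(f"Could not read image file {path}: {exc}") from exc


def read_raster(path: str | Path, channel: str | None = None) -> Raster:
    """Read a TIFF/PNG image as a float :class:`Raster`, unscaled.

    Multi-channel (RGB/RGBA) images require ``channel`` ("red", "green" or
    "blue") to select one plane; single-channel images ignore it.
    """
    path = Path(path)
    if not path.exists():
        raise ZebregError(f"Image file does not exist: {path}")
    arr = _load_array(path)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise UnsupportedFormatError(
                f"{path}: expected 2D image or RGB(A), got shape {arr.shape}"
            )
        if channel is None:
            raise UnsupportedFormatError(
                f"{path} is multi-channel; pass channel='red'|'green'|'blue'"
            )
        arr = arr[:, :, _CHANNEL_INDEX[channel]]
    elif arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: images with {arr.ndim} dimensions are not supported"
        )
    return Raster(arr)


def write_raster(path: str | Path, raster: Raster) -> None:
    """Write a raster to TIFF (any values) or PNG (integer values 0..65535)."""
    path = Path(path)
    px = raster.pixels
    integral = bool(np.all(px == np.round(px)))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        if integral and px.min() >= 0 and px.max() <= 65535:
            tifffile.imwrite(path, px.astype(np.uint16))
        else:
            tifffile.imwrite(path, px.astype(np.float64))
    elif suffix == ".png":
        if not integral or px.min() < 0 or px.max() > 65535:
            raise UnsupportedFormatError(
                "PNG output requires integer intensities in 0..65535; "
                "use TIFF for float data"
            )
        dtype = np.uint8 if px.max() <= 255 else np.uint16
        iio.imwrite(path, px.astype(dtype))
    else:
        raise UnsupportedFormatError(f"Unsupported raster suffix: {path.suffix}")


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask image; any nonzero pixel is foreground."""
    return BinaryMask(read_raster(path).pixels != 0)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a mask as 8-bit PNG/TIFF with foreground = 255."""
    write_raster(path, Raster(mask.pixels.astype(np.float64) * 255.0))


LANDMARK_HEADER = ["target_row", "target_col", "ref_row", "ref_col"]


def read_landmark_pairs(
    path: str | Path,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Read landmark correspondences from a 4-column CSV.

    The header must be ``target_row,target_col,ref_row,ref_col``.  Returns a
    list of ``((target_row, target_col), (ref_row, ref_col))`` pairs in file
    order; a header-only file yields an empty list.
    """
    path = Path(path)
    pairs: list[tuple[tuple[float, float], tuple[float, float]]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if [h.strip() for h in header] != LANDMARK_HEADER:
            raise ValidationError(
                f"{path}:1: expected header {','.join(LANDMARK_HEADER)}, "
                f"got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            try:
                tr, tc, rr, rc = (float(cell) for cell in row)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            pairs.append(((tr, tc), (rr, rc)))
    return pairs


def write_landmark_pairs(
    path: str | Path,
    pairs: list[tuple[tuple[float, float], tuple[float, float]]],
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LANDMARK_HEADER)
        for (tr, tc), (rr, rc) in pairs:
            writer.writerow([repr(float(tr)), repr(float(tc)), repr(float(rr)), repr(float(rc))])


_REFERENCE_STEMS = ("reference",)
_LABEL_IMAGE_STEM = "labels"


def read_atlas(directory: str | Path, stage: str = "") -> OrganAtlas:
    """Load an organ atlas from a directory.

    Expected layout: a ``reference.png``/``reference.tif`` raster plus either

    * one binary mask per organ, ``<organ>.png`` (any PNG that is not the
      reference or the label image), or
    * a label image ``labels.png`` (integer labels, 0 = background) with a
      name table ``labels.csv`` of rows ``label,name``.
    """
    directory = Path(directory)
    ref_path = None
    for stem in _REFERENCE_STEMS:
        for suffix in (".png", ".tif", ".tiff"):
            cand = directory / f"{stem}{suffix}"
            if cand.exists():
                ref_path = cand
                break
        if ref_path:
            break
    if ref_path is None:
        raise ZebregError(f"No reference.png/tif found in atlas directory {directory}")
    reference = read_raster(ref_path)

    label_img = directory / f"{_LABEL_IMAGE_STEM}.png"
    label_csv = directory / f"{_LABEL_IMAGE_STEM}.csv"
    organs: dict[str, BinaryMask] = {}
    if label_img.exists() and label_csv.exists():
        labels = read_raster(label_img).pixels.astype(np.intp)
        with open(label_csv, newline="") as fh:
            reader = csv.reader(fh)
            for row in reader:
                if not row or row[0].strip().lower() == "label":
                    continue
                value, name = int(row[0]), row[1].strip()
                if name in organs:
                    raise ValidationError(f"Duplicate organ name {name!r} in {label_csv}")
                organs[name] = BinaryMask(labels == value)
    else:
        for mask_path in sorted(directory.glob("*.png")):
            if mask_path.stem in _REFERENCE_STEMS or mask_path.stem == _LABEL_IMAGE_STEM:
                continue
            name = mask_path.stem
            mask = read_mask(mask_path)
            if mask.shape != reference.shape:
                raise ValidationError(
                    f"Organ {name!r} mask shape {mask.shape} does not match "
                    f"reference shape {reference.shape}"
                )
            organs[name] = mask
    return OrganAtlas(reference=reference, organs=organs, stage=stage)


def write_atlas(directory: str | Path, atlas: OrganAtlas) -> None:
    """Write an atlas as reference.tif plus one <organ>.png mask per organ."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_raster(directory / "reference.tif", atlas.reference)
    for name, mask in atlas.organs.items():
        write_mask(directory / f"{name}.png", mask)
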
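"""CT slice I/O, region-of-interest extraction and gray-level quantization.

Coordinates are 0-based and row-major; ROI extents are half-open
``[origin, origin + size)``.  Pixel values are carried as Hounsfield units
(HU) after applying the stored rescale slope/intercept.

Two input formats are supported:

* single-frame grayscale DICOM (requires the optional ``pydicom`` extra);
* a lossless raster fixture (PNG/TIFF) with a JSON sidecar holding
  ``{"rescale_slope": s, "rescale_intercept": b}``; ``HU = stored * s + b``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    BoundsError,
    DegenerateROIError,
    FormatError,
    ParameterError,
    UnsupportedInputError,
)

logger = logging.getLogger(__name__)

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


@dataclass
class CTSlice:
    """A single 2D CT slice in Hounsfield units."""

    pixel_hu: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixel_hu = np.asarray(self.pixel_hu, dtype=float)
        if self.pixel_hu.ndim != 2 or self.pixel_hu.size == 0:
            raise FormatError("slice must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.pixel_hu)):
            raise FormatError("slice contains non-finite HU values")

    @property
    def row_count(self) -> int:
        return self.pixel_hu.shape[0]

    @property
    def col_count(self) -> int:
        return self.pixel_hu.shape[1]


@dataclass(frozen=True)
class ROIDefinition:
    """Rectangular or elliptical region of interest inside a slice."""

    shape: str  # "rectangle" | "ellipse"
    origin_row: int
    origin_col: int
    height: int
    width: int

    def __post_init__(self):
        if self.shape not in ("rectangle", "ellipse"):
            raise ParameterError(f"unknown ROI shape {self.shape!r}")
        if self.height < 1 or self.width < 1:
            raise ParameterError("ROI height and width must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "ROIDefinition":
        with open(path) as fh:
            obj = json.load(fh)
        try:
            return cls(
                shape=obj["shape"],
                origin_row=int(obj["origin"][0]),
                origin_col=int(obj["origin"][1]),
                height=int(obj["size"][0]),
                width=int(obj["size"][1]),
            )
        except (KeyError, IndexError, TypeError) as exc:
            raise FormatError(f"bad ROI file {path}: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "shape": self.shape,
                    "origin": [self.origin_row, self.origin_col],
                    "size": [self.height, self.width],
                },
                fh,
                indent=2,
            )


@dataclass
class ROIPatch:
    """Masked HU pixels of an ROI plus summary statistics.

    ``grid`` is the bounding-box crop; ``mask`` marks pixels belonging to the
    ROI (all True for rectangles).  ``mean_hu``/``sd_hu`` are computed over
    masked pixels only, with population SD by default.
    """

    grid: np.ndarray
    mask: np.ndarray
    mean_hu: float
    sd_hu: float

    @property
    def pixels(self) -> np.ndarray:
        return self.grid[self.mask]


@dataclass
class QuantizedROI:
    """Gray levels of an ROI binned to ``Ng`` integer levels for GLCM work."""

    levels: np.ndarray
    ng: int
    hu_min: float
    hu_max: float
    mean_hu: float
    sd_hu: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.mask is None:
            self.mask = np.ones_like(self.levels, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.levels.shape:
            raise ParameterError("mask shape must match levels shape")
        valid = self.levels[self.mask]
        if valid.size and (valid.min() < 0 or valid.max() > self.ng - 1):
            raise ParameterError("quantized levels outside [0, Ng-1]")


def _read_sidecar(image_path: Path) -> tuple[float, float]:
    sidecar = image_path.with_suffix(".json")
    if not sidecar.exists():
        logger.info("no sidecar for %s; using identity HU mapping", image_path)
        return 1.0, 0.0
    with open(sidecar) as fh:
        obj = json.load(fh)
    return float(obj.get("rescale_slope", 1.0)), float(obj.get("rescale_intercept", 0.0))


def _load_raster(path: Path) -> CTSlice:
    import imageio.v3 as iio

    try:
        stored = iio.imread(path)
    except Exception as exc:  # imageio raises various subclasses
        raise FormatError(f"cannot read raster image {path}: {exc}") from exc
    if stored.ndim == 3:
        raise UnsupportedInputError(f"{path} is a color or multi-frame image")
    slope, intercept = _read_sidecar(path)
    hu = stored.astype(float) * slope + intercept
    return CTSlice(pixel_hu=hu, source_id=str(path))


def _load_dicom(path: Path) -> CTSlice:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise FormatError(
            "DICOM input requires the optional 'pydicom' dependency "
            "(pip install ct2bmd[dicom]); lossless raster fixtures need no extra"
        ) from exc
    try:
        ds = pydicom.dcmread(path)
        stored = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    if stored.ndim != 2:
        raise UnsupportedInputError(f"{path}: only single-frame grayscale DICOM is supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if not hasattr(ds, "RescaleSlope"):
        logger.info("no RescaleSlope in %s; using identity HU mapping", path)
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    hu = stored.astype(float) * slope + intercept
    return CTSlice(pixel_hu=hu, pixel_spacing=spacing, source_id=str(path))


def load_slice(path: str | Path) -> CTSlice:
    """Load a CT slice from DICOM or a lossless raster + sidecar fixture.

    HU values are ``stored * rescale_slope + rescale_intercept`` when rescale
    metadata is present, identity otherwise (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in _RASTER_SUFFIXES:
        return _load_raster(path)
    if suffix in _DICOM_SUFFIXES:
        return _load_dicom(path)
    # no recognized extension: sniff DICOM magic then fall back to raster
    with open(path, "rb") as fh:
        head = fh.read(132)
    if head[128:132] == b"DICM":
        return _load_dicom(path)
    return _load_raster(path)


def save_slice(ct: CTSlice, path: str | Path) -> None:
    """Write a slice as a 16-bit PNG/TIFF plus JSON sidecar, losslessly.

    HU values must be integral (clinical HU are); the stored value is
    ``hu - intercept`` with ``intercept = floor(min HU)`` and slope 1.
    """
    import imageio.v3 as iio

    path = Path(path)
    hu = ct.pixel_hu
    if not np.allclose(hu, np.round(hu)):
        raise ParameterError("lossless fixture format requires integral HU values")
    intercept = float(math.floor(hu.min()))
    stored = np.round(hu - intercept).astype(np.int64)
    if stored.max() > np.iinfo(np.uint16).max:
        raise ParameterError("HU range too wide for 16-bit fixture storage")
    iio.imwrite(path, stored.astype(np.uint16))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"rescale_slope": 1.0, "rescale_intercept": intercept}, fh)


def _ellipse_mask(height: int, width: int) -> np.ndarray:
    rr, cc = np.mgrid[0:height, 0:width]
    cr = (height - 1) / 2.0
    cc0 = (width - 1) / 2.0
    a = height / 2.0
    b = width / 2.0
    return ((rr - cr) / a) ** 2 + ((cc - cc0) / b) ** 2 <= 1.0


def extract_roi(ct: CTSlice, roi: ROIDefinition, *, sample_sd: bool = False) -> ROIPatch:
    """Cut an ROI out of a slice and report its mean/SD over masked pixels.

    SD is population SD (divide by n) unless ``sample_sd`` is set.
    """
    r0, c0 = roi.origin_row, roi.origin_col
    r1, c1 = r0 + roi.height, c0 + roi.width
    if r0 < 0 or c0 < 0 or r1 > ct.row_count or c1 > ct.col_count:
        raise BoundsError(
            f"ROI [{r0}:{r1}, {c0}:{c1}] outside slice "
            f"{ct.row_count}x{ct.col_count}"
        )
    grid = ct.pixel_hu[r0:r1, c0:c1].copy()
    if roi.shape == "ellipse":
        mask = _ellipse_mask(roi.height, roi.width)
        if mask.sum() < 4:
            raise DegenerateROIError("ellipse mask contains fewer than 4 pixels")
    else:
        mask = np.ones_like(grid, dtype=bool)
    vals = grid[mask]
    ddof = 1 if sample_sd else 0
    return ROIPatch(
        grid=grid,
        mask=mask,
        mean_hu=float(vals.mean()),
        sd_hu=float(vals.std(ddof=ddof)),
    )


def quantize(
    hu_grid: np.ndarray | ROIPatch,
    ng: int,
    bounds: tuple[float, float] | None = None,
) -> QuantizedROI:
    """Bin HU values into ``ng`` equal-width gray levels.

    Default bounds are the ROI's own min/max over masked pixels.  Values at or
    below ``hu_min`` map to level 0, at or above ``hu_max`` to ``ng - 1``.
    A degenerate range (``hu_min == hu_max``) maps everything to level 0.
    """
    if ng < 2:
        raise ParameterError(f"Ng must be >= 2, got {ng}")
    if isinstance(hu_grid, ROIPatch):
        grid = hu_grid.grid
        mask = hu_grid.mask
        mean_hu, sd_hu = hu_grid.mean_hu, hu_grid.sd_hu
    else:
        grid = np.asarray(hu_grid, dtype=float)
        if grid.ndim != 2 or grid.size == 0:
            raise ParameterError("HU grid must be a non-empty 2D array")
        mask = np.ones_like(grid, dtype=bool)
        mean_hu = float(grid.mean())
        sd_hu = float(grid.std())
    vals = grid[mask]
    if bounds is None:
        hu_min, hu_max = float(vals.min()), float(vals.max())
    else:
        hu_min, hu_max = float(bounds[0]), float(bounds[1])
        if hu_min > hu_max:
            raise ParameterError("hu_min must not exceed hu_max")
    if hu_min == hu_max:
        levels = np.zeros_like(grid, dtype=np.int64)
    else:
        scaled = (grid - hu_min) / (hu_max - hu_min) * ng
        levels = np.clip(np.floor(scaled), 0, ng - 1).astype(np.int64)
    return QuantizedROI(
        levels=levels,
        ng=ng,
        hu_min=hu_min,
        hu_max=hu_max,
        mean_hu=mean_hu,
        sd_hu=sd_hu,
        mask=mask,
    )
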
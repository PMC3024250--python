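"""Image loading, background correction and core-evaluability QC.

Stained tissue absorbs light, so the specimen is darker than a blank field
wherever stain is present. Correction therefore computes ``blank - image``
(clamped at zero), which flips polarity so that stained structures carry HIGH
intensity and the direction of the subsequent threshold sweep is unambiguous.
A core is evaluable when at least a configurable fraction (default one half)
of it is stained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .errors import ContractError, DegenerateInputError

logger = logging.getLogger(__name__)

#: Rec. 601 luma coefficients for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ImageCalibration:
    """Physical pixel pitch of the acquisition, in microns per pixel."""

    microns_per_pixel: float = 1.06

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ContractError("microns_per_pixel must be strictly positive")


@dataclass
class GrayImage:
    """A calibrated 2-D intensity raster.

    ``intensity_range`` declares the closed range the pixel values live in
    (0..255 for 8-bit input, 0..65535 for 16-bit, observed min/max after
    correction). Pixels are stored as float64 regardless of source bit depth
    so that background subtraction and rescaling stay exact.
    """

    pixels: np.ndarray
    calibration: ImageCalibration = field(default_factory=ImageCalibration)
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ContractError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise DegenerateInputError("zero-sized image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class QCResult:
    stained_fraction: float
    evaluable: bool
    reason: str  # ok | understained | blank | degenerate

    def __post_init__(self) -> None:
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise ContractError("stained_fraction must lie in [0, 1]")


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to single-channel luminance (Rec. 601)."""
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return arr[..., :3].astype(np.float64) @ _LUMA
    raise ContractError(f"unsupported raster shape {arr.shape}")


def _declared_range(arr: np.ndarray) -> tuple[float, float]:
    if arr.dtype == np.uint8:
        return (0.0, 255.0)
    if arr.dtype == np.uint16:
        return (0.0, 65535.0)
    lo, hi = float(np.min(arr)), float(np.max(arr))
    return (min(lo, 0.0), hi)


def load_image(path: str | Path, calibration: ImageCalibration | None = None) -> GrayImage:
    """Load a TIFF (or any decodable raster) as a calibrated grayscale image.

    RGB input is converted with standard Rec. 601 luminance weights. The
    declared intensity range records the source bit depth (0..255 / 0..65535).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specifics
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise DegenerateInputError(f"zero-sized image: {path}")
    rng = _declared_range(raw)
    gray = _to_grayscale(raw)
    return GrayImage(gray, calibration or ImageCalibration(), rng)


def save_image(image: GrayImage, path: str | Path, dtype: str = "uint8") -> None:
    """Write a grayscale image as TIFF at the requested bit depth."""
    info = np.iinfo(dtype)
    arr = np.clip(np.rint(image.pixels), info.min, info.max).astype(dtype)
    tifffile.imwrite(Path(path), arr)


def background_correct(image: GrayImage, blank: GrayImage) -> GrayImage:
    """Remove non-uniform background luminance using a blank-field image.

    Returns ``clamp(blank - image, 0)``: the specimen is darker than the blank
    wherever it is stained, so the corrected image has stain bright on a zero
    background and any smooth illumination gradient shared by both frames
    cancels. The declared range is re-derived from the observed values.
    """
    if image.shape != blank.shape:
        raise ContractError(
            f"image shape {image.shape} does not match blank shape {blank.shape}"
        )
    if image.calibration != blank.calibration:
        raise ContractError("image and blank carry different calibrations")
    corrected = np.clip(blank.pixels - image.pixels, 0.0, None)
    hi = float(corrected.max())
    if hi == 0.0 and float(np.max(blank.pixels - image.pixels)) < 0.0:
        logger.warning(
            "blank is darker than the specimen everywhere; inputs may be "
            "swapped - corrected image is all zero"
        )
    return GrayImage(corrected, image.calibration, (0.0, hi))


def _otsu_threshold(pixels: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(pixels))


def qc_core(
    image: GrayImage,
    stain_threshold: Optional[float] = None,
    min_fraction: float = 0.5,
    core_mask: Optional[np.ndarray] = None,
) -> QCResult:
    """Decide whether a background-corrected core is evaluable.

    ``stained_fraction`` is the fraction of pixels strictly above
    ``stain_threshold`` (Otsu's threshold when not given) within the core
    region (whole image unless ``core_mask`` is supplied). The core is
    evaluable iff the fraction reaches ``min_fraction``; half-stained is
    sufficient at the default.
    """
    pixels = image.pixels if core_mask is None else image.pixels[core_mask]
    if pixels.size == 0:
        raise DegenerateInputError("empty core region")
    if float(pixels.max()) == 0.0:
        return QCResult(0.0, False, "blank")
    if stain_threshold is None:
        if float(pixels.min()) == float(pixels.max()):
            # constant nonzero image: everything is "stained"
            stain_threshold = float(pixels.min()) - 1.0
        else:
            stain_threshold = _otsu_threshold(pixels)
    frac = float(np.mean(pixels > stain_threshold))
    if frac == 0.0:
        return QCResult(0.0, False, "blank")
    if frac < min_fraction:
        return QCResult(frac, False, "understained")
    return QCResult(frac, True, "ok")
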
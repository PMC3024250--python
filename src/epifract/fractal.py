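"""Box-counting fractal dimension of thresholded outline images.

The per-core score is produced by a five-step procedure: (1) threshold the
background-corrected grayscale image at a series of intensities, (2) extract
the morphological boundary (outline) of each binary mask, (3) count occupied
boxes of the outline on grids of increasing box size, (4) fit the slope of
log N(s) against log(1/s) restricted to box sizes whose physical edge lies in
a calibrated scale window (default 10-50 um), and (5) take the global maximum
of the dimension-versus-threshold curve as the core's fractal dimension.

The scale window restricts the regression to the range of physical scales
over which epithelial morphology behaves self-similarly; at the default
calibration of 1.06 um/px it corresponds to box edges of 10-47 pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure

from .config import PipelineConfig
from .errors import ContractError, CoreNotEvaluableError, UndefinedEstimateError
from .imaging import GrayImage, ImageCalibration, QCResult, background_correct, qc_core

logger = logging.getLogger(__name__)

_CROSS = generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class OutlineImage:
    """Binary boundary mask of a thresholded image, with provenance."""

    pixels: np.ndarray
    calibration: ImageCalibration
    threshold: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ContractError("outline must be a 2-D mask")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class BoxCountCurve:
    """Occupied-box counts N(s) over a ladder of box edge lengths s."""

    box_sizes: np.ndarray  # pixels, strictly increasing
    counts: np.ndarray
    calibration: ImageCalibration
    empty: bool = False

    def __post_init__(self) -> None:
        self.box_sizes = np.asarray(self.box_sizes, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.box_sizes.shape != self.counts.shape:
            raise ContractError("box_sizes and counts must have equal length")

    def sizes_um(self) -> np.ndarray:
        return self.box_sizes * self.calibration.microns_per_pixel


@dataclass(frozen=True)
class FDEstimate:
    """Slope of the log-log box-count regression inside the scale window."""

    fd: float
    r_squared: float
    scale_window: tuple[float, float]  # microns
    n_scales: int


@dataclass
class FDProfile:
    """Fractal dimension as a function of intensity threshold for one core."""

    thresholds: np.ndarray
    estimates: list[Optional[FDEstimate]]
    max_fd: FDEstimate = field(init=False)
    max_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        if len(self.estimates) != self.thresholds.size:
            raise ContractError("one estimate slot per threshold required")
        best: Optional[tuple[float, FDEstimate]] = None
        for thr, est in zip(self.thresholds, self.estimates):
            if est is None:
                continue
            # strict '>' keeps the smallest threshold on ties
            if best is None or est.fd > best[1].fd:
                best = (float(thr), est)
        if best is None:
            raise CoreNotEvaluableError(
                "no threshold produced a defined fractal-dimension estimate"
            )
        self.max_threshold, self.max_fd = best


def binarize(image: GrayImage, threshold: float) -> np.ndarray:
    """Threshold an image: mask pixel is True iff intensity >= threshold."""
    lo, hi = image.intensity_range
    if not lo <= threshold <= hi:
        raise ContractError(
            f"threshold {threshold} outside declared intensity range [{lo}, {hi}]"
        )
    return image.pixels >= threshold


def extract_outline(
    mask: np.ndarray, calibration: ImageCalibration, threshold: float = math.nan
) -> OutlineImage:
    """Morphological boundary of a binary mask under 4-connectivity.

    A pixel belongs to the outline iff it is set in the mask and at least one
    of its 4-neighbors is unset; neighbors beyond the image border count as
    unset, so the rim of a full mask is boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = binary_erosion(mask, structure=_CROSS, border_value=0)
    return OutlineImage(mask & ~interior, calibration, threshold)


def box_count(outline: OutlineImage, box_sizes: Sequence[int]) -> BoxCountCurve:
    """Count boxes of each size containing at least one outline pixel.

    The grid is axis-aligned and anchored at the top-left corner (no offset
    minimization); partial boxes at the right/bottom edges participate.
    """
    sizes = np.asarray(box_sizes, dtype=np.int64)
    if sizes.size == 0 or np.any(np.diff(sizes) <= 0):
        raise ContractError("box_sizes must be non-empty and strictly increasing")
    h, w = outline.pixels.shape
    if sizes[0] < 1 or sizes[-1] > min(h, w):
        raise ContractError(
            f"box sizes must lie in [1, min(H, W)] = [1, {min(h, w)}]"
        )
    mask = outline.pixels
    if not mask.any():
        return BoxCountCurve(sizes, np.zeros_like(sizes), outline.calibration, empty=True)
    counts = np.empty(sizes.size, dtype=np.int64)
    for i, s in enumerate(sizes):
        s = int(s)
        ph, pw = (-h) % s, (-w) % s
        padded = np.pad(mask, ((0, ph), (0, pw))) if (ph or pw) else mask
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        counts[i] = int(blocks.any(axis=(1, 3)).sum())
    return BoxCountCurve(sizes, counts, outline.calibration)


def default_box_sizes(
    calibration: ImageCalibration,
    scale_window_um: tuple[float, float] = (10.0, 50.0),
    ratio: float = 1.25,
) -> np.ndarray:
    """Geometric ladder of integer box sizes spanning the physical window.

    Only sizes whose physical edge s * (um/px) lies inside the window are
    returned; at 1.06 um/px and a 10-50 um window this yields 8 sizes between
    10 and 47 px.
    """
    lo_um, hi_um = scale_window_um
    if not 0 < lo_um < hi_um:
        raise ContractError("scale window must be an increasing positive pair")
    mpp = calibration.microns_per_pixel
    s_min = math.ceil(lo_um / mpp)
    s_max = math.floor(hi_um / mpp)
    if s_max < s_min:
        raise ContractError(
            f"no integer box size fits the window [{lo_um}, {hi_um}] um at "
            f"{mpp} um/px"
        )
    n = max(3, round(math.log(s_max / s_min) / math.log(ratio)) + 1)
    sizes = np.unique(np.rint(np.geomspace(s_min, s_max, n)).astype(np.int64))
    return sizes


def estimate_fd(
    curve: BoxCountCurve, scale_window_um: tuple[float, float] = (10.0, 50.0)
) -> FDEstimate:
    """OLS slope of log N(s) vs log(1/s) over sizes inside the scale window.

    At least three usable scales with positive counts are required. The
    reported dimension is clamped to [0, 2] (the admissible range for subsets
    of the plane); a fit outside that range indicates pathology and logs a
    warning.
    """
    sizes_um = curve.sizes_um()
    lo, hi = scale_window_um
    inside = (sizes_um >= lo) & (sizes_um <= hi)
    if curve.empty or int(inside.sum()) < 3:
        raise UndefinedEstimateError(
            f"need >=3 box sizes inside [{lo}, {hi}] um with positive counts"
        )
    counts = curve.counts[inside]
    if np.any(counts <= 0):
        raise UndefinedEstimateError("zero box counts inside the scale window")
    x = np.log(1.0 / curve.box_sizes[inside].astype(np.float64))
    y = np.log(counts.astype(np.float64))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - float(np.sum(resid**2)) / ss_tot
    fd = float(slope)
    if fd < 0.0 or fd > 2.0:
        logger.warning("fractal dimension %.3f outside [0, 2]; clamping", fd)
        fd = min(max(fd, 0.0), 2.0)
    return FDEstimate(fd, r2, (float(lo), float(hi)), int(inside.sum()))


def default_thresholds(image: GrayImage, n: int = 64) -> np.ndarray:
    """Evenly spaced thresholds between the 1st and 99th percentile of the
    nonzero intensities of a corrected image."""
    nz = image.pixels[image.pixels > 0]
    if nz.size == 0:
        raise CoreNotEvaluableError("image has no nonzero intensities")
    lo, hi = np.percentile(nz, [1.0, 99.0])
    if hi <= lo:
        return np.asarray([float(lo)])
    return np.linspace(lo, hi, n)


def fd_profile(
    image: GrayImage,
    thresholds: Optional[Sequence[float]] = None,
    scale_window_um: tuple[float, float] = (10.0, 50.0),
    min_outline_pixels: int = 100,
    box_sizes: Optional[Sequence[int]] = None,
) -> FDProfile:
    """Sweep intensity thresholds and estimate FD of each outline image.

    Thresholds whose outline has fewer than ``min_outline_pixels`` pixels (or
    whose regression is undefined) yield undefined estimates. The profile
    maximum is taken over defined estimates, smallest threshold winning ties.
    Raises :class:`CoreNotEvaluableError` when no threshold yields an
    estimate.
    """
    if thresholds is None:
        thresholds = default_thresholds(image)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0 or (
        thresholds.size > 1 and np.any(np.diff(thresholds) <= 0)
    ):
        raise ContractError("thresholds must be non-empty, strictly increasing")
    if box_sizes is None:
        box_sizes = default_box_sizes(image.calibration, scale_window_um)
    h, w = image.shape
    if min(h, w) < int(np.max(box_sizes)):
        raise ContractError(
            f"image {h}x{w} smaller than the largest scale-window box size "
            f"({int(np.max(box_sizes))} px); cannot estimate FD"
        )
    estimates: list[Optional[FDEstimate]] = []
    for thr in thresholds:
        mask = binarize(image, float(thr))
        outline = extract_outline(mask, image.calibration, float(thr))
        if outline.n_pixels < min_outline_pixels:
            estimates.append(None)
            continue
        try:
            est = estimate_fd(box_count(outline, box_sizes), scale_window_um)
        except UndefinedEstimateError:
            estimates.append(None)
            continue
        estimates.append(est)
    return FDProfile(thresholds, estimates)


def core_fd(
    image: GrayImage,
    blank: Optional[GrayImage] = None,
    config: Optional[PipelineConfig] = None,
) -> tuple[QCResult, Optional[FDProfile]]:
    """End-to-end per-core pipeline: correction, QC, threshold-sweep FD.

    With a blank frame the specimen is background-corrected against it;
    without one, correction degrades to a global inversion (max - image) so
    that stain is bright (disable via ``config.invert_without_blank``). Never
    raises on non-evaluable cores: the QC result is returned with a ``None``
    profile.
    """
    config = config or PipelineConfig()
    if blank is not None:
        corrected = background_correct(image, blank)
    elif config.invert_without_blank:
        logger.warning("no blank image supplied; falling back to global inversion")
        hi = float(image.pixels.max())
        corrected = GrayImage(hi - image.pixels, image.calibration, (0.0, hi))
    else:
        corrected = image
    qc = qc_core(
        corrected,
        stain_threshold=config.stain_threshold,
        min_fraction=config.min_stained_fraction,
    )
    if not qc.evaluable:
        return qc, None
    try:
        profile = fd_profile(
            corrected,
            thresholds=default_thresholds(corrected, config.n_thresholds),
            scale_window_um=config.scale_window,
            min_outline_pixels=config.min_outline_pixels,
            box_sizes=default_box_sizes(
                corrected.calibration, config.scale_window, config.box_ratio
            ),
        )
    except CoreNotEvaluableError:
        return QCResult(qc.stained_fraction, False, "degenerate"), None
    return qc, profile
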
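"""Interphase cortical microtubule array metrics.

Anisotropy and mean orientation come from the average nematic (fibril) tensor
of the image texture: per-pixel intensity gradients by centered differences,
per-pixel fibril direction orthogonal to the gradient, and the unweighted
average of the unit nematic tensors over ROI pixels with non-negligible
gradient. Anisotropy is the normalized eigenvalue difference
(lambda1 - lambda2)/(lambda1 + lambda2) of that tensor — 0 for an isotropic
array, 1 for perfectly parallel filaments — and the principal angle is the
orientation of the leading eigenvector.

Angle convention (used everywhere): degrees, measured counterclockwise from
the +x (column) axis, with the image y axis pointing down; orientations are
axial, i.e. reported modulo 180 in [0, 180).

Density follows the classic thresholded area-fraction recipe: IsoData
("default") threshold on the ROI histogram, density = 1 - foreground
fraction. Time-lapse stacks can be bleach-corrected by simple ratio (each
frame rescaled to the first frame's mean). Severing events arrive as manual
annotations; the frequency estimator is events / (cell area x duration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask
from skimage.filters import threshold_isodata

__all__ = [
    "IntensityImage",
    "ArrayMetrics",
    "SeveringRecord",
    "TimelapseStack",
    "nematic_anisotropy",
    "microtubule_density",
    "bleach_correct",
    "severing_frequency",
]

_GRAD_EPS = 1e-12
_MIN_ROI_PIXELS = 100


@dataclass(frozen=True)
class IntensityImage:
    """A 2D grayscale micrograph with physical pixel size and growth-axis angle.

    ``growth_axis_angle`` is the organ's elongation direction in image
    coordinates, degrees in [0, 180).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0  # um / pixel
    growth_axis_angle: float = 0.0  # degrees in [0, 180)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 16:
            raise ValueError("image must be 2D and at least 16x16")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0.0 <= self.growth_axis_angle < 180.0):
            raise ValueError("growth_axis_angle must be in [0, 180)")
        object.__setattr__(self, "pixels", px)


@dataclass
class ArrayMetrics:
    anisotropy: float
    principal_angle: float  # degrees in [0, 180); NaN when undefined
    angle_to_growth_axis: float  # degrees in [0, 90]; NaN when undefined
    density: float | None = None
    angle_defined: bool = True


@dataclass(frozen=True)
class SeveringRecord:
    """Manually annotated severing events for one cell."""

    cell_id: str
    events: tuple  # of (time_s, (x_um, y_um))
    cell_area: float  # um^2
    duration: float  # min

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for t, _pos in self.events:
            if not (0.0 <= t <= self.duration * 60.0):
                raise ValueError("event time outside observation window")


@dataclass(frozen=True)
class TimelapseStack:
    """Frames sharing geometry, acquired at a constant interval."""

    frames: tuple  # of IntensityImage
    frame_interval: float  # s

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a time-lapse needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        shape = self.frames[0].pixels.shape
        for f in self.frames:
            if f.pixels.shape != shape:
                raise ValueError("frames must share geometry")


def _roi_mask(shape: tuple[int, int], roi) -> np.ndarray:
    """Rasterize a polygon given as (x, y) vertex pairs into a boolean mask."""
    if roi is None:
        return np.ones(shape, dtype=bool)
    verts = np.asarray(getattr(roi, "exterior", roi))
    if hasattr(roi, "exterior"):  # shapely polygon
        verts = np.asarray(roi.exterior.coords)
    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(shape, verts[:, ::-1])


def acute_angle_between(theta1: float, theta2: float) -> float:
    """Acute angle in [0, 90] between two axial orientations in degrees."""
    d = abs(theta1 - theta2) % 180.0
    return min(d, 180.0 - d)


def nematic_anisotropy(image: IntensityImage, roi=None) -> ArrayMetrics:
    """Average-nematic-tensor anisotropy and orientation of an array ROI.

    Returns anisotropy in [0, 1], the principal (mean filament) angle in
    [0, 180), and its acute angle to the growth axis in [0, 90]. A flat ROI
    (zero gradient everywhere) yields anisotropy 0 with the angle flagged
    undefined.
    """
    px = image.pixels
    mask = _roi_mask(px.shape, roi)
    if mask.sum() < _MIN_ROI_PIXELS:
        raise ValueError(f"ROI must contain at least {_MIN_ROI_PIXELS} pixels")
    gy, gx = np.gradient(px)  # gy: d/drow, gx: d/dcol
    gnorm = np.hypot(gx, gy)
    sel = mask & (gnorm > _GRAD_EPS)
    if not np.any(sel):
        return ArrayMetrics(0.0, float("nan"), float("nan"), angle_defined=False)
    # fibril direction is orthogonal to the gradient
    ux = -gy[sel] / gnorm[sel]
    uy = gx[sel] / gnorm[sel]
    nxx = float(np.mean(ux * ux))
    nyy = float(np.mean(uy * uy))
    nxy = float(np.mean(ux * uy))
    # trace is 1 by construction, so lambda1 - lambda2 is the anisotropy
    anisotropy = float(np.hypot(nxx - nyy, 2.0 * nxy))
    anisotropy = min(1.0, max(0.0, anisotropy))
    theta = 0.5 * np.degrees(np.arctan2(2.0 * nxy, nxx - nyy)) % 180.0
    return ArrayMetrics(
        anisotropy=anisotropy,
        principal_angle=float(theta),
        angle_to_growth_axis=acute_angle_between(theta, image.growth_axis_angle),
    )


def microtubule_density(image: IntensityImage, roi=None) -> float:
    """Density as 1 - thresholded foreground fraction within the ROI.

    The IsoData ("default") threshold is computed on the whole image, and the
    foreground area fraction is measured within the ROI, mirroring the usual
    threshold-then-measure workflow; an all-background ROI therefore gives
    1.0. Note the complement convention: if the threshold selects filaments
    as foreground this returns the background fraction; the foreground
    fraction is simply 1 - density. Returns NaN for a constant image, where
    no threshold exists.
    """
    px = image.pixels
    mask = _roi_mask(px.shape, roi)
    if mask.sum() < _MIN_ROI_PIXELS:
        raise ValueError(f"ROI must contain at least {_MIN_ROI_PIXELS} pixels")
    if np.all(px == px.flat[0]):
        return float("nan")
    thr = threshold_isodata(px.ravel())
    foreground = float(np.mean(px[mask] > thr))
    return 1.0 - foreground


def bleach_correct(stack: TimelapseStack) -> TimelapseStack:
    """Simple-ratio bleach correction: scale each frame to the first frame's mean."""
    means = [float(f.pixels.mean()) for f in stack.frames]
    if means[0] <= 0:
        raise ValueError("first frame has non-positive mean intensity")
    if any(m == 0 for m in means):
        raise ValueError("a frame has zero mean intensity; cannot rescale")
    ref = means[0]
    frames = tuple(
        IntensityImage(
            f.pixels * (ref / m),
            pixel_size=f.pixel_size,
            growth_axis_angle=f.growth_axis_angle,
        )
        for f, m in zip(stack.frames, means)
    )
    return TimelapseStack(frames=frames, frame_interval=stack.frame_interval)


def severing_frequency(record: SeveringRecord) -> float:
    """Severing-event frequency in events * um^-2 * min^-1."""
    return len(record.events) / (record.cell_area * record.duration)
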
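"""Intrinsic optical imaging: fractional reflectance change, contours, overlay.

Sensory cortex is localized through the stimulus-evoked *decrease* in
reflected red light: per trial, dR/R = (mean stimulation image - mean
baseline image) / mean baseline image, averaged across trials. The map for a
body part is the closed contour drawn at a level near the minimum of the
Gaussian-smoothed dR/R image; overlaying these contours with the motor map in
shared Bregma-aligned millimeter coordinates tests whether the whisker
sensory representation coincides with the retraction hotspot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon
from skimage import measure

from .maps import REGIONS, AverageMap, masked_extremum

__all__ = [
    "ImageStack",
    "SensoryContour",
    "ContourError",
    "fractional_change",
    "extract_contour",
    "overlay",
    "write_stack",
    "read_stack",
]


class ContourError(RuntimeError):
    """No closed contour encloses the activity minimum at the requested level."""


@dataclass
class ImageStack:
    """Reflectance image stack for one stimulus with epoch metadata."""

    frames: np.ndarray  # (n_frames, rows, cols)
    n_baseline: int = 40
    n_stim: int = 40
    n_post: int = 20
    frame_rate_hz: float = 10.0
    mm_per_px: float = 0.06
    bregma_px: tuple[int, int] = (48, 12)  # (row, col)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        expected = self.n_baseline + self.n_stim + self.n_post
        if self.frames.shape[0] != expected:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != epochs total {expected}"
            )
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")

    @property
    def baseline(self) -> np.ndarray:
        return self.frames[: self.n_baseline]

    @property
    def stim(self) -> np.ndarray:
        return self.frames[self.n_baseline : self.n_baseline + self.n_stim]

    def px_to_mm(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Pixel (row, col) -> Bregma-aligned (ml_mm, ap_mm)."""
        ml = (np.asarray(col) - self.bregma_px[1]) * self.mm_per_px
        ap = (self.bregma_px[0] - np.asarray(row)) * self.mm_per_px
        return ml, ap

    def mm_to_px(self, ml_mm, ap_mm) -> tuple[np.ndarray, np.ndarray]:
        row = self.bregma_px[0] - np.asarray(ap_mm) / self.mm_per_px
        col = self.bregma_px[1] + np.asarray(ml_mm) / self.mm_per_px
        return row, col


def fractional_change(stacks: ImageStack | list[ImageStack]) -> np.ndarray:
    """Trial-averaged dR/R image; zero-baseline pixels are flagged NaN."""
    if isinstance(stacks, ImageStack):
        stacks = [stacks]
    if not stacks:
        raise ValueError("no stacks given")
    images = []
    for s in stacks:
        base = s.baseline.mean(axis=0)
        stim = s.stim.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            drr = np.where(base > 0, (stim - base) / base, np.nan)
        images.append(drr)
    return np.mean(images, axis=0)


@dataclass
class SensoryContour:
    """Closed iso-level polygon around one body part's activity minimum."""

    label: str
    polygon_mm: np.ndarray  # (N, 2) columns (ml_mm, ap_mm), closed
    level: float
    polygon_px: np.ndarray = field(repr=False, default=None)  # (N, 2) (row, col)

    @property
    def shape_mm(self) -> Polygon:
        return Polygon(self.polygon_mm)

    @property
    def area_mm2(self) -> float:
        return float(self.shape_mm.area)

    def contains_mm(self, ml_mm: float, ap_mm: float) -> bool:
        return bool(self.shape_mm.contains(Point(ml_mm, ap_mm)))


def extract_contour(
    drr: np.ndarray,
    smoothing_sigma: float = 5.0,
    level_fraction: float = 0.2,
    *,
    stack: ImageStack | None = None,
    mm_per_px: float | None = None,
    bregma_px: tuple[int, int] | None = None,
    label: str = "",
) -> SensoryContour:
    """Contour at ``level = min * (1 - level_fraction)`` of the smoothed image.

    ``level_fraction`` = 0.2 draws the contour at 80% of the peak signal depth,
    a tight outline of the activity focus. Among the closed contours at that
    level, the smallest one enclosing the global minimum is returned. Raises
    :class:`ContourError` when the image has no negative minimum or no closed
    enclosing contour exists (signal too flat or cut by the image border).
    """
    if not 0.0 < level_fraction < 1.0:
        raise ValueError("level_fraction must lie in (0, 1)")
    if stack is not None:
        mm_per_px = stack.mm_per_px
        bregma_px = stack.bregma_px
    if mm_per_px is None or bregma_px is None:
        raise ValueError("need stack= or both mm_per_px= and bregma_px= for mm output")

    img = np.asarray(drr, dtype=float)
    work = np.where(np.isfinite(img), img, 0.0)
    smoothed = gaussian_filter(work, smoothing_sigma) if smoothing_sigma > 0 else work
    vmin = float(smoothed.min())
    if vmin >= 0.0:
        raise ContourError("image has no negative minimum; no evoked signal")
    level = vmin * (1.0 - level_fraction)
    min_rc = np.unravel_index(int(np.argmin(smoothed)), smoothed.shape)
    min_pt = Point(min_rc[1], min_rc[0])

    best = None
    for cont in measure.find_contours(smoothed, level):
        closed = np.allclose(cont[0], cont[-1])
        if not closed:
            continue
        poly = Polygon(cont[:, ::-1])  # (col, row) = (x, y)
        if not poly.is_valid or not poly.contains(min_pt):
            continue
        if best is None or poly.area < best[1].area:
            best = (cont, poly)
    if best is None:
        raise ContourError("no closed contour encloses the minimum at this level")

    cont = best[0]
    ml, ap = (
        (cont[:, 1] - bregma_px[1]) * mm_per_px,
        (bregma_px[0] - cont[:, 0]) * mm_per_px,
    )
    return SensoryContour(
        label=label,
        polygon_mm=np.column_stack([ml, ap]),
        level=level,
        polygon_px=cont,
    )


def overlay(
    contours: list[SensoryContour],
    motor_map: AverageMap,
    *,
    whisker_label: str | None = None,
) -> dict:
    """Compare sensory contours with the motor map in shared mm coordinates.

    Locates the motor map's minimum site (the contralateral-retraction
    hotspot) and reports, per contour, whether that site's center falls
    inside it. ``overlap`` refers to the contour named ``whisker_label``
    (default: the first contour).
    """
    if not contours:
        raise ValueError("no contours given")
    mask = REGIONS["wS1"].mask_array(motor_map.grid)
    row, col, value = masked_extremum(motor_map.values, mask, "min")
    ml, ap = motor_map.grid.site_coord(row, col)
    containment = {c.label: c.contains_mm(ml, ap) for c in contours}
    if whisker_label is None:
        key = contours[0].label
    elif whisker_label in containment:
        key = whisker_label
    else:
        raise KeyError(f"no contour labeled {whisker_label!r}")
    return {
        "motor_min_site": (row, col),
        "motor_min_coord_mm": (ml, ap),
        "motor_min_value": value,
        "containment": containment,
        "overlap": containment[key],
    }


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-frame TIFF plus a JSON header sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    header = {
        "n_baseline": stack.n_baseline,
        "n_stim": stack.n_stim,
        "n_post": stack.n_post,
        "frame_rate_hz": stack.frame_rate_hz,
        "mm_per_px": stack.mm_per_px,
        "bregma_px": list(stack.bregma_px),
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    import tifffile

    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    frames = np.asarray(tifffile.imread(path), dtype=float)
    return ImageStack(
        frames=frames,
        n_baseline=header["n_baseline"],
        n_stim=header["n_stim"],
        n_post=header["n_post"],
        frame_rate_hz=header["frame_rate_hz"],
        mm_per_px=header["mm_per_px"],
        bregma_px=tuple(header["bregma_px"]),
    )
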
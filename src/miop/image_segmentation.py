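"""Anterior contour extraction from Scheimpflug-like grayscale frames.

The segmentation pipeline is deliberately standard and parameter-light:
3x3 median filter -> intensity normalization -> Otsu binarization -> largest
connected bright component -> per-column topmost boundary -> sub-pixel
refinement by a 3-point parabolic fit of the vertical intensity gradient.
Columns in which no boundary is found are dropped.  A report-only quality
check flags low-contrast frames, discontinuous contours and truncated
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label

from .airpuff_simulator import GrayscaleFrame
from .contour_core import ContourFrame, DeformationSequence
from .errors import ConfigError, NoContourFound

__all__ = [
    "SegmentationParams",
    "QualityThresholds",
    "QualityReport",
    "segment_anterior_contour",
    "quality_check",
    "read_image_stack",
]


@dataclass(frozen=True)
class SegmentationParams:
    median_size: int = 3
    min_area_frac: float = 0.01  # of total pixels
    refine_halfwidth: int = 3  # rows searched around the binary edge


@dataclass(frozen=True)
class QualityThresholds:
    min_contrast_ratio: float = 1.5
    max_gap_px: float = 5.0
    max_gap_mm: float = 0.5
    max_bad_frames: int = 5
    expected_frames: int = 140


@dataclass
class FrameFlags:
    frame_index: int
    low_contrast: bool = False
    discontinuous_contour: bool = False
    contrast_ratio: float = 0.0
    max_gap: float = 0.0


@dataclass
class QualityReport:
    frame_flags: List[FrameFlags]
    truncated: bool
    n_frames: int
    max_bad_frames: int = 5
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = not self.truncated and self.n_bad <= self.max_bad_frames

    @property
    def n_bad(self) -> int:
        return sum(
            1
            for f in self.frame_flags
            if f.low_contrast or f.discontinuous_contour
        )


def _subpixel_edge(column: np.ndarray, r0: int, halfwidth: int) -> float:
    """Refine a binary edge row to sub-pixel via the vertical gradient peak."""
    g = np.gradient(column)
    lo = max(1, r0 - halfwidth)
    hi = min(len(column) - 1, r0 + halfwidth + 1)
    if hi - lo < 1:
        return float(r0)
    r_star = lo + int(np.argmax(g[lo:hi]))
    gm, g0, gp = g[r_star - 1], g[r_star], g[r_star + 1] if r_star + 1 < len(g) else g[r_star]
    denom = gm - 2.0 * g0 + gp
    delta = 0.0 if denom == 0 else 0.5 * (gm - gp) / denom
    # +0.5: pixel r samples the band coverage of [r, r+1), so the gradient
    # peak sits half a pixel above the physical edge position.
    return float(r_star + np.clip(delta, -1.0, 1.0) + 0.5)


def segment_anterior_contour(
    image: GrayscaleFrame, params: SegmentationParams = SegmentationParams()
) -> ContourFrame:
    """Extract the anterior (topmost) corneal boundary in mm."""
    px = image.pixels
    if px.shape[1] < 32:
        raise ConfigError("image must have at least 32 columns")
    filtered = median_filter(px, size=params.median_size)
    lo, hi = filtered.min(), filtered.max()
    if hi <= lo:
        raise NoContourFound("image has no intensity variation")
    norm = (filtered - lo) / (hi - lo)
    binary = norm > threshold_otsu(norm)
    labels = label(binary)
    if labels.max() == 0:
        raise NoContourFound("no bright component after binarization")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < params.min_area_frac * px.size:
        raise NoContourFound("largest bright component below the minimum area")
    component = labels == best

    cols, zs = [], []
    for c in range(px.shape[1]):
        hits = np.flatnonzero(component[:, c])
        if hits.size == 0:
            continue
        cols.append(c)
        zs.append(_subpixel_edge(norm[:, c], int(hits[0]), params.refine_halfwidth))
    if len(cols) < 8:
        raise NoContourFound("contour covers fewer than 8 columns")
    cols = np.asarray(cols, dtype=float)
    return ContourFrame(
        frame_index=image.frame_index,
        time_ms=0.0,
        x=cols * image.pixel_size,
        z=np.asarray(zs) * image.pixel_size,
    )


def _image_flags(
    image: GrayscaleFrame, thr: QualityThresholds
) -> FrameFlags:
    px = image.pixels
    bright = float(np.percentile(px, 99))
    dark = float(np.percentile(px, 50))
    contrast = bright / dark if dark > 0 else (np.inf if bright > 0 else 0.0)
    flags = FrameFlags(frame_index=image.frame_index, contrast_ratio=contrast)
    if contrast < thr.min_contrast_ratio:
        flags.low_contrast = True
        return flags
    try:
        contour = segment_anterior_contour(image)
        gaps = np.diff(contour.x) / image.pixel_size
        flags.max_gap = float(gaps.max()) if gaps.size else 0.0
        if flags.max_gap > thr.max_gap_px:
            flags.discontinuous_contour = True
    except (NoContourFound, ConfigError):
        flags.discontinuous_contour = True
    return flags


def _contour_flags(frame: ContourFrame, thr: QualityThresholds) -> FrameFlags:
    gaps = np.diff(frame.x)
    flags = FrameFlags(
        frame_index=frame.frame_index,
        contrast_ratio=np.inf,
        max_gap=float(gaps.max()) if gaps.size else 0.0,
    )
    if flags.max_gap > thr.max_gap_mm:
        flags.discontinuous_contour = True
    return flags


def quality_check(
    frames: Union[DeformationSequence, Sequence[GrayscaleFrame]],
    thresholds: QualityThresholds = QualityThresholds(),
) -> QualityReport:
    """Flag low-quality frames; the sequence fails on truncation or when
    more than ``max_bad_frames`` individual frames are flagged."""
    if isinstance(frames, DeformationSequence):
        flag_list = [_contour_flags(f, thresholds) for f in frames.frames]
        n = frames.n_frames
    else:
        frames = list(frames)
        if not frames:
            raise ConfigError("empty frame sequence")
        flag_list = [_image_flags(f, thresholds) for f in frames]
        n = len(frames)
    return QualityReport(
        frame_flags=flag_list,
        truncated=n != thresholds.expected_frames,
        n_frames=n,
        max_bad_frames=thresholds.max_bad_frames,
    )


def read_image_stack(
    directory, pixel_size: float, pattern: str = "*.png"
) -> List[GrayscaleFrame]:
    """Load a stack of per-frame images (zero-padded filenames sort in order)."""
    from skimage.io import imread

    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise ConfigError(f"no images matching {pattern!r} in {directory}")
    out = []
    for i, p in enumerate(paths, start=1):
        arr = np.asarray(imread(p), dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        out.append(GrayscaleFrame(pixels=arr, pixel_size=pixel_size, frame_index=i))
    return out
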
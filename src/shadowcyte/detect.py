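"""Single-cell detection in full-frame shadow images.

The recognition pipeline: subtract the global mean (background removal),
threshold the absolute deviation at ``k_sigma`` standard deviations,
bridge one-pixel gaps with a single 3x3 binary closing pass, extract
8-connected components, keep those whose bounding box is 8-40 px on both
sides, and cut a 30x30 crop around each component centroid from the
original frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

CROP_SIZE = 30
MIN_BBOX = 8
MAX_BBOX = 40

__all__ = [
    "Detection",
    "CellCrop",
    "remove_background",
    "segment",
    "extract_objects",
    "crop_cells",
    "find_cells",
    "CROP_SIZE",
    "MIN_BBOX",
    "MAX_BBOX",
]


@dataclass(frozen=True)
class Detection:
    """One detected object: integer centroid, bbox (half-open), pixel count."""

    center: tuple[int, int]
    bbox: tuple[int, int, int, int]  # min_row, min_col, height, width
    component_size: int


@dataclass(frozen=True)
class CellCrop:
    """A 30x30 window around a detection, cut from the original frame.

    The detection center sits on patch pixel (14, 14).
    """

    patch: np.ndarray
    center: tuple[int, int]
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.patch.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"crop must be {CROP_SIZE}x{CROP_SIZE}, got {self.patch.shape}")


def remove_background(frame: np.ndarray) -> np.ndarray:
    """Signed deviation image: pixel minus the global frame mean."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    return frame.astype(np.float64) - frame.mean()


def segment(residual: np.ndarray, k_sigma: float = 3.0) -> np.ndarray:
    """Binarize the deviation image and bridge 1-px gaps.

    A pixel is foreground when ``|residual| > k_sigma * std(residual)``;
    one pass of 3x3 morphological closing then fills pixels lying between
    adjacent foreground pixels. A constant frame (zero deviation) yields
    an all-zero mask.
    """
    residual = np.asarray(residual, dtype=np.float64)
    sigma = residual.std()
    if sigma == 0:
        return np.zeros(residual.shape, dtype=np.uint8)
    mask = np.abs(residual) > k_sigma * sigma
    closed = ndimage.binary_closing(mask, structure=np.ones((3, 3), bool))
    # closing must only add pixels; the zero-padded border erosion must not
    # eat isolated foreground
    return (mask | closed).astype(np.uint8)


def extract_objects(mask: np.ndarray, merge_radius: float = 15.0) -> list[Detection]:
    """8-connected components whose bbox is 8-40 px on both sides.

    Centroids are computed on the binary mask and rounded with
    ``floor(x + 0.5)``; detections are ordered by (min_row, min_col).

    A single diffraction pattern can shed detached arcs of its outer
    bright ring that pass the size filter on their own; since each cell
    has exactly one pattern center, detections whose centers fall within
    ``merge_radius`` px (half a crop window) of a larger component's
    center are suppressed. Pass ``merge_radius=0`` to disable.
    """
    labels = measure.label(np.asarray(mask) > 0, connectivity=2)
    detections = []
    for region in measure.regionprops(labels):
        min_row, min_col, max_row, max_col = region.bbox
        height, width = max_row - min_row, max_col - min_col
        if not (MIN_BBOX <= height <= MAX_BBOX and MIN_BBOX <= width <= MAX_BBOX):
            continue
        cr, cc = region.centroid
        detections.append(
            Detection(
                center=(int(np.floor(cr + 0.5)), int(np.floor(cc + 0.5))),
                bbox=(min_row, min_col, height, width),
                component_size=int(region.area),
            )
        )
    if merge_radius > 0:
        detections.sort(key=lambda d: (-d.component_size, d.bbox[0], d.bbox[1]))
        kept: list[Detection] = []
        for det in detections:
            near = any(
                np.hypot(det.center[0] - k.center[0], det.center[1] - k.center[1])
                < merge_radius
                for k in kept
            )
            if not near:
                kept.append(det)
        detections = kept
    detections.sort(key=lambda d: (d.bbox[0], d.bbox[1]))
    return detections


def crop_cells(
    frame: np.ndarray, detections: list[Detection], source_id: str = ""
) -> list[CellCrop]:
    """30x30 crops from the ORIGINAL frame, centered on each detection.

    The window spans rows [r-14, r+16) so the center lands on patch pixel
    (14, 14). Detections whose window would leave the frame are dropped
    with a warning.
    """
    frame = np.asarray(frame)
    rows, cols = frame.shape
    half = CROP_SIZE // 2 - 1  # 14
    crops = []
    for det in detections:
        r, c = det.center
        r0, c0 = r - half, c - half
        if r0 < 0 or c0 < 0 or r0 + CROP_SIZE > rows or c0 + CROP_SIZE > cols:
            logger.warning("dropping detection at %s: crop window out of bounds", det.center)
            continue
        crops.append(
            CellCrop(
                patch=frame[r0 : r0 + CROP_SIZE, c0 : c0 + CROP_SIZE].copy(),
                center=det.center,
                source_id=source_id,
            )
        )
    return crops


def find_cells(
    frame: np.ndarray, k_sigma: float = 3.0, source_id: str = ""
) -> list[CellCrop]:
    """Full pipeline: background removal -> segment -> extract -> crop."""
    residual = remove_background(frame)
    mask = segment(residual, k_sigma=k_sigma)
    return crop_cells(frame, extract_objects(mask), source_id=source_id)
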
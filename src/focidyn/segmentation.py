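"""Nucleus isolation and focus detection.

The manual steps of an interactive analysis — drawing a region of
interest around the nucleus, smoothing, and applying "the appropriate
threshold" — are replaced here by reproducible surrogates: the nucleus
is the largest connected component above a global Otsu threshold of the
smoothed frame, and foci are connected components of the smoothed,
ROI-masked frame above ``nuclear mean + k * nuclear SD`` (default k = 3).

Per focus the area (pixel count x pixel area) and the mean *unsmoothed*
pixel intensity under the label are measured, together with the weighted
centroid in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import find_boundaries

__all__ = [
    "SegmentationParams",
    "NucleusROI",
    "FocusDetection",
    "extract_nucleus_roi",
    "detect_foci",
    "detect_stack",
    "measure_fpc",
    "detections_to_dataframe",
    "detections_from_dataframe",
]


@dataclass
class SegmentationParams:
    """Tunable knobs of the focus detector.

    ``k`` scales the focus threshold above the nuclear background
    (threshold = nuclear mean + k * nuclear SD of the smoothed frame);
    ``sigma_smooth_px`` is the Gaussian smoothing width in pixels;
    areas are in um^2.
    """

    k: float = 3.0
    sigma_smooth_px: float = 1.0
    min_area_um2: float = 0.15
    max_area_um2: float = 25.0
    min_nuclear_area_um2: float = 20.0


@dataclass
class NucleusROI:
    """Per-frame binary nucleus mask with its area in um^2."""

    masks: np.ndarray   # (n_frames, H, W) bool
    areas: np.ndarray   # (n_frames,) um^2

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class FocusDetection:
    """One segmented focus in one frame."""

    frame: int
    label: int
    x: float                # um, weighted centroid (column direction)
    y: float                # um (row direction)
    area: float             # um^2
    mean_intensity: float   # AU, mean of unsmoothed pixels under the label
    touches_border: bool = False

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


def extract_nucleus_roi(stack, params: SegmentationParams | None = None) -> NucleusROI:
    """Largest connected component above Otsu, per frame.

    Raises ``ValueError("no nucleus found")`` if no frame component
    reaches the minimum nuclear area.
    """
    params = params or SegmentationParams()
    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    if data.ndim == 2:
        data = data[None]
    ps = getattr(stack, "pixel_size", 1.0)
    px_area = ps * ps
    n, h, w = data.shape
    masks = np.zeros((n, h, w), dtype=bool)
    areas = np.zeros(n)
    for t in range(n):
        frame = gaussian(data[t], sigma=params.sigma_smooth_px, preserve_range=True)
        if np.ptp(frame) < 1e-12:
            raise ValueError("no nucleus found")
        thr = threshold_otsu(frame)
        lab = sk_label(frame > thr)
        if lab.max() == 0:
            raise ValueError("no nucleus found")
        sizes = np.bincount(lab.ravel())[1:]
        biggest = int(np.argmax(sizes)) + 1
        area = sizes[biggest - 1] * px_area
        if area < params.min_nuclear_area_um2:
            raise ValueError("no nucleus found")
        masks[t] = lab == biggest
        areas[t] = area
    return NucleusROI(masks=masks, areas=areas)


def detect_foci(
    frame_image: np.ndarray,
    mask: np.ndarray,
    params: SegmentationParams,
    pixel_size: float,
    frame_index: int = 0,
) -> tuple[list[FocusDetection], np.ndarray]:
    """Detect foci in one registered, ROI-masked frame.

    Returns the detections and the per-frame label image (0 background),
    which downstream event classification needs for overlap tests.
    """
    frame_image = np.asarray(frame_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return [], np.zeros(frame_image.shape, dtype=np.int32)
    smoothed = gaussian(frame_image, sigma=params.sigma_smooth_px, preserve_range=True)
    inside = smoothed[mask]
    thr = inside.mean() + params.k * inside.std()
    binary = (smoothed > thr) & mask
    lab = sk_label(binary).astype(np.int32)
    if lab.max() == 0:
        return [], lab
    px_area = pixel_size * pixel_size
    border = find_boundaries(mask, mode="inner")
    out: list[FocusDetection] = []
    keep = np.zeros(lab.max() + 1, dtype=bool)
    for rp in regionprops(lab, intensity_image=frame_image):
        area = rp.area * px_area
        if area < params.min_area_um2 or area > params.max_area_um2:
            continue
        keep[rp.label] = True
        cy, cx = rp.centroid_weighted
        touches = bool(border[tuple(rp.coords.T)].any())
        out.append(FocusDetection(
            frame=frame_index, label=int(rp.label),
            x=float(cx * pixel_size), y=float(cy * pixel_size),
            area=float(area), mean_intensity=float(rp.intensity_mean),
            touches_border=touches,
        ))
    lab = np.where(keep[lab], lab, 0).astype(np.int32)
    return out, lab


def detect_stack(
    stack,
    roi: NucleusROI,
    params: SegmentationParams | None = None,
) -> tuple[list[FocusDetection], np.ndarray]:
    """Run :func:`detect_foci` on every frame of a registered stack."""
    params = params or SegmentationParams()
    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    ps = getattr(stack, "pixel_size", 1.0)
    detections: list[FocusDetection] = []
    labels = np.zeros(data.shape, dtype=np.int32)
    for t in range(data.shape[0]):
        dets, lab = detect_foci(data[t], roi.masks[t], params, ps, frame_index=t)
        detections.extend(dets)
        labels[t] = lab
    return detections, labels


def measure_fpc(detections: list[FocusDetection], n_frames: int) -> np.ndarray:
    """Foci-per-cell series: integer count per frame, zero-filled."""
    counts = np.zeros(n_frames, dtype=int)
    for det in detections:
        counts[det.frame] += 1
    return counts


def detections_to_dataframe(detections: list[FocusDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.frame, d.label, d.x, d.y, d.area, d.mean_intensity, d.touches_border)
         for d in detections],
        columns=["frame", "label", "x_um", "y_um", "area_um2",
                 "mean_intensity", "touches_border"],
    )


def detections_from_dataframe(df: pd.DataFrame) -> list[FocusDetection]:
    return [
        FocusDetection(int(r.frame), int(r.label), float(r.x_um), float(r.y_um),
                       float(r.area_um2), float(r.mean_intensity),
                       bool(r.touches_border))
        for r in df.itertuples()
    ]
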
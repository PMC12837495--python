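"""Vessel segmentation by triangle-method adaptive thresholding.

Inside the extracted brain mask the gray-level histogram has a dominant
parenchyma peak and a long right tail of bright vessel pixels.  The
histogram is first rescaled so its peak height equals the gray distance
from the peak to the top level (255):

    NH_i = H_i * (255 - gray_level_peak) / H_peak

A straight line then joins the peak of the normalized histogram to the
top gray level at zero height, and the gray level whose histogram point
lies farthest (perpendicular Euclidean distance) from that line becomes
the binarization threshold.  Pixels at or above the threshold, ANDed
with the brain mask, form the vessel mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram",
    "NormalizedHistogram",
    "ThresholdResult",
    "masked_histogram",
    "normalize_histogram",
    "triangle_threshold",
    "segment_vessels",
]

N_LEVELS = 256
TOP = N_LEVELS - 1  # highest gray level; occupied by cranium in windowed CTA


@dataclass(frozen=True)
class Histogram:
    """Gray-level counts H_i over [0, 255]."""

    counts: np.ndarray  # int (256,)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(f"histogram must have {N_LEVELS} bins")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class NormalizedHistogram:
    """Histogram rescaled so NH at the peak equals 255 - gray_level_peak."""

    values: np.ndarray  # float (256,)
    gray_level_peak: int
    h_peak: int


@dataclass(frozen=True)
class ThresholdResult:
    """Adaptive threshold plus the per-level distances that selected it."""

    threshold: int
    distances: np.ndarray  # float, indexed by gray level over [peak, 255]
    gray_level_peak: int


def masked_histogram(img: np.ndarray, mask: np.ndarray) -> Histogram:
    """Gray-level histogram over the pixels where ``mask`` is true."""
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {mask.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    counts = np.bincount(img[mask].ravel().astype(np.int64), minlength=N_LEVELS)
    return Histogram(counts=counts[:N_LEVELS])


def normalize_histogram(h: Histogram) -> NormalizedHistogram:
    """Apply the peak normalization NH_i = H_i (255 - peak) / H_peak.

    When several gray levels tie for the maximal count, the peak gray
    level is the rounded mean of the tied levels and H_peak the shared
    maximal count.
    """
    counts = h.counts
    if counts.sum() == 0:
        raise ValueError("all-zero histogram")
    h_peak = int(counts.max())
    tied = np.flatnonzero(counts == h_peak)
    gray_level_peak = int(np.floor(tied.mean() + 0.5))  # round half away from zero
    values = counts * ((TOP - gray_level_peak) / h_peak)
    return NormalizedHistogram(
        values=values, gray_level_peak=gray_level_peak, h_peak=h_peak
    )


def triangle_threshold(nh: NormalizedHistogram) -> ThresholdResult:
    """Gray level farthest from the peak-to-top line.

    The line runs from (peak, NH_peak) to (255, 0); for every gray level
    g in [peak, 255] the perpendicular Euclidean distance from
    (g, NH_g) to the line is computed, and the argmax becomes the
    threshold (ties broken toward the lowest gray level).
    """
    p = nh.gray_level_peak
    if p >= TOP:
        raise ValueError("histogram peak at the top gray level: degenerate line")
    x0, y0 = float(p), float(nh.values[p])
    x1, y1 = float(TOP), 0.0
    dx, dy = x1 - x0, y1 - y0
    norm = float(np.hypot(dx, dy))
    g = np.arange(p, TOP + 1)
    y = nh.values[p : TOP + 1]
    distances = np.abs(dy * (g - x0) - dx * (y - y0)) / norm
    threshold = int(p + np.argmax(distances))  # argmax takes the first (lowest) maximum
    return ThresholdResult(threshold=threshold, distances=distances, gray_level_peak=p)


def segment_vessels(
    img: np.ndarray, brain: np.ndarray, return_details: bool = False
):
    """Binarize at the adaptive threshold and intersect with the brain mask.

    Pixels with gray value >= threshold count as vessel; the AND with the
    brain mask guarantees the result is a subset of the brain region.
    """
    img = np.asarray(img)
    brain = np.asarray(brain, dtype=bool)
    h = masked_histogram(img, brain)
    nh = normalize_histogram(h)
    res = triangle_threshold(nh)
    vessels = (img >= res.threshold) & brain
    if return_details:
        return vessels, h, nh, res
    return vessels
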
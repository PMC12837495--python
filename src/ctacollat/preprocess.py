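"""Brain-region extraction from windowed CTA-MIP slices.

The pipeline assumes the image was windowed from 0-450 HU into 8-bit
gray so that (almost all of) the cranium sits at the unique top value
255.  Brain extraction then proceeds by: binarize at 255 -> fill the
cranium interior -> XOR to isolate the brain -> three Sobel passes to
strip near-cranium boundary pixels -> morphological opening when a
calvarial defect lets the brain leak into the background.

Coordinate convention: row-major, origin top-left, 0-based indices.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "hu_to_8bit",
    "binarize_at_max",
    "flood_fill_8",
    "fill_cranium_interior",
    "xor_brain",
    "sobel_boundary_cleanup",
    "open_until_separated",
    "extract_brain_region",
    "read_gray_bmp",
    "write_gray_bmp",
    "read_dicom_hu",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element
_FOUR = ndimage.generate_binary_structure(2, 1)

# Sobel kernels, G = sqrt(Gx^2 + Gy^2), border pixels replicated.
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T

MAX_OPEN_ITERATIONS = 10


class SeparationError(RuntimeError):
    """Opening failed to detach the brain from the background leak."""


def hu_to_8bit(hu: np.ndarray) -> np.ndarray:
    """Window an integer HU raster to 8-bit gray over [0, 450] HU.

    Values <= 0 HU map to 0, >= 450 HU to 255, and intermediate values
    scale by 255/450 with half-away-from-zero rounding, so dense bone
    saturates at the top gray value.
    """
    hu = np.asarray(hu)
    if hu.size == 0:
        raise ValueError("empty HU raster")
    scaled = np.clip(hu, 0, 450) * (255.0 / 450.0)
    # numpy rounds half-to-even; emulate round-half-away-from-zero
    return np.floor(scaled + 0.5).astype(np.uint8)


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    return img


def binarize_at_max(img: np.ndarray) -> np.ndarray:
    """Mask of pixels at the top gray value 255 (the cranium candidates)."""
    return _check_gray(img) == 255


def flood_fill_8(mask: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """8-connected component of true pixels containing ``seed``.

    Returns an empty mask when the seed pixel is false.  ``seed`` is
    (row, col); out-of-bounds seeds raise ``IndexError``.
    """
    mask = np.asarray(mask, dtype=bool)
    r, c = seed
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise IndexError(f"seed {seed} outside image bounds {mask.shape}")
    if not mask[r, c]:
        return np.zeros_like(mask)
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    return labels == labels[r, c]


def fill_cranium_interior(cranium: np.ndarray) -> np.ndarray:
    """Cranium plus all pixels it encloses.

    Background is flood-filled from the image border (4-connected, the
    topological dual of the 8-connected foreground) and inverted, so the
    result is everything not reachable from outside.  An empty cranium
    returns an empty mask; the caller decides whether that is an error.
    """
    cranium = np.asarray(cranium, dtype=bool)
    if not cranium.any():
        return np.zeros_like(cranium)
    free = ~cranium
    border_seeds = np.zeros_like(free)
    border_seeds[0, :] = border_seeds[-1, :] = True
    border_seeds[:, 0] = border_seeds[:, -1] = True
    border_seeds &= free
    if not border_seeds.any():
        raise ValueError("cranium touches the whole border; no exterior exists")
    labels, _ = ndimage.label(free, structure=_FOUR)
    outside_labels = np.unique(labels[border_seeds])
    background = np.isin(labels, outside_labels) & free
    return ~background


def xor_brain(whole: np.ndarray, cranium: np.ndarray) -> np.ndarray:
    """Pixelwise XOR; with ``whole`` ⊇ ``cranium`` this is the brain interior."""
    whole = np.asarray(whole, dtype=bool)
    cranium = np.asarray(cranium, dtype=bool)
    if whole.shape != cranium.shape:
        raise ValueError(f"shape mismatch: {whole.shape} vs {cranium.shape}")
    return whole ^ cranium


def _sobel_magnitude(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    gx = ndimage.convolve(img, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(img, _SOBEL_Y, mode="nearest")
    return np.hypot(gx, gy)


def sobel_boundary_cleanup(
    img: np.ndarray, brain: np.ndarray, n_passes: int = 3, g_threshold: float = 255.0
) -> np.ndarray:
    """Peel high-gradient boundary layers off the brain region image.

    Partial-volume pixels near the cranium survive the XOR step; each of
    the ``n_passes`` passes computes the Sobel magnitude on the binary
    brain region image (mask scaled to 0/255) and removes mask pixels
    with G >= ``g_threshold``.  Only mask-boundary pixels reach the 255
    response, so each pass strips exactly one boundary layer while bright
    structures interior to the mask (the vessels) are untouched — a
    gradient on the raw grayscale would cut the vessels out of the brain
    mask and they could never survive the later AND.  Output is always a
    subset of the input mask.
    """
    img = _check_gray(img)
    mask = np.asarray(brain, dtype=bool).copy()
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    for _ in range(n_passes):
        g = _sobel_magnitude(mask.astype(float) * 255.0)
        mask &= ~(g >= g_threshold)
    return mask


def _reaches(component: np.ndarray, background: np.ndarray) -> bool:
    """True when the component contains any known-background pixel.

    The component is a maximal 8-connected set, so an 8-connected path of
    true pixels joins the brain to the background exactly when a
    background pixel lies inside the component.
    """
    return bool((component & background).any())


def open_until_separated(
    brain: np.ndarray,
    background: np.ndarray,
    centroid: tuple[int, int] | None = None,
    max_iterations: int = MAX_OPEN_ITERATIONS,
) -> np.ndarray:
    """Morphologically open the brain mask until it detaches from background.

    With an intact cranium the brain interior never touches the
    background and the mask is returned unchanged.  A calvarial defect
    leaves a channel joining the two; repeated opening with a growing
    effective structuring element (iteration i erodes and re-dilates i
    times with a 3x3 square, severing channels up to ~2i px wide) cuts
    the channel, after which only the component containing the brain
    centroid is kept.

    Raises ``SeparationError`` if ``max_iterations`` openings do not
    separate the regions.
    """
    brain = np.asarray(brain, dtype=bool)
    background = np.asarray(background, dtype=bool)
    if brain.shape != background.shape:
        raise ValueError("mask shapes differ")
    if not brain.any():
        return brain.copy()
    if centroid is None:
        com = ndimage.center_of_mass(brain)
        centroid = (int(round(com[0])), int(round(com[1])))

    def _brain_component(mask: np.ndarray) -> np.ndarray:
        if mask[centroid]:
            return flood_fill_8(mask, centroid)
        # centroid eroded away: fall back to the largest component
        labels, n = ndimage.label(mask, structure=_EIGHT)
        if n == 0:
            return np.zeros_like(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        return labels == (1 + int(np.argmax(sizes)))

    comp = _brain_component(brain)
    if not _reaches(comp, background):
        return brain.copy()
    for i in range(1, max_iterations + 1):
        opened = ndimage.binary_opening(brain, structure=_EIGHT, iterations=i)
        comp = _brain_component(opened)
        if comp.any() and not _reaches(comp, background):
            return comp
    raise SeparationError(
        f"brain still connected to background after {max_iterations} openings"
    )


def extract_brain_region(img: np.ndarray) -> np.ndarray:
    """Full brain-segmentation pipeline for one windowed slice.

    Composition: ``binarize_at_max`` -> largest 8-connected 255 component
    -> ``fill_cranium_interior`` -> ``xor_brain`` -> three-pass
    ``sobel_boundary_cleanup`` -> ``open_until_separated`` when the
    interior leaked into the background (calvarial defect).
    """
    img = _check_gray(img)
    top = binarize_at_max(img)
    if not top.any():
        raise ValueError("no cranium found: image contains no 255-valued pixel")
    labels, n = ndimage.label(top, structure=_EIGHT)
    sizes = ndimage.sum_labels(top, labels, index=np.arange(1, n + 1))
    cranium = labels == (1 + int(np.argmax(sizes)))

    whole = fill_cranium_interior(cranium)
    brain = xor_brain(whole, cranium)

    # leak detection: a defect lets the border fill run into the interior,
    # leaving essentially no enclosed area behind the XOR
    leaked = brain.sum() < 0.005 * brain.size
    if leaked:
        brain = ~cranium
    if not brain.any():
        raise ValueError("no cranium found: cranium has no interior")

    brain = sobel_boundary_cleanup(img, brain)

    # known-background reference: the non-cranium band on the image border
    background = np.zeros_like(cranium)
    background[0, :] = background[-1, :] = True
    background[:, 0] = background[:, -1] = True
    background &= ~cranium
    com = ndimage.center_of_mass(cranium)
    centroid = (int(round(com[0])), int(round(com[1])))
    if leaked:
        brain = open_until_separated(brain, background, centroid=centroid)
    else:
        comp = flood_fill_8(brain, centroid) if brain[centroid] else brain
        brain = comp if comp.any() else brain
    return brain & ~binarize_at_max(img)


def read_gray_bmp(path) -> np.ndarray:
    """Read an 8-bit grayscale image (BMP or any Pillow-readable format)."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_gray_bmp(arr: np.ndarray, path) -> None:
    """Write a uint8 image or boolean mask (scaled to 0/255) as BMP."""
    from PIL import Image

    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_dicom_hu(path) -> np.ndarray:
    """Read a single-frame monochrome DICOM slice and rescale to HU."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return np.rint(arr * slope + intercept).astype(int)
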
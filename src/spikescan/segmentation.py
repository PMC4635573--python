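"""Segment spread-panicle scans into labeled primary-branch regions.

The pipeline turns a low-resolution (nominally 72 dpi) RGB scan of a
spread-out rice panicle — dark plant material on a light scanner
background — into one labeled region per spikelet-bearing primary branch:

1. channel-mean grayscale,
2. Otsu automatic threshold,
3. binarization (dark foreground by default),
4. morphological opening with a radius-1 disk (the 3x3 diamond), which
   erases the thin rachis and branch stems while leaving the thicker
   spikelet-covered branch regions intact,
5. hole filling by morphological reconstruction from the border,
6. removal of connected components under 100 pixels (dust, awn fragments),
7. 8-connected component labelling.

Foreground components use 8-connectivity and holes use 4-connectivity,
the usual dual convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

__all__ = [
    "NoPanicleError",
    "SegmentationResult",
    "to_gray",
    "otsu_threshold",
    "binarize",
    "morphological_open",
    "fill_holes",
    "remove_small_objects",
    "label_components",
    "extract_branch_regions",
]

# 8-connected structuring element for component labelling
_EIGHT = np.ones((3, 3), dtype=bool)


class NoPanicleError(ValueError):
    """No foreground region survived the cleanup steps."""


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image to grayscale by the unweighted
    channel mean (R + G + B) / 3, rounded half-up to an integer.

    Parameters
    ----------
    img : ndarray
        H x W x 3 array of integer channel values in [0, 255].

    Returns
    -------
    ndarray of uint8, shape H x W.
    """
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("not an RGB image: expected an H x W x 3 array")
    mean = a.astype(np.float64).mean(axis=2)
    # round half-up, not banker's rounding
    return np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's automatic threshold on the 256-bin histogram.

    Returns the threshold ``t`` that maximizes the between-class variance
    of the split into {pixels <= t} and {pixels > t}; among ties the
    smallest ``t`` is returned.

    Raises
    ------
    ValueError
        If the image is constant ("degenerate histogram").
    """
    g = np.asarray(img)
    flat = np.clip(np.round(g.astype(np.float64)), 0, 255).astype(np.intp).ravel()
    hist = np.bincount(flat, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has a single intensity")
    total = hist.sum()
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                # P(value <= t)
    m0 = np.cumsum(p * levels)       # first moment of the low class
    mt = m0[-1]
    w1 = 1.0 - w0
    # between-class variance; invalid where a class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mt * w0 - m0) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    sigma_b[255] = -np.inf  # t=255 leaves the high class empty
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize(img: np.ndarray, t: int, polarity: str = "dark_foreground") -> np.ndarray:
    """Threshold a grayscale image into a boolean foreground mask.

    ``dark_foreground`` marks pixels <= t (panicle darker than scanner
    background, the default for these scans); ``light_foreground`` marks
    pixels > t; ``auto`` picks whichever class has fewer pixels (ties go
    to the dark class).
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold {t!r} outside [0, 255]")
    g = np.asarray(img)
    dark = g <= t
    if polarity == "dark_foreground":
        return dark
    if polarity == "light_foreground":
        return ~dark
    if polarity == "auto":
        n_dark = int(dark.sum())
        return dark if n_dark <= dark.size - n_dark else ~dark
    raise ValueError(f"unknown polarity {polarity!r}")


def morphological_open(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Opening (erosion then dilation) with a disk of the given radius.

    The default radius-1 disk is the 3x3 diamond; structures thinner than
    the element (the rachis, bare stems) vanish while the spikelet-covered
    branch regions survive.
    """
    if radius < 1:
        raise ValueError("opening radius must be >= 1")
    return ndi.binary_opening(np.asarray(mask, dtype=bool), structure=disk(radius))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not 4-connected to the image border.

    Equivalent to morphological reconstruction of the complemented mask
    from a border marker, then complementing back.
    """
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def remove_small_objects(mask: np.ndarray, min_pixels: int = 100) -> np.ndarray:
    """Delete 8-connected components with strictly fewer than
    ``min_pixels`` foreground pixels."""
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    m = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(m, structure=_EIGHT)
    if n == 0:
        return m.copy()
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= min_pixels
    keep[0] = False
    return keep[labels]


def label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label 8-connected foreground components 1..n in raster-scan order
    of their first pixel; background is 0.  Returns ``(labels, n)``."""
    labels, n = ndi.label(np.asarray(mask, dtype=bool), structure=_EIGHT)
    return labels.astype(np.int32), int(n)


@dataclass
class SegmentationResult:
    """Labeled branch regions plus (optionally) the intermediate masks."""

    labels: np.ndarray
    n_regions: int
    threshold: int
    steps: dict[str, np.ndarray] = field(default_factory=dict)


def extract_branch_regions(
    img: np.ndarray,
    *,
    polarity: str = "dark_foreground",
    opening_radius: int = 1,
    min_pixels: int = 100,
    keep_steps: bool = False,
) -> SegmentationResult:
    """Run the full segmentation pipeline on an RGB scan.

    With ``keep_steps`` the result carries every intermediate raster
    (gray, bin, open, fill, clean) plus an extraction-check ``overlay``,
    b + b·f with b the binary mask and f the final region mask: pixels
    coded 0 background / 1 discarded foreground / 2 retained foreground.

    Raises
    ------
    NoPanicleError
        If no region survives cleanup (e.g. a blank scan).
    """
    gray = to_gray(img)
    try:
        t = otsu_threshold(gray)
    except ValueError as exc:
        raise NoPanicleError(f"no panicle detected: {exc}") from exc
    binary = binarize(gray, t, polarity=polarity)
    opened = morphological_open(binary, radius=opening_radius)
    filled = fill_holes(opened)
    clean = remove_small_objects(filled, min_pixels=min_pixels)
    labels, n = label_components(clean)
    if n == 0:
        raise NoPanicleError("no panicle detected: zero regions after cleanup")
    steps: dict[str, np.ndarray] = {}
    if keep_steps:
        final_fg = labels > 0
        steps = {
            "gray": gray,
            "bin": binary,
            "open": opened,
            "fill": filled,
            "clean": clean,
            "overlay": binary.astype(np.uint8) + (binary & final_fg).astype(np.uint8),
        }
    return SegmentationResult(labels=labels, n_regions=n, threshold=t, steps=steps)
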
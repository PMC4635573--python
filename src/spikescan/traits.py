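"""Per-region and per-panicle branch traits.

For each labeled primary-branch region the pipeline measures

* ``area_px`` — the exact number of pixels in the region, and
* ``pbl2_px`` — the primary-branch length proxy: the major-axis length of
  the ellipse with the same normalized second central moments as the
  region.

Summing ``pbl2_px`` over the regions of one panicle gives TLPB2 (total
length of primary branches, endpoint convention 2); summing ``area_px``
gives the total branch-region area.  Both traits are linear in spikelet
number and drive the calibration model.

The moment computation includes the +1/12 per-pixel variance correction
on the diagonal by default, the convention of the classical region-props
measurement tools: each pixel is treated as a unit square rather than a
point mass, which keeps single-pixel and 1-px-thin regions
non-degenerate.  Pass ``pixel_correction=False`` for raw point moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

__all__ = [
    "RegionTraits",
    "PanicleMeasurement",
    "SkeletonVertices",
    "region_area",
    "region_major_axis",
    "measure_panicle",
    "skeleton_vertices",
    "px_to_cm",
    "cm_to_px",
]


def px_to_cm(length_px: float, dpi: float) -> float:
    """Convert a pixel length to centimetres at the given scan resolution."""
    return length_px * 2.54 / dpi


def cm_to_px(length_cm: float, dpi: float) -> float:
    return length_cm * dpi / 2.54


@dataclass(frozen=True)
class RegionTraits:
    """Traits of one labeled branch region."""

    label: int
    area_px: int
    pbl2_px: float            # moment-ellipse major axis
    minor_axis_px: float
    centroid: tuple[float, float]  # (row, col)


@dataclass
class PanicleMeasurement:
    """Aggregate traits of one panicle.

    ``snpp_manual`` (the manually counted spikelet number), ``pal_cm``
    and ``tlpb1_cm`` come from the manual measurement channel (a CSV
    column), never from the image.
    """

    panicle_id: str
    variety: str
    n_regions: int
    tlpb2_px: float
    tlpb2_cm: float
    total_area_px: int
    dpi: float
    snpp_manual: int | None = None
    pal_cm: float | None = None
    tlpb1_cm: float | None = None
    regions: list[RegionTraits] = field(default_factory=list)


def region_area(region: np.ndarray) -> int:
    """Pixel count of a region given as a boolean mask."""
    mask = np.asarray(region, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region")
    return n


def _moment_axes(
    rows: np.ndarray, cols: np.ndarray, pixel_correction: bool = True
) -> tuple[float, float]:
    """Major and minor axis lengths of the moment-equivalent ellipse.

    With area-normalized central second moments uxx (columns), uyy (rows)
    and uxy, each diagonal term optionally augmented by 1/12, the axis
    lengths are 2*sqrt(2)*sqrt(uxx + uyy +- sqrt((uxx-uyy)^2 + 4*uxy^2)).
    """
    r = rows - rows.mean()
    c = cols - cols.mean()
    uxx = float((c * c).mean())
    uyy = float((r * r).mean())
    uxy = float((r * c).mean())
    if pixel_correction:
        uxx += 1.0 / 12.0
        uyy += 1.0 / 12.0
    common = math.sqrt((uxx - uyy) ** 2 + 4.0 * uxy * uxy)
    major = 2.0 * math.sqrt(2.0) * math.sqrt(uxx + uyy + common)
    minor = 2.0 * math.sqrt(2.0) * math.sqrt(max(uxx + uyy - common, 0.0))
    return major, minor


def region_major_axis(region: np.ndarray, pixel_correction: bool = True) -> float:
    """Major-axis length (pixels) of the region's moment-equivalent
    ellipse — the image-based PBL2 of one branch region."""
    mask = np.asarray(region, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty region")
    major, _ = _moment_axes(rows.astype(float), cols.astype(float), pixel_correction)
    return major


def measure_panicle(
    labels: np.ndarray,
    n_regions: int,
    dpi: float = 72.0,
    *,
    panicle_id: str = "",
    variety: str = "",
    snpp_manual: int | None = None,
    pixel_correction: bool = True,
) -> PanicleMeasurement:
    """Measure every labeled region and aggregate to panicle traits.

    TLPB2 is the sum of region major axes; total area is the sum of
    region pixel counts.
    """
    if n_regions < 1:
        raise ValueError("no regions to measure")
    lab = np.asarray(labels)
    regions: list[RegionTraits] = []
    for lbl, sl in enumerate(ndi.find_objects(lab, max_label=n_regions), start=1):
        if sl is None:
            continue
        rows, cols = np.nonzero(lab[sl] == lbl)
        rows = rows.astype(float) + sl[0].start
        cols = cols.astype(float) + sl[1].start
        major, minor = _moment_axes(rows, cols, pixel_correction)
        regions.append(
            RegionTraits(
                label=lbl,
                area_px=rows.size,
                pbl2_px=major,
                minor_axis_px=minor,
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )
    tlpb2_px = float(sum(r.pbl2_px for r in regions))
    return PanicleMeasurement(
        panicle_id=panicle_id,
        variety=variety,
        n_regions=len(regions),
        tlpb2_px=tlpb2_px,
        tlpb2_cm=px_to_cm(tlpb2_px, dpi),
        total_area_px=int(sum(r.area_px for r in regions)),
        dpi=dpi,
        snpp_manual=snpp_manual,
        regions=regions,
    )


@dataclass
class SkeletonVertices:
    """Thinning-based skeleton with its branch topology markers."""

    skeleton: np.ndarray
    junctions: np.ndarray  # (k, 2) array of (row, col)
    terminals: np.ndarray  # (m, 2) array of (row, col)


def skeleton_vertices(mask: np.ndarray) -> SkeletonVertices:
    """Diagnostic skeleton of a mask with junction and terminal points.

    A terminal is a skeleton pixel with exactly one 8-connected skeleton
    neighbour; a junction has three or more.  Purely illustrative — not
    used in SNPP estimation.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        empty = np.empty((0, 2), dtype=int)
        return SkeletonVertices(np.zeros_like(m), empty, empty)
    skel = skeletonize(m)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nbrs = ndi.convolve(skel.astype(int), kernel, mode="constant")
    terminals = np.argwhere(skel & (nbrs == 1))
    junctions = np.argwhere(skel & (nbrs >= 3))
    return SkeletonVertices(skel, junctions, terminals)
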
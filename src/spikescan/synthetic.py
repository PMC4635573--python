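"""Synthetic spread-panicle scans with exact per-panicle ground truth.

The generator emulates the geometry of a rice panicle that has been
manually spread out and scanned at low resolution: a thin rachis curve
running down the image, with primary branches attached alternately left
and right.  Each branch is a gentle quadratic Bezier curve carrying
spikelets — small filled ellipses angled off the branch tangent at a
roughly constant linear density — so that each branch forms one thick,
connected blob while the rachis and bare stems stay 1–2 px thin.  The
segmentation pipeline's opening step then severs the thin connective
material exactly as it does on real scans, leaving one region per
branch.

Ground truth records, per branch, the true arc length and spikelet
count, and per panicle the totals plus the exact painted foreground
pixel count, so segmentation, trait extraction and calibration can all
be scored without any real scans.

Default intensities mimic a flatbed scan: dark plant material (~60) on a
light background (~235) with additive Gaussian channel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk

__all__ = [
    "LayoutError",
    "SyntheticPanicleSpec",
    "BranchTruth",
    "SyntheticGroundTruth",
    "generate_panicle",
    "generate_variety",
]

_MARGIN = 40          # canvas border, px; exceeds any spikelet reach
_ATTACH_SPACING = 40  # rachis arc length between consecutive branches, px
_FIRST_SPIKELET = 14  # arc offset of the first spikelet from the rachis, px
_MIN_GAP = disk(3)    # dilation footprint enforcing >= 3 px between branch blobs


class LayoutError(RuntimeError):
    """Branches could not be placed without overlap after bounded retries."""


@dataclass(frozen=True)
class SyntheticPanicleSpec:
    """Parameters of one synthetic panicle render.

    ``target_snpp`` fixes the total spikelet count exactly (branch
    lengths are then derived from the sampled densities); when ``None``
    branch lengths are drawn from ``branch_length_px`` and counts follow
    from the densities.
    """

    seed: int
    n_branches: int = 10
    target_snpp: int | None = None
    branch_length_px: tuple[float, float] = (100.0, 250.0)
    spikelets_per_px: float = 0.10        # mean linear density along a branch
    density_cv: float = 0.07              # per-branch density variability
    spikelet_axes_px: tuple[float, float] = (9.0, 4.0)  # semi-axes (a, b)
    spikelet_axes_jitter: float = 0.05
    rachis_width_px: int = 2
    dpi: float = 72.0
    background: int = 235
    foreground: int = 60
    noise_sd: float = 8.0

    def __post_init__(self):
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if self.spikelets_per_px <= 0 or self.density_cv < 0:
            raise ValueError("density parameters must be positive")
        if not 1 <= self.rachis_width_px <= 2:
            raise ValueError("rachis_width_px must be 1 or 2 (must vanish under opening)")


@dataclass(frozen=True)
class BranchTruth:
    length_px: float          # arc length of the branch curve
    spikelet_count: int
    spikelet_span_px: float   # arc span actually covered by spikelets


@dataclass(frozen=True)
class SyntheticGroundTruth:
    seed: int
    branches: tuple[BranchTruth, ...]
    total_length_px: float
    total_spikelet_span_px: float
    snpp: int
    painted_area_px: int = 0

    def __post_init__(self):
        assert self.snpp == sum(b.spikelet_count for b in self.branches)


def _bezier(p0, p1, p2, n=160):
    """Sample a quadratic Bezier as an (n, 2) float polyline with
    cumulative arc length."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, arc


def _point_at(pts, arc, s):
    """Point and unit tangent at arc position ``s`` along a polyline."""
    i = int(np.searchsorted(arc, s, side="right")) - 1
    i = min(max(i, 0), len(pts) - 2)
    seg = arc[i + 1] - arc[i]
    f = 0.0 if seg == 0 else (s - arc[i]) / seg
    p = pts[i] + f * (pts[i + 1] - pts[i])
    d = pts[i + 1] - pts[i]
    n = np.linalg.norm(d)
    return p, (d / n if n > 0 else np.array([1.0, 0.0]))


def _paint_polyline(mask, pts, width=1):
    pix = np.round(pts).astype(int)
    for (r0, c0), (r1, c1) in zip(pix[:-1], pix[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        for w in range(width):
            ccw = np.clip(cc + w, 0, mask.shape[1] - 1)
            rrw = np.clip(rr, 0, mask.shape[0] - 1)
            mask[rrw, ccw] = True


def _allocate_counts(rng, target, n, min_count=3):
    """Split ``target`` spikelets over ``n`` branches with mild
    variability, exactly conserving the total (largest-remainder)."""
    w = np.clip(rng.normal(1.0, 0.12, size=n), 0.5, 1.5)
    raw = target * w / w.sum()
    counts = np.floor(raw).astype(int)
    rem = target - counts.sum()
    order = np.argsort(raw - counts)[::-1]
    counts[order[:rem]] += 1
    # enforce the floor by borrowing from the largest branches
    for i in range(n):
        while counts[i] < min_count:
            j = int(np.argmax(counts))
            if counts[j] <= min_count:
                break
            counts[j] -= 1
            counts[i] += 1
    return counts


def generate_panicle(
    spec: SyntheticPanicleSpec,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render one synthetic panicle scan.

    Returns an H x W x 3 uint8 RGB image and its ground truth.
    Deterministic: the same spec (including seed) yields a bit-identical
    image and truth.

    Raises
    ------
    LayoutError
        If a branch cannot be placed without touching an existing branch
        blob after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_branches
    d0 = spec.spikelets_per_px

    # per-branch spikelet counts, densities and lengths
    if spec.target_snpp is not None:
        counts = _allocate_counts(rng, int(spec.target_snpp), n)
        dens = d0 * np.clip(1.0 + rng.normal(0.0, spec.density_cv, n), 0.5, 1.5)
        lengths = np.clip(counts / dens, 40.0, 320.0)
    else:
        lo, hi = spec.branch_length_px
        lengths = rng.uniform(lo, hi, n)
        dens = d0 * np.clip(1.0 + rng.normal(0.0, spec.density_cv, n), 0.5, 1.5)
        counts = np.maximum(np.round(lengths * dens).astype(int), 1)

    # canvas sized from the layout geometry
    rachis_len = _ATTACH_SPACING * (n + 1)
    max_len = float(lengths.max())
    reach = max_len * math.sin(math.radians(62)) + 2 * spec.spikelet_axes_px[0] + 12
    height = int(2 * _MARGIN + rachis_len + max_len + 2 * spec.spikelet_axes_px[0])
    width = int(2 * (_MARGIN + reach))
    mask = np.zeros((height, width), dtype=bool)

    # rachis: near-vertical curve with one gentle sideways bow; kept
    # gentle so branch clearances survive the local tangent rotation
    cx = width / 2.0
    amp = rng.uniform(3.0, 8.0) * (1 if rng.random() < 0.5 else -1)
    rr = np.linspace(0.0, rachis_len, 240)
    rachis_pts = np.stack(
        [_MARGIN + rr, cx + amp * np.sin(math.pi * rr / rachis_len)],
        axis=1,
    )
    seg = np.linalg.norm(np.diff(rachis_pts, axis=0), axis=1)
    rachis_arc = np.concatenate([[0.0], np.cumsum(seg)])
    _paint_polyline(mask, rachis_pts, width=spec.rachis_width_px)

    blobs = np.zeros_like(mask)  # spikelet blobs only, for collision checks
    branch_truths: list[BranchTruth] = []
    a0, b0 = spec.spikelet_axes_px

    for b in range(n):
        side = 1 if b % 2 == 0 else -1
        base, tangent = _point_at(rachis_pts, rachis_arc, _ATTACH_SPACING * (b + 1))
        length = float(lengths[b])
        count = int(counts[b])
        # branches fan slightly outward toward the panicle tip so that
        # same-side neighbours diverge instead of crossing; the angle is
        # measured off the local rachis tangent so the bow rotates the
        # whole neighbourhood rigidly instead of eating clearances
        normal = np.array([-tangent[1], tangent[0]]) * (
            1.0 if tangent[0] >= 0 else -1.0
        )
        phi_base = 40.0 + (10.0 * b / (n - 1) if n > 1 else 5.0)
        placed = False
        for attempt in range(8):
            damp = 0.5**attempt  # retries pull back toward the safe fan layout
            jitter = float(np.clip(rng.normal(0.0, 1.5), -3.5, 3.5)) * damp
            phi = math.radians(phi_base + jitter)
            direction = math.cos(phi) * tangent + side * math.sin(phi) * normal
            perp = np.array([-direction[1], direction[0]])
            bend = rng.uniform(-6.0, 6.0) * damp
            p2 = base + length * direction
            p1 = base + 0.5 * length * direction + bend * perp
            pts, arc = _bezier(base, p1, p2)

            stem = np.zeros_like(mask)
            blob = np.zeros_like(mask)
            _paint_polyline(stem, pts, width=1)
            total_arc = arc[-1]
            s_end = max(total_arc - 4.0, _FIRST_SPIKELET + 1.0)
            positions = (
                np.linspace(_FIRST_SPIKELET, s_end, count)
                if count > 1
                else np.array([(_FIRST_SPIKELET + s_end) / 2.0])
            )
            for j, s in enumerate(positions):
                p, tan = _point_at(pts, arc, s)
                theta = math.atan2(tan[0], tan[1])  # angle of tangent, image coords
                alt = 1 if j % 2 == 0 else -1
                ang = theta + alt * math.radians(40.0 + rng.normal(0.0, 6.0))
                a = a0 * (1.0 + rng.normal(0.0, spec.spikelet_axes_jitter))
                bb = b0 * (1.0 + rng.normal(0.0, spec.spikelet_axes_jitter))
                err, ecc = draw_ellipse(
                    p[0], p[1], max(bb, 1.5), max(a, 2.5),
                    shape=mask.shape, rotation=ang,
                )
                blob[err, ecc] = True

            if (ndi.binary_dilation(blob, structure=_MIN_GAP) & blobs).any():
                continue  # too close to an existing branch blob; redraw
            blobs |= blob
            mask |= stem
            mask |= blob
            span = float(positions[-1] - positions[0]) if count > 1 else 0.0
            branch_truths.append(
                BranchTruth(
                    length_px=float(total_arc),
                    spikelet_count=count,
                    spikelet_span_px=span,
                )
            )
            placed = True
            break
        if not placed:
            raise LayoutError(f"layout failure: branch {b} could not be placed")

    truth = SyntheticGroundTruth(
        seed=spec.seed,
        branches=tuple(branch_truths),
        total_length_px=float(sum(t.length_px for t in branch_truths)),
        total_spikelet_span_px=float(sum(t.spikelet_span_px for t in branch_truths)),
        snpp=int(sum(t.spikelet_count for t in branch_truths)),
        painted_area_px=int(mask.sum()),
    )

    # render: dark material on light background, independent channel noise
    img = np.where(mask, float(spec.foreground), float(spec.background))
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb, truth


def _n_branches_for(snpp: int) -> int:
    """Branch count scales with panicle size, within the usual 5-15."""
    return int(np.clip(round(snpp / 14), 5, 15))


def generate_variety(
    base_spec: SyntheticPanicleSpec,
    n_panicles: int,
    mean_snpp: float,
    snpp_spread: float = 0.2,
) -> list[tuple[np.ndarray, SyntheticGroundTruth]]:
    """Generate a variety: panicles whose true SNPP is lognormal around
    ``mean_snpp`` with coefficient of variation ``snpp_spread``.

    Deterministic per ``base_spec.seed``; panicle ``i`` uses the derived
    seed ``base_spec.seed * 100003 + i`` (kept below 2**31).
    """
    if n_panicles < 1:
        raise ValueError("n_panicles must be >= 1")
    rng = np.random.default_rng(base_spec.seed)
    sigma2 = math.log(1.0 + snpp_spread**2)
    mu = math.log(mean_snpp) - sigma2 / 2.0
    targets = np.maximum(
        np.round(rng.lognormal(mu, math.sqrt(sigma2), size=n_panicles)).astype(int), 20
    )
    out = []
    for i, target in enumerate(targets):
        spec_i = replace(
            base_spec,
            seed=int((base_spec.seed * 100003 + i) % (2**31 - 1)),
            target_snpp=int(target),
            n_branches=_n_branches_for(int(target)),
        )
        out.append(generate_panicle(spec_i))
    return out
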
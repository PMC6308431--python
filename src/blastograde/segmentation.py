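"""Embryo localisation and three-region isolation.

The embryo circumference is found on a binarised gradient-magnitude image
by a two-stage circular Hough transform (radii 100-150 px, then
150-200 px; the stronger detection wins, ties going to the larger
radius).  Around the detected circle three regions are cut:

* **ER** (expanded region): disk of ``radius + 5`` px — the whole embryo
  including the zona pellucida;
* **RR** (reduced region): disk of ``radius - 40`` px — inner cell mass
  plus blastocoel, trophectoderm excluded;
* **TE**: the annulus ``ER \\ RR`` — approximately the trophectoderm.

Coordinates are 0-based ``(row, col)``; a disk is the inclusive set
``distance <= radius``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.transform import hough_circle

from .imaging import StandardImage

#: radial windows of the two main search stages (inclusive bounds, px)
STAGE1_RANGE = (100, 150)
STAGE2_RANGE = (151, 200)

#: step between candidate radii in the Hough sweep
RADIUS_STEP = 2

#: minimum normalized accumulator strength for accepting a detection;
#: roughly the fraction of the ideal full-circle perimeter that voted
MIN_STRENGTH = 0.25

#: region offsets relative to the detected circle radius
ER_OFFSET = +5
RR_OFFSET = -40

BINARIZE_THRESHOLD = 128

#: IoU bands classifying a detection against a known true circle
IOU_FULL = 0.90
IOU_PARTIAL = 0.30

#: minimum fraction of above-background ER pixels for a "full" call
#: when no ground truth is available
DEFAULT_FILL_THRESHOLD = 0.5


class ParameterError(ValueError):
    pass


class DegenerateRegionError(ValueError):
    """Circle too small for the fixed -40 px reduced-region offset."""


@dataclass
class CircleDetection:
    """One detected circle: center (row, col), radius and vote strength.

    ``strength`` is the accumulator peak after normalisation by the ideal
    full-circle vote count, so a clean complete circumference scores near
    1 and a half circle near 0.5.  ``stage`` records which radial search
    window produced the detection.
    """

    center_row: float
    center_col: float
    radius: float
    strength: float
    stage: str = "stage1_100_150"

    def to_record(self) -> str:
        return (f"{self.center_row:.1f},{self.center_col:.1f},"
                f"{self.radius:.1f},{self.strength:.4f},{self.stage}")


@dataclass
class SegmentationResult:
    circle: Optional[CircleDetection]
    er_mask: np.ndarray = None  # type: ignore[assignment]
    rr_mask: np.ndarray = None  # type: ignore[assignment]
    te_mask: np.ndarray = None  # type: ignore[assignment]
    er_image: np.ndarray = None  # type: ignore[assignment]
    rr_image: np.ndarray = None  # type: ignore[assignment]
    te_image: np.ndarray = None  # type: ignore[assignment]
    status: str = "none"
    er_radius: float = 0.0
    rr_radius: float = 0.0
    source: Optional[StandardImage] = None


def gradient_magnitude(img: StandardImage | np.ndarray) -> np.ndarray:
    """Euclidean magnitude of the 3x3 Sobel derivative pair.

    Borders use reflected samples, so the output has the input's shape.
    """
    px = img.pixels if isinstance(img, StandardImage) else np.asarray(img)
    f = px.astype(np.float64)
    gr = ndimage.sobel(f, axis=0, mode="reflect")
    gc = ndimage.sobel(f, axis=1, mode="reflect")
    return np.hypot(gr, gc)


def rescale_gradient(grad: np.ndarray) -> np.ndarray:
    """Min-max rescale a gradient image to [0, 255] (flat input -> zeros)."""
    g = np.asarray(grad, dtype=np.float64)
    lo, hi = g.min(), g.max()
    if hi <= lo:
        return np.zeros_like(g)
    return (g - lo) * (255.0 / (hi - lo))


def binarize(arr: np.ndarray, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
    """Threshold at ``value >= threshold`` (the boundary value is kept)."""
    return np.asarray(arr) >= threshold


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _pooled_peak(acc_slice: np.ndarray) -> tuple[float, int, int]:
    """Peak of one accumulator slice after 3x3 sum pooling.

    Rasterisation spreads the votes of a perfect circle over a ~1 px
    neighbourhood of the true center; pooling gathers them so strength
    reads as a fraction of the full perimeter.
    """
    pooled = ndimage.uniform_filter(acc_slice, size=3, mode="constant") * 9.0
    idx = int(np.argmax(pooled))
    r, c = np.unravel_index(idx, pooled.shape)
    # subtract the background vote level so dense clutter (which votes
    # everywhere) does not masquerade as a circle
    background = float(np.median(pooled))
    return float(pooled[r, c]) - background, int(r), int(c)


def _arc_coverage(edge_rows: np.ndarray, edge_cols: np.ndarray,
                  center: tuple[float, float], radius: float,
                  radial_tol: float = 1.5, arc_bin_px: float = 3.0) -> float:
    """Fraction of a circle's circumference supported by edge pixels.

    Edge pixels within ``radial_tol`` of the circumference are binned by
    angle (bins ~``arc_bin_px`` of arc each); coverage is the fraction
    of occupied bins.  This is the detection strength: 1.0 for a
    complete circumference, ~0.5 for a half circle, and small for
    scattered clutter that merely intersects the annulus.
    """
    dr = edge_rows - center[0]
    dc = edge_cols - center[1]
    dist = np.hypot(dr, dc)
    on = np.abs(dist - radius) <= radial_tol
    if not on.any():
        return 0.0
    n_bins = max(8, int(round(2.0 * np.pi * radius / arc_bin_px)))
    ang = np.arctan2(dr[on], dc[on])
    bins = ((ang + np.pi) / (2.0 * np.pi) * n_bins).astype(int) % n_bins
    return float(len(np.unique(bins)) / n_bins)


def hough_circles(binary: np.ndarray, r_min: int, r_max: int,
                  step: int = RADIUS_STEP) -> list[CircleDetection]:
    """Candidate circles with radius in [r_min, r_max], strongest first.

    For each candidate radius the accumulator peak proposes a center;
    the candidate's strength is its arc coverage (see
    :func:`_arc_coverage`), so partially erased circumferences score in
    proportion to the arc that survives.
    """
    if r_min >= r_max:
        raise ParameterError(f"r_min ({r_min}) must be < r_max ({r_max})")
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return []
    radii = np.arange(r_min, r_max + 1, step)
    acc = hough_circle(binary, radii, normalize=True)
    erows, ecols = np.nonzero(binary)
    out: list[CircleDetection] = []
    for k, radius in enumerate(radii):
        _, r, c = _pooled_peak(acc[k])
        strength = _arc_coverage(erows, ecols, (r, c), float(radius))
        out.append(CircleDetection(center_row=r, center_col=c,
                                   radius=float(radius), strength=strength))
    out.sort(key=lambda d: (-d.strength, -d.radius))
    return out


def two_stage_detect(binary: np.ndarray,
                     min_strength: float = MIN_STRENGTH) -> Optional[CircleDetection]:
    """Run the 100-150 then 150-200 px searches and keep the stronger winner.

    Ties on strength are broken toward the larger radius.  Returns None
    when neither stage clears the minimum-strength floor (typical for
    small smartphone-regime embryos, which is what the rescaling rescue
    path exists for).
    """
    candidates = []
    for stage, (lo, hi) in (("stage1_100_150", STAGE1_RANGE),
                            ("stage2_150_200", STAGE2_RANGE)):
        found = hough_circles(binary, lo, hi)
        if found:
            best = found[0]
            best.stage = stage
            candidates.append(best)
    candidates = [c for c in candidates if c.strength >= min_strength]
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c.strength, c.radius))


def detect_circle(img: StandardImage | np.ndarray,
                  min_strength: float = MIN_STRENGTH) -> Optional[CircleDetection]:
    """Gradient -> rescale -> threshold 128 -> two-stage Hough, in one call."""
    grad = rescale_gradient(gradient_magnitude(img))
    return two_stage_detect(binarize(grad), min_strength=min_strength)


def isolate_regions(img: StandardImage, circle: CircleDetection) -> SegmentationResult:
    """Cut the ER / RR / TE region images around a detected circle."""
    if circle.radius + RR_OFFSET <= 0:
        raise DegenerateRegionError(
            f"radius {circle.radius} too small for RR offset {RR_OFFSET}")
    px = img.pixels
    center = (circle.center_row, circle.center_col)
    er_radius = circle.radius + ER_OFFSET
    rr_radius = circle.radius + RR_OFFSET
    er = disk_mask(px.shape, center, er_radius)
    rr = disk_mask(px.shape, center, rr_radius)
    te = er & ~rr
    seg = SegmentationResult(
        circle=circle,
        er_mask=er, rr_mask=rr, te_mask=te,
        er_image=np.where(er, px, 0).astype(np.uint8),
        rr_image=np.where(rr, px, 0).astype(np.uint8),
        te_image=np.where(te, px, 0).astype(np.uint8),
        er_radius=er_radius, rr_radius=rr_radius,
        source=img,
    )
    seg.status = classify_status(seg)
    return seg


def circle_iou(center_a: tuple[float, float], radius_a: float,
               center_b: tuple[float, float], radius_b: float,
               shape: tuple[int, int] = (480, 640)) -> float:
    """Intersection-over-union of two rasterised disks."""
    a = disk_mask(shape, center_a, radius_a)
    b = disk_mask(shape, center_b, radius_b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def classify_status(seg: SegmentationResult,
                    fill_threshold: float = DEFAULT_FILL_THRESHOLD,
                    truth_circle: Optional[tuple[tuple[float, float], float]] = None) -> str:
    """Grade a segmentation as ``full`` / ``partial`` / ``none``.

    With ground truth (synthetic images) the call is by IoU between the
    detected ER disk and the true embryo disk: full at >= 0.90, partial in
    [0.30, 0.90), none below.  Without ground truth, "full" means at
    least ``fill_threshold`` of ER pixels sit above the background level
    (median intensity outside ER).
    """
    if seg.circle is None:
        return "none"
    if truth_circle is not None:
        (tc, tr) = truth_circle  # true embryo circle; compare ER to ER
        iou = circle_iou((seg.circle.center_row, seg.circle.center_col),
                         seg.er_radius, tc, tr + ER_OFFSET, shape=seg.er_mask.shape)
        if iou >= IOU_FULL:
            return "full"
        return "partial" if iou >= IOU_PARTIAL else "none"
    px = seg.source.pixels if seg.source is not None else seg.er_image
    outside = px[~seg.er_mask]
    background = float(np.median(outside)) if outside.size else 0.0
    inside = px[seg.er_mask]
    if inside.size == 0:
        return "partial"
    frac = float((inside > background).mean())
    return "full" if frac >= fill_threshold else "partial"


def segment(img: StandardImage,
            min_strength: float = MIN_STRENGTH,
            fill_threshold: float = DEFAULT_FILL_THRESHOLD) -> SegmentationResult:
    """Full segmentation: detect the circle, then isolate ER/RR/TE."""
    circle = detect_circle(img, min_strength=min_strength)
    if circle is None:
        return SegmentationResult(circle=None, status="none", source=img)
    try:
        seg = isolate_regions(img, circle)
    except DegenerateRegionError:
        return SegmentationResult(circle=circle, status="none", source=img)
    seg.status = classify_status(seg, fill_threshold=fill_threshold)
    return seg
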
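"""Rescue path for small smartphone-regime embryo images.

Embryos photographed through a stereomicroscope ocular with a phone
camera occupy a tiny fraction of the frame (roughly 0.2-3% of the area
versus ~27% for inverted-microscope captures), so the main two-stage
Hough search (radii 100-200 px) cannot see them.  This module finds the
small embryo with a variable-range Hough sweep (falling back to a
watershed of the distance transform when the Hough fails), crops a box
around it, and expands the crop by bicubic polynomial interpolation

    f(x, y) = sum_{i=0..3} sum_{j=0..3} a_ij x^i y^j

fit to each 4x4 source neighbourhood, until the embryo radius reaches
the main pipeline's search window.  The expanded image is placed on a
standard 640x480 canvas and can then be segmented normally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_triangle
from skimage.morphology import remove_small_objects
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .imaging import RawImage, StandardImage, to_grayscale, stretch_intensity
from .segmentation import CircleDetection, hough_circles

#: radius windows of the variable-range Hough sweep (px)
SWEEP_WINDOWS = ((8, 20), (20, 45), (45, 75), (75, 100))

#: minimum accepted strength for a small-circle detection
SMALL_MIN_STRENGTH = 0.25

#: radius the embryo is expanded to (midpoint of the main Hough windows)
TARGET_RADIUS = 150.0

#: crop box side = CROP_FACTOR * detected radius
CROP_FACTOR = 3.0

MAX_SCALE = 20.0

#: watershed candidate acceptance: circularity 4*pi*A/P^2 and area floors
MIN_CIRCULARITY = 0.6
MIN_REGION_AREA = 50

CANVAS_SHAPE = (480, 640)


class CropError(ValueError):
    pass


@dataclass
class RescaleResult:
    found_by: str                         # hough_variable_range | watershed_fallback | not_found
    crop_box: Optional[tuple[int, int, int, int]] = None  # r0, c0, r1, c1
    scale_factor: float = 0.0
    output: Optional[StandardImage] = None
    small_circle: Optional[CircleDetection] = None

    def map_circle(self, center: tuple[float, float], radius: float
                   ) -> tuple[tuple[float, float], float]:
        """Map a circle from source coordinates into the output canvas."""
        if self.output is None:
            raise ValueError("no output to map into")
        r0, c0, r1, c1 = self.crop_box
        ch = (r1 - r0) * self.scale_factor
        cw = (c1 - c0) * self.scale_factor
        off_r = (CANVAS_SHAPE[0] - ch) / 2.0
        off_c = (CANVAS_SHAPE[1] - cw) / 2.0
        return ((off_r + (center[0] - r0) * self.scale_factor,
                 off_c + (center[1] - c0) * self.scale_factor),
                radius * self.scale_factor)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Classic global histogram equalization of an 8-bit image.

    Uses the cdf-min corrected mapping, so an image already occupying two
    extreme levels (or a single level) is left essentially unchanged.
    """
    g = np.asarray(img, dtype=np.uint8)
    hist = np.bincount(g.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(np.float64)
    nonzero = cdf[hist > 0]
    if nonzero.size == 0:
        return g.copy()
    cdf_min = nonzero[0]
    total = cdf[-1]
    if total <= cdf_min:  # constant image
        return g.copy()
    lut = np.round((cdf - cdf_min) / (total - cdf_min) * 255.0)
    return np.clip(lut, 0, 255).astype(np.uint8)[g]


#: an embryo inside the sweep's radius cap (100 px) covers at most ~10%
#: of a 640x480 frame; denser "foreground" is clutter, not an object
MAX_FOREGROUND_FRACTION = 0.25


def contrast_magnify_binarize(img: np.ndarray) -> np.ndarray:
    """2%-saturation contrast stretch, light smoothing, Otsu threshold.

    The foreground is the minority class.  Equalization amplifies
    background noise, so the stretched image is Gaussian-smoothed
    (sigma 1.5) before thresholding; the threshold is Rosin's triangle
    rule, which (unlike Otsu) stays reliable when the object covers well
    under 1% of the frame.  A constant image, or one whose "foreground"
    exceeds a quarter of the frame (structureless clutter), yields an
    all-false mask.
    """
    g = np.asarray(img, dtype=np.uint8)
    if g.min() == g.max():
        return np.zeros(g.shape, dtype=bool)
    stretched = stretch_intensity(g, saturation_fraction=0.02)
    smooth = ndimage.gaussian_filter(stretched.astype(np.float64), sigma=1.5)
    t = threshold_triangle(smooth)
    binary = smooth > t
    if binary.mean() > 0.5:  # foreground is the minority class
        binary = ~binary
    if binary.mean() > MAX_FOREGROUND_FRACTION:
        return np.zeros(g.shape, dtype=bool)
    # despeckle: drop components below the smallest plausible embryo
    # area (sweep radius floor 8 px -> ~200 px; half that to be safe)
    return remove_small_objects(binary, max_size=99)


def variable_range_hough(binary: np.ndarray,
                         min_strength: float = SMALL_MIN_STRENGTH
                         ) -> Optional[CircleDetection]:
    """Sweep small-radius windows and keep the overall strongest circle.

    The vote image is the boundary of the binary foreground (filled
    blobs would flood the accumulator from their interiors).
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return None
    edges = binary & ~ndimage.binary_erosion(binary)
    best: Optional[CircleDetection] = None
    for lo, hi in SWEEP_WINDOWS:
        found = hough_circles(edges, lo, hi, step=1 if hi <= 45 else 2)
        if found:
            cand = found[0]
            cand.stage = "rescue_variable_range"
            if best is None or cand.strength > best.strength:
                best = cand
    if best is not None and best.strength >= min_strength:
        return best
    return None


def watershed_fallback(binary: np.ndarray) -> Optional[np.ndarray]:
    """Distance-transform watershed; returns the best round region mask.

    Candidate regions are scored by circularity 4*pi*A/P^2; the largest
    sufficiently round region (circularity >= 0.6, area >= 50 px) wins.
    """
    fg = np.asarray(binary, dtype=bool)
    if not fg.any():
        return None
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=5, labels=fg)
    if len(peaks) == 0:
        return None
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers=markers, mask=fg)
    best_mask, best_score = None, 0.0
    for region in regionprops(labels):
        if region.area < MIN_REGION_AREA:
            continue
        perim = region.perimeter
        if perim <= 0:
            continue
        circ = 4.0 * np.pi * region.area / perim ** 2
        if circ < MIN_CIRCULARITY:
            continue
        score = circ * np.sqrt(region.area)
        if score > best_score:
            best_score = score
            best_mask = labels == region.label
    return best_mask


def _lagrange_weights(t: np.ndarray) -> np.ndarray:
    """Cubic Lagrange weights for nodes [-1, 0, 1, 2] at offsets t in [0,1).

    The tensor product of these weights over a 4x4 stencil is exactly the
    unique bicubic polynomial through the 16 samples, so interpolation is
    exact for surfaces polynomial of degree <= 3 in each coordinate.
    """
    w = np.empty(t.shape + (4,))
    w[..., 0] = -t * (t - 1.0) * (t - 2.0) / 6.0
    w[..., 1] = (t + 1.0) * (t - 1.0) * (t - 2.0) / 2.0
    w[..., 2] = -(t + 1.0) * t * (t - 2.0) / 2.0
    w[..., 3] = (t + 1.0) * t * (t - 1.0) / 6.0
    return w


class BicubicPatch:
    """Explicit coefficients a_ij of one 4x4-neighbourhood interpolant.

    ``evaluate`` computes f(x, y) = sum a_ij x^i y^j with (x, y) in local
    coordinates where the inner grid cell spans [0, 1]^2.  Used mainly to
    verify the fast separable path; the fitted surface reproduces the 16
    constraint samples exactly.
    """

    def __init__(self, samples: np.ndarray):
        samples = np.asarray(samples, dtype=np.float64)
        if samples.shape != (4, 4):
            raise ValueError("BicubicPatch needs a 4x4 sample block")
        nodes = np.array([-1.0, 0.0, 1.0, 2.0])
        v = np.vander(nodes, 4, increasing=True)  # v[k, i] = node_k^i
        # samples[k, l] = sum_ij a_ij x_k^i y_l^j  ->  S = V A V^T
        vinv = np.linalg.inv(v)
        self.coefficients = vinv @ samples @ vinv.T

    def evaluate(self, x: float, y: float) -> float:
        px = np.array([x ** i for i in range(4)])
        py = np.array([y ** j for j in range(4)])
        return float(px @ self.coefficients @ py)


def bicubic_expand(img: np.ndarray, crop_box: tuple[int, int, int, int],
                   scale_factor: float, clip: bool = True) -> np.ndarray:
    """Crop then upscale by local bicubic polynomial interpolation.

    Each output sample evaluates the bicubic surface fit to the 4x4
    source neighbourhood of its pre-image; edges are handled by clamped
    replication of border samples.
    """
    if scale_factor <= 1.0:
        raise ValueError("scale_factor must be > 1")
    r0, c0, r1, c1 = crop_box
    src = np.asarray(img, dtype=np.float64)[r0:r1, c0:c1]
    h, w = src.shape
    if h <= 4 or w <= 4:
        raise CropError(f"crop {h}x{w} too small for bicubic interpolation")
    out_h = int(round(h * scale_factor))
    out_w = int(round(w * scale_factor))
    # map output pixel centers onto source coordinates (align centers)
    rows = (np.arange(out_h) + 0.5) / scale_factor - 0.5
    cols = (np.arange(out_w) + 0.5) / scale_factor - 0.5
    r_base = np.floor(rows).astype(int)
    c_base = np.floor(cols).astype(int)
    tr = rows - r_base
    tc = cols - c_base
    wr = _lagrange_weights(tr)          # (out_h, 4)
    wc = _lagrange_weights(tc)          # (out_w, 4)
    r_idx = np.clip(r_base[:, None] + np.arange(-1, 3)[None, :], 0, h - 1)
    c_idx = np.clip(c_base[:, None] + np.arange(-1, 3)[None, :], 0, w - 1)
    # gather (out_h, 4, w) then contract rows, then columns
    rowsamp = src[r_idx, :]                         # (out_h, 4, w)
    rowmix = np.einsum("okw,ok->ow", rowsamp, wr)   # (out_h, w)
    colsamp = rowmix[:, c_idx]                      # (out_h, out_w, 4)
    out = np.einsum("owk,wk->ow", colsamp, wc)
    if clip:
        out = np.clip(np.round(out), 0, 255)
    return out


def rescale_image(raw: RawImage | np.ndarray,
                  target_radius: float = TARGET_RADIUS,
                  crop_factor: float = CROP_FACTOR) -> RescaleResult:
    """Find a small embryo, crop around it and expand onto a 640x480 canvas.

    Pipeline: grayscale -> histogram equalization -> contrast stretch +
    Otsu binarization -> variable-range Hough; if the Hough fails, a
    watershed of the distance transform proposes a round region whose
    equivalent disk (radius sqrt(area/pi)) takes its place.  ``not_found``
    is a value, not an error.
    """
    gray = to_grayscale(raw) if isinstance(raw, RawImage) else np.asarray(raw, dtype=np.uint8)
    eq = equalize_histogram(gray)
    binary = contrast_magnify_binarize(eq)
    circle = variable_range_hough(binary)
    found_by = "hough_variable_range"
    if circle is None:
        mask = watershed_fallback(binary)
        if mask is None:
            return RescaleResult(found_by="not_found")
        rows, cols = np.nonzero(mask)
        radius = float(np.sqrt(mask.sum() / np.pi))
        circle = CircleDetection(center_row=float(rows.mean()),
                                 center_col=float(cols.mean()),
                                 radius=radius, strength=0.0,
                                 stage="rescue_variable_range")
        found_by = "watershed_fallback"

    scale = min(target_radius / circle.radius, MAX_SCALE)
    if scale <= 1.0:
        scale = 1.0 + 1e-6
    half = crop_factor * circle.radius / 2.0
    h, w = gray.shape
    r0 = int(max(0, np.floor(circle.center_row - half)))
    r1 = int(min(h, np.ceil(circle.center_row + half)))
    c0 = int(max(0, np.floor(circle.center_col - half)))
    c1 = int(min(w, np.ceil(circle.center_col + half)))
    crop_box = (r0, c0, r1, c1)
    expanded = bicubic_expand(gray, crop_box, scale)

    canvas_h, canvas_w = CANVAS_SHAPE
    eh, ew = expanded.shape
    border = np.concatenate([expanded[0, :], expanded[-1, :],
                             expanded[:, 0], expanded[:, -1]])
    fill = float(np.median(border))
    canvas = np.full(CANVAS_SHAPE, fill)
    # center the expansion, cropping symmetrically if it overflows
    sr = max(0, (eh - canvas_h) // 2)
    sc = max(0, (ew - canvas_w) // 2)
    dr = max(0, (canvas_h - eh) // 2)
    dc = max(0, (canvas_w - ew) // 2)
    nh = min(eh, canvas_h)
    nw = min(ew, canvas_w)
    canvas[dr:dr + nh, dc:dc + nw] = expanded[sr:sr + nh, sc:sc + nw]
    std = StandardImage(pixels=np.clip(np.round(canvas), 0, 255).astype(np.uint8))
    return RescaleResult(found_by=found_by, crop_box=crop_box, scale_factor=scale,
                         output=std, small_circle=circle)
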
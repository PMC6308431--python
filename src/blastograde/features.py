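"""Texture/shape feature extraction and collinearity pruning.

Each segmented embryo yields 36 numeric variables: for each of the three
regions (ER, RR, TE) five grey-level co-occurrence matrix statistics plus
mean, standard deviation and above-background area fraction; and twelve
whole-embryo geometry/intensity variables.  Before training, variables
are pruned by iterated variance-inflation-factor elimination (drop the
worst VIF > 10, refit, repeat), which in the reference configuration
reduces 36 variables to 24.

GLCMs here are *masked*: a pixel pair is counted only when both pixels
lie inside the region mask, so the zero background never contaminates
the texture statistics.  (Library GLCM routines count every pair in the
bounding box, which is why the matrix is accumulated here directly.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segmentation import SegmentationResult, gradient_magnitude

GLCM_LEVELS = 8
GLCM_DISTANCE = 1
GLCM_ANGLES = (0, 45, 90, 135)
VIF_THRESHOLD = 10.0

#: sentinel for perfect collinearity
VIF_INF = np.inf

_REGION_STATS = ("glcm_contrast", "glcm_correlation", "glcm_energy",
                 "glcm_homogeneity", "glcm_entropy",
                 "mean_intensity", "std_intensity", "area_fraction")

_GLOBAL_FEATURES = (
    "er_radius", "rr_radius", "er_area", "te_area",
    "er_rr_mean_ratio", "te_rr_mean_ratio",
    "circle_strength", "gradient_energy_er", "border_contrast",
    "centroid_offset", "eccentricity_proxy", "er_histogram_entropy",
)

#: the frozen, ordered 36-variable schema
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{region}_{stat}" for region in ("er", "rr", "te") for stat in _REGION_STATS
) + _GLOBAL_FEATURES

assert len(FEATURE_NAMES) == 36


class EmptyRegionError(ValueError):
    pass


class ExtractionError(ValueError):
    pass


class IllPosedError(ValueError):
    pass


@dataclass
class GLCM:
    matrix: np.ndarray
    distance: int
    angle: int
    levels: int
    normalized: bool = False

    def normalize(self) -> "GLCM":
        total = self.matrix.sum()
        if total == 0:
            raise EmptyRegionError("GLCM has no pair counts")
        return GLCM(matrix=self.matrix / total, distance=self.distance,
                    angle=self.angle, levels=self.levels, normalized=True)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    source: Optional[SegmentationResult] = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


@dataclass
class VifReport:
    """Removal trace of the iterated VIF pruning.

    ``iterations`` lists one ``(removed_name, vif_value)`` per removal
    plus a final ``(None, max_vif)`` confirmation entry, so a 12-removal
    run reports 13 iterations.
    """

    iterations: list[tuple[Optional[str], float]] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)

    @property
    def removed(self) -> list[str]:
        return [name for name, _ in self.iterations if name is not None]

    def to_json_dict(self) -> dict:
        return {
            "iterations": [
                {"removed": name, "vif": (None if np.isinf(v) else float(v))}
                for name, v in self.iterations
            ],
            "final_vifs": {k: float(v) for k, v in self.final_vifs.items()},
        }


def quantize(pixels: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Map [0,255] intensities onto ``levels`` equal-width bins."""
    return np.minimum(np.asarray(pixels).astype(np.int64) * levels // 256, levels - 1)


_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_compute(region_image: np.ndarray, mask: Optional[np.ndarray] = None,
                 distance: int = GLCM_DISTANCE, angle: int = 0,
                 levels: int = GLCM_LEVELS) -> GLCM:
    """Symmetric masked co-occurrence counts at one (distance, angle).

    A pair contributes only if both of its pixels are in-mask; each pair
    is counted in both directions.
    """
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}, got {angle}")
    img = np.asarray(region_image)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    if mask.sum() < 2:
        raise EmptyRegionError("region needs at least 2 in-mask pixels")
    q = quantize(img, levels)
    dr, dc = _ANGLE_OFFSETS[angle]
    dr *= distance
    dc *= distance
    h, w = img.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    m = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(m, (a[valid], b[valid]), 1.0)
    m = m + m.T  # symmetric accumulation
    return GLCM(matrix=m, distance=distance, angle=angle, levels=levels)


def glcm_stats(g: GLCM) -> dict[str, float]:
    """Haralick-style statistics of a normalized GLCM.

    contrast = sum p(i,j) (i-j)^2; energy = sum p^2;
    homogeneity = sum p / (1 + |i-j|); entropy in bits with 0 log 0 = 0;
    correlation is the normalized covariance (defined as 1 for a
    zero-variance, i.e. single-level, region).
    """
    if not g.normalized:
        raise ValueError("glcm_stats requires a normalized GLCM")
    p = g.matrix
    n = g.levels
    i = np.arange(n)[:, None] * np.ones((1, n))
    j = i.T
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p ** 2).sum())
    homog = float((p / (1.0 + np.abs(i - j))).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 1e-15 or var_j <= 1e-15:
        corr = 1.0
    else:
        corr = float((p * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    return {"contrast": contrast, "correlation": corr, "energy": energy,
            "homogeneity": homog, "entropy": entropy}


def _region_features(image: np.ndarray, mask: np.ndarray,
                     background: float) -> list[float]:
    vals = image[mask].astype(np.float64)
    stats_acc = {k: 0.0 for k in ("contrast", "correlation", "energy",
                                  "homogeneity", "entropy")}
    for angle in GLCM_ANGLES:
        g = glcm_compute(image, mask, angle=angle).normalize()
        s = glcm_stats(g)
        for k in stats_acc:
            stats_acc[k] += s[k] / len(GLCM_ANGLES)
    mean = float(vals.mean())
    std = float(vals.std())
    area_frac = float((vals > background).mean())
    return [stats_acc["contrast"], stats_acc["correlation"], stats_acc["energy"],
            stats_acc["homogeneity"], stats_acc["entropy"], mean, std, area_frac]


def extract_features(seg: SegmentationResult) -> FeatureVector:
    """The full 36-variable vector for one full/partial segmentation."""
    if seg.status not in ("full", "partial"):
        raise ExtractionError(f"cannot extract features from status={seg.status!r}")
    px = seg.source.pixels if seg.source is not None else seg.er_image
    outside = px[~seg.er_mask]
    background = float(np.median(outside)) if outside.size else 0.0

    values: list[float] = []
    for image, mask in ((px, seg.er_mask), (px, seg.rr_mask), (px, seg.te_mask)):
        values.extend(_region_features(image, mask, background))

    er_vals = px[seg.er_mask].astype(np.float64)
    rr_vals = px[seg.rr_mask].astype(np.float64)
    te_vals = px[seg.te_mask].astype(np.float64)
    er_mean, rr_mean, te_mean = er_vals.mean(), rr_vals.mean(), te_vals.mean()
    eps = 1e-9

    grad = gradient_magnitude(px)
    grad_energy = float(np.sqrt((grad[seg.er_mask] ** 2).mean()))
    border_contrast = float(er_mean - background)

    above = (px > background) & seg.er_mask
    c = seg.circle
    if above.any():
        rows, cols = np.nonzero(above)
        centroid = (rows.mean(), cols.mean())
        offset = float(np.hypot(centroid[0] - c.center_row, centroid[1] - c.center_col))
        var_r = rows.var()
        var_c = cols.var()
        ecc = float(abs(var_r - var_c) / (var_r + var_c + eps))
    else:
        offset, ecc = 0.0, 0.0

    hist, _ = np.histogram(er_vals, bins=32, range=(0, 256))
    ph = hist / max(1, hist.sum())
    ph = ph[ph > 0]
    hist_entropy = float(-(ph * np.log2(ph)).sum())

    values.extend([
        float(seg.er_radius), float(seg.rr_radius),
        float(seg.er_mask.sum()), float(seg.te_mask.sum()),
        float(er_mean / (rr_mean + eps)), float(te_mean / (rr_mean + eps)),
        float(c.strength), grad_energy, border_contrast,
        offset, ecc, hist_entropy,
    ])
    return FeatureVector(values=np.asarray(values, dtype=np.float64), source=seg)


def vif(feature_matrix: np.ndarray, col: int) -> float:
    """Variance inflation factor 1/(1-R^2) of one column on the rest.

    The regression is ordinary least squares with an intercept.  Exact
    collinearity (R^2 = 1 within 1e-12) returns +inf.
    """
    x = np.asarray(feature_matrix, dtype=np.float64)
    n, k = x.shape
    if k < 2:
        raise IllPosedError("need at least 2 columns")
    if n <= k:
        raise IllPosedError(f"need more rows ({n}) than columns ({k})")
    y = x[:, col]
    others = np.delete(x, col, axis=1)
    design = np.column_stack([np.ones(n), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise IllPosedError(f"column {col} is constant")
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return VIF_INF
    return 1.0 / (1.0 - r2)


def vif_all(feature_matrix: np.ndarray) -> np.ndarray:
    return np.array([vif(feature_matrix, k) for k in range(feature_matrix.shape[1])])


def vif_prune(feature_matrix: np.ndarray,
              names: Sequence[str] | None = None,
              threshold: float = VIF_THRESHOLD) -> tuple[list[str], VifReport]:
    """Greedy iterated VIF elimination.

    Repeatedly drop the column with the largest VIF strictly above
    ``threshold`` (ties broken toward the earlier schema position) and
    refit until every remaining VIF is at or below the threshold.
    Returns the kept names and the removal report.
    """
    x = np.asarray(feature_matrix, dtype=np.float64)
    if names is None:
        names = list(FEATURE_NAMES[: x.shape[1]]) if x.shape[1] <= 36 else [
            f"x{k}" for k in range(x.shape[1])]
    names = list(names)
    if len(names) != x.shape[1]:
        raise ValueError("names length must match number of columns")
    report = VifReport()
    while True:
        if x.shape[0] <= x.shape[1]:
            raise IllPosedError(
                f"{x.shape[0]} rows cannot support {x.shape[1]}-column regressions")
        vifs = vif_all(x)
        worst = int(np.argmax(vifs))  # argmax returns the first (earliest) max
        if vifs[worst] <= threshold:
            report.iterations.append((None, float(np.max(vifs))))
            report.final_vifs = dict(zip(names, map(float, vifs)))
            return names, report
        report.iterations.append((names[worst], float(vifs[worst])))
        x = np.delete(x, worst, axis=1)
        del names[worst]
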
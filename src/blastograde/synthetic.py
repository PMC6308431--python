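"""Ground-truthed synthetic blastocyst images and feature datasets.

No study images ship with the package, so every detector and grader is
exercised on rendered stand-ins: a bright zona-pellucida ring at the
true radius, a textured trophectoderm annulus, a darker blastocoel with
an off-center inner-cell-mass blob, and a noisy background.  Three
acquisition regimes are emulated, calibrated to the typical fraction of
the frame an embryo occupies in each source:

* ``microscope``    — radius 100-200 px  (~24% of a 640x480 frame),
* ``smartphone_d1`` — radius 45-75 px    (~3% of the frame),
* ``smartphone_d2`` — radius 10-20 px    (~0.2% of the frame).

Grade (1 excellent/good, 2 fair, 3 poor) controls morphological
degradation: ring erasure, shape asymmetry and vacuole speckles.
Smartphone regimes are rendered at 1280x960 and block-averaged down to
640x480, mimicking optical capture through an ocular.

``generate_feature_dataset`` provides a labelled 24-variable Gaussian
surrogate for training experiments, and ``extend_with_collinear``
appends 12 near-linear combinations to exercise the 36 -> 24
variance-inflation pruning.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .imaging import RawImage, save_png
from .segmentation import ER_OFFSET, RR_OFFSET, disk_mask

REGIME_RADII = {
    "microscope": (100, 200),
    "smartphone_d1": (45, 75),
    "smartphone_d2": (10, 20),
}

#: per-grade degradation: (ring erasure fraction, asymmetry, n vacuoles)
GRADE_DEGRADATION = {
    1: (0.00, 0.00, 0),
    2: (0.15, 0.02, 3),
    3: (0.35, 0.06, 9),
}

FRAME_SHAPE = (480, 640)
SUPERSAMPLED_SHAPE = (960, 1280)

#: trophectoderm annulus thickness at radius 150 (scales linearly)
TE_THICKNESS_AT_150 = 40.0

DEFAULT_NOISE_SD = 5.0


class GeometryError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    regime: str = "microscope"
    radius_range: Optional[tuple[float, float]] = None
    grade: int = 1
    noise_sd: float = DEFAULT_NOISE_SD
    background: str = "flat"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIME_RADII:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.radius_range is None:
            self.radius_range = REGIME_RADII[self.regime]
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad radius range {self.radius_range}")
        if self.grade not in (1, 2, 3):
            raise ValueError("grade must be 1, 2 or 3")


@dataclass
class GroundTruth:
    center: tuple[float, float]
    radius: float
    grade: int
    er_mask: np.ndarray = None  # type: ignore[assignment]
    rr_mask: np.ndarray = None  # type: ignore[assignment]
    te_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.er_mask is None:
            er_r = self.radius + ER_OFFSET
            rr_r = max(0.0, self.radius + RR_OFFSET)
            self.er_mask = disk_mask(FRAME_SHAPE, self.center, er_r)
            self.rr_mask = (disk_mask(FRAME_SHAPE, self.center, rr_r)
                            if rr_r > 0 else np.zeros(FRAME_SHAPE, dtype=bool))
            self.te_mask = self.er_mask & ~self.rr_mask


def _render_frame(shape: tuple[int, int], center: tuple[float, float],
                  radius: float, grade: int, noise_sd: float,
                  background: str, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    erase_frac, asym, n_vac = GRADE_DEGRADATION[grade]

    # mild asymmetry: radius modulated around the circumference
    theta = np.arctan2(rr - center[0], cc - center[1])
    phase = rng.uniform(0, 2 * np.pi)
    r_eff = radius * (1.0 + asym * np.sin(2 * theta + phase))
    dist = np.hypot(rr - center[0], cc - center[1])

    if background == "gradient":
        img = 35.0 + 20.0 * (cc / w)
    else:
        img = np.full(shape, 40.0)

    te_thick = max(3.0, TE_THICKNESS_AT_150 * radius / 150.0)
    ring_thick = 3.0  # half-thickness of the zona ring, px

    inside = dist <= r_eff
    img[inside] = 110.0                                     # blastocoel
    te_band = inside & (dist >= r_eff - te_thick)
    img[te_band] = 140.0                                    # trophectoderm
    # trophectoderm texture
    tex = rng.normal(0.0, 18.0, size=shape)
    img[te_band] += tex[te_band]
    # bright zona pellucida ring at the true radius
    ring = np.abs(dist - r_eff) <= ring_thick
    img[ring] = 225.0

    if erase_frac > 0:  # erase arcs of the ring (poorer grades)
        a0 = rng.uniform(0, 2 * np.pi)
        span = erase_frac * 2 * np.pi
        ang = np.mod(theta - a0, 2 * np.pi)
        img[ring & (ang < span)] = 115.0

    # off-center inner cell mass blob
    icm_r = 0.35 * radius
    icm_off = 0.4 * radius
    icm_ang = rng.uniform(0, 2 * np.pi)
    icm_c = (center[0] + icm_off * np.sin(icm_ang), center[1] + icm_off * np.cos(icm_ang))
    icm = np.hypot(rr - icm_c[0], cc - icm_c[1]) <= icm_r
    img[icm & inside] = 170.0

    for _ in range(n_vac):  # vacuole speckles
        vr = rng.uniform(0.04, 0.10) * radius
        va = rng.uniform(0, 2 * np.pi)
        vd = rng.uniform(0, 0.8) * radius
        vc = (center[0] + vd * np.sin(va), center[1] + vd * np.cos(va))
        vac = np.hypot(rr - vc[0], cc - vc[1]) <= vr
        img[vac & inside] = 90.0

    img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0, 255)


def render_blastocyst(spec: SyntheticSpec) -> tuple[RawImage, GroundTruth]:
    """Render one embryo image with its exact circle/grade ground truth."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.radius_range
    radius = float(rng.uniform(lo, hi))
    h, w = FRAME_SHAPE
    margin = radius * 1.16 + 5  # covers asymmetric bulge + zona ring
    if 2 * margin >= min(h, w):
        raise GeometryError(f"radius {radius:.0f} too large for a {h}x{w} frame")
    center = (float(rng.uniform(margin, h - margin)),
              float(rng.uniform(margin, w - margin)))

    if spec.regime == "microscope":
        img = _render_frame(FRAME_SHAPE, center, radius, spec.grade,
                            spec.noise_sd, spec.background, rng)
    else:
        # render at 2x then block-average down, as through an ocular
        hi_center = (center[0] * 2, center[1] * 2)
        hi_img = _render_frame(SUPERSAMPLED_SHAPE, hi_center, radius * 2,
                               spec.grade, spec.noise_sd, spec.background, rng)
        img = hi_img.reshape(h, 2, w, 2).mean(axis=(1, 3))

    raw = RawImage(pixels=np.round(img).astype(np.uint8),
                   source_tag="synthetic")
    truth = GroundTruth(center=center, radius=radius, grade=spec.grade)
    return raw, truth


def measure_occupancy(truth_or_radius, shape: tuple[int, int] = FRAME_SHAPE
                      ) -> tuple[float, float]:
    """(area fraction, width-interception fraction) of an embryo circle.

    area = pi r^2 / (H W); interception = 2r / W.
    """
    if isinstance(truth_or_radius, GroundTruth):
        r = truth_or_radius.radius
    elif hasattr(truth_or_radius, "radius"):
        r = truth_or_radius.radius
    else:
        r = float(truth_or_radius)
    if r < 0:
        raise ValueError("radius must be non-negative")
    h, w = shape
    return float(np.pi * r * r / (h * w)), float(2.0 * r / w)


# -- feature-space surrogate datasets ----------------------------------

N_BASE_FEATURES = 24
N_COLLINEAR = 12


def generate_feature_dataset(n_per_class: int, separation: float = 6.0,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Three 24-D Gaussian grade clusters with controllable separation.

    Class means are ``separation`` sigma apart along random orthogonal
    directions; the shared within-class covariance contains correlated
    blocks of four variables (pairwise correlation 0.35) so that pruning
    and training see realistically collinear inputs while every base
    column stays comfortably below the VIF-10 pruning threshold.
    """
    if n_per_class < 5:
        raise ValueError("need at least 5 samples per class")
    rng = np.random.default_rng(seed)
    d = N_BASE_FEATURES
    # block-correlated covariance: blocks of 4 at rho = 0.35
    cov = np.eye(d)
    for b0 in range(0, d, 4):
        cov[b0:b0 + 4, b0:b0 + 4] = 0.35
        np.fill_diagonal(cov[b0:b0 + 4, b0:b0 + 4], 1.0)
    chol = np.linalg.cholesky(cov)
    dirs = np.linalg.qr(rng.normal(size=(d, 3)))[0].T  # 3 orthonormal rows
    xs, ys = [], []
    for cls in (1, 2, 3):
        mu = separation * dirs[cls - 1] * np.sqrt(1.0)
        z = rng.normal(size=(n_per_class, d))
        xs.append(z @ chol.T + mu)
        ys.extend([cls] * n_per_class)
    x = np.vstack(xs)
    y = np.asarray(ys)
    perm = rng.permutation(len(y))
    return x[perm], y[perm]


def extend_with_collinear(features: np.ndarray, seed: int = 0,
                          noise_sd: float = 0.01) -> tuple[np.ndarray, list[str]]:
    """Append 12 near-collinear columns (means of disjoint column pairs).

    Each appended column averages a disjoint pair of base columns
    (standardized and sign-aligned so the pair cannot cancel) plus tiny
    noise.  Predicting an appended column from the rest leaves only its
    own noise as residual, while predicting either source column leaves
    twice that noise, so the appended column always carries the largest
    VIF and greedy pruning removes exactly these twelve.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.shape[1] != N_BASE_FEATURES:
        raise ValueError(f"expected {N_BASE_FEATURES} base columns")
    rng = np.random.default_rng(seed)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    order = rng.permutation(N_BASE_FEATURES)
    extra = []
    names = [f"x{k}" for k in range(N_BASE_FEATURES)]
    for k in range(N_COLLINEAR):
        a, b = order[2 * k:2 * k + 2]
        sign = 1.0 if np.corrcoef(z[:, a], z[:, b])[0, 1] >= 0 else -1.0
        col = 0.5 * (z[:, a] + sign * z[:, b]) + rng.normal(0, noise_sd, size=x.shape[0])
        extra.append(col)
        names.append(f"dup{k}_of_{min(a, b)}_{max(a, b)}")
    return np.column_stack([x] + extra), names


def write_fixture_directory(out_dir: str | Path, specs: list[SyntheticSpec]) -> Path:
    """Render a set of images to PNG plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "regime", "grade", "center_row", "center_col",
                         "radius", "seed"])
        for k, spec in enumerate(specs):
            raw, truth = render_blastocyst(spec)
            name = f"embryo_{k:03d}_{spec.regime}_g{spec.grade}.png"
            save_png(raw.pixels, out_dir / name)
            writer.writerow([name, spec.regime, spec.grade,
                             f"{truth.center[0]:.1f}", f"{truth.center[1]:.1f}",
                             f"{truth.radius:.1f}", spec.seed])
    return manifest
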
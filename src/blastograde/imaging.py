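"""Image loading and standardization.

Every downstream stage of the grading pipeline works on a canonical
640x480, 8-bit grayscale, contrast-stretched image.  This module owns the
conversion from arbitrary input images (BMP/JPG/PNG, RGB or grayscale, any
resolution) to that canonical form.

Standardization steps:

1. grayscale conversion (ITU-R BT.601 luminance weights),
2. resize to 640x480 preserving aspect ratio, center-padding the short
   dimension with the median border intensity,
3. linear contrast stretch saturating 1% of pixels (0.5% at each tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

#: canonical working resolution (rows, cols)
STANDARD_SHAPE = (480, 640)

#: ITU-R BT.601 luminance weights for R, G, B
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: total fraction of pixels saturated by the intensity stretch
DEFAULT_SATURATION = 0.01

SUPPORTED_FORMATS = {".bmp", ".jpg", ".jpeg", ".png"}


class DecodeError(IOError):
    """Raised when an image file exists but cannot be decoded."""


class FormatError(ValueError):
    """Raised for file formats outside BMP/JPG/PNG."""


class ChannelError(ValueError):
    """Raised for channel counts other than 1 or 3."""


@dataclass
class RawImage:
    """An image as loaded from disk (or built in memory), unresized.

    ``pixels`` is ``(H, W)`` or ``(H, W, 3)`` uint8.  ``source_tag``
    records the acquisition regime (``microscope``, ``smartphone`` or
    ``synthetic``) so the pipeline can decide whether the rescaling
    rescue path applies.
    """

    pixels: np.ndarray
    source_tag: str = "microscope"
    origin_path: str = "in-memory"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3):
            raise ChannelError(f"expected 2-D or 3-D pixel array, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ChannelError(f"unsupported channel count {px.shape[2]} (need 1 or 3)")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"image too small: {px.shape[0]}x{px.shape[1]} (min 16x16)")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StandardImage:
    """The canonical 480x640 grayscale working image.

    ``pad_mask`` flags pixels introduced by aspect-preserving padding;
    segmentation treats them as background.
    """

    pixels: np.ndarray
    saturation_fraction: float = DEFAULT_SATURATION
    provenance: Optional[RawImage] = None
    pad_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixels.shape != STANDARD_SHAPE:
            raise ValueError(f"standard image must be {STANDARD_SHAPE}, got {self.pixels.shape}")
        if self.pad_mask is None:
            self.pad_mask = np.zeros(STANDARD_SHAPE, dtype=bool)


def load_image(path: str | Path, source_tag: str = "microscope") -> RawImage:
    """Load a BMP/JPG/PNG file into a :class:`RawImage` without resizing."""
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_FORMATS:
        raise FormatError(f"unsupported image format {path.suffix!r} for {path}")
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if len(im.getbands()) >= 3 else "L")
            px = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    return RawImage(pixels=px, source_tag=source_tag, origin_path=str(path))


def to_grayscale(img: RawImage | np.ndarray) -> np.ndarray:
    """Collapse to a single 8-bit channel.

    3-channel input is combined with BT.601 luminance weights and rounded
    half-up; single-channel input is returned unchanged (same buffer
    semantics as a copy).
    """
    px = img.pixels if isinstance(img, RawImage) else np.asarray(img)
    if px.ndim == 2:
        return px.astype(np.uint8, copy=True)
    if px.ndim == 3 and px.shape[2] == 3:
        w = np.asarray(GRAY_WEIGHTS)
        lum = px.astype(np.float64) @ w
        return np.floor(lum + 0.5).astype(np.uint8)
    raise ChannelError(f"unsupported channel layout {px.shape}")


def stretch_intensity(gray: np.ndarray, saturation_fraction: float = DEFAULT_SATURATION) -> np.ndarray:
    """Linear contrast stretch saturating ``saturation_fraction`` of pixels.

    The low ``saturation_fraction/2`` quantile maps to 0 and the high one
    to 255; a constant image is returned unchanged.
    """
    g = np.asarray(gray, dtype=np.float64)
    lo = np.quantile(g, saturation_fraction / 2.0)
    hi = np.quantile(g, 1.0 - saturation_fraction / 2.0)
    if hi <= lo:  # constant (or near-constant) image: stretch undefined
        return np.asarray(gray, dtype=np.uint8).copy()
    out = (g - lo) * (255.0 / (hi - lo))
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def _resize_pad(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aspect-preserving resize to 640x480 with median-border padding.

    Returns ``(image, pad_mask)``.
    """
    th, tw = STANDARD_SHAPE
    h, w = gray.shape
    scale = min(th / h, tw / w)
    nh = max(1, int(round(h * scale)))
    nw = max(1, int(round(w * scale)))
    if (nh, nw) != (h, w):
        resized = _sk_resize(gray.astype(np.float64), (nh, nw), order=1,
                             anti_aliasing=scale < 1.0, preserve_range=True)
        resized = np.clip(np.floor(resized + 0.5), 0, 255).astype(np.uint8)
    else:
        resized = gray.astype(np.uint8, copy=True)
    border = np.concatenate([resized[0, :], resized[-1, :], resized[:, 0], resized[:, -1]])
    fill = int(np.median(border))
    canvas = np.full(STANDARD_SHAPE, fill, dtype=np.uint8)
    pad_mask = np.ones(STANDARD_SHAPE, dtype=bool)
    r0 = (th - nh) // 2
    c0 = (tw - nw) // 2
    canvas[r0:r0 + nh, c0:c0 + nw] = resized
    pad_mask[r0:r0 + nh, c0:c0 + nw] = False
    return canvas, pad_mask


def standardize(img: RawImage | np.ndarray,
                saturation_fraction: float = DEFAULT_SATURATION) -> StandardImage:
    """Produce the canonical working image: gray, 640x480, stretched."""
    if not isinstance(img, RawImage):
        img = RawImage(pixels=np.asarray(img), source_tag="synthetic")
    gray = to_grayscale(img)
    canvas, pad_mask = _resize_pad(gray)
    stretched = stretch_intensity(canvas, saturation_fraction)
    return StandardImage(pixels=stretched, saturation_fraction=saturation_fraction,
                         provenance=img, pad_mask=pad_mask)


def save_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit single-channel PNG (masks saved as 0/255)."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path))
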
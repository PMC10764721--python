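"""Colour normalisation and single-channel representations of H&E overview images.

H&E-stained tissue is "purple-pink": its pixels carry more red and more blue
than green. The transform implemented here,

    T = ReLU(R - G) * ReLU(B - G)   (elementwise),

maps every achromatic pixel (greys, white background, black scanner marks,
bounding boxes) to exactly 0, along with any pen colour whose green channel
dominates either red or blue (blue, green, black, red and orange pens).
Purple-pink tissue keeps a strictly positive value, so the distribution of T
is bimodal and a single Otsu cut separates tissue from everything else.

The conventional baseline — Otsu on luminance — is provided alongside for
comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "IntensityMap",
    "MapKind",
    "normalize",
    "relu",
    "he_transform",
    "luminance",
]

#: Rec. 601 luma weights — the de-facto greyscale conversion in image libraries.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class MapKind(enum.Enum):
    """What a single-channel intensity map holds."""

    HE_TRANSFORM = "he_transform"
    LUMINANCE = "luminance"


@dataclass(frozen=True)
class RGBImage:
    """A normalised 3-channel raster; every channel value a float in [0, 1].

    ``channels`` has shape (height, width, 3) in R, G, B order, row-major,
    origin top-left, 0-based.
    """

    channels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(
                f"RGBImage requires shape (H, W, 3); got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("RGBImage channels must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(
                "RGBImage channel values must lie in [0, 1]; "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "channels", arr)

    @property
    def height(self) -> int:
        return self.channels.shape[0]

    @property
    def width(self) -> int:
        return self.channels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    @property
    def r(self) -> np.ndarray:
        return self.channels[..., 0]

    @property
    def g(self) -> np.ndarray:
        return self.channels[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.channels[..., 2]


@dataclass(frozen=True)
class IntensityMap:
    """A single-channel raster of non-negative values plus its provenance."""

    values: np.ndarray
    kind: MapKind = field(default=MapKind.HE_TRANSFORM)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"IntensityMap requires a 2-D array; got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("IntensityMap values must be finite")
        if arr.size and arr.min() < 0.0:
            raise ValueError("IntensityMap values must be non-negative")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalize(raw_image: np.ndarray) -> RGBImage:
    """Normalise an integer raster to floats in [0, 1].

    Accepts 8- or 16-bit rasters with 3 (RGB) or 4 (RGBA) planes. Each colour
    plane is divided by the sample type's maximum (255 or 65535). An alpha
    plane is composited over white before being dropped, matching the white
    padding slide scanners use.

    Parameters
    ----------
    raw_image : ndarray of shape (H, W, 3) or (H, W, 4)
        Unsigned-integer samples, 8 or 16 bits deep.

    Returns
    -------
    RGBImage
    """
    arr = np.asarray(raw_image)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(
            "expected a raster with 3 (RGB) or 4 (RGBA) planes; "
            f"got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        maxval = 255.0
    elif arr.dtype == np.uint16:
        maxval = 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        hi = int(arr.max(initial=0))
        if hi <= 255:
            maxval = 255.0
        elif hi <= 65535:
            maxval = 65535.0
        else:
            raise ValueError(
                f"integer raster exceeds 16-bit range (max sample {hi})"
            )
    else:
        raise ValueError(
            f"expected an integer sample type (8 or 16 bit); got dtype {arr.dtype}"
        )
    scaled = arr.astype(np.float64) / maxval
    if arr.shape[2] == 4:
        rgb, alpha = scaled[..., :3], scaled[..., 3:4]
        scaled = rgb * alpha + (1.0 - alpha)  # composite over white
    return RGBImage(np.clip(scaled, 0.0, 1.0))


def relu(x):
    """Rectifier: max(x, 0), applied elementwise when given an array."""
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("relu requires finite input")
    out = np.maximum(arr, 0.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def he_transform(image: RGBImage) -> IntensityMap:
    """Single-channel H&E representation T = ReLU(R-G) * ReLU(B-G).

    Exactly 0 wherever G >= R or G >= B (all greys; blue, green, black, red
    and orange pens), strictly positive on purple-pink pixels, and 1 only at
    pure magenta (1, 0, 1). Computed in double precision.
    """
    t = np.maximum(image.r - image.g, 0.0) * np.maximum(image.b - image.g, 0.0)
    return IntensityMap(t, MapKind.HE_TRANSFORM)


def luminance(image: RGBImage) -> IntensityMap:
    """Rec. 601 luminance 0.299 R + 0.587 G + 0.114 B, the baseline channel."""
    wr, wg, wb = LUMA_WEIGHTS
    y = wr * image.r + wg * image.g + wb * image.b
    return IntensityMap(np.clip(y, 0.0, 1.0), MapKind.LUMINANCE)
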
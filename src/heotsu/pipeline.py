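"""End-to-end segmentation: overview image -> transform -> Otsu -> tissue mask.

Two pipelines share the Otsu solver:

* ``segment_he`` — the purple-pink transform channel; tissue where T lies
  strictly *above* the threshold (the large exact-zero background mass must
  never be labelled tissue);
* ``segment_luminance`` — the conventional baseline; tissue where luminance
  lies strictly *below* the threshold (tissue is darker than background).

No morphological post-processing is applied by default; optional small-object
removal is available behind a flag. Coordinates are row-major, origin
top-left, 0-based, everywhere including mask files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.morphology import remove_small_objects
from skimage.transform import resize

from .otsu import ThresholdResult, build_histogram, otsu_threshold
from .transform import IntensityMap, RGBImage, he_transform, luminance, normalize

__all__ = [
    "BinaryMask",
    "SegmentationReport",
    "segment_he",
    "segment_luminance",
    "extract_overview",
    "mask_to_full_resolution",
    "write_mask_png",
    "read_mask_png",
]

logger = logging.getLogger("heotsu")

#: Default histogram resolution (classical Otsu is defined on 256 grey levels).
DEFAULT_N_BINS = 256
#: Default longer-side cap for overview extraction, in pixels.
DEFAULT_MAX_DIM = 2048
#: Schema tag written into every JSON report/manifest.
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel tissue labels aligned to an image (True = tissue)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.dtype != np.bool_:
            raise ValueError(
                f"BinaryMask requires a 2-D boolean array; got {arr.shape} {arr.dtype}"
            )
        object.__setattr__(self, "labels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def tissue_fraction(self) -> float:
        return float(self.labels.mean()) if self.labels.size else 0.0


@dataclass(frozen=True)
class SegmentationReport:
    """Provenance of one segmentation run, serialisable to JSON."""

    method: str  # "he_otsu" | "luminance_otsu"
    threshold_result: ThresholdResult
    tissue_fraction: float
    n_bins: int
    histogram_range: tuple[float, float]
    source_path: str = ""
    min_object_px: int = 0
    schema_version: int = field(default=SCHEMA_VERSION)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "method": self.method,
            "threshold": self.threshold_result.threshold,
            "between_class_variance": self.threshold_result.between_class_variance,
            "degenerate": self.threshold_result.degenerate,
            "tissue_fraction": self.tissue_fraction,
            "n_bins": self.n_bins,
            "histogram_range": list(self.histogram_range),
            "min_object_px": self.min_object_px,
            "source_path": self.source_path,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _segment(
    imap: IntensityMap,
    method: str,
    above: bool,
    n_bins: int,
    source_path: str,
    min_object_px: int,
) -> tuple[BinaryMask, SegmentationReport]:
    hist = build_histogram(imap, n_bins)
    result = otsu_threshold(hist)
    if result.degenerate:
        logger.warning(
            "%s: degenerate histogram (constant channel); returning empty mask%s",
            method,
            f" for {source_path}" if source_path else "",
        )
        labels = np.zeros(imap.shape, dtype=bool)
    elif above:
        labels = imap.values > result.threshold
    else:
        labels = imap.values < result.threshold
    if min_object_px > 0 and labels.any():
        labels = remove_small_objects(labels, min_size=min_object_px)
    mask = BinaryMask(labels)
    report = SegmentationReport(
        method=method,
        threshold_result=result,
        tissue_fraction=mask.tissue_fraction,
        n_bins=n_bins,
        histogram_range=(float(hist.bin_edges[0]), float(hist.bin_edges[-1])),
        source_path=source_path,
        min_object_px=min_object_px,
    )
    return mask, report


def segment_he(
    image: RGBImage,
    n_bins: int = DEFAULT_N_BINS,
    source_path: str = "",
    min_object_px: int = 0,
) -> tuple[BinaryMask, SegmentationReport]:
    """Segment purple-pink tissue: Otsu on T = ReLU(R-G) * ReLU(B-G).

    Requires no per-image tuning. A slide with no pinkish pixels at all
    (T identically 0) yields a degenerate threshold and an all-false mask.
    """
    return _segment(
        he_transform(image), "he_otsu", True, n_bins, source_path, min_object_px
    )


def segment_luminance(
    image: RGBImage,
    n_bins: int = DEFAULT_N_BINS,
    source_path: str = "",
    min_object_px: int = 0,
) -> tuple[BinaryMask, SegmentationReport]:
    """Baseline: Otsu on Rec. 601 luminance; tissue = darker than threshold."""
    return _segment(
        luminance(image), "luminance_otsu", False, n_bins, source_path, min_object_px
    )


def _read_pyramidal_tiff(path: Path, max_dim: int) -> np.ndarray:
    """Pick the smallest pyramid level whose longer side is >= max_dim."""
    with tifffile.TiffFile(path) as tf:
        levels = tf.series[0].levels
        arrays = None
        chosen = None
        for level in sorted(levels, key=lambda lv: max(lv.shape[:2])):
            if max(level.shape[:2]) >= max_dim:
                chosen = level
                break
        if chosen is None:  # every level smaller than max_dim: take the largest
            chosen = max(levels, key=lambda lv: max(lv.shape[:2]))
        arrays = chosen.asarray()
    return arrays


def extract_overview(slide_path, max_dim: int = DEFAULT_MAX_DIM) -> RGBImage:
    """Read a slide overview whose longer side is at most ``max_dim`` pixels.

    Plain PNG/JPEG/TIFF rasters are read directly; pyramidal TIFFs are read
    from the smallest level still at least ``max_dim`` on its longer side and
    then downscaled. Images already small enough are never upsampled.
    """
    path = Path(slide_path)
    if not path.exists():
        raise OSError(f"cannot read slide file: {path} (no such file)")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            raw = _read_pyramidal_tiff(path, max_dim)
        else:
            from PIL import Image

            with Image.open(path) as im:
                if im.mode not in ("RGB", "RGBA"):
                    im = im.convert("RGB")
                raw = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - report format with the error
        raise OSError(f"cannot read {suffix or 'image'} file {path}: {exc}") from exc
    if raw.ndim == 2:  # greyscale: replicate to RGB
        raw = np.stack([raw] * 3, axis=-1)
    image = normalize(raw)
    longer = max(image.shape)
    if longer > max_dim:
        scale = max_dim / longer
        out_shape = (
            max(1, round(image.height * scale)),
            max(1, round(image.width * scale)),
        )
        resized = resize(
            image.channels, out_shape + (3,), order=1, anti_aliasing=True,
            preserve_range=True,
        )
        image = RGBImage(np.clip(resized, 0.0, 1.0))
    return image


def mask_to_full_resolution(
    mask: BinaryMask, target_height: int, target_width: int
) -> BinaryMask:
    """Nearest-neighbour upscaling of a mask to full-resolution dimensions."""
    h, w = mask.shape
    if target_height < h or target_width < w:
        raise ValueError(
            f"target ({target_height}x{target_width}) smaller than mask ({h}x{w})"
        )
    rows = (np.arange(target_height) * h) // target_height
    cols = (np.arange(target_width) * w) // target_width
    return BinaryMask(mask.labels[np.ix_(rows, cols)])


def write_mask_png(mask: BinaryMask, path) -> None:
    """Write a mask as single-channel 8-bit PNG: 0 = non-tissue, 255 = tissue."""
    iio.imwrite(Path(path), (mask.labels.astype(np.uint8) * 255))


def read_mask_png(path) -> BinaryMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127)
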
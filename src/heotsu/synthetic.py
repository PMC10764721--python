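"""Synthetic H&E slide overviews with per-class ground-truth masks.

Emulates the content of low-magnification overviews of H&E-stained biopsy
slides well enough to exercise every pipeline property without real data:

* near-white background (slide glass + scanner padding), achromatic;
* tissue as smooth irregular blobs in eosin/haematoxylin purple-pink; a
  slide carries one base stain colour (serial sections share a stain batch)
  with small per-pixel jitter;
* pen strokes as random polylines in blue, green, black, red, orange or
  pink — pink is deliberately drawn from the tissue colour model to
  reproduce the documented pink-pen failure mode;
* a thin dark bounding box near the border, as scanners burn in;
* dark achromatic blobs and text-like bars standing in for scanning
  artefacts.

Colour ranges are constructed so that blue/green/black pens have G >= R,
and red/orange pens have B < G, hence transform value exactly 0 — the
classes of artefact the method claims to reject. Every slide is fully
reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import disk, line
from skimage.morphology import disk as disk_footprint

from .pipeline import BinaryMask, SCHEMA_VERSION
from .transform import RGBImage

__all__ = [
    "PEN_COLOUR_CLASSES",
    "SlideSpec",
    "SyntheticSlide",
    "sample_tissue_colour",
    "sample_pen_colour",
    "generate_slide",
    "generate_suite",
    "write_slide",
    "write_suite",
]

PEN_COLOUR_CLASSES = ("blue", "green", "black", "red", "orange", "pink")

#: Truth-mask classes, in drawing/priority order (later classes claim pixels).
MASK_CLASSES = ("background", "tissue", "pen", "box", "scanner")

#: Per-pixel colour jitter: N(0, 0.02) truncated at one standard deviation.
#: Truncation keeps the jitter from flipping the sign of the R-G / B-G gaps
#: the colour model guarantees.
_JITTER_SIGMA = 0.02


@dataclass(frozen=True)
class SlideSpec:
    """Recipe for one synthetic slide."""

    height: int = 256
    width: int = 320
    tissue_blobs: int = 2
    pen_strokes: tuple[tuple[str, int], ...] = ()  # (colour_class, width px)
    bounding_box: bool = False
    scanner_blobs: int = 0
    pen_over_tissue: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError(f"slide must be at least 32x32; got {self.height}x{self.width}")
        if self.tissue_blobs < 0 or self.scanner_blobs < 0:
            raise ValueError("blob counts must be non-negative")
        strokes = tuple((str(c), int(w)) for c, w in self.pen_strokes)
        for colour, width in strokes:
            if colour not in PEN_COLOUR_CLASSES:
                raise ValueError(
                    f"unknown pen colour class {colour!r}; expected one of {PEN_COLOUR_CLASSES}"
                )
            if not 1 <= width <= min(self.height, self.width) // 4:
                raise ValueError(f"pen width {width} does not fit a {self.height}x{self.width} slide")
        object.__setattr__(self, "pen_strokes", strokes)

    @property
    def category(self) -> str:
        if self.pen_strokes:
            return "pen"
        if self.bounding_box or self.scanner_blobs:
            return "scanner"
        return "clean"

    def to_dict(self) -> dict:
        return {
            "height": self.height,
            "width": self.width,
            "tissue_blobs": self.tissue_blobs,
            "pen_strokes": [list(s) for s in self.pen_strokes],
            "bounding_box": self.bounding_box,
            "scanner_blobs": self.scanner_blobs,
            "pen_over_tissue": self.pen_over_tissue,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlideSpec":
        d = dict(d)
        d["pen_strokes"] = tuple((c, w) for c, w in d.get("pen_strokes", []))
        return cls(**d)


@dataclass(frozen=True)
class SyntheticSlide:
    """A generated overview plus one ground-truth mask per component class."""

    image: RGBImage
    truth: dict  # class name -> BinaryMask
    spec: SlideSpec = field(default_factory=SlideSpec)

    @property
    def category(self) -> str:
        return self.spec.category


def _jitter(base: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """Base colour(s) plus truncated per-pixel jitter, clipped to [0, 1]."""
    noise = np.clip(
        rng.normal(0.0, _JITTER_SIGMA, (n, 3)), -_JITTER_SIGMA, _JITTER_SIGMA
    )
    return np.clip(np.atleast_2d(base) + noise, 0.0, 1.0)


def _tissue_base(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Base eosin/haematoxylin stain colours: R > G and B > G by >= 0.10."""
    r = rng.uniform(0.75, 0.95, n)
    g = rng.uniform(0.45, 0.65, n)
    b = rng.uniform(g + 0.10, 0.85)
    return np.stack([r, g, b], axis=1)


def sample_tissue_colour(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Draw purple-pink tissue colours (per-sample base + jitter).

    Every sample satisfies R > G and B > G, so its transform value is
    strictly positive.
    """
    m = 1 if n is None else int(n)
    out = _jitter(_tissue_base(rng, m), rng, m)
    return out[0] if n is None else out


def sample_pen_colour(
    colour_class: str, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Draw pen-ink colours for one colour class.

    Blue, green and black inks satisfy G >= R; red and orange satisfy B < G;
    all five therefore map to transform value exactly 0. Pink ink is drawn
    from the tissue colour model and is deliberately confusable with eosin.
    """
    if colour_class not in PEN_COLOUR_CLASSES:
        raise ValueError(
            f"unknown pen colour class {colour_class!r}; expected one of {PEN_COLOUR_CLASSES}"
        )
    m = 1 if n is None else int(n)
    if colour_class == "pink":
        out = _jitter(_tissue_base(rng, m), rng, m)
    elif colour_class == "blue":
        r = rng.uniform(0.05, 0.20, m)
        g = r + rng.uniform(0.0, 0.10, m)
        b = rng.uniform(0.70, 0.95, m)
        out = np.stack([r, g, b], axis=1)
    elif colour_class == "green":
        g = rng.uniform(0.50, 0.80, m)
        r = rng.uniform(0.05, g - 0.10)
        b = rng.uniform(0.05, g - 0.05)
        out = np.stack([r, g, b], axis=1)
    elif colour_class == "black":
        v = rng.uniform(0.02, 0.15, m)
        g = np.clip(v + rng.uniform(0.0, 0.02, m), 0.0, 1.0)
        out = np.stack([v, g, v], axis=1)
    elif colour_class == "red":
        r = rng.uniform(0.70, 0.95, m)
        g = rng.uniform(0.15, 0.35, m)
        b = rng.uniform(0.02, g - 0.02)
        out = np.stack([r, g, b], axis=1)
    else:  # orange
        r = rng.uniform(0.85, 0.98, m)
        g = rng.uniform(0.45, 0.60, m)
        b = rng.uniform(0.05, g - 0.05)
        out = np.stack([r, g, b], axis=1)
    return out[0] if n is None else out


def _tissue_mask(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of smooth irregular blobs: wobbled discs, boundary perturbed by
    a Gaussian-smoothed random field with kernel width 5% of min dimension."""
    h, w = spec.height, spec.width
    min_dim = min(h, w)
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.tissue_blobs):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        radius = rng.uniform(0.12, 0.22) * min_dim
        field = gaussian_filter(rng.standard_normal((h, w)), sigma=0.05 * min_dim)
        scale = np.abs(field).max()
        if scale > 0:
            field = field / scale
        wobble = radius * (1.0 + 0.35 * field)
        dist = np.hypot(yy - cy, xx - cx)
        blob = dist < wobble
        if not blob.any():
            raise ValueError("tissue blob has zero area; spec does not fit the raster")
        mask |= blob
    return mask


def _pen_mask(spec: SlideSpec, width: int, rng: np.random.Generator) -> np.ndarray:
    """A random polyline of the given stroke width, in pixels."""
    h, w = spec.height, spec.width
    n_vertices = int(rng.integers(3, 6))
    ys = rng.integers(int(0.1 * h), int(0.9 * h), n_vertices)
    xs = rng.integers(int(0.1 * w), int(0.9 * w), n_vertices)
    mask = np.zeros((h, w), dtype=bool)
    for (y0, x0), (y1, x1) in zip(zip(ys, xs), zip(ys[1:], xs[1:])):
        rr, cc = line(int(y0), int(x0), int(y1), int(x1))
        mask[rr, cc] = True
    radius = max(1, width // 2)
    return binary_dilation(mask, structure=disk_footprint(radius))


def _box_mask(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    """A 3-px-thick rectangle near the border."""
    h, w = spec.height, spec.width
    m_top = int(rng.integers(2, max(3, int(0.06 * h))))
    m_left = int(rng.integers(2, max(3, int(0.06 * w))))
    m_bot = h - int(rng.integers(2, max(3, int(0.06 * h))))
    m_right = w - int(rng.integers(2, max(3, int(0.06 * w))))
    mask = np.zeros((h, w), dtype=bool)
    t = 3
    mask[m_top : m_top + t, m_left:m_right] = True
    mask[m_bot - t : m_bot, m_left:m_right] = True
    mask[m_top:m_bot, m_left : m_left + t] = True
    mask[m_top:m_bot, m_right - t : m_right] = True
    return mask


def _scanner_mask(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    """Dark blobs and text-like glyph bars."""
    h, w = spec.height, spec.width
    min_dim = min(h, w)
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.scanner_blobs):
        if rng.random() < 0.5:  # blob
            cy = int(rng.uniform(0.1 * h, 0.9 * h))
            cx = int(rng.uniform(0.1 * w, 0.9 * w))
            radius = int(max(2, rng.uniform(0.02, 0.05) * min_dim))
            rr, cc = disk((cy, cx), radius, shape=(h, w))
            mask[rr, cc] = True
        else:  # text-like run of short bars
            cy = int(rng.uniform(0.1 * h, 0.85 * h))
            cx = int(rng.uniform(0.1 * w, 0.6 * w))
            bar_h = max(2, int(0.02 * min_dim))
            bar_w = max(2, int(0.012 * min_dim))
            for i in range(int(rng.integers(4, 9))):
                x0 = cx + i * 2 * bar_w
                mask[cy : cy + bar_h, x0 : min(x0 + bar_w, w)] = True
    return mask


def generate_slide(spec: SlideSpec) -> SyntheticSlide:
    """Render a slide from its spec; bit-identical for identical specs.

    Drawing priority (later claims the pixel, in the truth masks and in the
    image): tissue, then pen, then bounding box, then scanner artefacts.
    When ``pen_over_tissue`` is false, tissue takes priority over pen
    instead, so strokes only show on the background.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # achromatic near-white background with mild grain
    grey = np.clip(
        rng.uniform(0.92, 0.99) + rng.normal(0.0, 0.01, (h, w)), 0.0, 1.0
    )
    img = np.repeat(grey[..., None], 3, axis=2)

    tissue = _tissue_mask(spec, rng)
    pen = np.zeros((h, w), dtype=bool)
    pen_pixels: list[tuple[np.ndarray, str]] = []
    for colour_class, width in spec.pen_strokes:
        stroke = _pen_mask(spec, width, rng)
        pen_pixels.append((stroke, colour_class))
        pen |= stroke
    box = _box_mask(spec, rng) if spec.bounding_box else np.zeros((h, w), dtype=bool)
    scanner = _scanner_mask(spec, rng)

    # resolve claims: scanner > box > (pen vs tissue per flag)
    if spec.pen_over_tissue:
        tissue_final = tissue & ~pen
        pen_final = pen.copy()
    else:
        tissue_final = tissue.copy()
        pen_final = pen & ~tissue
    tissue_final &= ~box & ~scanner
    pen_final &= ~box & ~scanner
    box_final = box & ~scanner
    scanner_final = scanner
    background = ~(tissue_final | pen_final | box_final | scanner_final)

    # paint tissue: one base stain colour per slide, per-pixel jitter
    base = _tissue_base(rng)[0]
    n_tissue = int(tissue_final.sum())
    if n_tissue:
        img[tissue_final] = _jitter(base, rng, n_tissue)
    # paint pens stroke by stroke (each stroke keeps its colour class)
    for stroke, colour_class in pen_pixels:
        visible = stroke & pen_final
        n = int(visible.sum())
        if n:
            img[visible] = sample_pen_colour(colour_class, rng, n)
    if box_final.any():
        img[box_final] = rng.uniform(0.05, 0.25)  # dark achromatic
    if scanner_final.any():
        img[scanner_final] = rng.uniform(0.02, 0.30)  # dark achromatic

    truth = {
        "tissue": BinaryMask(tissue_final),
        "background": BinaryMask(background),
        "pen": BinaryMask(pen_final),
        "box": BinaryMask(box_final),
        "scanner": BinaryMask(scanner_final),
    }
    return SyntheticSlide(image=RGBImage(img), truth=truth, spec=spec)


def generate_suite(
    n_clean: int,
    n_pen: int,
    n_scanner: int,
    seed: int,
    include_pink: bool = False,
    height: int = 256,
    width: int = 320,
) -> list[SyntheticSlide]:
    """Deterministic suite of slides: clean, pen-marked, scanner-artefact.

    Per-slide seeds derive from the master seed. Pen colours cycle through
    blue, green, black and red (plus pink only when requested); scanner
    slides carry a bounding box and dark blobs.
    """
    if min(n_clean, n_pen, n_scanner) < 0:
        raise ValueError("slide counts must be non-negative")
    total = n_clean + n_pen + n_scanner
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=max(total, 1))
    colours = ["blue", "green", "black", "red"] + (["pink"] if include_pink else [])
    specs: list[SlideSpec] = []
    for i in range(n_clean):
        specs.append(SlideSpec(height=height, width=width, seed=int(seeds[len(specs)])))
    for i in range(n_pen):
        colour = colours[i % len(colours)]
        specs.append(
            SlideSpec(
                height=height,
                width=width,
                pen_strokes=((colour, 5), (colour, 3)),
                seed=int(seeds[len(specs)]),
            )
        )
    for i in range(n_scanner):
        specs.append(
            SlideSpec(
                height=height,
                width=width,
                bounding_box=True,
                scanner_blobs=2,
                seed=int(seeds[len(specs)]),
            )
        )
    return [generate_slide(s) for s in specs]


def write_slide(slide: SyntheticSlide, out_dir, stem: str) -> dict:
    """Write image + truth masks as PNG with a JSON sidecar; returns the sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img8 = np.round(slide.image.channels * 255).astype(np.uint8)
    image_name = f"{stem}.png"
    iio.imwrite(out_dir / image_name, img8)
    mask_names = {}
    for cls in MASK_CLASSES:
        name = f"{stem}_mask_{cls}.png"
        iio.imwrite(out_dir / name, slide.truth[cls].labels.astype(np.uint8) * 255)
        mask_names[cls] = name
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "image": image_name,
        "masks": mask_names,
        "category": slide.category,
        "spec": slide.spec.to_dict(),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar


def write_suite(slides: list[SyntheticSlide], out_dir) -> Path:
    """Write a fixture suite plus a manifest JSON listing every file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, slide in enumerate(slides):
        stem = f"slide_{i:03d}"
        sidecar = write_slide(slide, out_dir, stem)
        entries.append({"stem": stem, "sidecar": f"{stem}.json", **sidecar})
    manifest = {"schema_version": SCHEMA_VERSION, "n_slides": len(slides), "slides": entries}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
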
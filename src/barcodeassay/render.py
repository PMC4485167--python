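"""Synthetic rendering of barcode-formatted assay strips.

Renders Code 39 barcodes as 8-bit grayscale rasters, and assay variants
in which the wide bars of the "positive" character of a pair are
physically divided into test line (3 mm), white barrier (~0.5 mm) and
control line (2 mm) — the geometry of the microfluidic strip plate.
Strip darkness is parameterised directly as a target optical density
ratio (ODR) on the white background, so scenarios compose with the
densitometry definitions: gray = background × (1 − ODR).

Optical degradation (Gaussian blur for optics, a linear lighting
gradient for uneven illumination, seeded Gaussian pixel noise for the
sensor) is applied in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .code39 import BarcodeSpec, ElementPattern, encode_char, encode_string

__all__ = [
    "AssayLayout",
    "RenderScenario",
    "StripRegion",
    "render_barcode",
    "render_assay",
    "assay_regions",
    "background_region",
    "apply_lighting",
    "write_png",
    "read_image",
]

MM_PER_INCH = 25.4


@dataclass(frozen=True)
class AssayLayout:
    """Physical geometry of the strip plate and the printed barcode.

    The narrow module equals the control-line width (2 mm); wide printed
    elements are ``wide_ratio`` narrow modules.  A divided wide bar is
    test + barrier + control = 3 + 0.5 + 2 = 5.5 mm, which still
    classifies as wide against a 2 mm narrow module.

    Parameters
    ----------
    character_pair:
        ``(positive_char, negative_char)``; the positive character is
        the glyph whose wide bars are divided into binding strips.
    test_line_width, control_line_width, barrier_width:
        Strip geometry in mm (defaults 3 / 2 / 0.5).
    strip_height:
        Height of the rendered plate in mm.
    dpi:
        Raster resolution; the narrow module must span at least 2 px.
        The 600 dpi default is the coarsest round resolution at which a
        2 x 15 mm control strip holds the default three sampling groups
        of 4715 pixels each.
    """

    character_pair: tuple[str, str] = ("-", "+")
    test_line_width: float = 3.0
    control_line_width: float = 2.0
    barrier_width: float = 0.5
    strip_height: float = 15.0
    dpi: float = 600.0
    background_gray: int = 255
    printed_gray: int = 0
    wide_ratio: float = 3.0
    quiet_zone_modules: float = 10.0

    def __post_init__(self) -> None:
        for name in ("test_line_width", "control_line_width", "barrier_width",
                     "strip_height", "dpi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.printed_gray <= 255 or not 0 <= self.background_gray <= 255:
            raise ValueError("gray levels must lie in [0, 255]")
        pos, neg = self.character_pair
        wide_bars = [r for r, w in encode_char(pos).elements
                     if r == "bar" and w == "wide"]
        if len(wide_bars) != 2:
            raise ValueError(
                f"positive character {pos!r} has {len(wide_bars)} wide bars; "
                "the divided-bar assay needs exactly 2 (4 strips)"
            )
        encode_char(neg)

    @property
    def narrow_mm(self) -> float:
        return self.control_line_width

    @property
    def wide_mm(self) -> float:
        return self.wide_ratio * self.narrow_mm

    @property
    def divided_bar_mm(self) -> float:
        return self.test_line_width + self.barrier_width + self.control_line_width

    def px(self, mm: float) -> int:
        """mm → px, rounded half-up."""
        return int(np.floor(mm * self.dpi / MM_PER_INCH + 0.5))


@dataclass(frozen=True)
class RenderScenario:
    """Strip darkness and optical degradation for one render.

    ``strip_odrs`` maps 1-based strip index → target ODR in [0, 1];
    omitted strips render blank.  ``blur_sigma`` is in mm; its default
    is calibrated jointly with the decoder's darkness threshold so that
    the divided wide bar only fuses into a single wide bar once the
    strips are dark enough, reproducing the harder "−" read.
    """

    strip_odrs: Mapping[int, float] = field(default_factory=dict)
    blur_sigma: float = 0.35
    lighting: tuple[Literal["none", "linear_gradient"], float] = ("none", 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for idx, odr in self.strip_odrs.items():
            if not 0.0 <= odr <= 1.0:
                raise ValueError(f"strip {idx}: target ODR {odr} outside [0, 1]")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")
        model, amp = self.lighting
        if model not in ("none", "linear_gradient"):
            raise ValueError(f"unknown lighting model {model!r}")
        if not 0.0 <= amp <= 0.5:
            raise ValueError("lighting amplitude must lie in [0, 0.5]")


@dataclass(frozen=True)
class StripRegion:
    """Pixel rectangle of one binding strip (half-open, top-left origin)."""

    strip_index: int
    role: Literal["test", "control"]
    x: int
    y: int
    width: int
    height: int

    @property
    def rect(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.width, self.height)


# --- geometry -----------------------------------------------------------

def _segments(
    spec: BarcodeSpec, layout: AssayLayout, divide: bool
) -> list[tuple[str, float, int | None]]:
    """Flatten the barcode into (kind, width_mm, strip_index) segments.

    kind ∈ {"bar", "space", "strip", "barrier"}; strip_index is set for
    "strip" segments only.  When ``divide`` is true, every wide bar of
    an occurrence of the positive character becomes test strip, barrier,
    control strip (strips numbered 1.. across the barcode).
    """
    pos_char = layout.character_pair[0]
    segs: list[tuple[str, float, int | None]] = []
    segs.append(("space", layout.quiet_zone_modules * layout.narrow_mm, None))
    next_strip = 1
    for k, c in enumerate(spec.full_sequence):
        if k > 0:
            segs.append(("space", layout.narrow_mm, None))  # inter-char gap
        pattern: ElementPattern = encode_char(c)
        is_assay_char = divide and c == pos_char
        for role, width_class in pattern.elements:
            wide = width_class == "wide"
            if role == "bar" and wide and is_assay_char:
                segs.append(("strip", layout.test_line_width, next_strip))
                segs.append(("barrier", layout.barrier_width, None))
                segs.append(("strip", layout.control_line_width, next_strip + 1))
                next_strip += 2
            else:
                w = layout.wide_mm if wide else layout.narrow_mm
                segs.append((role, w, None))
    segs.append(("space", layout.quiet_zone_modules * layout.narrow_mm, None))
    return segs


def _edges_px(segs: Sequence[tuple[str, float, int | None]],
              layout: AssayLayout) -> list[tuple[str, int, int, int | None]]:
    """Cumulative mm → px edges (round half-up per edge, no drift)."""
    out = []
    mm = 0.0
    left = 0
    for kind, width, idx in segs:
        mm += width
        right = layout.px(mm)
        out.append((kind, left, right, idx))
        left = right
    return out


def _check_resolution(layout: AssayLayout) -> None:
    narrow_px = layout.narrow_mm * layout.dpi / MM_PER_INCH
    if narrow_px < 2.0:
        raise ValueError(
            f"dpi {layout.dpi} gives a narrow module of {narrow_px:.2f} px; "
            "at least 2 px are required — raise dpi or widen the module"
        )


# --- rendering ----------------------------------------------------------

def _compose_columns(
    spec: BarcodeSpec,
    layout: AssayLayout,
    strip_odrs: Mapping[int, float] | None,
    divide: bool,
) -> np.ndarray:
    _check_resolution(layout)
    odrs = dict(strip_odrs or {})
    segs = _edges_px(_segments(spec, layout, divide), layout)
    width = segs[-1][2]
    cols = np.full(width, float(layout.background_gray))
    for kind, left, right, idx in segs:
        if kind == "bar":
            cols[left:right] = layout.printed_gray
        elif kind == "strip":
            odr = odrs.get(idx, 0.0)
            cols[left:right] = layout.background_gray * (1.0 - odr)
    return cols


def render_barcode(spec: BarcodeSpec | str, layout: AssayLayout | None = None
                   ) -> np.ndarray:
    """Render a plain printed barcode (no assay strips, no degradation).

    Bars are drawn at ``printed_gray``, spaces and quiet zones at
    ``background_gray``.  Returns an 8-bit grayscale array of shape
    (height_px, width_px).
    """
    layout = layout or AssayLayout()
    if isinstance(spec, str):
        spec = encode_string(spec)
    cols = _compose_columns(spec, layout, None, divide=False)
    img = np.tile(cols, (layout.px(layout.strip_height), 1))
    return img.round().clip(0, 255).astype(np.uint8)


def render_assay(
    spec: BarcodeSpec | str,
    layout: AssayLayout | None = None,
    scenario: RenderScenario | None = None,
) -> np.ndarray:
    """Render a barcode-formatted assay under a degradation scenario.

    Every occurrence of the layout's positive character has its two wide
    bars divided into (test, barrier, control) strips whose darkness is
    taken from ``scenario.strip_odrs``; the printed remainder of the
    barcode is drawn black.  Blur, lighting gradient and seeded pixel
    noise are applied in that order; the result is clipped to [0, 255].
    """
    layout = layout or AssayLayout()
    scenario = scenario or RenderScenario()
    if isinstance(spec, str):
        spec = encode_string(spec)
    cols = _compose_columns(spec, layout, scenario.strip_odrs, divide=True)
    img = np.tile(cols, (layout.px(layout.strip_height), 1)).astype(float)
    if scenario.blur_sigma > 0:
        sigma_px = scenario.blur_sigma * layout.dpi / MM_PER_INCH
        img = ndimage.gaussian_filter(img, sigma=sigma_px, mode="nearest")
    model, amp = scenario.lighting
    if model != "none" and amp > 0:
        img = apply_lighting(img, model, amp)
    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(scenario.seed)
        img = img + rng.normal(0.0, scenario.noise_sigma, size=img.shape)
    return img.round().clip(0, 255).astype(np.uint8)


def assay_regions(
    spec: BarcodeSpec | str, layout: AssayLayout | None = None,
    inset_mm: float = 0.0,
) -> list[StripRegion]:
    """Pixel rectangles of the binding strips in a rendered assay.

    Strips are numbered 1.. in left-to-right order; within each divided
    wide bar the first (3 mm) strip is the test line and the second
    (2 mm) the control line.  ``inset_mm`` shrinks each rectangle from
    both vertical edges — measuring the strip interior avoids the bias
    optical blur introduces at the edges.
    """
    layout = layout or AssayLayout()
    if isinstance(spec, str):
        spec = encode_string(spec)
    height = layout.px(layout.strip_height)
    inset = layout.px(inset_mm)
    regions = []
    for kind, left, right, idx in _edges_px(_segments(spec, layout, True), layout):
        if kind == "strip":
            role = "test" if idx % 2 == 1 else "control"
            l, r = left + inset, right - inset
            if r - l < 2:
                raise ValueError(
                    f"inset {inset_mm} mm leaves strip {idx} only {r - l} px wide"
                )
            regions.append(StripRegion(idx, role, l, 0, r - l, height))
    return regions


def background_region(
    spec: BarcodeSpec | str, layout: AssayLayout | None = None,
    margin_modules: float = 1.0,
) -> tuple[int, int, int, int]:
    """A background rectangle inside the leading quiet zone.

    Spans the same rows as the strips, inset by ``margin_modules``
    narrow modules from both the image edge and the first bar so blur
    spill-over from the barcode does not contaminate it.
    """
    layout = layout or AssayLayout()
    if isinstance(spec, str):
        spec = encode_string(spec)
    x0 = layout.px(margin_modules * layout.narrow_mm)
    x1 = layout.px((layout.quiet_zone_modules - margin_modules) * layout.narrow_mm)
    if x1 - x0 < 2:
        raise ValueError("quiet zone too small for a background region")
    return (x0, 0, x1 - x0, layout.px(layout.strip_height))


def apply_lighting(image: np.ndarray, model: str = "linear_gradient",
                   amplitude: float = 0.0) -> np.ndarray:
    """Apply an uneven-illumination model (multiplicative, clipped).

    ``linear_gradient`` scales columns by a left-to-right ramp spanning
    ``[1 − amplitude, 1 + amplitude]`` — side lighting instead of
    top lighting.  ``amplitude`` must lie in [0, 0.5].
    """
    if not 0.0 <= amplitude <= 0.5:
        raise ValueError("lighting amplitude must lie in [0, 0.5]")
    if model == "none" or amplitude == 0.0:
        return image.copy()
    if model != "linear_gradient":
        raise ValueError(f"unknown lighting model {model!r}")
    w = image.shape[-1]
    ramp = np.linspace(1.0 - amplitude, 1.0 + amplitude, w)
    out = np.clip(image.astype(float) * ramp, 0, 255)
    if np.issubdtype(image.dtype, np.integer):
        return out.round().astype(image.dtype)
    return out


# --- I/O ----------------------------------------------------------------

def write_png(image: np.ndarray, path: str, rgb: bool = False) -> None:
    """Write an image as PNG (8-bit grayscale, or 24-bit RGB if asked)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = arr.round().clip(0, 255).astype(np.uint8)
    if rgb and arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    Image.fromarray(arr).save(path)


def read_image(path: str) -> np.ndarray:
    """Read a PNG/TIFF image as uint8 (grayscale 2-D or RGB 3-D)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB" if im.mode in ("RGBA", "P", "CMYK") else "L")
        return np.asarray(im)
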
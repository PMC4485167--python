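"""Scanline decoding of Code 39 barcodes from raster images.

The pipeline mirrors what a phone barcode app does with one scan line:

1. average a central horizontal band of rows into a 1-D profile,
2. binarize columns against a local background estimate using an ODR
   threshold (a column is "dark" when its fractional darkening versus
   the background exceeds ``bar_threshold_odr``), collect run lengths,
3. cluster run lengths into narrow/wide, split on inter-character gaps,
   map 9-element groups through the Code 39 table, and use the
   start/stop character to detect reading direction.

Because binarization is in ODR terms, the decode outcome is invariant
under uniform intensity scaling of the image.  The darkness threshold
and the renderer's default optical blur jointly set the readability
floors: a narrow control bar becomes readable at a lower strip ODR
than a divided wide bar, whose 0.5 mm white barrier must blur-fill
before the bar reads as wide — which is why the "−" (positive-assay)
glyph needs darker strips than "+".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .code39 import START_STOP, decode_pattern, encode_string
from .densitometry import image_luminosity
from .render import AssayLayout, RenderScenario, render_assay

__all__ = [
    "DecodeConfig",
    "ScanProfile",
    "Run",
    "DecodeResult",
    "extract_scanline",
    "binarize_runs",
    "classify_and_decode",
    "decode_image",
    "min_readable_odr",
    "readability_sweep",
]


@dataclass(frozen=True)
class DecodeConfig:
    """Decoder tuning.

    bar_threshold_odr:
        Minimum ODR versus the local background for a column to count
        as dark.  Calibrated jointly with the renderer's default blur
        (0.35 mm) so that on the 0.04 ODR grid the floors are 0.24 for
        "+" and 0.44 for "−".
    ratio_cut:
        Wide/narrow boundary as a multiple of the narrow-width
        estimate; used only when run-length clustering is degenerate.
    band_fraction:
        Fraction of image height averaged into the scan profile.
    background_percentile:
        Upper percentile of the profile used as the local background
        (robust to glare).
    """

    bar_threshold_odr: float = 0.20
    ratio_cut: float = 2.0
    band_fraction: float = 0.2
    require_quiet_zones: bool = False
    background_percentile: float = 95.0
    min_cluster_separation: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.bar_threshold_odr < 1:
            raise ValueError("bar_threshold_odr must lie in (0, 1)")
        if not 1 < self.ratio_cut < 3:
            raise ValueError("ratio_cut must lie in (1, 3)")
        if not 0 < self.band_fraction <= 1:
            raise ValueError("band_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class ScanProfile:
    """Column-wise mean luminosity over a horizontal band of rows."""

    values: np.ndarray
    band_rows: tuple[int, int]


@dataclass(frozen=True)
class Run:
    dark: bool
    length: int


Status = Literal["ok", "no_start_stop", "unknown_pattern", "quiet_zone_violation"]


@dataclass(frozen=True)
class DecodeResult:
    payload: str
    orientation: Literal["forward", "reversed"]
    per_char_margin: tuple[float, ...]
    status: Status
    detail: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def as_dict(self) -> dict:
        return {
            "payload": self.payload,
            "orientation": self.orientation,
            "per_char_margin": list(self.per_char_margin),
            "status": self.status,
            "detail": self.detail,
        }


def _fail(status: Status, detail: str = "") -> DecodeResult:
    return DecodeResult("", "forward", (), status, detail)


def extract_scanline(image: np.ndarray,
                     config: DecodeConfig | None = None) -> ScanProfile:
    """Average the configured central band of rows into a 1-D profile."""
    config = config or DecodeConfig()
    lum = image_luminosity(image)
    h, w = lum.shape
    if h < 5 or w < 1:
        raise ValueError(f"image of shape {lum.shape} is too small to scan")
    band = max(1, int(round(h * config.band_fraction)))
    r0 = (h - band) // 2
    return ScanProfile(lum[r0:r0 + band].mean(axis=0), (r0, r0 + band))


def binarize_runs(profile: ScanProfile,
                  config: DecodeConfig | None = None
                  ) -> tuple[list[Run], int, int]:
    """Threshold the profile at an ODR level and collect runs.

    The local background is the profile's upper percentile; a column is
    dark iff its ODR versus that background strictly exceeds
    ``bar_threshold_odr``.  Returns the run sequence with leading and
    trailing light runs trimmed, plus the trimmed light margins (for
    quiet-zone checks).
    """
    config = config or DecodeConfig()
    values = np.asarray(profile.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty scan profile")
    bg = float(np.percentile(values, config.background_percentile))
    if bg <= 0:
        return [], 0, 0
    dark = (bg - values) / bg > config.bar_threshold_odr
    if not dark.any():
        return [], values.size, 0
    edges = np.flatnonzero(np.diff(dark.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [dark.size]))
    runs = [Run(bool(dark[bounds[i]]), int(bounds[i + 1] - bounds[i]))
            for i in range(len(bounds) - 1)]
    leading = runs[0].length if not runs[0].dark else 0
    trailing = runs[-1].length if not runs[-1].dark else 0
    if not runs[0].dark:
        runs = runs[1:]
    if runs and not runs[-1].dark:
        runs = runs[:-1]
    return runs, leading, trailing


def _two_means(lengths: np.ndarray) -> tuple[float, float]:
    """1-D 2-means on run lengths; returns (narrow, wide) centroids."""
    lo, hi = float(lengths.min()), float(lengths.max())
    c = np.array([lo, hi])
    for _ in range(50):
        wide = np.abs(lengths - c[1]) < np.abs(lengths - c[0])
        if wide.all() or (~wide).all():
            break
        new = np.array([lengths[~wide].mean(), lengths[wide].mean()])
        if np.allclose(new, c):
            c = new
            break
        c = new
    return float(c[0]), float(c[1])


def _classify_widths(lengths: np.ndarray, config: DecodeConfig
                     ) -> tuple[np.ndarray, float, float]:
    """Wide/narrow labels, decision boundary, narrow estimate."""
    narrow_c, wide_c = _two_means(lengths)
    if narrow_c <= 0 or wide_c / max(narrow_c, 1e-9) < config.min_cluster_separation:
        # degenerate clustering (e.g. all runs one width): ratio_cut fallback
        narrow_est = float(np.median(lengths))
        boundary = config.ratio_cut * narrow_est
    else:
        small = lengths[np.abs(lengths - narrow_c) <= np.abs(lengths - wide_c)]
        narrow_est = float(np.median(small))
        boundary = 0.5 * (narrow_c + wide_c)
    return lengths > boundary, boundary, narrow_est


def classify_and_decode(runs: Sequence[Run],
                        config: DecodeConfig | None = None,
                        quiet: tuple[int, int] | None = None) -> DecodeResult:
    """Turn an alternating run sequence into a decoded payload.

    Expects runs to start and end dark.  A barcode of n characters has
    9 runs per character plus one light gap between characters, i.e.
    10n − 1 runs.  If the first character is not the start/stop symbol
    the sequence is retried reversed and the orientation reported.
    """
    config = config or DecodeConfig()
    runs = list(runs)
    if not runs:
        return _fail("no_start_stop", "no dark runs found")
    for i, r in enumerate(runs):
        if r.dark != (i % 2 == 0):
            return _fail("unknown_pattern", f"runs do not alternate at index {i}")
    if (len(runs) + 1) % 10 != 0:
        return _fail(
            "unknown_pattern",
            f"{len(runs)} runs do not form whole characters (10n-1 expected)",
        )
    if config.require_quiet_zones and quiet is not None:
        lengths = np.array([r.length for r in runs], dtype=float)
        _, _, narrow_est = _classify_widths(lengths, config)
        need = 10.0 * narrow_est
        if quiet[0] < need or quiet[1] < need:
            return _fail(
                "quiet_zone_violation",
                f"quiet zones {quiet} px; at least {need:.0f} px required",
            )

    def attempt(seq: list[Run]) -> tuple[str, tuple[float, ...]] | None:
        lengths = np.array([r.length for r in seq], dtype=float)
        is_wide, boundary, narrow_est = _classify_widths(lengths, config)
        chars: list[str] = []
        margins: list[float] = []
        for k in range(0, len(seq), 10):
            group = seq[k:k + 9]
            widths = "".join("W" if w else "N" for w in is_wide[k:k + 9])
            c = decode_pattern(widths)
            if c is None:
                return None
            chars.append(c)
            gm = np.abs(lengths[k:k + 9] - boundary) / max(narrow_est, 1e-9)
            margins.append(float(gm.min()))
        return "".join(chars), tuple(margins)

    decoded = attempt(runs)
    orientation: Literal["forward", "reversed"] = "forward"
    if decoded is None or not decoded[0].startswith(START_STOP):
        rev = attempt(runs[::-1])
        if rev is not None and rev[0].startswith(START_STOP):
            decoded, orientation = rev, "reversed"
    if decoded is None:
        return _fail("unknown_pattern", "a 9-element group is not in the table")
    text, margins = decoded
    if not (text.startswith(START_STOP) and text.endswith(START_STOP)):
        return _fail("no_start_stop", f"raw read {text!r} lacks start/stop framing")
    payload = text[1:-1]
    if not payload:
        return _fail("no_start_stop", "empty payload between start/stop characters")
    if START_STOP in payload:
        return _fail("unknown_pattern", f"stray start/stop inside payload {text!r}")
    return DecodeResult(payload, orientation, margins, "ok")


def decode_image(image: np.ndarray,
                 config: DecodeConfig | None = None) -> DecodeResult:
    """extract_scanline → binarize_runs → classify_and_decode."""
    config = config or DecodeConfig()
    profile = extract_scanline(image, config)
    runs, lead, trail = binarize_runs(profile, config)
    return classify_and_decode(runs, config, quiet=(lead, trail))


# --- readability --------------------------------------------------------

def _floor_scenario(expected: str, layout: AssayLayout, grid_odr: float,
                    template: RenderScenario) -> RenderScenario:
    """Strip ODRs for a readability probe of one character of the pair.

    The positive glyph needs all four strips dark; the negative glyph
    arises when only the control strips (2 and 4) carry signal.
    """
    pos, neg = layout.character_pair
    if expected == pos:
        odrs = {1: grid_odr, 2: grid_odr, 3: grid_odr, 4: grid_odr}
    elif expected == neg:
        odrs = {1: 0.0, 2: grid_odr, 3: 0.0, 4: grid_odr}
    else:
        raise ValueError(
            f"character {expected!r} is not in the layout pair {layout.character_pair}"
        )
    return RenderScenario(
        strip_odrs=odrs, blur_sigma=template.blur_sigma,
        lighting=template.lighting, noise_sigma=template.noise_sigma,
        seed=template.seed,
    )


def min_readable_odr(
    character: str,
    layout: AssayLayout | None = None,
    config: DecodeConfig | None = None,
    scenario_template: RenderScenario | None = None,
    odr_grid: Sequence[float] | None = None,
) -> float | None:
    """Smallest grid ODR at which the assay decodes as ``character``.

    Renders the assay barcode at every grid ODR and decodes it; the
    floor is the smallest grid value that decodes correctly *and* whose
    every larger grid value also decodes (monotone readability).
    Returns ``None`` when no grid suffix is fully readable.
    """
    layout = layout or AssayLayout()
    config = config or DecodeConfig()
    template = scenario_template or RenderScenario()
    grid = np.asarray(
        odr_grid if odr_grid is not None else np.arange(0.04, 1.0 + 1e-9, 0.04)
    )
    if (np.diff(grid) <= 0).any() or grid.min() < 0 or grid.max() > 1:
        raise ValueError("odr_grid must be ascending within [0, 1]")
    spec = encode_string(layout.character_pair[0])
    readable = []
    for g in grid:
        img = render_assay(spec, layout, _floor_scenario(character, layout, float(g), template))
        readable.append(decode_image(img, config).payload == character)
    floor = None
    for g, ok in zip(grid[::-1], readable[::-1]):
        if not ok:
            break
        floor = float(g)
    return floor


def readability_sweep(
    layout: AssayLayout | None = None,
    config: DecodeConfig | None = None,
    scenario_template: RenderScenario | None = None,
    odr_grid: Sequence[float] | None = None,
) -> "list[dict]":
    """Per-character readability over the ODR grid (rows of dicts).

    One row per (character, grid ODR) with the decode outcome — the
    synthetic analogue of printing the barcode at preset grayscale
    values and checking which darkness levels the scanner app reads.
    """
    layout = layout or AssayLayout()
    config = config or DecodeConfig()
    template = scenario_template or RenderScenario()
    grid = np.asarray(
        odr_grid if odr_grid is not None else np.arange(0.04, 1.0 + 1e-9, 0.04)
    )
    spec = encode_string(layout.character_pair[0])
    rows = []
    for character in layout.character_pair:
        for g in grid:
            scen = _floor_scenario(character, layout, float(g), template)
            res = decode_image(render_assay(spec, layout, scen), config)
            rows.append({
                "character": character,
                "target_odr": round(float(g), 6),
                "decoded": res.payload,
                "readable": res.payload == character,
                "status": res.status,
            })
    return rows
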
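"""Luminosity, region sampling, and the optical density ratio (ODR).

The scanometric readout quantifies strip darkening relative to the
white background:

    ODR = (I_b − I_s) / I_b

where ``I_b`` is the background luminosity and ``I_s`` the binding-site
luminosity.  ODR is 0 for a blank strip, 1 for a fully black strip on a
white background, and is invariant under uniform intensity scaling —
the property that makes it robust to overall exposure.

RGB pixels are reduced to luminosity with the standard weighted
average I = 0.299 R + 0.587 G + 0.114 B (configurable weights).
Each region is sampled as three disjoint groups of 4715 pixels, from
which the pooled mean and across-group dispersion are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LuminosityModel",
    "SamplingPlan",
    "RegionSample",
    "StripMeasurement",
    "luminosity",
    "image_luminosity",
    "odr",
    "sample_region",
    "sample_regions",
    "measure_assay",
    "flat_field_correct",
]

Rect = tuple[int, int, int, int]  # (x, y, width, height), half-open


@dataclass(frozen=True)
class LuminosityModel:
    """RGB → luminosity weights; must sum to 1."""

    weights: tuple[float, float, float] = (0.299, 0.587, 0.114)

    def __post_init__(self) -> None:
        w = self.weights
        if len(w) != 3 or any(not 0 <= x <= 1 for x in w):
            raise ValueError("weights must be three values in [0, 1]")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {sum(w)})")


@dataclass(frozen=True)
class SamplingPlan:
    """How pixels are drawn from a region.

    Each region is split into ``groups_per_region`` equal-height,
    vertically stacked sub-rectangles; each contributes a centered
    block of exactly ``pixels_per_group`` pixels.  Groups are disjoint
    by construction.
    """

    groups_per_region: int = 3
    pixels_per_group: int = 4715

    def __post_init__(self) -> None:
        if self.groups_per_region < 1 or self.pixels_per_group < 1:
            raise ValueError("groups_per_region and pixels_per_group must be >= 1")


@dataclass(frozen=True)
class RegionSample:
    """Sampled luminosities for one region."""

    group_means: tuple[float, ...]
    mean: float          # pooled over the union of group pixels
    sd: float            # across-group standard deviation (ddof=1)
    n_pixels: int


@dataclass(frozen=True)
class StripMeasurement:
    """ODR measurement of one binding strip against the background."""

    strip_index: int
    group_means: tuple[float, ...]
    I_s: float
    I_s_sd: float
    I_b: float
    odr: float
    lighter_than_background: bool = False

    def as_dict(self) -> dict:
        return {
            "strip_index": self.strip_index,
            "I_s": self.I_s,
            "I_s_sd": self.I_s_sd,
            "I_b": self.I_b,
            "odr": self.odr,
            "lighter_than_background": self.lighter_than_background,
        }


def luminosity(pixel: Sequence[float] | np.ndarray,
               model: LuminosityModel | None = None) -> float | np.ndarray:
    """Weighted-average luminosity of RGB values (0–255 in, 0–255 out).

    Accepts a single (R, G, B) triple or an array whose last axis is
    the channel axis.  Grayscale input (R = G = B = v) returns v.
    """
    model = model or LuminosityModel()
    arr = np.asarray(pixel, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB values along the last axis")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    out = arr @ np.asarray(model.weights)
    return float(out) if out.ndim == 0 else out


def image_luminosity(image: np.ndarray,
                     model: LuminosityModel | None = None) -> np.ndarray:
    """Reduce an image to a float luminosity array (2-D in → unchanged)."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return np.asarray(luminosity(arr, model), dtype=float)
    raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")


def odr(I_b: float, I_s: float) -> float:
    """Optical density ratio (I_b − I_s) / I_b.

    0 when the strip matches the background, 1 when fully black.  A
    strip lighter than the background (glare) yields a negative value
    and a warning rather than a clamp, so QC can catch it.
    """
    if I_b <= 0:
        raise ValueError("background luminosity I_b must be positive")
    if I_s < 0:
        raise ValueError("strip luminosity I_s must be non-negative")
    value = (I_b - I_s) / I_b
    if value < 0:
        warnings.warn(
            f"strip brighter than background (I_s={I_s:.2f} > I_b={I_b:.2f}); "
            "negative ODR returned", stacklevel=2,
        )
    return value


def _group_rects(region: Rect, plan: SamplingPlan) -> list[Rect]:
    x, y, w, h = region
    k = plan.groups_per_region
    bounds = [y + (h * i) // k for i in range(k + 1)]
    return [(x, bounds[i], w, bounds[i + 1] - bounds[i]) for i in range(k)]


def sample_region(image: np.ndarray, region: Rect,
                  plan: SamplingPlan | None = None,
                  model: LuminosityModel | None = None) -> RegionSample:
    """Sample one region as disjoint pixel groups.

    The region is split into ``groups_per_region`` stacked sub-
    rectangles; from each, a centered contiguous block (row-major) of
    exactly ``pixels_per_group`` pixels is taken.
    """
    plan = plan or SamplingPlan()
    lum = image_luminosity(image, model)
    x, y, w, h = region
    if x < 0 or y < 0 or x + w > lum.shape[1] or y + h > lum.shape[0]:
        raise ValueError(f"region {region} exceeds image bounds {lum.shape[::-1]}")
    need = plan.groups_per_region * plan.pixels_per_group
    if w * h < need:
        raise ValueError(
            f"region {region} has {w * h} pixels; the sampling plan needs "
            f"{need} ({plan.groups_per_region} groups x {plan.pixels_per_group})"
        )
    groups: list[np.ndarray] = []
    for gx, gy, gw, gh in _group_rects(region, plan):
        flat = lum[gy:gy + gh, gx:gx + gw].ravel()
        if flat.size < plan.pixels_per_group:
            raise ValueError(
                f"sub-rectangle holds {flat.size} pixels; "
                f"{plan.pixels_per_group} needed per group — enlarge the region"
            )
        start = (flat.size - plan.pixels_per_group) // 2
        groups.append(flat[start:start + plan.pixels_per_group])
    means = tuple(float(g.mean()) for g in groups)
    pooled = float(np.concatenate(groups).mean())
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return RegionSample(means, pooled, sd, sum(g.size for g in groups))


def sample_regions(image: np.ndarray, regions: Sequence[Rect],
                   plan: SamplingPlan | None = None,
                   model: LuminosityModel | None = None) -> list[RegionSample]:
    """Sample several regions under one plan."""
    return [sample_region(image, r, plan, model) for r in regions]


def measure_assay(image: np.ndarray,
                  strip_regions: Sequence,  # StripRegion or Rect
                  background: Rect,
                  plan: SamplingPlan | None = None,
                  model: LuminosityModel | None = None) -> list[StripMeasurement]:
    """Measure each strip's ODR against a shared background region."""
    bg = sample_region(image, background, plan, model)
    out = []
    for i, reg in enumerate(strip_regions, start=1):
        rect = reg.rect if hasattr(reg, "rect") else tuple(reg)
        idx = getattr(reg, "strip_index", i)
        s = sample_region(image, rect, plan, model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = odr(bg.mean, s.mean)
        out.append(StripMeasurement(
            strip_index=idx, group_means=s.group_means, I_s=s.mean,
            I_s_sd=s.sd, I_b=bg.mean, odr=value,
            lighter_than_background=value < 0,
        ))
    return out


def flat_field_correct(image: np.ndarray,
                       background_estimate: np.ndarray | None = None,
                       smooth_window: int | None = None) -> np.ndarray:
    """Divide out smooth illumination and restore the background level.

    When no estimate is supplied, the illumination field is estimated
    from the image itself: the per-column upper percentile (95th) is
    morphologically closed along x (maximum then minimum filter) with a
    window wider than the widest bar — closing bridges the dark bars
    while leaving smooth illumination ramps unchanged — then lightly
    smoothed.  The corrected image is rescaled so the background's
    median equals its pre-correction median.
    """
    lum = image_luminosity(image)
    h, w = lum.shape
    if background_estimate is None:
        window = smooth_window or max(25, w // 12)
        col_bg = np.percentile(lum, 95, axis=0)
        col_bg = ndimage.maximum_filter1d(col_bg, size=window, mode="nearest")
        col_bg = ndimage.minimum_filter1d(col_bg, size=window, mode="nearest")
        col_bg = ndimage.uniform_filter1d(col_bg, size=max(window // 4, 3),
                                          mode="nearest")
        est = np.tile(col_bg, (h, 1))
    else:
        est = np.asarray(background_estimate, dtype=float)
        if est.ndim == 1:
            est = np.tile(est, (h, 1))
        if est.shape != lum.shape:
            raise ValueError("background estimate shape does not match image")
    if est.min() <= 0:
        raise ValueError("background estimate must be strictly positive")
    target = float(np.median(est))
    out = lum / est * target
    if np.issubdtype(np.asarray(image).dtype, np.integer) and np.asarray(image).ndim == 2:
        return out.round().clip(0, 255).astype(np.uint8)
    return np.clip(out, 0, 255)
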
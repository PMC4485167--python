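"""Dose–response calibration for the scanometric readout.

A sandwich immunoassay's ODR rises with analyte concentration and
saturates once the binding sites fill; the package models this with
the four-parameter logistic (4PL)

    ODR(c) = lower + (upper − lower) / (1 + (midpoint / c)^slope)

with ``lower`` the blank-level ODR, ``upper`` the saturation ODR,
``midpoint`` the concentration at half response (EC50) and ``slope``
the Hill coefficient.  The curve is monotone increasing for slope > 0,
so it has a closed-form inverse used for concentration estimation.  A
three-parameter Langmuir-type form (lower fixed, slope = 1) is
available as an alternative.

Concentrations are carried as plain numbers with an attached unit
string; no unit conversion is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CalibrationCurve",
    "ConcentrationEstimate",
    "four_param_logistic",
    "fit_calibration",
    "estimate_concentration",
    "make_synthetic_calibration",
    "load_calibration_table",
]


def four_param_logistic(c, lower, upper, midpoint, slope):
    """Monotone-increasing 4PL; c = 0 maps to the lower asymptote."""
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, float(lower))
    pos = c > 0
    out[pos] = lower + (upper - lower) / (1.0 + (midpoint / c[pos]) ** slope)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted monotone dose–response model with an inverse."""

    lower: float
    upper: float
    midpoint: float
    slope: float
    residual_scale: float
    valid_range: tuple[float, float]
    concentration_unit: str = "mIU/mL"
    model: str = "4pl"

    def predict(self, concentration) -> float | np.ndarray:
        out = four_param_logistic(
            np.atleast_1d(concentration), self.lower, self.upper,
            self.midpoint, self.slope,
        )
        return float(out[0]) if np.isscalar(concentration) else out

    def inverse(self, odr_value: float) -> float:
        """Closed-form inverse on the open response interval."""
        if not self.lower < odr_value < self.upper:
            raise ValueError(
                f"ODR {odr_value} outside the open response interval "
                f"({self.lower:.4f}, {self.upper:.4f})"
            )
        frac = (self.upper - self.lower) / (odr_value - self.lower) - 1.0
        return self.midpoint * frac ** (-1.0 / self.slope)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "model": self.model,
            "lower": self.lower, "upper": self.upper,
            "midpoint": self.midpoint, "slope": self.slope,
            "residual_scale": self.residual_scale,
            "valid_range": list(self.valid_range),
            "concentration_unit": self.concentration_unit,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "CalibrationCurve":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
        return cls(
            lower=data["lower"], upper=data["upper"],
            midpoint=data["midpoint"], slope=data["slope"],
            residual_scale=data["residual_scale"],
            valid_range=tuple(data["valid_range"]),
            concentration_unit=data.get("concentration_unit", ""),
            model=data.get("model", "4pl"),
        )


@dataclass(frozen=True)
class ConcentrationEstimate:
    value: float | None
    interval: tuple[float, float] | None
    flag: Literal["ok", "below_range", "saturated"]
    unit: str = ""

    def as_dict(self) -> dict:
        return {
            "value": self.value,
            "interval": list(self.interval) if self.interval else None,
            "flag": self.flag,
            "unit": self.unit,
        }


def _check_points(conc: np.ndarray, odr: np.ndarray) -> None:
    if conc.size < 5:
        raise ValueError(f"need at least 5 calibration points, got {conc.size}")
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    if np.ptp(odr) < 1e-6:
        raise ValueError("calibration ODRs are all equal: no dynamic range to fit")
    rho = stats.spearmanr(conc, odr).statistic
    if not rho > 0:
        raise ValueError(
            f"calibration points are not monotone increasing (spearman rho={rho:.2f})"
        )


def fit_calibration(
    points: pd.DataFrame | Sequence[tuple[float, float]],
    model: Literal["4pl", "langmuir"] = "4pl",
    concentration_unit: str = "mIU/mL",
    slope_floor_fraction: float = 0.05,
) -> CalibrationCurve:
    """Least-squares fit of the dose–response model.

    ``points`` is a DataFrame with columns ``concentration`` and ``odr``
    (or an iterable of pairs).  The quantifiable ``valid_range`` is the
    concentration span over which the fitted curve's slope exceeds
    ``slope_floor_fraction`` of its maximum, intersected with the data
    span — outside it the curve is too flat to invert usefully.
    """
    if isinstance(points, pd.DataFrame):
        conc = points["concentration"].to_numpy(dtype=float)
        odr = points["odr"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        conc, odr = arr[:, 0], arr[:, 1]
    _check_points(conc, odr)

    lo0, hi0 = float(odr.min()), float(odr.max())
    half = (lo0 + hi0) / 2
    pos = conc[conc > 0]
    mid0 = float(np.interp(half, np.sort(odr), conc[np.argsort(odr)]))
    if not np.isfinite(mid0) or mid0 <= 0:
        mid0 = float(np.median(pos)) if pos.size else 1.0

    if model == "4pl":
        p0 = [max(lo0, 0.0), min(hi0, 1.0), mid0, 1.5]
        bounds = ([0.0, 0.0, 1e-9, 0.1], [1.0, 1.0, np.inf, 10.0])
        fun = four_param_logistic
    elif model == "langmuir":
        def fun(c, lower, upper, midpoint):  # slope fixed at 1
            return four_param_logistic(c, lower, upper, midpoint, 1.0)
        p0 = [max(lo0, 0.0), min(hi0, 1.0), mid0]
        bounds = ([0.0, 0.0, 1e-9], [1.0, 1.0, np.inf])
    else:
        raise ValueError(f"unknown calibration model {model!r}")

    try:
        popt, _ = optimize.curve_fit(
            fun, conc, odr, p0=p0, bounds=bounds, maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"calibration fit did not converge: {exc}") from exc
    if model == "langmuir":
        lower, upper, midpoint, slope = *popt, 1.0
    else:
        lower, upper, midpoint, slope = popt
    if upper <= lower:
        raise ValueError("fitted curve has no dynamic range (upper <= lower)")
    resid = odr - four_param_logistic(conc, lower, upper, midpoint, slope)
    dof = max(conc.size - len(popt), 1)
    residual_scale = float(np.sqrt((resid ** 2).sum() / dof))

    # quantifiable span: where the fitted slope exceeds its floor
    cmax = float(conc.max()) if conc.max() > 0 else midpoint * 10
    grid = np.geomspace(max(cmax * 1e-4, 1e-9), cmax, 512)
    deriv = np.gradient(
        four_param_logistic(grid, lower, upper, midpoint, slope), grid
    )
    keep = deriv >= slope_floor_fraction * deriv.max()
    lo_c, hi_c = float(grid[keep].min()), float(grid[keep].max())
    return CalibrationCurve(
        lower=float(lower), upper=float(upper), midpoint=float(midpoint),
        slope=float(slope), residual_scale=residual_scale,
        valid_range=(lo_c, hi_c), concentration_unit=concentration_unit,
        model=model,
    )


def estimate_concentration(odr_value: float,
                           curve: CalibrationCurve) -> ConcentrationEstimate:
    """Invert the fitted curve, flagging values it cannot support.

    ODRs at or below the curve's response at the lower end of the valid
    range are flagged ``below_range``; at or above the upper end,
    ``saturated`` (the curve is too flat there to extrapolate).  The
    interval is the inverse image of ``odr ± residual_scale``.
    """
    lo_c, hi_c = curve.valid_range
    lo_odr, hi_odr = curve.predict(lo_c), curve.predict(hi_c)
    if odr_value <= lo_odr:
        return ConcentrationEstimate(None, None, "below_range", curve.concentration_unit)
    if odr_value >= hi_odr:
        return ConcentrationEstimate(None, None, "saturated", curve.concentration_unit)
    value = curve.inverse(odr_value)
    s = curve.residual_scale
    lo = curve.inverse(odr_value - s) if odr_value - s > lo_odr else lo_c
    hi = curve.inverse(odr_value + s) if odr_value + s < hi_odr else hi_c
    return ConcentrationEstimate(value, (lo, hi), "ok", curve.concentration_unit)


def make_synthetic_calibration(
    n: int = 8,
    lower: float = 0.04,
    upper: float = 0.55,
    midpoint: float = 5.0,
    slope: float = 2.0,
    noise_sd: float = 0.02,
    cmax: float = 25.0,
    seed: int = 0,
    concentration_unit: str = "mIU/mL",
) -> pd.DataFrame:
    """Synthetic dose–response table for a saturating sandwich assay.

    Defaults emulate the hCG-like regime: blank-level ODR ~0.04,
    saturation ODR ~0.55 approached near 15 concentration units, with
    quantitation up to 25.  Concentrations are a blank plus a geometric
    ladder up to ``cmax``; ODRs get i.i.d. Gaussian noise (sd in ODR
    units), clipped to [0, 1].
    """
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    conc = np.concatenate(([0.0], np.geomspace(cmax / 50.0, cmax, n - 1)))
    odr = four_param_logistic(conc, lower, upper, midpoint, slope)
    odr = np.clip(odr + rng.normal(0.0, noise_sd, size=conc.shape), 0.0, 1.0)
    return pd.DataFrame({
        "concentration": conc, "odr": odr,
        "unit": concentration_unit,
    })


def load_calibration_table(path: str) -> pd.DataFrame:
    """Read a (concentration, odr[, sd]) CSV calibration table."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("concentration", "odr") if c not in cols]
    if missing:
        raise ValueError(f"calibration CSV lacks column(s): {', '.join(missing)}")
    out = df.rename(columns={cols[k]: k for k in cols})
    return out
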
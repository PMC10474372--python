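"""Dose-response curve fitting and area-under-the-curve standardization.

Drug screens report cell viability (fraction of untreated control) at a
handful of concentrations.  The training target of the response model is the
normalized area under the dose-response curve (AUDRC): 0 means complete cell
death across the dose range, 1 means no effect, and values above 1 mean the
treatment favoured growth.  Two variants are provided:

* ``AUDRC1`` — trapezoidal integration over the experiment's own dose range;
  comparable only within one assay design, because the value depends on the
  chosen minimum/maximum concentrations.
* ``AUDRC2`` — a four-parameter logistic (4PL) curve is fitted first and then
  integrated over a standardized 100 pM - 100 uM window, making values
  comparable across studies.

Both areas are computed over log10 concentration and divided by the log10
width of the integration window, which is what anchors the 0/1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "DoseResponseCurve",
    "FourPLParams",
    "AUDRCValue",
    "fit_4pl",
    "audrc_trapezoid",
    "audrc_standardized",
    "STANDARD_CMIN",
    "STANDARD_CMAX",
]

#: Standardized integration window for AUDRC2: 100 pM to 100 uM.
STANDARD_CMIN = 1e-10
STANDARD_CMAX = 1e-4


@dataclass
class DoseResponseCurve:
    """Viability measurements of one (cell line, drug) pair.

    Concentrations are molar and strictly positive; viabilities are fractions
    of the untreated control (1 = control) and may exceed 1.  Records with
    missing values must be excluded upstream.
    """

    concentrations: np.ndarray
    viabilities: np.ndarray
    cell_id: str = ""
    drug_id: str = ""
    study: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viabilities = np.asarray(self.viabilities, dtype=float)
        if self.concentrations.shape != self.viabilities.shape:
            raise ValueError("concentrations and viabilities must have equal length")
        if self.concentrations.size < 2:
            raise ValueError("a dose-response curve needs at least 2 points")
        if not np.all(np.isfinite(self.concentrations)) or not np.all(
            np.isfinite(self.viabilities)
        ):
            raise ValueError("missing or non-finite values in dose-response curve")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive (molar)")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.viabilities = self.viabilities[order]


@dataclass
class FourPLParams:
    """Four-parameter logistic fit: v(x) = lower + (upper-lower)/(1+(x/ec50)^slope).

    ``status`` is ``"ok"`` for a converged fit and ``"fallback-constant"``
    when the data were degenerate or the optimizer failed, in which case
    ``upper == lower`` holds the mean viability.  ``upper >= lower`` by
    convention (the curve is reparameterized by negating the slope if the
    optimizer lands in the mirrored solution).
    """

    upper: float
    lower: float
    ec50: float
    slope: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok" and not self.ec50 > 0:
            raise ValueError("ec50 must be positive for a converged fit")

    def predict(self, concentrations) -> np.ndarray:
        """Evaluate the fitted curve at molar concentrations."""
        x = np.asarray(concentrations, dtype=float)
        if self.status == "fallback-constant":
            return np.full_like(x, self.upper)
        t = np.log10(x) - np.log10(self.ec50)
        return self.lower + (self.upper - self.lower) / (1.0 + 10.0 ** (self.slope * t))


@dataclass(frozen=True)
class AUDRCValue:
    """Normalized area under a dose-response curve."""

    value: float
    variant: str  # "audrc1" | "audrc2"


def _4pl_log10(t, upper, lower, log_ec50, slope):
    return lower + (upper - lower) / (1.0 + 10.0 ** (slope * (t - log_ec50)))


def fit_4pl(curve: DoseResponseCurve) -> FourPLParams:
    """Least-squares 4PL fit in log10-concentration space.

    Initialization: asymptotes from the means at the extreme doses, EC50 at
    the dose nearest half-range, slope 1.  Degenerate data (a single distinct
    concentration, or constant viability) and optimizer failures return a
    ``fallback-constant`` parameter set at the mean viability.
    """
    t = np.log10(curve.concentrations)
    v = curve.viabilities
    if np.unique(t).size < 2:
        raise ValueError("fitting requires at least 2 distinct concentrations")
    mean_v = float(np.mean(v))
    if np.ptp(v) == 0.0:
        return FourPLParams(mean_v, mean_v, np.nan, 0.0, status="fallback-constant")

    lo_mean = float(np.mean(v[t <= t[0] + 1e-12]))
    hi_mean = float(np.mean(v[t >= t[-1] - 1e-12]))
    upper0, lower0 = max(lo_mean, hi_mean), min(lo_mean, hi_mean)
    half = 0.5 * (upper0 + lower0)
    ec50_0 = t[np.argmin(np.abs(v - half))]
    span = max(np.ptp(v), 1e-6)
    width = t[-1] - t[0]
    p0 = (upper0, lower0, float(ec50_0), 1.0)
    bounds = (
        [np.min(v) - 2 * span, np.min(v) - 2 * span, t[0] - 2 * width, -50.0],
        [np.max(v) + 2 * span, np.max(v) + 2 * span, t[-1] + 2 * width, 50.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            _4pl_log10, t, v, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return FourPLParams(mean_v, mean_v, np.nan, 0.0, status="fallback-constant")
    upper, lower, log_ec50, slope = (float(x) for x in popt)
    if not all(np.isfinite([upper, lower, log_ec50, slope])):
        return FourPLParams(mean_v, mean_v, np.nan, 0.0, status="fallback-constant")
    if upper < lower:  # mirrored parameterization: swap and negate the slope
        upper, lower, slope = lower, upper, -slope
    return FourPLParams(upper, lower, 10.0**log_ec50, slope, status="ok")


def audrc_trapezoid(curve: DoseResponseCurve) -> AUDRCValue:
    """AUDRC1: trapezoidal area over the experiment's own log10 dose range."""
    t = np.log10(curve.concentrations)
    width = t[-1] - t[0]
    if width <= 0:
        raise ValueError("dose range has zero log-width")
    area = float(np.trapezoid(curve.viabilities, t))
    return AUDRCValue(area / width, variant="audrc1")


def audrc_standardized(
    params: FourPLParams,
    cmin: float = STANDARD_CMIN,
    cmax: float = STANDARD_CMAX,
) -> AUDRCValue:
    """AUDRC2: fitted 4PL integrated over a standardized dose window.

    The fitted curve is numerically integrated over
    ``[log10(cmin), log10(cmax)]`` and divided by the window's log10 width,
    so a flat curve at the control level yields exactly 1 and a flat curve at
    zero viability yields exactly 0, regardless of the raw experiment's
    dose range.
    """
    if cmin <= 0 or cmin >= cmax:
        raise ValueError("require 0 < cmin < cmax")
    t0, t1 = np.log10(cmin), np.log10(cmax)
    if params.status == "fallback-constant":
        return AUDRCValue(float(params.upper), variant="audrc2")
    area, _ = integrate.quad(
        _4pl_log10,
        t0,
        t1,
        args=(params.upper, params.lower, np.log10(params.ec50), params.slope),
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
    )
    return AUDRCValue(float(area) / (t1 - t0), variant="audrc2")
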
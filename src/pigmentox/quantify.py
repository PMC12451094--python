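"""External linear calibration and the unit conversions used in the study.

Signals (absorbance, peak area) map to concentrations through an ordinary
least-squares line fitted to external standards; unknowns are quantified by
inverse prediction ``(signal − intercept)/slope`` with an extrapolation
flag outside the calibrated range.  Two stoichiometric conversions cover
the worked examples: mass fraction → molarity (e.g. 0.1% w/w SDS at
M = 288.38 g mol⁻¹ is 3.47 mM) and dose-based dilution of a stock
component (e.g. 0.79 mM iron in an extract dosed at 0.73 g L⁻¹ gives
0.58 µM in the emulsion, assuming extract density 1 g mL⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "invert_calibration",
    "mass_fraction_to_molarity",
    "dilute_component",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear signal = slope·concentration + intercept map.

    ``range`` records the calibrated concentration span (µM); predictions
    outside it are flagged as extrapolation.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    analyte: str = ""
    range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("zero slope: calibration is not invertible")
        if self.n_points < 2:
            raise ValueError("calibration needs ≥2 points")

    def predict(self, conc):
        """Expected signal at concentration ``conc`` (µM)."""
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def invert(self, signal):
        """Concentration (µM) and extrapolation flag for a measured signal."""
        return invert_calibration(self, signal)


def fit_calibration(standards: Sequence[tuple[float, float]], analyte: str = "",
                    through_origin: bool = False) -> CalibrationCurve:
    """Ordinary least-squares calibration line through external standards.

    ``standards`` is a sequence of (concentration µM, signal) pairs with at
    least two distinct concentrations.  ``through_origin`` drops the
    intercept (uncentred R² is then reported, as statsmodels defines it).
    """
    arr = np.asarray(list(standards), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("standards must be ≥2 (concentration, signal) pairs")
    conc, signal = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("singular design: all standard concentrations are equal")

    X = conc[:, None] if through_origin else sm.add_constant(conc)
    res = sm.OLS(signal, X).fit()
    if through_origin:
        slope, intercept = float(res.params[0]), 0.0
    else:
        intercept, slope = float(res.params[0]), float(res.params[1])
    if slope == 0:
        raise ValueError("degenerate standards: fitted slope is zero")
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rsquared),
        n_points=int(arr.shape[0]),
        analyte=analyte,
        range=(float(conc.min()), float(conc.max())),
    )


def invert_calibration(curve: CalibrationCurve, signal: float) -> tuple[float, bool]:
    """Inverse prediction (signal − intercept)/slope with extrapolation flag.

    Negative concentrations (signal below the intercept for a positive
    slope) are returned as computed, flagged as extrapolation; truncation
    is left to the caller.
    """
    conc = (float(signal) - curve.intercept) / curve.slope
    lo, hi = curve.range
    extrapolated = not (lo <= conc <= hi)
    return conc, extrapolated


def mass_fraction_to_molarity(fraction_pct_ww: float, molar_mass: float,
                              solution_density: float = 1.0) -> float:
    """Molarity (mM) of a component given as % w/w of the solution.

    grams per litre = fraction/100 × density (g mL⁻¹) × 1000 mL L⁻¹;
    divide by the molar mass (g mol⁻¹) and express in mmol L⁻¹.
    """
    if fraction_pct_ww < 0:
        raise ValueError("mass fraction must be ≥ 0")
    if molar_mass <= 0 or solution_density <= 0:
        raise ValueError("molar mass and density must be positive")
    grams_per_litre = fraction_pct_ww / 100.0 * solution_density * 1000.0
    return grams_per_litre / molar_mass * 1000.0


def dilute_component(stock_conc_mM: float, dose_g_per_L: float,
                     stock_density: float = 1.0) -> float:
    """Concentration (µM) of a stock component after dosing the stock.

    Dosing ``dose_g_per_L`` grams of stock per litre dilutes the stock by
    ``dose / (1000 · density)``; the result is expressed in µM.  Dosing
    1000 g L⁻¹ of a unit-density stock is the identity dilution.
    """
    if stock_conc_mM < 0 or dose_g_per_L < 0:
        raise ValueError("concentrations and doses must be ≥ 0")
    if stock_density <= 0:
        raise ValueError("density must be positive")
    dilution = dose_g_per_L / (1000.0 * stock_density)
    return stock_conc_mM * dilution * 1000.0
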
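"""Spectral colorimetry: turbidity correction, peak metrics, CIELAB, CIEDE2000.

Absorbance spectra A(λ) on 380–780 nm are converted to transmittance
T(λ) = 10^(−A), integrated against the CIE 1931 2° colour-matching
functions weighted by standard illuminant C (both shipped as packaged CSV
tables on a 5 nm grid), and mapped to CIELAB.  Colour differences use the
CIEDE2000 formula with parametric factors k_L = k_C = k_H = 1.

The scalar turbidity correction A(522) − A(750) serves the concentration
channel (pigment quantification against a cyanidin-3-glucoside calibration);
the Lab pipeline consumes the full spectrum uncorrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .dataio import AbsorbanceSpectrum

__all__ = [
    "LabColor",
    "SpectralTables",
    "turbidity_correct",
    "lambda_max",
    "spectral_shift",
    "spectrum_to_lab",
    "delta_e2000",
]

# CIELAB piecewise cube-root constants
_EPS = 216.0 / 24389.0
_KAPPA = 24389.0 / 27.0


@dataclass(frozen=True)
class LabColor:
    """CIELAB coordinates under a stated illuminant and observer.

    Chroma C* = sqrt(a*² + b*²) and hue angle h° = atan2(b*, a*) in
    degrees on [0, 360) are derived.  For the achromatic point
    a* = b* = 0 the hue is undefined; it is reported as 0 with
    ``hue_undefined`` set.
    """

    L: float
    a: float
    b: float
    illuminant: str = "C"
    observer: str = "2deg"

    @property
    def C(self) -> float:
        return math.hypot(self.a, self.b)

    @property
    def hue_undefined(self) -> bool:
        return self.a == 0.0 and self.b == 0.0

    @property
    def h_deg(self) -> float:
        if self.hue_undefined:
            return 0.0
        return math.degrees(math.atan2(self.b, self.a)) % 360.0

    def __iter__(self):
        return iter((self.L, self.a, self.b))


@dataclass(frozen=True)
class SpectralTables:
    """CIE colour-matching functions and illuminant power on a 5 nm grid."""

    wavelengths: np.ndarray
    cmf_x: np.ndarray
    cmf_y: np.ndarray
    cmf_z: np.ndarray
    illuminant: np.ndarray
    step: float = 5.0

    @classmethod
    def load(cls) -> "SpectralTables":
        """Load the packaged CIE 1931 2° observer and illuminant C tables."""
        pkg = resources.files("pigmentox") / "_cie_data"
        cmf = pd.read_csv(str(pkg / "cie_1931_2deg_5nm.csv"), comment="#")
        ill = pd.read_csv(str(pkg / "illuminant_c_5nm.csv"), comment="#")
        if not np.array_equal(cmf["wavelength_nm"], ill["wavelength_nm"]):
            raise ValueError("colour-matching and illuminant grids misaligned")
        return cls(
            wavelengths=cmf["wavelength_nm"].to_numpy(float),
            cmf_x=cmf["xbar"].to_numpy(float),
            cmf_y=cmf["ybar"].to_numpy(float),
            cmf_z=cmf["zbar"].to_numpy(float),
            illuminant=ill["power"].to_numpy(float),
        )

    def white_point(self) -> tuple[float, float, float]:
        """Illuminant tristimulus (Xn, Yn, Zn) with Yn normalised to 100."""
        k = 100.0 / float(np.sum(self.illuminant * self.cmf_y))
        Xn = k * float(np.sum(self.illuminant * self.cmf_x))
        Zn = k * float(np.sum(self.illuminant * self.cmf_z))
        return Xn, 100.0, Zn


_DEFAULT_TABLES: SpectralTables | None = None


def _tables(tables: SpectralTables | None) -> SpectralTables:
    global _DEFAULT_TABLES
    if tables is not None:
        return tables
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = SpectralTables.load()
    return _DEFAULT_TABLES


# ---------------------------------------------------------------------------
# scalar spectral operations
# ---------------------------------------------------------------------------

def turbidity_correct(spec: AbsorbanceSpectrum, peak_nm: float = 522.0,
                      reference_nm: float = 750.0) -> float:
    """Scattering-corrected absorbance A(peak) − A(reference).

    The near-infrared reading at 750 nm, where the pigment does not absorb,
    estimates residual turbidity and is subtracted from the peak reading.
    A negative result (reference above peak) is returned as-is with a
    warning — it flags a scattering artifact, not an error.
    """
    lo, hi = min(peak_nm, reference_nm), max(peak_nm, reference_nm)
    if not spec.covers(lo, hi):
        raise ValueError(
            f"spectrum [{spec.wavelengths[0]:g}, {spec.wavelengths[-1]:g}] nm does not "
            f"cover {lo:g} and {hi:g} nm"
        )
    corrected = float(spec.interp(peak_nm) - spec.interp(reference_nm))
    if corrected < 0:
        warnings.warn(
            f"A({reference_nm:g}) exceeds A({peak_nm:g}): negative corrected absorbance "
            f"{corrected:.4g} suggests a scattering artifact", RuntimeWarning, stacklevel=2,
        )
    return corrected


def lambda_max(spec: AbsorbanceSpectrum, window: tuple[float, float] = (450.0, 650.0),
               refine_halfwidth: float = 10.0) -> float:
    """Wavelength of maximum absorbance in ``window``, parabolically refined.

    The grid maximum (ties broken toward the lowest wavelength) is refined
    by a least-squares parabola fitted over ±``refine_halfwidth`` nm around
    it; pooling the neighbourhood keeps the vertex stable on broad bands
    whose top is flatter than the measurement noise.  At a window edge, or
    when the local fit is not concave, the grid value is returned
    unrefined.
    """
    lo, hi = window
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if mask.sum() < 5:
        raise ValueError(f"need ≥5 grid points inside window {window}, have {int(mask.sum())}")
    w = spec.wavelengths[mask]
    a = spec.absorbances[mask]
    i = int(np.argmax(a))  # argmax returns the first (lowest-λ) maximum
    if i == 0 or i == a.size - 1:
        return float(w[i])
    near = np.abs(w - w[i]) <= refine_halfwidth
    if near.sum() < 3:
        return float(w[i])
    c2, c1, _ = np.polyfit(w[near] - w[i], a[near], 2)
    if c2 >= 0:  # flat or non-concave neighbourhood: keep grid point
        return float(w[i])
    vertex = float(w[i] - c1 / (2.0 * c2))
    return float(np.clip(vertex, w[near][0], w[near][-1]))


def spectral_shift(spec_ref: AbsorbanceSpectrum, spec_test: AbsorbanceSpectrum,
                   window: tuple[float, float] = (450.0, 650.0),
                   tol_nm: float = 0.25) -> tuple[float, str, float]:
    """Peak shift and relative intensity change between two spectra.

    Returns ``(delta_nm, kind, rel_abs_change_pct)`` where
    ``delta_nm = λmax(test) − λmax(ref)``; positive shifts are
    *bathochromic* (toward longer wavelengths), negative *hypsochromic*,
    and shifts within ``tol_nm`` are classified ``"none"``.

    The relative absorbance change uses the **larger** peak absorbance as
    denominator: a hyperchromic change from 1.0 to 1.25 is reported as
    (1.25 − 1.0)/1.25 × 100 = 20%, and symmetrically for a hypochromic
    change.
    """
    for s in (spec_ref, spec_test):
        if not s.covers(*window):
            raise ValueError("both spectra must cover the analysis window")
    lam_ref = lambda_max(spec_ref, window)
    lam_test = lambda_max(spec_test, window)
    delta = lam_test - lam_ref
    kind = "none" if abs(delta) <= tol_nm else ("bathochromic" if delta > 0 else "hypsochromic")

    a_ref = float(spec_ref.interp(lam_ref))
    a_test = float(spec_test.interp(lam_test))
    larger = max(a_ref, a_test)
    rel = 0.0 if larger == 0 else (a_test - a_ref) / larger * 100.0
    return float(delta), kind, rel


# ---------------------------------------------------------------------------
# absorbance → CIELAB
# ---------------------------------------------------------------------------

def _f(t: np.ndarray | float):
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(t), (_KAPPA * t + 16.0) / 116.0)


def spectrum_to_lab(spec: AbsorbanceSpectrum, tables: SpectralTables | None = None) -> LabColor:
    """Convert an absorbance spectrum to CIELAB (illuminant C, 2° observer).

    The spectrum is linearly resampled to the 5 nm table grid; transmittance
    T = 10^(−A) is integrated against illuminant-weighted colour-matching
    functions (rectangular rule), normalised so the perfect transmitter
    maps to the white point L* = 100, a* = b* = 0.
    """
    tb = _tables(tables)
    lo, hi = tb.wavelengths[0], tb.wavelengths[-1]
    if spec.wavelengths[0] > lo + 10.0 or spec.wavelengths[-1] < hi - 10.0:
        raise ValueError(
            f"spectrum [{spec.wavelengths[0]:g}, {spec.wavelengths[-1]:g}] nm leaves a "
            f"coverage gap > 10 nm on [{lo:g}, {hi:g}]"
        )
    A = np.interp(tb.wavelengths, spec.wavelengths, spec.absorbances)
    T = np.power(10.0, -A)

    S = tb.illuminant
    k = 100.0 / float(np.sum(S * tb.cmf_y))
    X = k * float(np.sum(T * S * tb.cmf_x))
    Y = k * float(np.sum(T * S * tb.cmf_y))
    Z = k * float(np.sum(T * S * tb.cmf_z))
    Xn, Yn, Zn = tb.white_point()

    fx, fy, fz = _f(X / Xn), _f(Y / Yn), _f(Z / Zn)
    return LabColor(
        L=float(116.0 * fy - 16.0),
        a=float(500.0 * (fx - fy)),
        b=float(200.0 * (fy - fz)),
    )


# ---------------------------------------------------------------------------
# CIEDE2000
# ---------------------------------------------------------------------------

def delta_e2000(lab1: LabColor, lab2: LabColor,
                kL: float = 1.0, kC: float = 1.0, kH: float = 1.0) -> float:
    """CIEDE2000 colour difference ΔE₀₀ between two Lab colours.

    Implements the full formula: G chroma rescaling of a*, primed
    lightness/chroma/hue differences with the hue-averaging rules, the
    weighting functions S_L, S_C, S_H, the T hue-dependence term and the
    R_T rotation term that corrects the blue region.  Parametric factors
    default to k_L = k_C = k_H = 1.
    """
    if isinstance(lab1, LabColor) and isinstance(lab2, LabColor):
        if (lab1.illuminant, lab1.observer) != (lab2.illuminant, lab2.observer):
            raise ValueError("colour difference requires a common illuminant/observer")
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2

    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - math.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1.0 + G) * a1, (1.0 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)

    def hue(ap, b):
        if ap == 0.0 and b == 0.0:
            return 0.0
        return math.degrees(math.atan2(b, ap)) % 360.0

    h1p, h2p = hue(a1p, b1), hue(a2p, b2)

    dLp = L2 - L1
    dCp = C2p - C1p

    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        dhp = h2p - h1p
        if dhp > 180.0:
            dhp -= 360.0
        elif dhp < -180.0:
            dhp += 360.0
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lbar = 0.5 * (L1 + L2)
    Cbarp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0.0:
        hbarp = h1p + h2p
    else:
        s = h1p + h2p
        if abs(h1p - h2p) <= 180.0:
            hbarp = 0.5 * s
        elif s < 360.0:
            hbarp = 0.5 * (s + 360.0)
        else:
            hbarp = 0.5 * (s - 360.0)

    T = (1.0
         - 0.17 * math.cos(math.radians(hbarp - 30.0))
         + 0.24 * math.cos(math.radians(2.0 * hbarp))
         + 0.32 * math.cos(math.radians(3.0 * hbarp + 6.0))
         - 0.20 * math.cos(math.radians(4.0 * hbarp - 63.0)))
    dtheta = 30.0 * math.exp(-(((hbarp - 275.0) / 25.0) ** 2))
    RC = 2.0 * math.sqrt(Cbarp**7 / (Cbarp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbar - 50.0) ** 2 / math.sqrt(20.0 + (Lbar - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbarp
    SH = 1.0 + 0.015 * Cbarp * T
    RT = -math.sin(math.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return math.sqrt(tL * tL + tC * tC + tH * tH + RT * tC * tH)
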
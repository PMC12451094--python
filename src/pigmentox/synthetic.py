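"""Seeded generator of replicate kinetic series and pH-dependent spectra.

The generator is the testbed's stand-in for the storage experiment: it
draws replicate concentration–time series from the same first-order decay
and logistic accumulation models the fitting stage estimates, and visible
absorbance spectra with the pH behaviour of an acylated anthocyanin
extract (single band moving 522 → 546 nm and weakening as the flavylium
cation deprotonates between pH 2 and 6; an anionic surfactant shifts and
intensifies the band below pH 6).

Replicate structure mirrors the study design: ``n_prep`` independent
emulsion preparations, each measured ``n_meas`` times.  Preparations carry
a lognormal random effect on the rate constant (default CV 10%);
measurements add i.i.d. Gaussian noise truncated at zero.  All randomness
flows from one ``numpy.random.default_rng`` seed, so a given seed
reproduces byte-identical data on any platform.

``PRESETS`` encodes the study conditions: decay rates per pH for the
pigment channel and, for each oxidation product × pH × extract dose, the
published rate constant, induction time and plateau; the sigmoid ``c0`` is
back-calculated from the induction time via
``c0 = cmax / (1 + exp(2 + k·t_ind))`` so that fitting a preset recovers
the published induction behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import AbsorbanceSpectrum, KineticSeries, SampleMeta
from .kinetics import sigmoid_value

__all__ = ["ScenarioConfig", "gen_kinetic_series", "gen_spectrum", "PRESETS", "preset"]

#: storage sampling grid (days) used by all presets
DEFAULT_DAYS = (0.0, 1.0, 3.0, 5.0, 7.0, 10.0, 14.0, 17.0, 21.0)

#: pigment degradation rate k (day⁻¹) per pH, anthocyanin channel
DECAY_K = {2.0: 1.44, 3.0: 0.30, 4.0: 0.06, 6.0: 0.09}

#: day-0 pigment concentration (µM cyanidin-3-glucoside equivalents)
DECAY_C0 = 24.0

#: spectral band centre (nm) and peak absorbance per pH, without surfactant
_BAND_CENTER = {2.0: 522.0, 3.0: 524.0, 4.0: 528.0, 6.0: 546.0}
_BAND_AMP = {2.0: 1.00, 3.0: 0.80, 4.0: 0.51, 6.0: 0.41}
#: with surfactant: centre shift (nm) and peak absorbance
_SDS_SHIFT = {2.0: +8.0, 3.0: +6.0, 4.0: +2.0, 6.0: -6.0}
_SDS_AMP = {2.0: 1.25, 3.0: 1.15, 4.0: 1.00, 6.0: 0.42}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated condition: model truth, noise, design and seed."""

    pH: float
    analyte: str
    model: str  # "decay" | "sigmoid"
    true_params: tuple  # (C0, k) or (c0, cmax, k)
    extract_dose: float = 0.73
    noise_sd: float | None = None  # µM; None → 5% of dynamic range
    days: tuple = DEFAULT_DAYS
    n_prep: int = 2
    n_meas: int = 2
    prep_cv: float = 0.10  # lognormal CV of the preparation effect on k
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.n_prep < 1 or self.n_meas < 1:
            raise ValueError("n_prep and n_meas must be ≥ 1")
        if self.model not in ("decay", "sigmoid"):
            raise ValueError(f"unknown model {self.model!r}")

    def curve(self, t):
        if self.model == "decay":
            C0, k = self.true_params
            return C0 * np.exp(-k * np.asarray(t, dtype=float))
        return sigmoid_value(self.true_params, t)

    def _default_noise(self) -> float:
        c = self.curve(np.asarray(self.days, dtype=float))
        return 0.05 * float(c.max() - c.min())


def _with_k(cfg: ScenarioConfig, k: float) -> tuple:
    if cfg.model == "decay":
        return (cfg.true_params[0], k)
    return (cfg.true_params[0], cfg.true_params[1], k)


def gen_kinetic_series(cfg: ScenarioConfig) -> list[KineticSeries]:
    """Draw one :class:`KineticSeries` per preparation × measurement.

    The preparation random effect multiplies the rate constant by a
    lognormal factor with unit mean and CV ``cfg.prep_cv``; measurement
    noise is additive Gaussian with SD ``cfg.noise_sd`` truncated at zero.
    Deterministic for a given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.days, dtype=float)
    sd = cfg.noise_sd if cfg.noise_sd is not None else cfg._default_noise()
    k_true = cfg.true_params[-1]

    # unit-mean lognormal: sigma² = ln(1 + CV²), mu = −sigma²/2
    sig2 = math.log(1.0 + cfg.prep_cv**2)
    out: list[KineticSeries] = []
    rep = 0
    for prep in range(cfg.n_prep):
        k_prep = k_true * float(rng.lognormal(mean=-sig2 / 2.0, sigma=math.sqrt(sig2)))
        curve = replace(cfg, true_params=_with_k(cfg, k_prep)).curve(t)
        for _ in range(cfg.n_meas):
            rep += 1
            values = np.clip(curve + rng.normal(0.0, sd, size=t.size), 0.0, None)
            meta = SampleMeta(
                sample_id=f"sim_pH{cfg.pH:g}_{cfg.analyte}",
                pH=cfg.pH,
                extract_dose=cfg.extract_dose,
                replicate=rep,
            )
            out.append(KineticSeries(meta=meta, analyte=cfg.analyte, times=t, values=values))
    return out


def _interp_ph(table: dict[float, float], pH: float) -> float:
    xs = np.array(sorted(table))
    ys = np.array([table[x] for x in xs])
    return float(np.interp(pH, xs, ys))


def gen_spectrum(pH: float, with_SDS: bool = False, day: float = 0.0,
                 seed: int = 0, noise_sd: float = 0.002,
                 extract_dose: float = 0.73) -> AbsorbanceSpectrum:
    """Synthetic visible spectrum of the pigment extract on a 1 nm grid.

    A single Gaussian band whose centre moves 522 → 546 nm and whose
    amplitude falls 1.0 → 0.41 as pH rises 2 → 6 (piecewise-linear through
    the intermediate pH anchors); the band also broadens toward high pH.
    ``with_SDS`` applies the surfactant's centre shift (+8/+6/+2/−6 nm at
    pH 2/3/4/6) and amplitude change.  Storage for ``day`` days attenuates
    the band by the pH's first-order pigment decay constant.  A small flat
    baseline plus seeded Gaussian noise completes the spectrum.
    """
    if not (2.0 <= pH <= 6.0):
        raise ValueError(f"pH {pH} outside the generator's calibrated range [2, 6]")
    rng = np.random.default_rng(seed)
    wl = np.arange(380.0, 781.0, 1.0)

    center = _interp_ph(_BAND_CENTER, pH)
    amp = _interp_ph(_BAND_AMP, pH)
    if with_SDS:
        center += _interp_ph(_SDS_SHIFT, pH)
        amp = _interp_ph(_SDS_AMP, pH)
    width = 45.0 + 7.5 * (pH - 2.0)  # nm; bands broaden toward high pH
    amp *= math.exp(-_interp_ph(DECAY_K, pH) * day)

    band = amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    baseline = 0.01
    A = band + baseline + rng.normal(0.0, noise_sd, size=wl.size)
    A = np.clip(A, -0.049, None)
    meta = SampleMeta(
        sample_id=f"sim_spec_pH{pH:g}{'_SDS' if with_SDS else ''}",
        pH=pH,
        extract_dose=extract_dose,
    )
    return AbsorbanceSpectrum(meta=meta, wavelengths=wl, absorbances=A, day=day)


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------

def _sigmoid_c0(cmax: float, k: float, t_ind: float | None, c0_direct: float | None) -> float:
    """Back out c0 from the published induction time (or use a direct value)."""
    if t_ind is None:
        return float(c0_direct)
    return cmax / (1.0 + math.exp(2.0 + k * t_ind))


# (analyte, pH, extract g/L) -> (t_ind days or None, k day⁻¹, cmax µM, c0 when t_ind is None)
_SIGMOID_TABLE: dict[tuple[str, float, float], tuple[float | None, float, float, float | None]] = {
    ("LOOH", 2.0, 0.0): (None, 4.0, 300.0, 67.0),
    ("LOOH", 2.0, 0.73): (None, 1.9, 300.0, 67.0),
    ("LOOH", 3.0, 0.0): (6.3, 1.6, 2172.0, None),
    ("LOOH", 3.0, 0.73): (5.7, 0.9, 986.0, None),
    ("LOOH", 4.0, 0.0): (2.9, 0.3, 255.0, None),
    ("LOOH", 4.0, 0.73): (8.8, 0.5, 40.0, None),
    ("LOOH", 6.0, 0.0): (9.1, 0.2, 484.0, None),
    ("LOOH", 6.0, 0.73): (20.8, 0.1, 40.0, None),
    ("propanal", 2.0, 0.0): (1.1, 1.3, 2000.0, None),
    ("propanal", 2.0, 0.73): (0.8, 1.8, 2000.0, None),
    ("propanal", 3.0, 0.0): (1.8, 0.6, 3270.0, None),
    ("propanal", 3.0, 0.73): (6.5, 1.6, 1500.0, None),
    ("propanal", 4.0, 0.0): (7.3, 1.0, 86.0, None),
    ("propanal", 4.0, 0.73): (6.6, 1.1, 60.0, None),
    ("propanal", 6.0, 0.0): (11.8, 0.6, 200.0, None),
    ("propanal", 6.0, 0.73): (10.8, 0.5, 150.0, None),
    ("hexanal", 2.0, 0.0): (0.8, 1.4, 400.0, None),
    ("hexanal", 2.0, 0.73): (1.3, 1.0, 400.0, None),
    ("hexanal", 3.0, 0.0): (2.7, 1.0, 1241.0, None),
    ("hexanal", 3.0, 0.73): (5.2, 1.0, 800.0, None),
    ("hexanal", 4.0, 0.0): (12.4, 0.9, 86.0, None),
    ("hexanal", 4.0, 0.73): (5.9, 1.0, 60.0, None),
    ("hexanal", 6.0, 0.0): (10.0, 1.0, 82.0, None),
    ("hexanal", 6.0, 0.73): (7.9, 0.9, 70.0, None),
}


def _build_presets() -> dict[str, ScenarioConfig]:
    presets: dict[str, ScenarioConfig] = {}
    for pH, k in DECAY_K.items():
        presets[f"pH{pH:g}_anthocyanin"] = ScenarioConfig(
            pH=pH, analyte="anthocyanin", model="decay",
            true_params=(DECAY_C0, k), noise_sd=0.05 * DECAY_C0,
        )
    for (analyte, pH, dose), (t_ind, k, cmax, c0_direct) in _SIGMOID_TABLE.items():
        c0 = _sigmoid_c0(cmax, k, t_ind, c0_direct)
        tag = "" if dose > 0 else "_noextract"
        presets[f"pH{pH:g}_{analyte}{tag}"] = ScenarioConfig(
            pH=pH, analyte=analyte, model="sigmoid",
            true_params=(c0, cmax, k), extract_dose=dose,
        )
    return presets


PRESETS: dict[str, ScenarioConfig] = _build_presets()


def preset(name: str, seed: int | None = None, **overrides) -> ScenarioConfig:
    """Look up a named study-condition preset, optionally reseeded/overridden."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(cfg, **overrides) if overrides else cfg
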
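"""Domain containers and CSV/JSON input-output shared by all pipeline stages.

Kinetic observations travel as long-format (tidy) CSV with one row per
measurement: ``sample_id, pH, extract_dose, replicate, analyte, day, value``.
Units are fixed: concentrations in µM, time in days, wavelengths in nm.
No unit inference is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANALYTES = ("anthocyanin", "LOOH", "propanal", "hexanal")

KINETIC_COLUMNS = ("sample_id", "pH", "extract_dose", "replicate", "analyte", "day", "value")


class SchemaError(ValueError):
    """A required column is absent or an enum value is unknown."""


class ParseError(ValueError):
    """A cell could not be parsed as the declared type."""


class ValidationError(ValueError):
    """A structurally valid file violates a domain invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity and composition of one emulsion (or buffer) sample.

    ``extract_dose`` is the pigment-extract dose in g L⁻¹ (the study used
    0.73 g L⁻¹ black carrot extract); ``oil_fraction`` and
    ``surfactant_conc`` are % w/w.
    """

    sample_id: str
    pH: float
    extract_dose: float = 0.0
    oil_fraction: float = 1.0
    surfactant_conc: float = 0.1
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.pH <= 14.0):
            raise ValidationError(f"pH {self.pH} outside [0, 14]")
        if self.extract_dose < 0:
            raise ValidationError(f"extract_dose {self.extract_dose} < 0")
        if self.replicate < 1:
            raise ValidationError(f"replicate {self.replicate} < 1")


@dataclass(frozen=True)
class KineticSeries:
    """Concentration-versus-time observations for one replicate and analyte.

    ``times`` (days) must be strictly increasing; ``values`` (µM) must be
    non-negative and of equal length.
    """

    meta: SampleMeta
    analyte: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.analyte not in ANALYTES:
            raise SchemaError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("times and values must be 1-D arrays of equal length")
        if t.size and t.min() < 0:
            raise ValidationError("negative time")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing within a replicate")
        if v.size and v.min() < 0:
            raise ValidationError("negative concentration")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Wavelength-indexed absorbance A(λ) with sample metadata.

    Wavelengths (nm) must be strictly ascending inside [380, 780].  Slightly
    negative absorbances (≥ −0.05) are tolerated as instrument noise.
    """

    meta: SampleMeta
    wavelengths: np.ndarray
    absorbances: np.ndarray
    day: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbances", a)
        if w.shape != a.shape or w.ndim != 1:
            raise ValidationError("wavelengths and absorbances must be 1-D and equal length")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavelengths must be strictly ascending and unique")
        if w.size and (w.min() < 380.0 - 1e-9 or w.max() > 780.0 + 1e-9):
            raise ValidationError("wavelengths must lie within [380, 780] nm")
        if a.size and a.min() < -0.05:
            raise ValidationError("absorbance below -0.05 noise tolerance")

    def covers(self, lo: float, hi: float) -> bool:
        return bool(self.wavelengths.size) and self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def interp(self, nm: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of A(λ); caller must ensure coverage."""
        return np.interp(nm, self.wavelengths, self.absorbances)


def read_kinetic_csv(path: str | Path, schema: dict[str, str] | None = None) -> list[KineticSeries]:
    """Read a tidy kinetic CSV into one :class:`KineticSeries` per
    (sample_id, analyte, replicate) group, rows sorted by day.

    ``schema`` optionally maps canonical column names to the names used in
    the file, e.g. ``{"day": "time_d"}``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("kinetic CSV %s is empty; returning no series", path)
        return []
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in KINETIC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    if df.empty:
        logger.warning("kinetic CSV %s has a header but no rows", path)
        return []

    for col in ("pH", "extract_dose", "day", "value"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"non-numeric {col!r} at {path} line {row}: {df[col][bad.idxmax()]!r}")
        df[col] = parsed

    n_missing = int(df["value"].isna().sum() + df["day"].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with empty day/value cells", n_missing)
        df = df.dropna(subset=["day", "value"])

    out: list[KineticSeries] = []
    for (sid, analyte, rep), g in df.groupby(["sample_id", "analyte", "replicate"], sort=True):
        g = g.sort_values("day")
        if g["day"].duplicated().any():
            d = g.loc[g["day"].duplicated(), "day"].iloc[0]
            raise ValidationError(
                f"duplicated day {d} for sample {sid!r}, analyte {analyte!r}, replicate {rep}"
            )
        meta = SampleMeta(
            sample_id=str(sid),
            pH=float(g["pH"].iloc[0]),
            extract_dose=float(g["extract_dose"].iloc[0]),
            replicate=int(rep),
        )
        out.append(
            KineticSeries(
                meta=meta,
                analyte=str(analyte),
                times=g["day"].to_numpy(float),
                values=g["value"].to_numpy(float),
            )
        )
    return out


def write_kinetic_csv(series: Iterable[KineticSeries], path: str | Path) -> Path:
    """Serialize series back to the tidy layout read by :func:`read_kinetic_csv`."""
    path = Path(path)
    rows = []
    for s in series:
        for t, v in zip(s.times, s.values):
            rows.append(
                {
                    "sample_id": s.meta.sample_id,
                    "pH": s.meta.pH,
                    "extract_dose": s.meta.extract_dose,
                    "replicate": s.meta.replicate,
                    "analyte": s.analyte,
                    "day": t,
                    "value": v,
                }
            )
    pd.DataFrame(rows, columns=list(KINETIC_COLUMNS)).to_csv(path, index=False)
    return path


def read_spectrum_csv(path: str | Path, meta: SampleMeta | None = None, day: float = 0.0) -> AbsorbanceSpectrum:
    """Read a two-column spectrum CSV (wavelength_nm, absorbance)."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "absorbance"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    df = df.sort_values("wavelength_nm")
    if meta is None:
        meta = SampleMeta(sample_id=Path(path).stem, pH=7.0)
    return AbsorbanceSpectrum(
        meta=meta,
        wavelengths=df["wavelength_nm"].to_numpy(float),
        absorbances=df["absorbance"].to_numpy(float),
        day=day,
    )


#: ordered union of per-fit report columns; non-applicable cells stay empty
_REPORT_COLUMNS = [
    "sample_id", "pH", "extract_dose", "replicate", "analyte", "kind",
    "C0_hat", "c0_hat", "cmax_hat", "k_hat", "t_half", "t_star", "t_ind",
    "rss", "n_obs", "converged",
]


def write_fit_report(fits: Sequence, path: str | Path, config: dict | None = None,
                     seed: int | None = None) -> Path:
    """Write one CSV row per fitted replicate plus a JSON sidecar.

    Accepts any mix of decay and sigmoid fit results (duck-typed on their
    ``to_row()`` method).  The CSV carries the union of columns; statistics
    that do not apply to a fit kind are left as empty cells.  The sidecar
    ``<path>.meta.json`` records the run configuration and seed.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("write_fit_report requires at least one fit")
    path = Path(path)
    rows = [f.to_row() for f in fits]
    df = pd.DataFrame(rows)
    cols = [c for c in _REPORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df = df[cols]
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"config": config or {}, "seed": seed, "n_fits": len(fits)}, indent=2))
    return path


def read_fit_report(path: str | Path) -> pd.DataFrame:
    """Read back a fit report written by :func:`write_fit_report`."""
    return pd.read_csv(path)
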
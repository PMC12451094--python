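"""Kinetic models for pigment loss and lipid-oxidation product build-up.

Two models cover the storage experiments:

* **First-order decay** ``C(t) = C0 · exp(−k t)`` for pigment degradation,
  with half-life ``t_1/2 = ln 2 / k``.
* **Sigmoidal (logistic) accumulation**
  ``c(t) = cmax / (1 + ((cmax − c0)/c0) · exp(−k t))``
  for hydroperoxides and volatile aldehydes.  The curve's inflection point
  (where the second derivative changes sign) sits at
  ``t* = ln((cmax − c0)/c0) / k`` with value ``cmax/2`` and slope
  ``k·cmax/4``; the tangent drawn there crosses ``c = 0`` at
  ``t_ind = t* − 2/k``, the induction period.  A non-positive intercept
  means no induction phase can be constructed and is reported as ``None``
  (rendered "—" in tables).

Both models are fitted by bounded nonlinear least squares on the original
concentration scale (zero observations are admissible; a log transform is
used only to initialise the decay fit).  The sigmoid fit is multi-started
over log-spaced rate constants because the logistic RSS surface has flat
valleys in ``k`` when the observation grid misses the propagation phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .dataio import KineticSeries, SampleMeta, ValidationError

__all__ = [
    "FirstOrderDecay",
    "SigmoidAccumulation",
    "DecayResults",
    "SigmoidResults",
    "FitError",
    "sigmoid_value",
    "half_life",
    "fit_decay",
    "fit_sigmoid",
    "inflection_point",
    "induction_time",
    "aggregate_replicates",
]

LN2 = math.log(2.0)

#: multi-start grid over the rate constant (day⁻¹), log-spaced ×4
K_STARTS = (0.05, 0.2, 0.8, 3.2, 12.8)

#: lower bound keeping (cmax − c0)/c0 finite
C0_FLOOR = 1e-6


class FitError(RuntimeError):
    """Raised when a series is degenerate for the requested model."""


# ---------------------------------------------------------------------------
# model functions and closed-form derived statistics
# ---------------------------------------------------------------------------

def sigmoid_value(params: Sequence[float], t):
    """Logistic accumulation curve c(t) = cmax / (1 + A·e^(−k t)), A = (cmax−c0)/c0.

    ``params`` is ``(c0, cmax, k)``; ``t`` may be scalar or array (days).
    The curve starts at ``c(0) = c0``, rises strictly monotonically and
    saturates at ``cmax``.
    """
    c0, cmax, k = (float(p) for p in params)
    if c0 <= 0:
        raise ValueError(f"c0 must be positive, got {c0}")
    if cmax <= c0:
        raise ValueError(f"cmax ({cmax}) must exceed c0 ({c0})")
    A = (cmax - c0) / c0
    return cmax / (1.0 + A * np.exp(-k * np.asarray(t, dtype=float)))


def half_life(k: float) -> float:
    """Half-life ln2/k (days) of a first-order process with rate k (day⁻¹)."""
    if k <= 0:
        raise ValueError(f"half_life requires k > 0, got {k}")
    return LN2 / k


def inflection_point(fit) -> tuple[float, float, float]:
    """Inflection of the logistic curve: (t*, c(t*), dc/dt(t*)).

    Accepts a :class:`SigmoidResults` or a ``(c0, cmax, k)`` triple.
    Closed forms: ``t* = ln((cmax−c0)/c0)/k``, ``c(t*) = cmax/2``,
    ``slope = k·cmax/4``.  ``t* ≤ 0`` (inflection before the start of
    observation, i.e. ``cmax ≤ 2·c0``) is legitimate and returned as-is.
    """
    c0, cmax, k = _unpack_sigmoid_params(fit)
    if not (cmax > c0 > 0 and k > 0):
        raise ValueError("inflection_point requires cmax > c0 > 0 and k > 0")
    t_star = math.log((cmax - c0) / c0) / k
    return t_star, cmax / 2.0, k * cmax / 4.0


def induction_time(fit) -> float | None:
    """Induction period: x-intercept of the tangent at the inflection point.

    The tangent ``y = cmax/2 + (k·cmax/4)(t − t*)`` reaches ``y = 0`` at
    ``t_ind = t* − 2/k = (ln((cmax−c0)/c0) − 2)/k``.  When the intercept is
    non-positive no induction phase can be constructed and ``None`` is
    returned (tables render it as "—").
    """
    c0, cmax, k = _unpack_sigmoid_params(fit)
    t_star, _, _ = inflection_point((c0, cmax, k))
    t_ind = t_star - 2.0 / k
    return t_ind if t_ind > 0 else None


def _unpack_sigmoid_params(fit) -> tuple[float, float, float]:
    if hasattr(fit, "c0_hat"):
        return float(fit.c0_hat), float(fit.cmax_hat), float(fit.k_hat)
    c0, cmax, k = fit
    return float(c0), float(cmax), float(k)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class DecayResults:
    """Fitted first-order decay: estimates, half-life and diagnostics."""

    C0_hat: float
    k_hat: float
    rss: float
    n_obs: int
    converged: bool
    k_at_bound: bool = False
    meta: SampleMeta | None = None
    analyte: str = "anthocyanin"
    times: np.ndarray | None = None
    values: np.ndarray | None = None

    kind = "decay"
    param_names = ("C0_hat", "k_hat")

    @property
    def t_half(self) -> float:
        """Half-life ln2/k̂ (days); ``inf`` when k̂ is pinned at zero."""
        return math.inf if self.k_hat <= 0 else LN2 / self.k_hat

    @property
    def params(self) -> np.ndarray:
        return np.array([self.C0_hat, self.k_hat])

    def predict(self, t):
        return self.C0_hat * np.exp(-self.k_hat * np.asarray(t, dtype=float))

    def to_row(self) -> dict:
        row = {
            "kind": self.kind,
            "C0_hat": self.C0_hat,
            "k_hat": self.k_hat,
            "t_half": self.t_half,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "analyte": self.analyte,
        }
        if self.meta is not None:
            row.update(
                sample_id=self.meta.sample_id,
                pH=self.meta.pH,
                extract_dose=self.meta.extract_dose,
                replicate=self.meta.replicate,
            )
        return row

    def summary(self) -> str:
        lines = [
            "First-order decay fit",
            "=" * 42,
            f"{'analyte':<14}{self.analyte:>28}",
            f"{'n obs':<14}{self.n_obs:>28d}",
            f"{'C0 (µM)':<14}{self.C0_hat:>28.6g}",
            f"{'k (day⁻¹)':<14}{self.k_hat:>28.6g}",
            f"{'t½ (days)':<14}{self.t_half:>28.6g}",
            f"{'RSS (µM²)':<14}{self.rss:>28.6g}",
            f"{'converged':<14}{str(self.converged):>28}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted decay curve; marks the half-life."""
        ax = _plot_fit(self, ax, f"decay fit: k={self.k_hat:.3g}/day, t½={self.t_half:.3g} d")
        if math.isfinite(self.t_half):
            ax.axvline(self.t_half, ls=":", color="grey", lw=1)
        return ax


@dataclass
class SigmoidResults:
    """Fitted logistic accumulation with inflection and induction statistics."""

    c0_hat: float
    cmax_hat: float
    k_hat: float
    rss: float
    n_obs: int
    converged: bool
    meta: SampleMeta | None = None
    analyte: str = "LOOH"
    times: np.ndarray | None = None
    values: np.ndarray | None = None

    kind = "sigmoid"
    param_names = ("c0_hat", "cmax_hat", "k_hat")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.c0_hat, self.cmax_hat, self.k_hat])

    @property
    def t_star(self) -> float | None:
        """Inflection abscissa (days); ``None`` for a non-converged fit."""
        if not self.converged:
            return None
        return inflection_point((self.c0_hat, self.cmax_hat, self.k_hat))[0]

    @property
    def t_ind(self) -> float | None:
        """Induction period (days) or ``None`` when no induction phase exists."""
        if not self.converged:
            return None
        return induction_time((self.c0_hat, self.cmax_hat, self.k_hat))

    @property
    def inflection_before_start(self) -> bool:
        return self.converged and self.t_star is not None and self.t_star <= 0

    def predict(self, t):
        return sigmoid_value((self.c0_hat, self.cmax_hat, self.k_hat), t)

    def to_row(self) -> dict:
        row = {
            "kind": self.kind,
            "c0_hat": self.c0_hat,
            "cmax_hat": self.cmax_hat,
            "k_hat": self.k_hat,
            "t_star": self.t_star,
            "t_ind": self.t_ind,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "analyte": self.analyte,
        }
        if self.meta is not None:
            row.update(
                sample_id=self.meta.sample_id,
                pH=self.meta.pH,
                extract_dose=self.meta.extract_dose,
                replicate=self.meta.replicate,
            )
        return row

    def summary(self) -> str:
        t_ind = "—" if self.t_ind is None else f"{self.t_ind:.4g}"
        t_star = "—" if self.t_star is None else f"{self.t_star:.4g}"
        lines = [
            "Sigmoidal accumulation fit",
            "=" * 42,
            f"{'analyte':<14}{self.analyte:>28}",
            f"{'n obs':<14}{self.n_obs:>28d}",
            f"{'c0 (µM)':<14}{self.c0_hat:>28.6g}",
            f"{'cmax (µM)':<14}{self.cmax_hat:>28.6g}",
            f"{'k (day⁻¹)':<14}{self.k_hat:>28.6g}",
            f"{'t* (days)':<14}{t_star:>28}",
            f"{'t_ind (days)':<14}{t_ind:>28}",
            f"{'RSS (µM²)':<14}{self.rss:>28.6g}",
            f"{'converged':<14}{str(self.converged):>28}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points, fitted curve, inflection tangent and t_ind."""
        label = f"sigmoid fit: k={self.k_hat:.3g}/day"
        if self.t_ind is not None:
            label += f", t_ind={self.t_ind:.3g} d"
        ax = _plot_fit(self, ax, label)
        if self.converged and self.t_star is not None and self.t_star > 0:
            t_star, c_at, slope = inflection_point((self.c0_hat, self.cmax_hat, self.k_hat))
            span = np.array([max(t_star - 2.5 / self.k_hat, 0.0), t_star + 2.5 / self.k_hat])
            ax.plot(span, c_at + slope * (span - t_star), "--", color="grey", lw=1)
        return ax


def _plot_fit(res, ax, label: str):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if res.times is not None:
        ax.plot(res.times, res.values, "o", ms=4, alpha=0.7, label="observed")
        hi = float(np.max(res.times))
    else:
        hi = 5.0 * (1.0 / res.k_hat if res.k_hat > 0 else 1.0)
    tt = np.linspace(0.0, hi, 200)
    ax.plot(tt, res.predict(tt), "-", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("concentration (µM)")
    ax.legend(fontsize=8)
    return ax


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class _KineticModel:
    """Shared construction: from arrays, a KineticSeries, or a tidy frame."""

    min_points: int = 3

    def __init__(self, times, values, meta: SampleMeta | None = None, analyte: str | None = None):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.values = v[order]
        self.meta = meta
        self.analyte = analyte
        if self.times.size < self.min_points:
            raise FitError(
                f"{type(self).__name__} needs ≥{self.min_points} timepoints, got {self.times.size}"
            )
        if np.unique(self.times).size < self.min_points:
            raise FitError(f"{type(self).__name__} needs ≥{self.min_points} distinct timepoints")
        if self.values.min() < 0:
            raise FitError("negative concentrations are not admissible")

    @classmethod
    def from_series(cls, series: KineticSeries):
        return cls(series.times, series.values, meta=series.meta, analyte=series.analyte)

    @classmethod
    def from_dataframe(cls, df, time_col: str = "day", value_col: str = "value", **kw):
        return cls(df[time_col].to_numpy(float), df[value_col].to_numpy(float), **kw)


class FirstOrderDecay(_KineticModel):
    """Exponential decay model C(t) = C0·e^(−k t) fitted by bounded NLS.

    The fit runs on the original concentration scale so that zero
    observations are admissible; a log-linear regression on the strictly
    positive observations provides the starting values.  ``k`` is bounded
    below by 0: a pinned estimate yields ``t_half = inf`` and sets the
    ``k_at_bound`` flag.
    """

    min_points = 3

    def fit(self) -> DecayResults:
        t, v = self.times, self.values
        if not np.any(v > 0):
            raise FitError("degenerate series: all observations are zero")

        pos = v > 0
        if pos.sum() >= 2 and np.unique(t[pos]).size >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(v[pos]), 1)
            k0 = max(-slope, 0.0)
            C00 = float(np.exp(intercept))
        else:
            k0, C00 = 1.0, float(v.max())
        C00 = min(max(C00, 1e-12), 10.0 * v.max() + 1e-12)

        def resid(p):
            return p[0] * np.exp(-p[1] * t) - v

        sol = least_squares(
            resid,
            x0=[C00, k0],
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        C0_hat, k_hat = float(sol.x[0]), float(sol.x[1])
        k_at_bound = k_hat <= 1e-8  # numerically indistinguishable from the bound
        if k_at_bound:
            k_hat = 0.0
            warnings.warn("decay rate pinned at lower bound 0; t_half reported as inf",
                          RuntimeWarning, stacklevel=2)
        return DecayResults(
            C0_hat=C0_hat,
            k_hat=k_hat,
            rss=float(np.sum(sol.fun**2)),
            n_obs=int(t.size),
            converged=bool(sol.success),
            k_at_bound=k_at_bound,
            meta=self.meta,
            analyte=self.analyte or "anthocyanin",
            times=t.copy(),
            values=v.copy(),
        )


class SigmoidAccumulation(_KineticModel):
    """Logistic accumulation model fitted by multi-start bounded NLS.

    Bounds: ``c0 ∈ [1e-6, 2·min positive observation]``,
    ``cmax ∈ [0.8·max, 3·max]``, ``k > 0``.  Five starts over the
    log-spaced rate grid ``{0.05, 0.2, 0.8, 3.2, 12.8}`` day⁻¹; the
    best-RSS solution wins, ties (relative RSS within 1e-10) broken toward
    the smallest ``k``.  Flat series — range below twice the robust noise
    floor estimated from successive differences — are returned flagged as
    non-converged with derived statistics ``None``.
    """

    min_points = 4

    def fit(self) -> SigmoidResults:
        t, v = self.times, self.values
        vmax = float(v.max())
        if vmax <= 0:
            raise FitError("degenerate series: all observations are zero")

        diffs = np.abs(np.diff(v))
        noise_floor = 1.4826 * float(np.median(diffs)) / math.sqrt(2.0)
        vrange = vmax - float(v.min())
        if vrange <= max(2.0 * noise_floor, 1e-12 + 1e-9 * vmax) and noise_floor < 0.05 * vmax:
            return SigmoidResults(
                c0_hat=float(v.mean()), cmax_hat=vmax * 1.0001 + 1e-9, k_hat=0.0,
                rss=float(np.sum((v - v.mean()) ** 2)), n_obs=int(t.size),
                converged=False, meta=self.meta, analyte=self.analyte or "LOOH",
                times=t.copy(), values=v.copy(),
            )

        min_pos = float(v[v > 0].min())
        # upper bound on c0 from the early-time level: twice the larger of the
        # smallest positive observation and the mean at the first timepoint
        # (zero-truncated noise can push single observations far below c0)
        first_mean = float(v[t == t.min()].mean())
        c0_hi = 2.0 * max(min_pos, first_mean, C0_FLOOR)
        lb = [C0_FLOOR, 0.8 * vmax, 1e-6]
        ub = [c0_hi, 3.0 * vmax, np.inf]

        def resid(p):
            A = (p[1] - p[0]) / p[0]
            return p[1] / (1.0 + A * np.exp(-p[2] * t)) - v

        c0_start = min(max(first_mean, min_pos, 2.0 * C0_FLOOR), c0_hi)
        best = None
        for k0 in K_STARTS:
            sol = least_squares(
                resid,
                x0=[c0_start, min(max(vmax, lb[1]), ub[1]), k0],
                bounds=(lb, ub),
                method="trf",
                xtol=1e-12, ftol=1e-10, gtol=1e-12,
            )
            rss = float(np.sum(sol.fun**2))
            if best is None:
                best = (rss, sol)
            else:
                best_rss = best[0]
                scale = max(best_rss, rss, 1e-300)
                if rss < best_rss - 1e-10 * scale:
                    best = (rss, sol)
                elif abs(rss - best_rss) <= 1e-10 * scale and sol.x[2] < best[1].x[2]:
                    best = (rss, sol)

        rss, sol = best
        c0_hat, cmax_hat, k_hat = (float(x) for x in sol.x)
        if cmax_hat <= c0_hat:  # degenerate corner; treat as non-converged
            cmax_hat = c0_hat * (1 + 1e-9)
            converged = False
        else:
            converged = bool(sol.success)
        return SigmoidResults(
            c0_hat=c0_hat, cmax_hat=cmax_hat, k_hat=k_hat,
            rss=rss, n_obs=int(t.size), converged=converged,
            meta=self.meta, analyte=self.analyte or "LOOH",
            times=t.copy(), values=v.copy(),
        )


# ---------------------------------------------------------------------------
# functional façade and replicate aggregation
# ---------------------------------------------------------------------------

def fit_decay(series: KineticSeries) -> DecayResults:
    """Fit first-order decay to one replicate series."""
    return FirstOrderDecay.from_series(series).fit()


def fit_sigmoid(series: KineticSeries) -> SigmoidResults:
    """Fit the logistic accumulation model to one replicate series."""
    return SigmoidAccumulation.from_series(series).fit()


def _condition_key(fit):
    if fit.meta is None:
        return (fit.analyte,)
    return (fit.analyte, fit.meta.pH, fit.meta.extract_dose)


def aggregate_replicates(fits: Sequence) -> dict:
    """Mean ± SD of parameters and derived statistics across replicate fits.

    All fits must share the model kind and the condition (analyte, pH,
    extract dose).  For decay fits the summary carries **both**
    ``t_half_mean`` — the mean of per-replicate half-lives — and
    ``t_half_of_mean_k = ln2 / mean(k)``.  These differ whenever the
    replicate rate constants differ (Jensen's inequality: 1/k is convex),
    so averaging per-replicate half-lives is not the same as inverting the
    averaged rate; reports must carry both.

    For sigmoid fits, induction times of ``None`` (no induction phase) are
    excluded from the t_ind average; if no replicate has one, ``t_ind_mean``
    is ``None``.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValidationError("aggregate_replicates requires ≥2 replicate fits")
    kinds = {f.kind for f in fits}
    if len(kinds) != 1:
        raise ValidationError(f"mixed fit kinds {kinds}")
    keys = {_condition_key(f) for f in fits}
    if len(keys) != 1:
        raise ValidationError(f"mixed conditions {keys}")

    kind = fits[0].kind
    out: dict = {"kind": kind, "n": len(fits), "analyte": fits[0].analyte}
    if fits[0].meta is not None:
        out["pH"] = fits[0].meta.pH
        out["extract_dose"] = fits[0].meta.extract_dose

    for name in fits[0].param_names:
        vals = np.array([getattr(f, name) for f in fits], dtype=float)
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=1))

    if kind == "decay":
        th = np.array([f.t_half for f in fits], dtype=float)
        out["t_half_mean"] = float(th.mean())
        out["t_half_sd"] = float(th.std(ddof=1))
        k_mean = out["k_hat_mean"]
        out["t_half_of_mean_k"] = math.inf if k_mean <= 0 else LN2 / k_mean
    else:
        ts = np.array([f.t_star for f in fits if f.t_star is not None], dtype=float)
        if ts.size:
            out["t_star_mean"] = float(ts.mean())
            out["t_star_sd"] = float(ts.std(ddof=1)) if ts.size > 1 else 0.0
        tind = np.array([f.t_ind for f in fits if f.t_ind is not None], dtype=float)
        out["n_t_ind"] = int(tind.size)
        if tind.size:
            out["t_ind_mean"] = float(tind.mean())
            out["t_ind_sd"] = float(tind.std(ddof=1)) if tind.size > 1 else 0.0
        else:
            out["t_ind_mean"] = None
            out["t_ind_sd"] = None
    return out
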
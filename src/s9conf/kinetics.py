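"""Kitz-Wilson analysis of irreversible enzyme inhibition.

The two-step mechanism E + I <-(Ki)-> EI -(k2)-> EI' under pseudo-first-order
conditions ([I] >> [E]) gives exponential loss of activity,
ln[E] = -k't + ln[E0], with the apparent rate constant saturating in inhibitor
concentration: k' = k2 [I] / (Ki + [I]). Linearizing, 1/k' = (Ki/k2)(1/[I]) +
1/k2, so an ordinary least-squares line through (1/[I], 1/k') yields
k2 = 1/intercept and Ki = slope * k2.

Unit convention: concentrations enter in uM, k' and k2 are per minute, and Ki
is reported in mM (the scale on which inhibition constants of chloromethyl
ketones are quoted); the uM -> mM conversion is explicit in the fit report.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats


class KineticsError(Exception):
    pass


@dataclasses.dataclass
class InactivationSeries:
    """Residual-activity time course at one inhibitor concentration.

    ``activity`` is the fraction of initial activity [E]/[E0], in (0, 1];
    times in minutes, concentration in uM.
    """

    conc_uM: float
    times_min: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.conc_uM <= 0:
            raise KineticsError("inhibitor concentration must be positive")
        if self.times_min.shape != self.activity.shape:
            raise KineticsError("times and activities must have equal length")
        if np.any(self.times_min < 0) or np.any(np.diff(self.times_min) <= 0):
            raise KineticsError("times must be non-negative and strictly increasing")
        if np.any(self.activity <= 0):
            raise KineticsError("activities must be positive (log-linear fit undefined at 0)")
        if np.any(self.activity > 1.0 + 1e-9):
            raise KineticsError("activities are fractions of initial and cannot exceed 1")


@dataclasses.dataclass
class PseudoFirstOrderFit:
    conc_uM: float
    k_prime: float          # min^-1
    r_squared: float
    no_inactivation: bool   # flagged when the fitted slope is >= 0


def fit_pseudo_first_order(series: InactivationSeries) -> PseudoFirstOrderFit:
    """k' from the ordinary least-squares slope of ln(activity) on time."""
    if len(series.times_min) < 3:
        raise KineticsError("need at least 3 time points")
    res = stats.linregress(series.times_min, np.log(series.activity))
    k_prime = -res.slope
    return PseudoFirstOrderFit(
        conc_uM=series.conc_uM,
        k_prime=float(max(k_prime, 0.0)),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
        no_inactivation=k_prime <= 0,
    )


@dataclasses.dataclass
class KineticsFit:
    Ki_mM: float
    k2_per_min: float
    slope: float            # Ki/k2 in uM*min (double-reciprocal slope)
    intercept: float        # 1/k2 in min
    r_squared: float
    per_series: list[PseudoFirstOrderFit]
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "Ki_mM": self.Ki_mM,
            "k2_per_min": self.k2_per_min,
            "reciprocal_slope_uM_min": self.slope,
            "reciprocal_intercept_min": self.intercept,
            "r_squared": self.r_squared,
            "degenerate": self.degenerate,
            "k_prime_per_min": {f.conc_uM: f.k_prime for f in self.per_series},
        }


def fit_kitz_wilson(
    pairs: list[tuple[float, float]] | list[PseudoFirstOrderFit],
) -> KineticsFit:
    """Double-reciprocal fit of ([I] uM, k' min^-1) pairs.

    OLS of 1/k' on 1/[I]; k2 = 1/intercept, Ki = slope * k2 (converted to
    mM). A non-positive intercept means the data never approach saturation
    and k2 is not identifiable. A zero slope (k' independent of [I]) is
    flagged degenerate with Ki = 0.
    """
    fits = [
        p if isinstance(p, PseudoFirstOrderFit) else PseudoFirstOrderFit(p[0], p[1], 1.0, p[1] <= 0)
        for p in pairs
    ]
    concs = np.array([f.conc_uM for f in fits])
    kps = np.array([f.k_prime for f in fits])
    if len(np.unique(concs)) < 3:
        raise KineticsError("need k' at >= 3 distinct inhibitor concentrations")
    if np.any(kps <= 0):
        raise KineticsError("all k' must be positive for the reciprocal fit")
    res = stats.linregress(1.0 / concs, 1.0 / kps)
    slope, intercept = float(res.slope), float(res.intercept)
    if intercept <= 0:
        raise KineticsError(
            "saturation not identifiable: non-positive reciprocal intercept"
        )
    k2 = 1.0 / intercept
    Ki_uM = slope * k2
    degenerate = abs(slope) < 1e-12 or Ki_uM <= 0
    return KineticsFit(
        Ki_mM=max(Ki_uM, 0.0) / 1000.0,
        k2_per_min=k2,
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        per_series=fits,
        degenerate=degenerate,
    )


def analyze_inactivation(series_list: list[InactivationSeries]) -> KineticsFit:
    """Full pipeline: per-concentration k' fits, then the reciprocal fit."""
    return fit_kitz_wilson([fit_pseudo_first_order(s) for s in series_list])


def fit_saturation_nonlinear(
    pairs: list[tuple[float, float]],
) -> tuple[float, float]:
    """Direct nonlinear fit of k' = k2 [I] / (Ki + [I]); cross-check for the
    double-reciprocal estimator, not the headline fit. Returns (Ki_mM, k2)."""
    concs = np.array([c for c, _ in pairs], dtype=float)
    kps = np.array([k for _, k in pairs], dtype=float)
    p0 = (np.median(concs), kps.max() * 1.5)
    popt, _ = optimize.curve_fit(
        lambda I, Ki, k2: k2 * I / (Ki + I), concs, kps, p0=p0, maxfev=10000
    )
    Ki_uM, k2 = popt
    return float(Ki_uM) / 1000.0, float(k2)


def read_series_csv(path) -> list[InactivationSeries]:
    """Read time courses from CSV with columns conc_uM, time_min,
    activity_frac (one row per measurement)."""
    df = pd.read_csv(path)
    required = {"conc_uM", "time_min", "activity_frac"}
    missing = required - set(df.columns)
    if missing:
        raise KineticsError(f"CSV missing columns: {sorted(missing)}")
    out = []
    for conc, grp in df.groupby("conc_uM"):
        grp = grp.sort_values("time_min")
        out.append(
            InactivationSeries(
                conc_uM=float(conc),
                times_min=grp["time_min"].to_numpy(),
                activity=grp["activity_frac"].to_numpy(),
            )
        )
    return out
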
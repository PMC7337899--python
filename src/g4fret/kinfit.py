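"""Ensemble kinetic estimators: survival decay, Michaelis-Menten, RecA assembly.

Spot-survival series are fitted with

    N(t) = N0 * (f * exp(-k t) + 1 - f),

where ``f`` is the fraction of molecules competent to complete unwinding
(fixed at 1 unless a plateau is evident), ``k`` in 1/min.  Unwinding
rates across an ATP titration are fitted with the Michaelis-Menten law
``r = Vmax * a / (Km + a)``.  RecA assembly kinetics reduce histogram
time series to the low-FRET fraction, its plateau and the half-time at
which half the plateau is reached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .detection import SpotCountSeries
from .fretstats import FretHistogram

__all__ = [
    "DecayFit",
    "MMFit",
    "AssemblyKinetics",
    "fit_decay",
    "fit_mm",
    "assembly_kinetics",
]


@dataclass
class DecayFit:
    """Single-exponential (optionally plateaued) spot-survival fit."""

    k_per_min: float
    f_active: float
    n0: float
    k_se: float
    f_se: float
    n0_se: float
    rss: float
    converged: bool
    plateau_fitted: bool

    def ci95_k(self) -> tuple:
        return (self.k_per_min - 1.96 * self.k_se, self.k_per_min + 1.96 * self.k_se)


def _decay_model(t_min, n0, k, f):
    return n0 * (f * np.exp(-k * t_min) + 1.0 - f)


def fit_decay(
    series: SpotCountSeries,
    fit_plateau: Optional[bool] = None,
    use_smoothed: bool = False,
) -> DecayFit:
    """Nonlinear least-squares fit of the spot-survival decay.

    ``fit_plateau=None`` enables the plateau term automatically when the
    terminal fraction exceeds 0.2 (substrates like T9 leave a large
    protein-bound but unwound-incompetent population).  The fit uses the
    raw counts by default; ``use_smoothed=True`` fits the window-3
    smoothed series instead (the smoothing correlates neighboring
    residuals, so the reported standard errors are then optimistic).
    """
    if use_smoothed:
        if series.too_short:
            raise ValueError("series too short for smoothing; need >= 3 points")
        t_min = series.t_smooth_s / 60.0
        y = series.smoothed
    else:
        t_min = series.t_s / 60.0
        y = series.counts.astype(float)
    if series.too_short or series.smoothed.size < 4:
        if t_min.size < 4:
            raise ValueError("need >= 4 points for the decay fit")
    n0_0 = float(np.max(y))
    terminal = float(y[-1] / n0_0) if n0_0 > 0 else 0.0
    if fit_plateau is None:
        fit_plateau = terminal > 0.2

    f0 = float(np.clip(1.0 - terminal, 0.05, 1.0)) if fit_plateau else 1.0
    # log-linear initialization for k on the early decaying part
    floor = n0_0 * (1.0 - f0)
    resid0 = np.maximum(y - floor, n0_0 * 1e-3)
    early = t_min <= (t_min[0] + 0.6 * (t_min[-1] - t_min[0]))
    if early.sum() >= 2 and np.ptp(t_min[early]) > 0:
        slope = np.polyfit(t_min[early], np.log(resid0[early]), 1)[0]
        k0 = float(np.clip(-slope, 1e-3, 1e3))
    else:
        k0 = 0.5

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fit_plateau:
                popt, pcov = curve_fit(
                    _decay_model, t_min, y,
                    p0=[n0_0, k0, f0],
                    bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, 1.0]),
                    maxfev=20000,
                )
                n0, k, f = popt
                ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
                n0_se, k_se, f_se = ses
            else:
                popt, pcov = curve_fit(
                    lambda t, n0, k: _decay_model(t, n0, k, 1.0),
                    t_min, y, p0=[n0_0, k0],
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    maxfev=20000,
                )
                n0, k = popt
                f = 1.0
                ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
                n0_se, k_se = ses
                f_se = 0.0
    except RuntimeError:
        converged = False
        n0, k, f = n0_0, k0, f0
        n0_se = k_se = f_se = math.inf
    if not np.all(np.isfinite([n0_se, k_se])):
        converged = False
    rss = float(np.sum((y - _decay_model(t_min, n0, k, f)) ** 2))
    return DecayFit(
        k_per_min=float(k), f_active=float(f), n0=float(n0),
        k_se=float(k_se), f_se=float(f_se), n0_se=float(n0_se),
        rss=rss, converged=converged, plateau_fitted=bool(fit_plateau),
    )


@dataclass
class MMFit:
    """Michaelis-Menten fit of unwinding rate versus ATP concentration."""

    vmax_per_min: float
    km_um: float
    vmax_se: float
    km_se: float
    rss: float
    ill_conditioned: bool = False


def fit_mm(atp_um: Sequence[float], rates_per_min: Sequence[float]) -> MMFit:
    """Least-squares fit of ``r = Vmax * a / (Km + a)``.

    Requires at least three distinct ATP concentrations; initialization
    takes ``Vmax`` from the largest rate and ``Km`` from the ATP value at
    half-maximum by interpolation.
    """
    a = np.asarray(atp_um, dtype=float)
    r = np.asarray(rates_per_min, dtype=float)
    if a.shape != r.shape:
        raise ValueError("atp and rates must have equal length")
    if np.unique(a).size < 3:
        raise ValueError("need >= 3 distinct ATP concentrations")
    ill = bool(np.allclose(r, r[0]))

    vmax0 = float(np.max(r))
    order = np.argsort(a)
    half = vmax0 / 2.0
    km0 = float(np.interp(half, r[order], a[order])) if vmax0 > 0 else 1.0
    km0 = float(np.clip(km0, np.min(a[a > 0], initial=1.0), np.max(a)))

    def mm(a_, vmax, km):
        return vmax * a_ / (km + a_)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            mm, a, r, p0=[max(vmax0, 1e-6), max(km0, 1e-3)],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    vmax, km = popt
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    if not np.all(np.isfinite(ses)):
        ill = True
    rss = float(np.sum((r - mm(a, vmax, km)) ** 2))
    return MMFit(
        vmax_per_min=float(vmax), km_um=float(km),
        vmax_se=float(ses[0]), km_se=float(ses[1]), rss=rss, ill_conditioned=ill,
    )


@dataclass
class AssemblyKinetics:
    """RecA filament-formation kinetics from a histogram time series."""

    times_min: np.ndarray
    fractions: np.ndarray
    fractions_isotonic: np.ndarray
    plateau: float
    t_half_min: float  # NaN when half-plateau is never crossed


def assembly_kinetics(
    hists: Sequence[FretHistogram],
    times_s: Optional[Sequence[float]] = None,
    boundary_e: float = 0.15,
) -> AssemblyKinetics:
    """Assembled fraction over time, plateau and half-time.

    The assembled fraction at each time is the histogram mass below
    ``boundary_e`` (the filament-stretched low-FRET population).  A
    nondecreasing (isotonic) envelope defines the plateau as its final
    value; ``t_half`` is the linear-interpolation crossing of half the
    plateau.
    """
    if len(hists) < 3:
        raise ValueError("need >= 3 time points for assembly kinetics")
    if times_s is None:
        times_s = [h.t_s for h in hists]
        if any(t is None for t in times_s):
            raise ValueError("histograms lack time labels; pass times_s")
    t = np.asarray(times_s, dtype=float) / 60.0
    frac = np.array([h.mass_below(boundary_e) for h in hists])
    iso = np.maximum.accumulate(frac)
    plateau = float(iso[-1])
    half = plateau / 2.0
    if plateau <= 0 or not np.any(iso >= half):
        t_half = float("nan")
    else:
        idx = int(np.argmax(iso >= half))
        if idx == 0:
            t_half = float(t[0])
        else:
            t0, t1 = t[idx - 1], t[idx]
            f0, f1 = iso[idx - 1], iso[idx]
            t_half = float(t0 + (half - f0) / max(f1 - f0, 1e-12) * (t1 - t0))
    return AssemblyKinetics(
        times_min=t, fractions=frac, fractions_isotonic=iso,
        plateau=plateau, t_half_min=t_half,
    )
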
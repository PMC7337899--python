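"""Per-molecule FRET, ALEX donor-only filtering, histograms and Gaussian fits.

The apparent FRET of a molecule is computed from the first ten
green-excitation frames after leakage correction,

    E = (I_A - l * I_D) / ((I_A - l * I_D) + I_D),

clipped to [-0.1, 1.1].  The leakage fraction ``l`` can be supplied or
estimated from the donor-only population (molecules with no direct
acceptor signal under red excitation), whose mean apparent E equals
``l / (1 + l)``.  Histograms are area-normalized; mixtures of Gaussians
are fitted to the binned densities with free or restrained centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from lmfit.models import GaussianModel

from .photophysics import IntensityTrace

__all__ = [
    "molecule_fret",
    "filter_donor_only",
    "estimate_leakage",
    "FretHistogram",
    "build_histogram",
    "GaussComponent",
    "GaussianMixFit",
    "fit_gaussians",
]


def molecule_fret(
    trace: IntensityTrace,
    leakage: float = 0.0,
    n_frames: int = 10,
    min_total: float = 20.0,
) -> float:
    """Leakage-corrected apparent FRET of one molecule.

    Averages donor and acceptor over the first ``n_frames`` green frames
    (background-subtracted), applies the leakage correction and clips to
    [-0.1, 1.1].  Returns NaN for traces with fewer than five usable green
    frames or with total signal below ``min_total`` (all-background
    traces), which are excluded downstream.
    """
    g = np.flatnonzero(trace.green)[:n_frames]
    if g.size < 5:
        return float("nan")
    i_d = float(np.mean(trace.donor[g]) - trace.background)
    i_a = float(np.mean(trace.acceptor[g]) - trace.background)
    fc = i_a - leakage * i_d
    total = fc + i_d
    if total < min_total:
        return float("nan")
    return float(np.clip(fc / total, -0.1, 1.1))


def filter_donor_only(trace: IntensityTrace, red_threshold: float = 50.0) -> bool:
    """Keep a molecule iff it shows direct acceptor signal under red excitation.

    Red-excitation acceptor emission is independent of FRET, so its absence
    identifies donor-only molecules (dark or photobleached acceptor).
    Traces without red frames are kept with a warning — they cannot be
    filtered.
    """
    r = np.flatnonzero(trace.red)
    if r.size == 0:
        warnings.warn(
            "trace has no red-excitation frames; donor-only filtering skipped",
            stacklevel=2,
        )
        return True
    return float(np.mean(trace.acceptor[r]) - trace.background) > red_threshold


def estimate_leakage(
    traces: Sequence[IntensityTrace],
    red_threshold: float = 50.0,
    n_frames: int = 10,
) -> float:
    """Estimate donor leakage from the donor-only population.

    Donor-only molecules have ``I_A = l * I_D``, hence an uncorrected
    apparent E of ``l / (1 + l)``; inverting the population mean gives
    ``l``.  Raises if no donor-only molecules are present.
    """
    es = [
        molecule_fret(tr, leakage=0.0, n_frames=n_frames)
        for tr in traces
        if not filter_donor_only(tr, red_threshold)
    ]
    es = [e for e in es if np.isfinite(e)]
    if not es:
        raise ValueError("no donor-only molecules found; cannot estimate leakage")
    e = float(np.mean(es))
    return e / (1.0 - e)


@dataclass
class FretHistogram:
    """Area-normalized population FRET histogram."""

    edges: np.ndarray
    density: np.ndarray
    n_molecules: int
    condition: str = ""
    t_s: Optional[float] = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def mass_below(self, boundary: float) -> float:
        """Probability mass at FRET values below ``boundary``."""
        width = np.diff(self.edges)
        frac = np.clip((boundary - self.edges[:-1]) / width, 0.0, 1.0)
        return float(np.sum(self.density * width * frac))


def build_histogram(
    e_values: Sequence[float],
    bin_width: float = 0.02,
    e_range: Tuple[float, float] = (0.0, 1.0),
    condition: str = "",
    t_s: Optional[float] = None,
) -> FretHistogram:
    """Area-normalized histogram of per-molecule FRET values.

    NaN entries (undefined molecules) are dropped; remaining values are
    clipped into the histogram range so correction overshoot lands in the
    edge bins.  Raises on empty input.
    """
    e = np.asarray(e_values, dtype=float)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValueError("no valid FRET values to histogram")
    lo, hi = e_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    clipped = np.clip(e, lo, hi - 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    density = counts / (e.size * bin_width)
    return FretHistogram(
        edges=edges, density=density, n_molecules=int(e.size),
        condition=condition, t_s=t_s,
    )


@dataclass
class GaussComponent:
    center: float
    sigma: float
    weight: float  # area under the component


@dataclass
class GaussianMixFit:
    """Least-squares Gaussian mixture fit to a binned FRET density."""

    components: List[GaussComponent]
    restrained: bool
    rss: float
    ill_conditioned: bool = False

    @property
    def dominant(self) -> GaussComponent:
        return max(self.components, key=lambda c: c.weight)


def _initial_centers(hist: FretHistogram, k: int) -> List[float]:
    d = hist.density
    # light smoothing to suppress single-bin noise peaks
    sm = np.convolve(d, np.ones(3) / 3.0, mode="same")
    interior = (sm[1:-1] >= sm[:-2]) & (sm[1:-1] >= sm[2:])
    peak_idx = np.flatnonzero(interior) + 1
    peak_idx = peak_idx[np.argsort(-sm[peak_idx])]
    centers = list(hist.centers[peak_idx[:k]])
    while len(centers) < k:
        q = (len(centers) + 1.0) / (k + 1.0)
        centers.append(float(hist.edges[0] + q * (hist.edges[-1] - hist.edges[0])))
    return centers


def fit_gaussians(
    hist: FretHistogram,
    k: int = 1,
    restrained_centers: Optional[Sequence[float]] = None,
) -> GaussianMixFit:
    """Fit ``k`` Gaussian components to the binned density.

    With ``restrained_centers`` the component centers are held fixed (used
    for RecA-bound time series where the end-point fit defines them).
    Components are returned sorted by center.  The fit is flagged
    ill-conditioned when the requested components exceed the
    distinguishable support or the covariance cannot be estimated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    restrained = restrained_centers is not None
    if restrained and len(restrained_centers) != k:
        raise ValueError("restrained_centers must have length k")
    x = hist.centers
    y = hist.density

    occupied = int(np.sum(y > 0))
    ill = k > max(occupied, 1)

    if restrained:
        centers0 = list(restrained_centers)
    else:
        centers0 = _initial_centers(hist, k)
    model = None
    params = None
    for i, c0 in enumerate(centers0):
        gm = GaussianModel(prefix=f"g{i}_")
        p = gm.make_params(
            center=c0, sigma=0.05, amplitude=max(float(np.max(y)) * 0.1, 1e-3)
        )
        p[f"g{i}_center"].set(min=-0.1, max=1.1, vary=not restrained)
        p[f"g{i}_sigma"].set(min=hist.bin_width / 2.0, max=0.5)
        p[f"g{i}_amplitude"].set(min=0.0)
        if model is None:
            model, params = gm, p
        else:
            model = model + gm
            params.update(p)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, x=x)
    comps = []
    for i in range(k):
        comps.append(
            GaussComponent(
                center=float(result.params[f"g{i}_center"].value),
                sigma=float(result.params[f"g{i}_sigma"].value),
                weight=float(result.params[f"g{i}_amplitude"].value),
            )
        )
    comps.sort(key=lambda c: c.center)
    if result.covar is None and not restrained and k > 1:
        ill = True
    rss = float(np.sum(result.residual**2))
    return GaussianMixFit(components=comps, restrained=restrained, rss=rss,
                          ill_conditioned=ill)
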
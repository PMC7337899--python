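"""Per-trace stage segmentation of real-time flow unwinding traces.

A productive trace passes through four stages: (I) protein binding,
detected as the PIFE donor-intensity step; (II) repetitive G4
unfolding/refolding, visible as FRET fluctuation between the folded and
transiently-unfolded levels; (III) duplex unwinding, a monotone FRET
decline to the unwound level; (IV) strand release, the donor drop to
background.  The ligand protocol adds a low-FRET dislodging lag between
binding and the fluctuation.

Boundary estimation works in leakage-corrected apparent-FRET space.
Because PIFE multiplies the donor, a state with true FRET E appears at

    E_app = E / (E + (1 - E) * pife)

while a protein is bound; the expected state levels are derived from the
rendering parameters.  The stage-II/III boundary is the last down-crossing
of the folded/unfolded midlevel (after it the trace never returns to the
folded level), interpolated between frame centers.  Since frame values
are time averages (a zero-phase box filter), midlevel crossings of steps
and linear ramps are preserved, so the stage-III dwell is estimated
without frame-quantization bias as twice the interval from the commit
crossing to the ramp-midpoint crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel

from .photophysics import IntensityTrace, PhotoParams, bare_fret
from .substrates import Substrate

__all__ = [
    "SegmentationConfig",
    "StageSegments",
    "DwellTable",
    "detect_binding",
    "segment_stages",
    "segment_traces",
    "build_dwell_table",
    "stage_rates",
    "dwell_histogram",
    "apparent_level",
]

STAGES = ("binding", "g4_resolution", "duplex_unwinding", "release")


def apparent_level(e_true: float, pife: float) -> float:
    """Leakage-corrected apparent FRET of a bound state with true FRET ``e_true``."""
    return e_true / (e_true + (1.0 - e_true) * pife)


@dataclass
class SegmentationConfig:
    """Thresholds and expected levels for stage segmentation.

    Levels are in leakage-corrected apparent-FRET space.  Build from the
    rendering parameters with :meth:`from_photo` so the thresholds match
    the simulated photophysics.
    """

    leakage: float = 0.08
    pife_factor: float = 1.4
    e_folded: float = 0.50
    e_unfolded: float = 0.35
    e_unwound: float = 0.10
    e_ligand: float = 0.20
    e_bare: float = 0.50
    has_g4: bool = True
    pife_threshold: float = 1.2
    pife_consecutive: int = 5
    release_fraction: float = 0.25
    release_consecutive: int = 5
    var_window: int = 10
    var_factor: float = 3.0
    min_fluctuation_s: float = 1.0

    @classmethod
    def from_photo(cls, photo: PhotoParams, substrate: Substrate) -> "SegmentationConfig":
        return cls(
            leakage=photo.leakage,
            pife_factor=photo.pife_factor,
            e_folded=photo.e_folded,
            e_unfolded=photo.e_unfolded,
            e_unwound=photo.e_unwound,
            e_ligand=photo.e_ligand,
            e_bare=bare_fret(substrate, photo),
            has_g4=substrate.has_g4,
        )

    # --- derived apparent levels -----------------------------------------
    @property
    def level_folded(self) -> float:
        e = self.e_folded if self.has_g4 else self.e_bare
        return apparent_level(e, self.pife_factor)

    @property
    def level_unfolded(self) -> float:
        return apparent_level(self.e_unfolded, self.pife_factor)

    @property
    def level_unwound(self) -> float:
        return apparent_level(self.e_unwound, self.pife_factor)

    @property
    def level_ligand(self) -> float:
        return apparent_level(self.e_ligand, self.pife_factor)

    @property
    def threshold_commit(self) -> float:
        """Midlevel separating the folded state from the unwinding ramp."""
        if self.has_g4:
            return 0.5 * (self.level_folded + self.level_unfolded)
        # no G4: the ramp starts at the bare bound level; use a level near
        # the ramp top so the crossing marks the decline onset
        top = 0.9 * self.e_bare + 0.1 * self.e_unwound
        return apparent_level(top, self.pife_factor)

    @property
    def threshold_ramp_mid(self) -> float:
        """Apparent level of the true-FRET midpoint of the unwinding ramp."""
        start = self.e_unfolded if self.has_g4 else self.e_bare
        return apparent_level(0.5 * (start + self.e_unwound), self.pife_factor)

    @property
    def threshold_lag_exit(self) -> float:
        return 0.5 * (self.level_ligand + self.level_unfolded)


@dataclass
class StageSegments:
    """Stage boundary times (s) of one trace; NaN marks absent events."""

    t_flow: float
    t_bind: float = math.nan
    t_lag_end: float = math.nan
    t_g4_start: float = math.nan
    t_g4_end: float = math.nan
    t_dup_end: float = math.nan
    t_release: float = math.nan
    has_fluctuation: bool = False
    fluctuation_s: float = 0.0
    accepted: bool = False
    reason: str = ""
    molecule_id: int = 0

    @property
    def stage_i(self) -> float:
        return self.t_bind - self.t_flow

    @property
    def stage_ii(self) -> float:
        return self.t_g4_end - self.t_bind

    @property
    def stage_iii(self) -> float:
        return self.t_dup_end - self.t_g4_end

    @property
    def stage_iv(self) -> float:
        return self.t_release - self.t_dup_end

    def to_dict(self) -> Dict[str, float]:
        return {
            "molecule_id": self.molecule_id,
            "t_flow": self.t_flow,
            "t_bind": self.t_bind,
            "t_lag_end": self.t_lag_end,
            "t_g4_end": self.t_g4_end,
            "t_dup_end": self.t_dup_end,
            "t_release": self.t_release,
            "stage_i": self.stage_i,
            "stage_ii": self.stage_ii,
            "stage_iii": self.stage_iii,
            "stage_iv": self.stage_iv,
            "has_fluctuation": self.has_fluctuation,
            "accepted": self.accepted,
            "reason": self.reason,
        }


def _corrected_e(
    trace: IntensityTrace, leakage: float, min_total: float = 30.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Leakage-corrected apparent FRET at green-frame centers.

    Frames whose total signal falls below ``min_total`` counts carry no
    FRET information (released or photobleached molecule) and are set to
    zero rather than left as an ill-conditioned ratio.
    """
    g = trace.green
    i_d = trace.donor[g] - trace.background
    i_a = trace.acceptor[g] - trace.background
    fc = i_a - leakage * i_d
    total = fc + i_d
    e = np.where(total >= min_total, fc / np.maximum(total, 1e-9), 0.0)
    tc = trace.t[g] + trace.frame_s / 2.0
    return tc, e


def _first_run(mask: np.ndarray, length: int) -> int:
    """Index of the first run of ``length`` consecutive True values, or -1."""
    if mask.size < length:
        return -1
    run = 0
    for i, v in enumerate(mask):
        run = run + 1 if v else 0
        if run >= length:
            return i - length + 1
    return -1


def detect_binding(
    trace: IntensityTrace,
    t_flow: float,
    config: Optional[SegmentationConfig] = None,
) -> float:
    """PIFE-based binding time: earliest time after flow where the donor
    stays at or above ``pife_threshold`` times the pre-flow median for at
    least ``pife_consecutive`` consecutive green frames.  NaN if never.
    """
    config = config or SegmentationConfig()
    g = trace.green
    t = trace.t[g]
    donor = trace.donor[g] - trace.background
    pre = donor[t < t_flow]
    if pre.size < 3:
        raise ValueError("need >= 3 pre-flow green frames to detect binding")
    med = float(np.median(pre))
    post = t >= t_flow
    cond = donor[post] >= config.pife_threshold * med
    idx = _first_run(cond, config.pife_consecutive)
    if idx < 0:
        return math.nan
    return float(t[post][idx])


def _last_downcross(tc: np.ndarray, e: np.ndarray, level: float) -> float:
    """Interpolated time of the last crossing of ``level`` from above.

    Frame values are box-filtered samples at frame centers, so linear
    interpolation between the last sample at/above the level and the next
    one approximates the zero-phase crossing of the underlying signal.
    Returns NaN when the trace never sits at/above the level.
    """
    above = np.flatnonzero(e >= level)
    if above.size == 0:
        return math.nan
    i = above[-1]
    if i == len(e) - 1:
        return float(tc[i])
    e0, e1 = e[i], e[i + 1]
    frac = (e0 - level) / max(e0 - e1, 1e-12)
    frac = min(max(frac, 0.0), 1.0)
    return float(tc[i] + frac * (tc[i + 1] - tc[i]))


def _refine_decline(
    tw: np.ndarray,
    ew: np.ndarray,
    t_coarse: float,
    config: SegmentationConfig,
    frame_s: float,
    t_release: float,
    t0_lo: float = -0.35,
    t0_hi: float = 0.35,
) -> Tuple[float, float]:
    """Least-squares refinement of the commit time and stage-III dwell.

    Fits the frame-averaged piecewise model — constant pre-commit level,
    linear apparent-FRET decline of duration ``d``, constant unwound
    level — to the samples around the coarse commit crossing.  This keeps
    the dwell estimate unbiased even when the decline completes within a
    single frame, where threshold crossings alone cannot resolve it.
    Returns ``(t_commit, dwell)``.
    """
    level_r = (
        config.level_unfolded if config.has_g4
        else apparent_level(config.e_bare, config.pife_factor)
    )
    level_u = config.level_unwound

    # Window: the trailing pre-commit run at the folded level when it is
    # resolvable; otherwise (a sub-frame folded flash before commitment)
    # back to the last sub-midlevel frame, so the final transiently
    # unfolded dwell anchors the free pre-commit level instead of being
    # absorbed into the ramp.
    lo = t_coarse + t0_lo - 0.7
    pre = np.flatnonzero((tw < t_coarse) & (tw >= lo))
    run = 0
    for j in pre[::-1]:
        if ew[j] >= config.threshold_commit:
            run += 1
        else:
            break
    threshold_back = (
        config.threshold_commit if run >= 3 else config.threshold_ramp_mid
    )
    for j in pre[::-1]:
        if ew[j] < threshold_back:
            lo = tw[j] + frame_s / 2.0
            break
    hi = min(t_coarse + 3.0, t_release - 0.1, tw[-1])
    m = (tw >= lo) & (tw <= hi)
    t = tw[m]
    y = ew[m]
    if t.size < 4:
        return t_coarse, frame_s

    ss = 5
    offs = (np.arange(ss) + 0.5) / ss * frame_s - frame_s / 2.0
    tt = t[None, :, None] + offs[None, None, :]

    def sse(t0s: np.ndarray, ds: np.ndarray) -> np.ndarray:
        # Frame value = box average (supersampled).  The pre-commit level
        # L is free and enters linearly: model = ramp_part + L * pre_frac,
        # so the optimal L is solved in closed form per (t0, d).
        t0 = t0s[:, None, None]
        d = ds[:, None, None]
        pre_mask = tt < t0
        frac = np.clip((tt - t0) / d, 0.0, 1.0)
        ramp = np.where(pre_mask, 0.0, level_r + (level_u - level_r) * frac)
        a = ramp.mean(axis=2)
        b = pre_mask.mean(axis=2)
        bb = (b * b).sum(axis=1)
        lvl = np.where(
            bb > 1e-9, (b * (y[None, :] - a)).sum(axis=1) / np.maximum(bb, 1e-9), 0.0
        )
        lvl = np.clip(lvl, level_u, 1.0)
        model = a + lvl[:, None] * b
        return ((model - y[None, :]) ** 2).sum(axis=1)

    # physically the decline lasts a few hundred ms; cap well above that
    d_max = 2.5
    t0_grid = t_coarse + np.arange(t0_lo, t0_hi + 1e-9, 0.05)
    d_grid = np.geomspace(0.02, d_max, 25)
    tg, dg = np.meshgrid(t0_grid, d_grid, indexing="ij")
    errs = sse(tg.ravel(), dg.ravel())
    best = int(np.argmin(errs))
    t0_b, d_b = tg.ravel()[best], dg.ravel()[best]
    # refine
    t0_grid = t0_b + np.arange(-0.06, 0.061, 0.01)
    d_grid = d_b * np.geomspace(0.5, 2.0, 25)
    d_grid = d_grid[(d_grid >= 0.01) & (d_grid <= d_max)]
    tg, dg = np.meshgrid(t0_grid, d_grid, indexing="ij")
    errs = sse(tg.ravel(), dg.ravel())
    best = int(np.argmin(errs))
    return float(tg.ravel()[best]), float(dg.ravel()[best])


def segment_stages(
    trace: IntensityTrace,
    t_flow: float,
    config: Optional[SegmentationConfig] = None,
    ligand_protocol: bool = False,
) -> StageSegments:
    """Segment one flow trace into the four unwinding stages.

    Rejected traces (no binding, no committed decline, disordered
    boundaries) carry a ``reason`` code and are excluded from dwell
    statistics by :func:`build_dwell_table`.
    """
    config = config or SegmentationConfig()
    seg = StageSegments(t_flow=t_flow, molecule_id=trace.molecule_id)
    tc, e = _corrected_e(trace, config.leakage)
    if tc.size < 10:
        seg.reason = "too_short"
        return seg

    try:
        seg.t_bind = detect_binding(trace, t_flow, config)
    except ValueError:
        seg.reason = "no_preflow"
        return seg
    if math.isnan(seg.t_bind):
        seg.reason = "no_binding"
        return seg

    # Donor release: sustained drop to a fraction of the pre-flow median.
    g = trace.green
    tg = trace.t[g]
    donor = trace.donor[g] - trace.background
    pre_med = float(np.median(donor[tg < t_flow]))
    post = tg >= seg.t_bind
    low = donor[post] < config.release_fraction * pre_med
    idx = _first_run(low, config.release_consecutive)
    seg.t_release = float(tg[post][idx]) if idx >= 0 else math.nan

    t_hi = seg.t_release if not math.isnan(seg.t_release) else tc[-1]
    window = (tc >= seg.t_bind) & (tc <= t_hi)
    if window.sum() < 5:
        seg.reason = "no_window"
        return seg
    tw, ew = tc[window], e[window]

    t_coarse = _last_downcross(tw, ew, config.threshold_commit)
    if math.isnan(t_coarse):
        seg.reason = "no_commit"
        return seg
    t_mid = _last_downcross(tw, ew, config.threshold_ramp_mid)
    rel = seg.t_release if not math.isnan(seg.t_release) else tw[-1]
    if not math.isnan(t_mid) and t_mid - t_coarse > 1.2:
        # The folded-level crossing sits well before the final decline: the
        # last folded dwell was sub-frame, so anchor on the ramp midlevel
        # and let the fit place the commit within the preceding window.
        seg.t_g4_end, dwell = _refine_decline(
            tw, ew, t_mid, config, trace.frame_s, rel, t0_lo=-2.0, t0_hi=0.1
        )
    else:
        seg.t_g4_end, dwell = _refine_decline(
            tw, ew, t_coarse, config, trace.frame_s, rel
        )
    seg.t_dup_end = seg.t_g4_end + dwell
    if not math.isnan(seg.t_release):
        seg.t_dup_end = min(seg.t_dup_end, seg.t_release)

    # Traces whose acceptor went dark before release have a near-zero
    # corrected FRET tail instead of the unwound plateau: reject them.
    tail = (tc > seg.t_dup_end + 0.2) & (
        tc < (seg.t_release if not math.isnan(seg.t_release) else tc[-1]) - 0.1
    )
    if tail.sum() >= 5 and float(np.mean(e[tail])) < 0.5 * config.level_unwound:
        seg.reason = "low_fret_tail"
        return seg

    # A genuine completion shows the unwound plateau before the donor is
    # lost; a donor that bleaches mid-fluctuation does not.  Require at
    # least one frame at the unwound level (clearly below the ramp start
    # but above the dead-trace zero) between commitment and release.
    t_stop = seg.t_release if not math.isnan(seg.t_release) else tc[-1]
    ramp_start = (
        config.level_unfolded if config.has_g4
        else apparent_level(config.e_bare, config.pife_factor)
    )
    zone = (tc >= seg.t_g4_end) & (tc <= t_stop)
    at_unwound = (
        (e[zone] > 0.5 * config.level_unwound)
        & (e[zone] < 0.5 * (config.level_unwound + ramp_start))
    )
    if not at_unwound.any():
        seg.reason = "no_unwound_plateau"
        return seg

    # FRET fluctuation (repetitive unfolding) between binding and commit.
    pre_e = e[tc < t_flow][-50:]  # last pre-flow frames: a single steady state
    noise_var = float(np.var(pre_e)) if pre_e.size >= 5 else 0.0
    stage2 = (tc >= seg.t_bind) & (tc <= seg.t_g4_end)
    e2 = e[stage2]
    w = config.var_window
    if e2.size >= w:
        sw = np.lib.stride_tricks.sliding_window_view(e2, w)
        rollvar = sw.var(axis=1)
        exceeding = rollvar > config.var_factor * max(noise_var, 1e-6)
        seg.fluctuation_s = float(exceeding.sum()) * trace.frame_s
        seg.has_fluctuation = seg.fluctuation_s >= config.min_fluctuation_s
        if seg.has_fluctuation:
            first = int(np.argmax(exceeding))
            seg.t_g4_start = float(tc[stage2][first])

    if ligand_protocol:
        lag_zone = (tc >= seg.t_bind) & (tc <= seg.t_g4_end)
        above = e[lag_zone] >= config.threshold_lag_exit
        idx = _first_run(above, 3)
        seg.t_lag_end = float(tc[lag_zone][idx]) if idx >= 0 else math.nan

    # Ordering validation
    times = [t_flow, seg.t_bind, seg.t_g4_end, seg.t_dup_end]
    if not math.isnan(seg.t_release):
        times.append(seg.t_release)
    if any(b < a - 1e-9 for a, b in zip(times, times[1:])):
        seg.reason = "disordered"
        return seg
    if math.isnan(seg.t_release):
        seg.reason = "no_release"
        return seg
    seg.accepted = True
    return seg


def segment_traces(
    traces: Sequence[IntensityTrace],
    t_flow: float,
    config: Optional[SegmentationConfig] = None,
    ligand_protocol: bool = False,
) -> List[StageSegments]:
    return [segment_stages(tr, t_flow, config, ligand_protocol) for tr in traces]


@dataclass
class DwellTable:
    """Per-stage dwell lists across accepted traces."""

    dwells: Dict[str, np.ndarray] = field(default_factory=dict)

    def n(self, stage: str) -> int:
        return len(self.dwells.get(stage, ()))

    def mean(self, stage: str) -> float:
        return float(np.mean(self.dwells[stage]))

    def sem(self, stage: str) -> float:
        d = self.dwells[stage]
        return float(np.std(d, ddof=1) / math.sqrt(len(d))) if len(d) > 1 else math.nan


def build_dwell_table(segments: Sequence[StageSegments]) -> DwellTable:
    """Collect stage dwells from accepted segmentations."""
    acc = [s for s in segments if s.accepted]
    table = {
        "binding": np.array([s.stage_i for s in acc]),
        "g4_resolution": np.array([s.stage_ii for s in acc]),
        "duplex_unwinding": np.array([s.stage_iii for s in acc]),
        "release": np.array([s.stage_iv for s in acc]),
    }
    table = {k: v[np.isfinite(v)] for k, v in table.items()}
    return DwellTable(dwells=table)


def stage_rates(table: DwellTable, min_n: int = 150) -> pd.DataFrame:
    """Stage rates (1/s) as inverse mean dwells with propagated SEM.

    ``rate_sem = sem_dwell / mean^2`` (first-order propagation).  Stages
    with fewer than ``min_n`` contributing traces are flagged.
    """
    if not any(table.n(s) for s in STAGES):
        raise ValueError("dwell table is empty")
    rows = []
    for stage in STAGES:
        n = table.n(stage)
        if n == 0:
            continue
        mean = table.mean(stage)
        sem = table.sem(stage)
        rows.append(
            {
                "stage": stage,
                "n": n,
                "mean_s": mean,
                "sem_s": sem,
                "rate_per_s": 1.0 / mean if mean > 0 else math.inf,
                "rate_sem_per_s": sem / mean**2 if mean > 0 else math.nan,
                "low_n": n < min_n,
            }
        )
    return pd.DataFrame(rows)


def dwell_histogram(
    dwells: Sequence[float], bins: int = 12
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Histogram of stage dwells with a Gaussian fit of its mode.

    Returns ``(counts, edges, fit)`` where ``fit`` holds the fitted center
    and width.  Requires at least 20 dwells.
    """
    d = np.asarray(dwells, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 20:
        raise ValueError(f"need >= 20 dwells for a histogram fit, got {d.size}")
    counts, edges = np.histogram(d, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = GaussianModel()
    params = model.make_params(
        center=float(np.mean(d)), sigma=float(np.std(d)), amplitude=float(counts.max())
    )
    # dwells are nonnegative; keep the fit inside the observed range
    params["center"].set(min=0.0, max=float(edges[-1]))
    params["sigma"].set(min=float(edges[1] - edges[0]) / 2.0,
                        max=float(edges[-1] - edges[0]))
    params["amplitude"].set(min=0.0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        result = model.fit(counts, params, x=centers)
    fit = {
        "center_s": float(result.params["center"].value),
        "sigma_s": float(result.params["sigma"].value),
    }
    return counts, edges, fit
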
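"""Stochastic kinetic model of helicase-mediated G-quadruplex unwinding.

A single surface-tethered molecule progresses through four stages:

I.   binding — the helicase loads on the 3' tail (pseudo-first-order rate
     ``k_bind`` at the working protein concentration);
II.  G4 resolution — repetitive cycles of transient unfolding (rate
     ``k_unfold``) and refolding (rate ``k_refold``); each unfolding
     attempt commits to duplex unwinding with probability ``p_commit``;
III. duplex unwinding — a single exponential dwell (rate ``k_dup``);
IV.  tracking-strand release (rate ``k_rel``), after which the donor
     strand leaves the surface.

ATP dependence enters microscopically through a shared saturable factor
``atp / (Km + atp)`` applied to ``k_unfold`` and ``k_dup``; the ensemble
spot-survival rate follows the Michaelis-Menten law
``Vmax * atp / (Km + atp)``.

A G4-stabilizing ligand adds a dislodging lag (state ``LIGAND_LAG``)
between binding and the first unfolding cycle; its mean defaults to
``(ligand_stage2_slowdown - 1)`` times the ligand-free stage-II mean, so
the expected total G4-resolution time is ``ligand_stage2_slowdown`` times
the ligand-free value.

The simulation is exact (event-driven); waiting times in every state are
exponential with the state's total exit rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .substrates import Substrate

__all__ = [
    "HelicaseParams",
    "StateTrajectory",
    "SurvivalCounts",
    "atp_scale",
    "with_atp",
    "expected_stage2_duration",
    "unwinding_rate_at_atp",
    "sample_stage2_durations",
    "simulate_helicase_trace",
    "simulate_survival_counts",
    "STATES",
]

#: Molecular states (piecewise-constant over time).
STATES = (
    "FREE",
    "LIGAND_EXCESS",
    "LIGAND_WASHED",
    "BOUND",
    "G4_FOLDED_B",
    "G4_UNFOLDED_B",
    "LIGAND_LAG",
    "DUPLEX_UNWINDING",
    "UNWOUND_HELD",
    "RELEASED",
)

_MAX_EVENTS = 1_000_000


@dataclass
class HelicaseParams:
    """Microscopic and ensemble rate parameters for one helicase.

    Rates are 1/s except ``vmax`` (1/min, ensemble spot-survival maximum)
    and ``km`` (uM ATP at half saturation, shared between the ensemble law
    and the microscopic ATP scaling).
    """

    k_bind: float = 0.2
    k_unfold: float = 0.324
    k_refold: float = 1.0
    p_commit: float = 0.2
    k_dup: float = 3.1
    k_rel: float = 0.5
    vmax: float = 0.36
    km: float = 72.0
    f_active: float = 1.0
    parallel_competent: bool = True
    ligand_lag_rate: Optional[float] = None
    ligand_stage2_slowdown: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k_bind", "k_unfold", "k_refold", "k_dup", "k_rel", "vmax", "km"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.p_commit <= 1.0:
            raise ValueError(f"p_commit must be in (0, 1], got {self.p_commit}")
        if not 0.0 <= self.f_active <= 1.0:
            raise ValueError(f"f_active must be in [0, 1], got {self.f_active}")
        if self.ligand_stage2_slowdown < 1.0:
            raise ValueError("ligand_stage2_slowdown must be >= 1")

    def effective_lag_rate(self) -> float:
        """Escape rate from the ligand-dislodging lag.

        Defaults to ``1 / ((slowdown - 1) * tau_II)`` so that lag plus
        cycling averages ``slowdown * tau_II``; a slowdown of exactly 1
        means no lag.
        """
        if self.ligand_lag_rate is not None:
            return self.ligand_lag_rate
        extra = (self.ligand_stage2_slowdown - 1.0) * expected_stage2_duration(self)
        return math.inf if extra <= 0 else 1.0 / extra


def atp_scale(atp_um: float, km_um: float) -> float:
    """Saturable ATP factor ``atp / (Km + atp)`` in [0, 1)."""
    if atp_um < 0:
        raise ValueError("atp must be >= 0")
    return atp_um / (km_um + atp_um) if (km_um + atp_um) > 0 else 0.0


def with_atp(params: HelicaseParams, atp_um: float) -> HelicaseParams:
    """Copy of ``params`` with ATP-dependent rates scaled for ``atp_um``."""
    s = atp_scale(atp_um, params.km)
    return replace(params, k_unfold=params.k_unfold * s, k_dup=params.k_dup * s)


def expected_stage2_duration(params: HelicaseParams) -> float:
    """Closed-form mean stage-II (G4 resolution) duration in seconds.

    The number of unfolding attempts before commitment is geometric with
    success probability ``p_commit``; each attempt costs one folded dwell
    (mean ``1/k_unfold``) and every non-committing attempt adds one
    transiently-unfolded dwell (mean ``1/k_refold``):

        tau_II = 1 / (p * k_unfold) + (1 - p) / (p * k_refold)
    """
    p = params.p_commit
    if p <= 0:
        raise ValueError("p_commit = 0 never commits; stage II is infinite")
    if params.k_unfold <= 0 or params.k_refold <= 0:
        raise ValueError("k_unfold and k_refold must be > 0")
    return 1.0 / (p * params.k_unfold) + (1.0 - p) / (p * params.k_refold)


def unwinding_rate_at_atp(params: HelicaseParams, atp_um: float) -> float:
    """Ensemble unwinding rate (1/min): ``Vmax * atp / (Km + atp)``."""
    return params.vmax * atp_scale(atp_um, params.km)


def sample_stage2_durations(
    params: HelicaseParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Monte-Carlo draw of ``n`` stage-II durations.

    Samples the alternating scheme directly (geometric attempt count,
    gamma-distributed folded and unfolded dwell sums); used as the fast
    large-n simulation against which the closed form is checked.
    """
    attempts = rng.geometric(params.p_commit, size=n)
    folded = rng.standard_gamma(attempts) / params.k_unfold
    unfolded = rng.standard_gamma(attempts - 1) / params.k_refold
    return folded + unfolded


@dataclass
class StateTrajectory:
    """Piecewise-constant molecular state over time.

    ``segments`` are contiguous ``(state, t_start, t_end)`` tuples starting
    at t = 0; ``RELEASED`` is absorbing.  ``truth`` holds the ground-truth
    event times used by recovery tests (``t_bind``, ``t_commit``,
    ``t_dup_end``, ``t_release``; NaN when the event did not occur).
    """

    segments: List[Tuple[str, float, float]]
    active: bool
    t_end: float
    truth: Dict[str, float] = field(default_factory=dict)

    def states(self) -> List[str]:
        return [s for s, _, _ in self.segments]

    def duration_in(self, state: str) -> float:
        return sum(t1 - t0 for s, t0, t1 in self.segments if s == state)

    def entry_time(self, state: str) -> float:
        for s, t0, _ in self.segments:
            if s == state:
                return t0
        return math.nan

    def state_at(self, t: float) -> str:
        for s, t0, t1 in self.segments:
            if t0 <= t < t1:
                return s
        return self.segments[-1][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["state", "start_s", "end_s"])

    def validate(self) -> None:
        """Raise AssertionError if the segment invariants are violated."""
        assert self.segments, "empty trajectory"
        assert self.segments[0][1] == 0.0, "must start at t = 0"
        for (s0, a0, b0), (s1, a1, b1) in zip(self.segments, self.segments[1:]):
            assert b0 == a1, "segments must be contiguous"
            assert b0 > a0, "segments must have positive duration"
        states = self.states()
        assert states.count("DUPLEX_UNWINDING") <= 1
        if "RELEASED" in states:
            assert states[-1] == "RELEASED", "RELEASED is absorbing"


def _seg_append(segs, state, t0, t1):
    if t1 > t0:
        segs.append((state, t0, t1))


def simulate_helicase_trace(
    params: HelicaseParams,
    substrate: Substrate,
    t_flow: float,
    t_end: float,
    atp_um: float = 2000.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    t_ligand: float = 5.0,
    t_wash: float = 15.0,
) -> StateTrajectory:
    """Event-driven simulation of one real-time flow trace.

    Protein and ATP flow in at ``t_flow``; the trajectory is truncated at
    ``t_end``.  With probability ``1 - f_active`` (or always, for a
    parallel G4 with ``parallel_competent=False``) the molecule binds and
    cycles but never commits to duplex unwinding.  Substrates whose tail
    is below the helicase footprint never bind (the trace stays FREE).

    For ligand-bearing substrates the pre-flow schedule is
    FREE -> LIGAND_EXCESS (at ``t_ligand``) -> LIGAND_WASHED (at
    ``t_wash``), and a LIGAND_LAG dislodging dwell is inserted between
    binding and the first unfolding cycle.
    """
    if t_flow >= t_end:
        raise ValueError(f"t_flow ({t_flow}) must be < t_end ({t_end})")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = with_atp(params, atp_um)
    ligand = substrate.spec.ligand != "none"
    if ligand and not (0 <= t_ligand < t_wash <= t_flow):
        raise ValueError("ligand protocol requires 0 <= t_ligand < t_wash <= t_flow")

    segs: List[Tuple[str, float, float]] = []
    truth: Dict[str, float] = {
        "t_bind": math.nan,
        "t_lag_end": math.nan,
        "t_commit": math.nan,
        "t_dup_end": math.nan,
        "t_release": math.nan,
        "n_cycles": 0,
    }
    idle_state = "FREE"
    if ligand:
        _seg_append(segs, "FREE", 0.0, t_ligand)
        _seg_append(segs, "LIGAND_EXCESS", t_ligand, t_wash)
        idle_state = "LIGAND_WASHED"
        idle_from = t_wash
    else:
        idle_from = 0.0

    def _finish(active: bool) -> StateTrajectory:
        traj = StateTrajectory(segments=segs, active=active, t_end=t_end, truth=truth)
        return traj

    if not substrate.helicase_loading_competent or p.k_bind <= 0:
        _seg_append(segs, idle_state, idle_from, t_end)
        return _finish(False)

    t_bind = t_flow + rng.exponential(1.0 / p.k_bind)
    if t_bind >= t_end:
        _seg_append(segs, idle_state, idle_from, t_end)
        return _finish(False)
    _seg_append(segs, idle_state, idle_from, t_bind)
    truth["t_bind"] = t_bind

    blocked = substrate.is_parallel and not p.parallel_competent
    active = (not blocked) and (rng.random() < p.f_active)
    cursor = t_bind

    if ligand:
        lag_rate = p.effective_lag_rate()
        lag = 0.0 if math.isinf(lag_rate) else rng.exponential(1.0 / lag_rate)
        if cursor + lag >= t_end:
            _seg_append(segs, "LIGAND_LAG", cursor, t_end)
            return _finish(active)
        _seg_append(segs, "LIGAND_LAG", cursor, cursor + lag)
        cursor += lag
        truth["t_lag_end"] = cursor

    committed = False
    if substrate.has_g4:
        if p.k_unfold <= 0 or p.k_refold <= 0:
            raise ValueError("k_unfold and k_refold must be > 0 for G4 substrates")
        for _ in range(_MAX_EVENTS):
            dwell = rng.exponential(1.0 / p.k_unfold)
            if cursor + dwell >= t_end:
                _seg_append(segs, "G4_FOLDED_B", cursor, t_end)
                return _finish(active)
            _seg_append(segs, "G4_FOLDED_B", cursor, cursor + dwell)
            cursor += dwell
            truth["n_cycles"] += 1
            if active and rng.random() < p.p_commit:
                committed = True
                break
            dwell = rng.exponential(1.0 / p.k_refold)
            if cursor + dwell >= t_end:
                _seg_append(segs, "G4_UNFOLDED_B", cursor, t_end)
                return _finish(active)
            _seg_append(segs, "G4_UNFOLDED_B", cursor, cursor + dwell)
            cursor += dwell
        else:  # pragma: no cover - guards runaway loops
            raise RuntimeError("event budget exceeded in stage II")
    else:
        # No G4 block: a short engagement dwell precedes duplex unwinding.
        dwell = rng.exponential(1.0 / p.k_unfold) if p.k_unfold > 0 else math.inf
        if not active or cursor + dwell >= t_end:
            _seg_append(segs, "BOUND", cursor, t_end)
            return _finish(active)
        _seg_append(segs, "BOUND", cursor, cursor + dwell)
        cursor += dwell
        committed = True

    truth["t_commit"] = cursor
    if p.k_dup <= 0:
        _seg_append(segs, "DUPLEX_UNWINDING", cursor, t_end)
        return _finish(active)
    dwell = rng.exponential(1.0 / p.k_dup)
    if cursor + dwell >= t_end:
        _seg_append(segs, "DUPLEX_UNWINDING", cursor, t_end)
        return _finish(active)
    _seg_append(segs, "DUPLEX_UNWINDING", cursor, cursor + dwell)
    cursor += dwell
    truth["t_dup_end"] = cursor

    dwell = rng.exponential(1.0 / p.k_rel) if p.k_rel > 0 else math.inf
    if cursor + dwell >= t_end:
        _seg_append(segs, "UNWOUND_HELD", cursor, t_end)
        return _finish(active)
    _seg_append(segs, "UNWOUND_HELD", cursor, cursor + dwell)
    cursor += dwell
    truth["t_release"] = cursor
    _seg_append(segs, "RELEASED", cursor, t_end)
    return _finish(active)


@dataclass
class SurvivalCounts:
    """Per-time spot counts from a simulated field-sampling survival assay.

    ``counts`` has shape ``(n_views, n_times)``; each scheduled time images
    fresh fields of view, so counts are independent across times with mean
    ``spots_per_view * (f_active * exp(-r t) + 1 - f_active)``.
    """

    times_s: np.ndarray
    counts: np.ndarray
    spots_per_view: int
    truth: Dict[str, float]

    def total(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def simulate_survival_counts(
    params: HelicaseParams,
    substrate: Substrate,
    atp_um: float,
    n_views: int,
    spots_per_view: int,
    times_s: Sequence[float],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SurvivalCounts:
    """Ensemble shortcut for the spot-survival assay.

    Each active molecule (probability ``f_active``; zero for substrates
    that cannot load the helicase or for parallel G4 with an incompetent
    protein) disappears with the ensemble rate ``r = Vmax*atp/(Km+atp)``
    (1/min); inactive molecules persist.  Spot counts are binomial draws
    per molecule.
    """
    if spots_per_view <= 0:
        raise ValueError(f"spots_per_view must be > 0, got {spots_per_view}")
    if n_views <= 0:
        raise ValueError(f"n_views must be > 0, got {n_views}")
    times = np.asarray(times_s, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be ascending")
    if rng is None:
        rng = np.random.default_rng(seed)

    competent = substrate.helicase_loading_competent and not (
        substrate.is_parallel and not params.parallel_competent
    )
    f_eff = params.f_active if competent else 0.0
    r_per_min = unwinding_rate_at_atp(params, atp_um)
    p_survive = f_eff * np.exp(-r_per_min * times / 60.0) + (1.0 - f_eff)
    counts = rng.binomial(spots_per_view, p_survive, size=(n_views, times.size))
    truth = {
        "rate_per_min": r_per_min,
        "f_active": f_eff,
        "vmax_per_min": params.vmax,
        "km_um": params.km,
        "atp_um": atp_um,
        "n0": float(n_views * spots_per_view),
    }
    return SurvivalCounts(
        times_s=times, counts=counts, spots_per_view=spots_per_view, truth=truth
    )
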
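"""Stochastic 1-D lattice model of RecA nucleoprotein filament assembly.

RecA coats single-stranded DNA at one monomer per ``site_nt`` nucleotides
(3 nt at the default).  A filament becomes stable only once a nucleus of
``nucleus_monomers`` monomers (6, i.e. 18 nt) has formed on a contiguous
free stretch; shorter tails support only transient sub-nucleus clusters
that bind and release dynamically.

When the filament fills the tail and abuts a non-parallel G4, it can
transiently open the G4 (rate ``k_invade``) and extend into the freed
nucleotides.  G4 reclosure (rate ``k_g4_refold``; much slower in Na+
buffer, which destabilizes the fold) competes with the filament and
displaces any monomers inside the G4 region — clusters trimmed below the
nucleus collapse.  A bound G4 ligand slows invasion by
``ligand_slowdown`` and is ejected once the cumulative open-G4 dwell
reaches ``eject_dwell_s``.  Parallel G4s never open.

Two observables are produced:

* :func:`simulate_reca_trace` — an exact (Gillespie) coverage trajectory
  for one molecule, rendered to FRET downstream;
* :func:`simulate_reca_population` — the ensemble assembly kinetics
  (fraction of molecules reaching the filament-coated low-FRET state),
  parameterized by a per-substrate plateau and mean assembly time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .substrates import Substrate

__all__ = [
    "RecAParams",
    "CoverageTrajectory",
    "AssemblyPopulation",
    "simulate_reca_trace",
    "simulate_reca_population",
    "coverage_summary",
]


@dataclass
class RecAParams:
    """Rate parameters of the lattice model (1/s unless noted).

    ``k_nuc`` applies to any competent free stretch (a full nucleus where
    the stretch allows it, otherwise a transient sub-nucleus cluster);
    ``k_ext``/``k_off`` are per-end monomer addition/loss for stable
    filaments; ``k_sub_off`` is the dissolution rate of sub-nucleus
    clusters.  ``eject_dwell_s`` is the cumulative open-G4 dwell needed to
    eject a bound ligand.
    """

    site_nt: int = 3
    nucleus_monomers: int = 6
    k_nuc: float = 0.2
    k_ext: float = 1.0
    k_off: float = 0.01
    k_sub_off: float = 0.3
    k_invade: float = 0.3
    k_g4_refold: float = 0.3
    eject_dwell_s: float = 2.0
    ligand_slowdown: float = 3.0

    def __post_init__(self) -> None:
        if self.site_nt < 1:
            raise ValueError("site_nt must be >= 1")
        if self.nucleus_monomers < 1:
            raise ValueError("nucleus_monomers must be >= 1")
        for name in ("k_nuc", "k_ext", "k_off", "k_sub_off", "k_invade", "k_g4_refold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ligand_slowdown < 1:
            raise ValueError("ligand_slowdown must be >= 1")


@dataclass
class CoverageTrajectory:
    """Event-sampled filament coverage of one molecule.

    Arrays are aligned per event: time (s), bound monomer count, whether
    the G4 is open, and whether the ligand is still bound.  The state is
    right-continuous (each row holds from its time to the next row's).
    """

    t: np.ndarray
    monomers: np.ndarray
    g4_open: np.ndarray
    ligand_bound: np.ndarray
    capacity_tail: int
    capacity_total: int
    t_end: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "monomers": self.monomers,
                "g4_open": self.g4_open,
                "ligand_bound": self.ligand_bound,
            }
        )

    def coverage_at(self, times: np.ndarray) -> np.ndarray:
        """Monomer count at arbitrary times (right-continuous step)."""
        idx = np.searchsorted(self.t, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.t) - 1)
        return self.monomers[idx]


def coverage_summary(traj: CoverageTrajectory, high_frac: float = 0.9) -> Dict[str, float]:
    """Dwell-weighted summary statistics of a coverage trajectory.

    ``longest_high_s`` is the longest contiguous period with coverage at or
    above ``high_frac`` of total capacity; ``final_high_s`` the length of
    the trailing such period; ``n_open_toggles`` counts G4 open/close
    transitions.
    """
    t = np.append(traj.t, traj.t_end)
    dur = np.diff(t)
    high = traj.monomers >= high_frac * traj.capacity_total
    longest = current = 0.0
    for h, d in zip(high, dur):
        current = current + d if h else 0.0
        longest = max(longest, current)
    final = 0.0
    for h, d in zip(high[::-1], dur[::-1]):
        if not h:
            break
        final += d
    toggles = int(np.sum(traj.g4_open[1:] != traj.g4_open[:-1]))
    return {
        "longest_high_s": longest,
        "final_high_s": final,
        "n_open_toggles": toggles,
        "time_high_s": float(dur[high].sum()),
    }


def simulate_reca_trace(
    params: RecAParams,
    substrate: Substrate,
    t_end: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> CoverageTrajectory:
    """Exact stochastic simulation of filament assembly on one molecule."""
    if rng is None:
        rng = np.random.default_rng(seed)
    site = params.site_nt
    nucleus = params.nucleus_monomers
    cap_tail = substrate.spec.tail_nt // site
    cap_total = substrate.tracking_nt // site
    openable = substrate.has_g4 and not substrate.is_parallel

    m = 0
    g4_open = False
    ligand = substrate.spec.ligand != "none"
    open_dwell = 0.0
    t = 0.0

    rows_t: List[float] = [0.0]
    rows_m: List[int] = [0]
    rows_open: List[bool] = [False]
    rows_lig: List[bool] = [ligand]

    def record(tt: float) -> None:
        rows_t.append(tt)
        rows_m.append(m)
        rows_open.append(g4_open)
        rows_lig.append(ligand)

    while t < t_end:
        cap_now = cap_total if (g4_open or not substrate.has_g4) else cap_tail
        events: List[tuple] = []
        if m == 0 and cap_now >= 1 and params.k_nuc > 0:
            events.append(("nucleate", params.k_nuc))
        if 0 < m < cap_now and params.k_ext > 0:
            events.append(("extend", params.k_ext))
        if m >= nucleus and params.k_off > 0:
            events.append(("end_off", params.k_off))
        if 0 < m < nucleus and params.k_sub_off > 0:
            events.append(("dissolve", params.k_sub_off))
        if openable and not g4_open and cap_tail > 0 and m >= cap_tail and params.k_invade > 0:
            rate = params.k_invade / (params.ligand_slowdown if ligand else 1.0)
            events.append(("open_g4", rate))
        if g4_open and params.k_g4_refold > 0:
            events.append(("reclose", params.k_g4_refold))

        total = sum(r for _, r in events)
        if total <= 0:
            break
        wait = rng.exponential(1.0 / total)
        t_next = t + wait
        if g4_open and ligand:
            # Ligand ejection can occur mid-interval once the cumulative
            # open-G4 dwell crosses the threshold.
            remaining = params.eject_dwell_s - open_dwell
            if remaining <= min(wait, t_end - t):
                t_eject = t + max(remaining, 0.0)
                open_dwell = params.eject_dwell_s
                ligand = False
                t = t_eject
                record(t)
                continue
        if g4_open:
            open_dwell += min(wait, t_end - t)
        if t_next >= t_end:
            break
        t = t_next
        u = rng.random() * total
        acc = 0.0
        kind = events[-1][0]
        for name, rate in events:
            acc += rate
            if u < acc:
                kind = name
                break
        if kind == "nucleate":
            m = min(nucleus, cap_now)
        elif kind == "extend":
            m += 1
        elif kind == "end_off":
            m -= 1
            if m < nucleus:
                m = 0
        elif kind == "dissolve":
            m = 0
        elif kind == "open_g4":
            g4_open = True
        elif kind == "reclose":
            g4_open = False
            m = min(m, cap_tail)
            if m < nucleus:
                m = 0
        record(t)

    return CoverageTrajectory(
        t=np.asarray(rows_t),
        monomers=np.asarray(rows_m, dtype=int),
        g4_open=np.asarray(rows_open, dtype=bool),
        ligand_bound=np.asarray(rows_lig, dtype=bool),
        capacity_tail=cap_tail,
        capacity_total=cap_total,
        t_end=t_end,
    )


# Per-substrate defaults for the ensemble assembly kinetics: fraction of
# molecules that ever reach the filament-coated state, and the mean
# single-molecule assembly time of that competent subpopulation.
_POPULATION_DEFAULTS = {
    # (has_g4, parallel, ligand, cation) -> (plateau, mean assembly s)
    "t40": (1.00, 72.0),
    "g4_t15": (0.75, 150.0),
    "t15": (0.80, 240.0),
    "g4_t15_ligand": (0.60, 480.0),
    "g4_t15_na": (0.95, 150.0),
    "parallel": (0.05, 600.0),
}


def default_population_kinetics(substrate: Substrate) -> tuple:
    """(plateau fraction, mean assembly time s) for a default substrate."""
    if substrate.is_parallel:
        return _POPULATION_DEFAULTS["parallel"]
    if substrate.has_g4:
        if substrate.spec.ligand != "none":
            return _POPULATION_DEFAULTS["g4_t15_ligand"]
        if substrate.spec.buffer_cation == "Na":
            return _POPULATION_DEFAULTS["g4_t15_na"]
        return _POPULATION_DEFAULTS["g4_t15"]
    if substrate.spec.tail_nt >= 18:
        return _POPULATION_DEFAULTS["t40"]
    return _POPULATION_DEFAULTS["t15"]


@dataclass
class AssemblyPopulation:
    """Per-molecule assembly outcome over a sampling schedule.

    ``assembled`` has shape ``(n_molecules, n_times)``: True once a
    molecule has reached the stable filament-coated state.
    """

    times_s: np.ndarray
    assembled: np.ndarray
    substrate: Substrate
    truth: Dict[str, float]

    def fraction(self) -> np.ndarray:
        return self.assembled.mean(axis=0)


def simulate_reca_population(
    params: RecAParams,
    substrate: Substrate,
    times_s: Sequence[float],
    n_molecules: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    plateau: Optional[float] = None,
    mean_assembly_s: Optional[float] = None,
) -> AssemblyPopulation:
    """Ensemble assembly kinetics for histogram time series.

    Each molecule is assembly-competent with probability ``plateau``;
    competent molecules reach the coated state after an exponential time
    with the given mean.  Defaults come from the substrate class (tail
    length, G4 presence/topology, ligand, buffer cation).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    times = np.asarray(times_s, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    d_plateau, d_mean = default_population_kinetics(substrate)
    plateau = d_plateau if plateau is None else plateau
    mean_assembly_s = d_mean if mean_assembly_s is None else mean_assembly_s
    if not 0.0 <= plateau <= 1.0:
        raise ValueError("plateau must be in [0, 1]")

    capable = rng.random(n_molecules) < plateau
    t_assemble = np.where(
        capable, rng.exponential(mean_assembly_s, size=n_molecules), np.inf
    )
    assembled = t_assemble[:, None] <= times[None, :]
    truth = {
        "plateau": plateau,
        "mean_assembly_s": mean_assembly_s,
        "t_half_min": (mean_assembly_s * math.log(2.0)) / 60.0,
    }
    return AssemblyPopulation(
        times_s=times, assembled=assembled, substrate=substrate, truth=truth
    )
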
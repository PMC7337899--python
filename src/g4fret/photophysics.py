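"""Render molecular state trajectories into dye intensities and movies.

Green-excitation frames obey the two-channel rendering equations

    I_D = i_total * (1 - E) * pife * quench_D  (+ background, noise)
    I_A = i_total * E * quench_A + leakage * I_D  (+ background, noise)

with per-state apparent FRET E, protein-induced fluorescence enhancement
(PIFE) of the donor while a protein is bound, ligand-induced quenching of
both channels, and a single donor-to-acceptor leakage term.  Red-excitation
frames report direct acceptor excitation (independent of E), which is what
lets the ALEX filter discriminate donor-only molecules.  Each frame value
is the time average of the underlying signal over the frame (the camera
integrates), computed by supersampling the trajectory.

The ligand histogram shift (0.5 -> 0.2) is rendered phenomenologically as
a distinct apparent E plus a total-intensity reduction: an equal quench of
both channels cannot move an intensity ratio, so the shift must involve an
apparent-efficiency change whatever its physical mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinetics import StateTrajectory
from .reca import AssemblyPopulation, CoverageTrajectory
from .substrates import Substrate

__all__ = [
    "PhotoParams",
    "IntensityTrace",
    "FrameStack",
    "bare_fret",
    "state_fret",
    "render_trace",
    "render_movie",
    "population_fret_samples",
]

#: Apparent FRET of a fully RecA-coated long lattice.
FULL_FILAMENT_E = 0.05
#: Apparent FRET of a filament confined to a short (T15-like) tail.
PARTIAL_FILAMENT_E = 0.20


@dataclass
class PhotoParams:
    """Rendering parameters.

    ``i_total`` is the total photon budget per green frame for a molecule
    at E = 0 without PIFE; ``alex_pattern`` is the per-block frame count
    (green, dark, red).  ``noise=False`` renders exact noiseless means
    (still offset by ``background``).
    """

    i_total: float = 500.0
    pife_factor: float = 1.4
    quench_excess: float = 0.5
    quench_washed: float = 0.8
    leakage: float = 0.08
    background: float = 20.0
    read_sigma: float = 3.0
    # Oxygen scavenging + Trolox make photobleaching slow relative to the
    # unwinding kinetics (lifetimes of tens of minutes under illumination);
    # a few percent of long flow traces still bleach and exercise the
    # segmentation rejection paths.
    donor_bleach_rate: float = 1.0 / 3000.0
    acceptor_bleach_rate: float = 1.0 / 4000.0
    acceptor_dark_fraction: float = 0.15
    frame_s: float = 0.1
    alex_pattern: Tuple[int, int, int] = (10, 1, 10)
    red_excitation_factor: float = 0.8
    noise: bool = True
    # Apparent FRET per state
    e_folded: float = 0.50
    e_unfolded: float = 0.35
    e_ligand: float = 0.20
    e_unwound: float = 0.10

    def __post_init__(self) -> None:
        for name in ("e_folded", "e_unfolded", "e_ligand", "e_unwound"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("i_total", "pife_factor", "quench_excess", "quench_washed",
                     "red_excitation_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.frame_s <= 0:
            raise ValueError("frame_s must be > 0")
        if not 0.0 <= self.leakage < 1.0:
            raise ValueError("leakage must be in [0, 1)")


def bare_fret(substrate: Substrate, photo: Optional[PhotoParams] = None) -> float:
    """Apparent FRET of the protein-free substrate.

    Folded G4 substrates sit at ``e_folded`` (0.5); a washed-ligand G4 at
    ``e_ligand`` (0.2); bare tails interpolate with length between T15
    (0.75) and T40 (0.30) — longer single strands put the dyes further
    apart on average.
    """
    photo = photo or PhotoParams()
    if substrate.has_g4:
        if substrate.spec.ligand != "none":
            return photo.e_ligand
        return photo.e_folded
    return float(np.interp(substrate.tracking_nt, [15.0, 40.0], [0.75, 0.30]))


def state_fret(state: str, substrate: Substrate, photo: PhotoParams) -> float:
    """Apparent FRET assigned to a helicase-pathway state."""
    base = bare_fret(substrate, photo)
    table = {
        "FREE": base,
        "BOUND": base,
        "LIGAND_EXCESS": photo.e_ligand,
        "LIGAND_WASHED": photo.e_ligand,
        "LIGAND_LAG": photo.e_ligand,
        "G4_FOLDED_B": photo.e_folded,
        "G4_UNFOLDED_B": photo.e_unfolded,
        "UNWOUND_HELD": photo.e_unwound,
        "RELEASED": 0.0,
    }
    if state == "DUPLEX_UNWINDING":
        # rendered as a ramp; callers use ramp endpoints
        return photo.e_unfolded if substrate.has_g4 else base
    try:
        return table[state]
    except KeyError:
        raise KeyError(f"no FRET value mapped for state {state!r}") from None


@dataclass
class IntensityTrace:
    """Per-frame donor/acceptor counts with excitation labels.

    ``exc`` holds ``'G'`` (green/donor excitation), ``'D'`` (dark) or
    ``'R'`` (red/acceptor excitation) per frame.  ``t`` is the frame start
    time.  ``background`` is the rendered per-frame background offset
    (identical in both channels) so analysis code can subtract it.
    """

    t: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    exc: np.ndarray
    frame_s: float
    background: float
    molecule_id: int = 0
    truth: Dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def green(self) -> np.ndarray:
        return self.exc == "G"

    @property
    def red(self) -> np.ndarray:
        return self.exc == "R"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.t)),
                "t_s": self.t,
                "exc": self.exc,
                "donor": self.donor,
                "acceptor": self.acceptor,
            }
        )


def _alex_labels(n_frames: int, pattern: Tuple[int, int, int]) -> np.ndarray:
    g, d, r = pattern
    block = np.array(["G"] * g + ["D"] * d + ["R"] * r)
    reps = int(np.ceil(n_frames / block.size))
    return np.tile(block, reps)[:n_frames]


def _piecewise_profile(
    traj: StateTrajectory, substrate: Substrate, photo: PhotoParams
) -> List[Tuple[float, float, float, float, float, float, float, bool]]:
    """Per-segment rendering profile.

    Returns tuples ``(t0, t1, e0, e1, pife, quench_d, quench_a, donor_present)``
    with E linearly interpolated from e0 to e1 across the segment (equal
    for all states except the duplex-unwinding ramp).
    """
    bound_states = {
        "BOUND", "G4_FOLDED_B", "G4_UNFOLDED_B", "LIGAND_LAG",
        "DUPLEX_UNWINDING", "UNWOUND_HELD",
    }
    out = []
    for state, t0, t1 in traj.segments:
        pife = photo.pife_factor if state in bound_states else 1.0
        if state == "LIGAND_EXCESS":
            q = photo.quench_excess
        elif state in ("LIGAND_WASHED", "LIGAND_LAG"):
            q = photo.quench_washed
        else:
            q = 1.0
        donor_present = state != "RELEASED"
        if state == "DUPLEX_UNWINDING":
            e0 = photo.e_unfolded if substrate.has_g4 else bare_fret(substrate, photo)
            e1 = photo.e_unwound
        else:
            e0 = e1 = state_fret(state, substrate, photo)
        out.append((t0, t1, e0, e1, pife, q, q, donor_present))
    return out


def render_trace(
    traj,
    photo: PhotoParams,
    substrate: Substrate,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    alex: bool = False,
    n_frames: Optional[int] = None,
    molecule_id: int = 0,
    supersample: int = 8,
) -> IntensityTrace:
    """Render a state or coverage trajectory into an intensity trace.

    Frame values are time averages of the underlying signal over each
    frame (``supersample`` sub-samples per frame).  With ``alex=True``
    frames follow the (green, dark, red) excitation pattern; otherwise the
    trace is continuous green excitation (real-time flow movies).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(traj, CoverageTrajectory):
        profile = _coverage_profile(traj, substrate, photo)
        t_end = traj.t_end
    elif isinstance(traj, StateTrajectory):
        profile = _piecewise_profile(traj, substrate, photo)
        t_end = traj.t_end
    else:
        raise TypeError(f"cannot render {type(traj).__name__}")

    total_frames = n_frames if n_frames is not None else int(round(t_end / photo.frame_s))
    if total_frames <= 0:
        raise ValueError("trajectory too short for a single frame")
    frame_t = np.arange(total_frames) * photo.frame_s
    offs = (np.arange(supersample) + 0.5) / supersample * photo.frame_s
    t_fine = (frame_t[:, None] + offs[None, :]).ravel()

    e = np.zeros_like(t_fine)
    pife = np.ones_like(t_fine)
    qd = np.ones_like(t_fine)
    qa = np.ones_like(t_fine)
    donor_on = np.zeros_like(t_fine, dtype=bool)
    for t0, t1, e0, e1, pf, q_d, q_a, present in profile:
        mask = (t_fine >= t0) & (t_fine < t1)
        if not mask.any():
            continue
        if e0 == e1:
            e[mask] = e0
        else:
            frac = (t_fine[mask] - t0) / (t1 - t0)
            e[mask] = e0 + (e1 - e0) * frac
        pife[mask] = pf
        qd[mask] = q_d
        qa[mask] = q_a
        donor_on[mask] = present

    # Photobleaching and the acceptor-dark subpopulation
    acceptor_dark = bool(rng.random() < photo.acceptor_dark_fraction)
    t_dbleach = (
        rng.exponential(1.0 / photo.donor_bleach_rate)
        if photo.donor_bleach_rate > 0 else math.inf
    )
    t_ableach = (
        rng.exponential(1.0 / photo.acceptor_bleach_rate)
        if photo.acceptor_bleach_rate > 0 else math.inf
    )
    if acceptor_dark:
        t_ableach = 0.0
    donor_on = donor_on & (t_fine < t_dbleach)
    acceptor_on = t_fine < t_ableach

    e_eff = np.where(acceptor_on, e, 0.0)
    d_fine = photo.i_total * (1.0 - e_eff) * pife * qd * donor_on
    a_fret_fine = photo.i_total * e_eff * qa * donor_on
    a_red_fine = photo.i_total * photo.red_excitation_factor * qa * acceptor_on

    def frame_mean(x):
        return x.reshape(total_frames, supersample).mean(axis=1)

    m_d_green = frame_mean(d_fine)
    m_a_green = frame_mean(a_fret_fine) + photo.leakage * m_d_green
    m_a_red = frame_mean(a_red_fine)

    exc = _alex_labels(total_frames, photo.alex_pattern) if alex else np.full(
        total_frames, "G"
    )
    m_d = np.where(exc == "G", m_d_green, 0.0)
    m_a = np.where(exc == "G", m_a_green, np.where(exc == "R", m_a_red, 0.0))

    if photo.noise:
        donor = rng.poisson(m_d + photo.background) + rng.normal(
            0.0, photo.read_sigma, total_frames
        )
        acceptor = rng.poisson(m_a + photo.background) + rng.normal(
            0.0, photo.read_sigma, total_frames
        )
    else:
        donor = m_d + photo.background
        acceptor = m_a + photo.background

    truth = {
        "acceptor_dark": acceptor_dark,
        "t_donor_bleach": t_dbleach,
        "t_acceptor_bleach": t_ableach,
    }
    if isinstance(traj, StateTrajectory):
        truth.update(traj.truth)
        truth["active"] = traj.active
    return IntensityTrace(
        t=frame_t,
        donor=donor.astype(float),
        acceptor=acceptor.astype(float),
        exc=exc,
        frame_s=photo.frame_s,
        background=photo.background,
        molecule_id=molecule_id,
        truth=truth,
    )


def reca_fret(substrate: Substrate, covered_nt: float, photo: Optional[PhotoParams] = None) -> float:
    """Coverage-interpolated apparent FRET for RecA-bound substrates.

    Anchored at the bare-substrate value for zero coverage, the
    partial-filament value (0.20) when only the tail is coated, and the
    full-filament value (0.05) once ~36 nt or more are stretched.
    """
    photo = photo or PhotoParams()
    base = bare_fret(substrate, photo)
    tail = substrate.spec.tail_nt
    anchors_x = [0.0]
    anchors_y = [base]
    if substrate.has_g4 and tail > 0:
        anchors_x.append(float(tail))
        anchors_y.append(PARTIAL_FILAMENT_E)
    full_nt = max(36.0, float(tail) + 1.0) if not substrate.has_g4 else 36.0
    if substrate.tracking_nt >= 36 or not substrate.has_g4:
        anchors_x.append(min(full_nt, float(max(substrate.tracking_nt, 1))))
        anchors_y.append(
            FULL_FILAMENT_E if substrate.tracking_nt >= 36 else PARTIAL_FILAMENT_E
        )
    return float(np.interp(covered_nt, anchors_x, anchors_y))


def _coverage_profile(
    traj: CoverageTrajectory, substrate: Substrate, photo: PhotoParams
) -> List[Tuple[float, float, float, float, float, float, float, bool]]:
    out = []
    t = np.append(traj.t, traj.t_end)
    for i in range(len(traj.t)):
        t0, t1 = t[i], t[i + 1]
        if t1 <= t0:
            continue
        covered_nt = traj.monomers[i] * (
            substrate.tracking_nt / max(traj.capacity_total, 1)
        )
        e = reca_fret(substrate, covered_nt, photo)
        q = photo.quench_washed if traj.ligand_bound[i] else 1.0
        pife = photo.pife_factor if traj.monomers[i] > 0 else 1.0
        out.append((t0, t1, e, e, pife, q, q, True))
    return out


@dataclass
class FrameStack:
    """Two-channel rendered image sequence (16-bit).

    ``donor`` and ``acceptor`` have shape (frames, height, width); the
    acceptor channel is shifted by ``channel_offset`` (dy, dx) relative to
    the donor channel (identity by default).
    """

    donor: np.ndarray
    acceptor: np.ndarray
    t: np.ndarray
    exc: np.ndarray
    frame_s: float
    background: float
    read_sigma: float
    psf_sigma_px: float
    channel_offset: Tuple[float, float] = (0.0, 0.0)
    sidecar: List[Dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    def green_average(self, n: int = 10) -> np.ndarray:
        """Mean of the first ``n`` green-excitation donor frames."""
        idx = np.flatnonzero(self.exc == "G")[:n]
        if idx.size == 0:
            raise ValueError("no green-excitation frames in stack")
        return self.donor[idx].mean(axis=0)

    def save_tiff(self, donor_path, acceptor_path) -> None:
        import tifffile

        tifffile.imwrite(donor_path, self.donor)
        tifffile.imwrite(acceptor_path, self.acceptor)


class OvercrowdedError(ValueError):
    """More molecules than the layout can hold at the minimum separation."""


def _grid_positions(
    n: int, shape: Tuple[int, int], min_sep: float, margin: int, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    pitch = int(math.ceil(min_sep))
    ys = np.arange(margin, h - margin, pitch)
    xs = np.arange(margin, w - margin, pitch)
    if ys.size * xs.size < n:
        raise OvercrowdedError(
            f"{n} molecules do not fit a {h}x{w} field at separation {min_sep}"
        )
    cells = [(y, x) for y in ys for x in xs]
    idx = rng.choice(len(cells), size=n, replace=False)
    jitter = rng.uniform(-0.3, 0.3, size=(n, 2))
    pos = np.array([cells[i] for i in idx], dtype=float) + jitter
    return pos  # (y, x)


def _stamp(image: np.ndarray, y: float, x: float, photons: float, sigma: float) -> None:
    rad = int(math.ceil(4 * sigma))
    yi, xi = int(round(y)), int(round(x))
    ys = np.arange(yi - rad, yi + rad + 1)
    xs = np.arange(xi - rad, xi + rad + 1)
    gy = np.exp(-0.5 * ((ys - y) / sigma) ** 2)
    gx = np.exp(-0.5 * ((xs - x) / sigma) ** 2)
    kernel = np.outer(gy, gx)
    kernel /= kernel.sum()
    y0, y1 = max(ys[0], 0), min(ys[-1] + 1, image.shape[0])
    x0, x1 = max(xs[0], 0), min(xs[-1] + 1, image.shape[1])
    image[y0:y1, x0:x1] += photons * kernel[
        y0 - ys[0] : y1 - ys[0], x0 - xs[0] : x1 - xs[0]
    ]


def render_movie(
    traces: Sequence[IntensityTrace],
    image_shape: Tuple[int, int] = (64, 128),
    psf_sigma_px: float = 1.2,
    min_sep_px: float = 10.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    background: float = 5.0,
    read_sigma: float = 2.0,
    channel_offset: Tuple[float, float] = (0.0, 0.0),
    noise: bool = True,
) -> FrameStack:
    """Render intensity traces as diffraction-limited spots in a movie.

    Each molecule becomes a 2-D Gaussian spot pair (donor/acceptor
    channels); the ground-truth sidecar lists true centers and molecule
    identities.  Traces should be rendered noiseless (their means are used
    as expected spot photons; their background offset is removed) — pixel
    noise is added here.
    """
    if not traces:
        raise ValueError("no traces to render")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_frames = len(traces[0])
    if any(len(tr) != n_frames for tr in traces):
        raise ValueError("all traces must have the same frame count")
    margin = int(math.ceil(4 * psf_sigma_px)) + 2
    pos = _grid_positions(len(traces), image_shape, min_sep_px, margin, rng)

    donor = np.full((n_frames, *image_shape), background, dtype=float)
    acceptor = np.full((n_frames, *image_shape), background, dtype=float)
    dy, dx = channel_offset
    sidecar = []
    for tr, (y, x) in zip(traces, pos):
        sidecar.append(
            {"molecule_id": int(tr.molecule_id), "y": float(y), "x": float(x),
             "y_acceptor": float(y + dy), "x_acceptor": float(x + dx)}
        )
        d_photons = np.maximum(tr.donor - tr.background, 0.0)
        a_photons = np.maximum(tr.acceptor - tr.background, 0.0)
        for f in range(n_frames):
            if d_photons[f] > 0:
                _stamp(donor[f], y, x, d_photons[f], psf_sigma_px)
            if a_photons[f] > 0:
                _stamp(acceptor[f], y + dy, x + dx, a_photons[f], psf_sigma_px)

    if noise:
        donor = rng.poisson(donor).astype(float) + rng.normal(0, read_sigma, donor.shape)
        acceptor = rng.poisson(acceptor).astype(float) + rng.normal(
            0, read_sigma, acceptor.shape
        )
    donor16 = np.clip(np.round(donor), 0, 65535).astype(np.uint16)
    acceptor16 = np.clip(np.round(acceptor), 0, 65535).astype(np.uint16)
    return FrameStack(
        donor=donor16,
        acceptor=acceptor16,
        t=traces[0].t.copy(),
        exc=traces[0].exc.copy(),
        frame_s=traces[0].frame_s,
        background=background,
        read_sigma=read_sigma,
        psf_sigma_px=psf_sigma_px,
        channel_offset=channel_offset,
        sidecar=sidecar,
    )


def population_fret_samples(
    pop: AssemblyPopulation,
    time_index: int,
    rng: np.random.Generator,
    photo: Optional[PhotoParams] = None,
    sigma: float = 0.04,
) -> np.ndarray:
    """Per-molecule apparent FRET at one sampling time of a RecA series.

    Assembled molecules sit at the full-filament value; the rest at the
    substrate's bare (or ligand-shifted) value, with Gaussian molecule-to-
    molecule spread.
    """
    photo = photo or PhotoParams()
    assembled = pop.assembled[:, time_index]
    base = bare_fret(pop.substrate, photo)
    e = np.where(assembled, FULL_FILAMENT_E, base)
    return np.clip(e + rng.normal(0.0, sigma, size=e.size), -0.1, 1.1)
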
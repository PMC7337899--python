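"""DNA substrates for single-molecule G-quadruplex (G4) unwinding assays.

The assays use surface-immobilized partial-duplex DNA: a duplex anchor
(default 18 bp), an optional G4 block on the 3' single-stranded extension,
and a homopolymer-dT loading tail.  A donor (Cy3) and an acceptor (Cy5)
dye flank the structured region so FRET reports on the folding state.

Only lengths, topology, ligand state and buffer cation enter downstream
computations; base identity is carried for naming.  The parallel G4 block
(c-Myc-type) is modeled by its length and topology alone because no
computation here depends on its sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "SubstrateSpec",
    "Substrate",
    "SubstrateError",
    "build_substrate",
    "reca_nucleation_capacity",
    "HELICASE_FOOTPRINT_NT",
    "RECA_SITE_NT",
    "RECA_NUCLEUS_MONOMERS",
]

#: Minimum 3' tail for productive helicase loading (Rep-family footprint).
HELICASE_FOOTPRINT_NT = 8

#: Single-stranded DNA occluded per RecA monomer.
RECA_SITE_NT = 3

#: Monomers needed for a stable RecA nucleus (6 x 3 nt = 18 nt).
RECA_NUCLEUS_MONOMERS = 6

_TOPOLOGIES = ("nonparallel", "parallel", "none")
_LIGANDS = ("none", "braco19", "nmm")
_CATIONS = ("K", "Na")


class SubstrateError(ValueError):
    """Invalid substrate specification."""


@dataclass(frozen=True)
class SubstrateSpec:
    """Declarative description of a partial-duplex FRET substrate.

    Parameters
    ----------
    duplex_bp
        Length of the duplex anchor in base pairs (> 0).
    g4_motif
        Repeat unit of the G4-forming block (e.g. ``"TTAGGG"``).  Ignored
        when ``g4_repeats`` is zero.
    g4_repeats
        Number of motif repeats; zero means no G4 block.
    g4_topology
        ``"nonparallel"``, ``"parallel"`` or ``"none"``.  Must be ``"none"``
        exactly when ``g4_repeats`` is zero.
    tail_nt
        Length of the homopolymer-dT 3' loading tail in nucleotides.
    ligand
        G4-stabilizing ligand present: ``"none"``, ``"braco19"`` or ``"nmm"``.
    ligand_washed
        True once excess (free) ligand has been washed out, leaving only the
        G4-bound ligand.
    buffer_cation
        ``"K"`` (stabilizes G4 folding) or ``"Na"`` (destabilizes it).
    label
        Optional display name override (used e.g. for the parallel c-Myc
        construct whose sequence is not modeled).
    """

    duplex_bp: int = 18
    g4_motif: str = "TTAGGG"
    g4_repeats: int = 4
    g4_topology: str = "nonparallel"
    tail_nt: int = 15
    ligand: str = "none"
    ligand_washed: bool = False
    buffer_cation: str = "K"
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.duplex_bp <= 0:
            raise SubstrateError(f"duplex_bp must be > 0, got {self.duplex_bp}")
        if self.g4_repeats < 0:
            raise SubstrateError(f"g4_repeats must be >= 0, got {self.g4_repeats}")
        if self.tail_nt < 0:
            raise SubstrateError(f"tail_nt must be >= 0, got {self.tail_nt}")
        if self.g4_topology not in _TOPOLOGIES:
            raise SubstrateError(f"unknown g4_topology {self.g4_topology!r}")
        if (self.g4_topology == "none") != (self.g4_repeats == 0):
            raise SubstrateError(
                "g4_topology must be 'none' exactly when g4_repeats == 0 "
                f"(got topology={self.g4_topology!r}, repeats={self.g4_repeats})"
            )
        if self.g4_repeats > 0 and not self.g4_motif:
            raise SubstrateError("g4_motif must be nonempty when g4_repeats > 0")
        if self.ligand not in _LIGANDS:
            raise SubstrateError(f"unknown ligand {self.ligand!r}")
        if self.buffer_cation not in _CATIONS:
            raise SubstrateError(f"unknown buffer_cation {self.buffer_cation!r}")

    def with_(self, **changes) -> "SubstrateSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class Substrate:
    """A built substrate with derived geometric and loading properties.

    ``tracking_nt`` is the single-stranded length the motor must traverse
    (G4 block + tail); the competence flags are deterministic functions of
    ``SubstrateSpec`` (tail >= 8 nt for helicase loading, tail >= 18 nt for
    stable RecA nucleation).
    """

    spec: SubstrateSpec
    g4_nt: int
    tracking_nt: int
    helicase_loading_competent: bool
    reca_nucleation_competent: bool
    name: str

    @property
    def has_g4(self) -> bool:
        return self.g4_nt > 0

    @property
    def is_parallel(self) -> bool:
        return self.spec.g4_topology == "parallel"


def _render_name(spec: SubstrateSpec, g4_nt: int) -> str:
    if spec.label:
        core = spec.label
    elif g4_nt > 0:
        core = f"G4({spec.g4_motif}x{spec.g4_repeats})-T{spec.tail_nt}"
    else:
        core = f"T{spec.tail_nt}"
    if spec.ligand != "none":
        lig = {"braco19": "BRACO-19", "nmm": "NMM"}[spec.ligand]
        core += f"+{lig}" + ("(washed)" if spec.ligand_washed else "")
    if spec.buffer_cation != "K":
        core += f"[{spec.buffer_cation}+]"
    return core


def build_substrate(spec: SubstrateSpec) -> Substrate:
    """Derive lengths, loading competences and a stable display name.

    Examples
    --------
    >>> build_substrate(SubstrateSpec()).tracking_nt   # (24 + 15)
    39
    """
    g4_nt = len(spec.g4_motif) * spec.g4_repeats if spec.g4_repeats > 0 else 0
    tracking_nt = g4_nt + spec.tail_nt
    return Substrate(
        spec=spec,
        g4_nt=g4_nt,
        tracking_nt=tracking_nt,
        helicase_loading_competent=spec.tail_nt >= HELICASE_FOOTPRINT_NT,
        reca_nucleation_competent=spec.tail_nt >= RECA_SITE_NT * RECA_NUCLEUS_MONOMERS,
        name=_render_name(spec, g4_nt),
    )


def reca_nucleation_capacity(
    substrate: Substrate,
    site_nt: int = RECA_SITE_NT,
    nucleus_monomers: int = RECA_NUCLEUS_MONOMERS,
) -> bool:
    """Whether the free tail supports a stable RecA nucleus.

    A filament nucleus of ``nucleus_monomers`` monomers, each occluding
    ``site_nt`` nucleotides, requires a contiguous free stretch of
    ``site_nt * nucleus_monomers`` nucleotides (18 nt at the defaults).
    """
    if site_nt < 1:
        raise ValueError(f"site_nt must be >= 1, got {site_nt}")
    if nucleus_monomers < 1:
        raise ValueError(f"nucleus_monomers must be >= 1, got {nucleus_monomers}")
    return substrate.spec.tail_nt >= site_nt * nucleus_monomers
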
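"""Named, seeded synthetic-data scenarios with ground-truth sidecars.

Each scenario bundles a substrate, an actor (UvrD, Rep, Rep-X or RecA),
fully specified kinetic ground truth and a sampling schedule.  The
defaults encode the study conditions this package emulates:

* stage-II (G4 resolution) means of 40 / 20 / 10 s for UvrD / Rep / Rep-X
  at 2 mM ATP, with a shared commit probability (0.2) and refolding rate
  (1 /s); the unfolding attempt rate is solved per protein so the
  ATP-scaled closed-form mean hits the target;
* a stage-III (duplex unwinding) rate of 3 /s and a shared binding rate
  of 0.2 /s for all three helicases;
* ensemble survival Vmax values reproducing the 2-minute spot-loss
  fractions (75 / 50 / 25 % for Rep-X / Rep / UvrD on G4-T15), the no-G4
  controls (1.37 / 1.32 / 2.86 /min for T15 / G4-duplex / T40), the
  parallel c-Myc values (0.44 /min, Km 215 uM, Rep-X) and the T9 rates
  (0.157 / 0.163 / 0.184 /min with a 40 % active fraction);
* Km of 72 uM for non-parallel G4 substrates (one third of the parallel
  value) and 18 uM for the T40 control (four-fold lower);
* BRACO-19 dislodging scenarios with 10-minute losses of 25 / 65 / 85 %
  and a two-fold slowed G4-resolution stage;
* RecA assembly plateaus of 1.0 / 0.75 / 0.8 / 0.6 (T40 / G4-T15 / T15 /
  ligand-bound G4-T15) with half-times ordered T40 < G4-T15 < T15 <
  ligand-bound.

Generation is deterministic for a fixed (name, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    HelicaseParams,
    atp_scale,
    expected_stage2_duration,
    simulate_helicase_trace,
    simulate_survival_counts,
    with_atp,
)
from .photophysics import PhotoParams, bare_fret, render_trace
from .reca import RecAParams, simulate_reca_population
from .substrates import Substrate, SubstrateSpec, build_substrate

__all__ = ["Scenario", "list_scenarios", "get_scenario", "generate", "ATP_WORKING_UM"]

ATP_WORKING_UM = 2000.0

# Stage-II (G4 resolution) target means at working ATP, seconds.
_TAU2 = {"uvrd": 40.0, "rep": 20.0, "repx": 10.0}
_P_COMMIT = 0.2
_K_REFOLD = 1.0
_K_BIND = 0.2
_K_REL = 0.5
_K_DUP_EFF = 3.0  # stage-III rate at working ATP, 1/s

_KM_NONPARALLEL = 215.0 / 3.0  # ~72 uM
_KM_PARALLEL = 215.0
_KM_T40 = _KM_NONPARALLEL / 4.0  # ~18 uM


def _loss_rate_per_min(loss_fraction: float, minutes: float) -> float:
    """Exponential rate that loses ``loss_fraction`` of spots in ``minutes``."""
    return math.log(1.0 / (1.0 - loss_fraction)) / minutes


def _vmax_from_rate(rate_per_min: float, km: float, atp: float = ATP_WORKING_UM) -> float:
    return rate_per_min / atp_scale(atp, km)


def _helicase(
    actor: str,
    km: float = _KM_NONPARALLEL,
    vmax: float = 0.36,
    f_active: float = 1.0,
    parallel_competent: bool = True,
    tau2: Optional[float] = None,
) -> HelicaseParams:
    """Calibrated helicase parameters for one scenario.

    The base unfolding and duplex rates are solved so that their
    ATP-scaled values at 2 mM give the target stage-II mean and the 3 /s
    stage-III rate.
    """
    tau = tau2 if tau2 is not None else _TAU2[actor]
    s = atp_scale(ATP_WORKING_UM, km)
    refold_part = (1.0 - _P_COMMIT) / (_P_COMMIT * _K_REFOLD)
    k_unfold = 1.0 / (_P_COMMIT * s * (tau - refold_part))
    return HelicaseParams(
        k_bind=_K_BIND,
        k_unfold=k_unfold,
        k_refold=_K_REFOLD,
        p_commit=_P_COMMIT,
        k_dup=_K_DUP_EFF / s,
        k_rel=_K_REL,
        vmax=vmax,
        km=km,
        f_active=f_active,
        parallel_competent=parallel_competent,
    )


_G4_T15 = SubstrateSpec()  # (TTAGGG)x4 - T15, non-parallel
_G4_T9 = SubstrateSpec(tail_nt=9)
_T15 = SubstrateSpec(g4_repeats=0, g4_topology="none", tail_nt=15)
_T40 = SubstrateSpec(g4_repeats=0, g4_topology="none", tail_nt=40)
# Same length/composition as the G4 construct but pre-annealed as duplex
_G4_DUPLEX = SubstrateSpec(g4_repeats=0, g4_topology="none", tail_nt=15,
                           label="G4duplex-T15")
_CMYC_T15 = SubstrateSpec(g4_motif="GGGTGG", g4_repeats=4, g4_topology="parallel",
                          tail_nt=15, label="cMyc-T15")
_G4_T15_BRACO = SubstrateSpec(ligand="braco19", ligand_washed=True)
_G4_T15_NA = SubstrateSpec(buffer_cation="Na")

# Default ATP titration series, uM.
_ATP_SERIES = (1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0)
_ATP_SERIES_T40 = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 500.0, 2000.0)

# Survival sampling schedule: 2-s short movies every 30 s for 10 min.
_SURVIVAL_TIMES = tuple(np.arange(0.0, 601.0, 30.0))
_RECA_TIMES = tuple(np.arange(0.0, 1801.0, 60.0))


@dataclass
class Scenario:
    """A named study condition with complete ground truth."""

    name: str
    kind: str  # 'survival' | 'titration' | 'flow' | 'histogram' | 'reca'
    substrate_spec: SubstrateSpec
    actor: str
    helicase: Optional[HelicaseParams] = None
    reca: Optional[RecAParams] = None
    reca_plateau: Optional[float] = None
    reca_mean_assembly_s: Optional[float] = None
    atp_um: Sequence[float] = (ATP_WORKING_UM,)
    times_s: Sequence[float] = _SURVIVAL_TIMES
    n_views: int = 20
    spots_per_view: int = 350
    n_molecules: int = 300
    t_flow_s: float = 10.0
    t_end_s: float = 150.0
    seed: int = 7
    notes: str = ""

    @property
    def substrate(self) -> Substrate:
        return build_substrate(self.substrate_spec)

    def ground_truth(self) -> Dict:
        """Complete ground-truth parameter record for the sidecar."""
        sub = self.substrate
        truth: Dict = {
            "scenario": self.name,
            "kind": self.kind,
            "actor": self.actor,
            "substrate": sub.name,
            "tracking_nt": sub.tracking_nt,
            "atp_um": list(self.atp_um),
        }
        if self.helicase is not None:
            h = self.helicase
            truth["helicase"] = asdict(h)
            truth["f_active"] = h.f_active
            at = with_atp(h, ATP_WORKING_UM)
            truth["expected_stage2_s"] = expected_stage2_duration(at)
            truth["stage3_rate_per_s"] = at.k_dup
            truth["rate_at_working_atp_per_min"] = h.vmax * atp_scale(
                ATP_WORKING_UM, h.km
            )
        if self.reca is not None:
            truth["reca"] = asdict(self.reca)
            truth["plateau"] = self.reca_plateau
            truth["mean_assembly_s"] = self.reca_mean_assembly_s
            if self.reca_plateau and self.reca_mean_assembly_s:
                truth["t_half_min"] = self.reca_mean_assembly_s * math.log(2) / 60.0
        return truth


def _survival(name, spec, actor, vmax, km, f_active=1.0, parallel_competent=True,
              notes="", **kw) -> Scenario:
    return Scenario(
        name=name, kind="survival", substrate_spec=spec, actor=actor,
        helicase=_helicase(actor, km=km, vmax=vmax, f_active=f_active,
                           parallel_competent=parallel_competent),
        notes=notes, **kw,
    )


def _build_catalog() -> Dict[str, Scenario]:
    cat: Dict[str, Scenario] = {}

    def add(s: Scenario) -> None:
        cat[s.name] = s

    # --- G4-T15 survival at 2 mM ATP: 75/50/25% loss in 2 min ------------
    for actor, loss in (("repx", 0.75), ("rep", 0.50), ("uvrd", 0.25)):
        vmax = _vmax_from_rate(_loss_rate_per_min(loss, 2.0), _KM_NONPARALLEL)
        add(_survival(
            f"g4t15_{actor}_survival", _G4_T15, actor, vmax, _KM_NONPARALLEL,
            notes=f"{actor} on non-parallel G4-T15; calibrated so {loss:.0%} of "
                  "spots are lost within 2 min at 2 mM ATP.",
        ))

    # --- ATP titrations ---------------------------------------------------
    for actor in ("uvrd", "rep", "repx"):
        base = cat[f"g4t15_{actor}_survival"]
        add(Scenario(
            name=f"g4t15_{actor}_atp_titration", kind="titration",
            substrate_spec=_G4_T15, actor=actor, helicase=base.helicase,
            atp_um=_ATP_SERIES,
            notes="ATP titration (1 uM - 2 mM) of the G4-T15 survival assay.",
        ))
    add(Scenario(
        name="t40_rep_atp_titration", kind="titration", substrate_spec=_T40,
        actor="rep", helicase=_helicase("rep", km=_KM_T40, vmax=2.86),
        atp_um=_ATP_SERIES_T40,
        notes="No-G4 T40 partial-duplex control; Vmax 2.86 /min, Km ~18 uM "
              "(four-fold below the G4 substrate).",
    ))
    add(Scenario(
        name="t15_rep_atp_titration", kind="titration", substrate_spec=_T15,
        actor="rep", helicase=_helicase("rep", km=_KM_NONPARALLEL, vmax=1.37),
        atp_um=_ATP_SERIES,
        notes="No-G4 T15 control; Vmax 1.37 /min.",
    ))
    add(Scenario(
        name="g4duplex_rep_atp_titration", kind="titration",
        substrate_spec=_G4_DUPLEX, actor="rep",
        helicase=_helicase("rep", km=_KM_NONPARALLEL, vmax=1.32),
        atp_um=_ATP_SERIES,
        notes="G4 sequence pre-annealed into duplex (no folded G4); "
              "Vmax 1.32 /min.",
    ))
    add(Scenario(
        name="cmyc_repx_atp_titration", kind="titration",
        substrate_spec=_CMYC_T15, actor="repx",
        helicase=_helicase("repx", km=_KM_PARALLEL, vmax=0.44, f_active=0.75),
        atp_um=_ATP_SERIES,
        notes="Parallel c-Myc-type G4; only Rep-X resolves it "
              "(Vmax 0.44 /min, Km 215 uM, ~75% of molecules lost in 10 min).",
    ))

    # --- T9 short-tail scenarios: 40% active fraction ---------------------
    for actor, rate in (("uvrd", 0.157), ("rep", 0.163), ("repx", 0.184)):
        add(_survival(
            f"t9_{actor}_survival", _G4_T9, actor,
            _vmax_from_rate(rate, _KM_NONPARALLEL), _KM_NONPARALLEL,
            f_active=0.4,
            notes=f"Short T9 tail: only 40% of molecules complete unwinding; "
                  f"rate {rate} /min.",
        ))

    # --- Parallel G4 with Rep/UvrD: no resolution -------------------------
    for actor in ("rep", "uvrd"):
        add(_survival(
            f"cmyc_{actor}_survival", _CMYC_T15, actor,
            0.30, _KM_PARALLEL, f_active=0.10, parallel_competent=False,
            notes=f"{actor} cannot resolve the parallel G4; ~10% loss in 10 min.",
        ))

    # --- BRACO-19 dislodging: 25/65/85% loss in 10 min --------------------
    for actor, loss in (("uvrd", 0.25), ("rep", 0.65), ("repx", 0.85)):
        vmax = _vmax_from_rate(_loss_rate_per_min(loss, 10.0), _KM_NONPARALLEL)
        add(_survival(
            f"braco_{actor}_survival", _G4_T15_BRACO, actor, vmax,
            _KM_NONPARALLEL,
            notes=f"Washed BRACO-19 bound to G4; {actor} dislodges it and "
                  f"unwinds ({loss:.0%} loss in 10 min).",
        ))

    # --- Real-time flow traces -------------------------------------------
    for actor in ("uvrd", "rep", "repx"):
        base = cat[f"g4t15_{actor}_survival"]
        add(Scenario(
            name=f"g4t15_{actor}_flow", kind="flow", substrate_spec=_G4_T15,
            actor=actor, helicase=base.helicase, n_molecules=300,
            t_flow_s=10.0, t_end_s=50.0 + 8.0 * _TAU2[actor],
            notes="Real-time flow traces showing binding (PIFE), repetitive "
                  "G4 unfolding, duplex unwinding and strand release.",
        ))
    add(Scenario(
        name="t15_rep_flow", kind="flow", substrate_spec=_T15, actor="rep",
        helicase=_helicase("rep", km=_KM_NONPARALLEL, vmax=1.37, tau2=20.0),
        n_molecules=300, t_flow_s=10.0, t_end_s=80.0,
        notes="No-G4 control flow traces: no repetitive FRET fluctuation, "
              "only delayed strand departure.",
    ))
    add(Scenario(
        name="cmyc_rep_flow", kind="flow", substrate_spec=_CMYC_T15, actor="rep",
        helicase=_helicase("rep", km=_KM_PARALLEL, vmax=0.30,
                           parallel_competent=False),
        n_molecules=200, t_flow_s=10.0, t_end_s=120.0,
        notes="Rep on parallel G4: binds and cycles but never unwinds.",
    ))
    for actor in ("rep", "repx"):
        base = cat[f"g4t15_{actor}_survival"]
        add(Scenario(
            name=f"braco_{actor}_flow", kind="flow",
            substrate_spec=_G4_T15_BRACO, actor=actor, helicase=base.helicase,
            n_molecules=200, t_flow_s=25.0, t_end_s=80.0 + 8.0 * _TAU2[actor],
            notes="Seven-step ligand protocol: ligand flow, wash, protein "
                  "loading, dislodging lag, G4 resolution, duplex unwinding, "
                  "strand departure.",
        ))

    # --- Population FRET histogram (no protein) ---------------------------
    add(Scenario(
        name="g4t15_histogram", kind="histogram", substrate_spec=_G4_T15,
        actor="none", n_molecules=6000,
        notes="DNA-only ALEX short movies (21 frames each) for the folded-G4 "
              "FRET histogram; >6000 molecules, peak at ~0.5.",
    ))

    # --- RecA assembly -----------------------------------------------------
    reca_defaults = RecAParams()
    reca_na = RecAParams(k_g4_refold=0.002)
    for name, spec, params, plateau, mean_s, notes in (
        ("reca_t40", _T40, reca_defaults, 1.00, 72.0,
         "Stable filament on T40; full assembly."),
        ("reca_g4t15", _G4_T15, reca_defaults, 0.75, 150.0,
         "Dynamic invasion of the non-parallel G4; ~75% plateau."),
        ("reca_t15", _T15, reca_defaults, 0.80, 240.0,
         "T15 below the 18-nt stable nucleus: transient binding, ~80% plateau."),
        ("reca_g4t15_braco", _G4_T15_BRACO, reca_defaults, 0.60, 480.0,
         "Ligand-bound G4 slows invasion; ~60% plateau in 30 min."),
        ("reca_cmyc_t15", _CMYC_T15, reca_defaults, 0.05, 600.0,
         "Parallel G4 is never disrupted; coverage limited to the tail."),
        ("reca_g4t15_na", _G4_T15_NA, reca_na, 0.95, 150.0,
         "Na+ buffer destabilizes the G4: complete unfolding, T40-like."),
    ):
        add(Scenario(
            name=name, kind="reca", substrate_spec=spec, actor="reca",
            reca=params, reca_plateau=plateau, reca_mean_assembly_s=mean_s,
            times_s=_RECA_TIMES, n_molecules=2000, notes=notes,
        ))

    return cat


def list_scenarios() -> Dict[str, Scenario]:
    """The full scenario catalog (rebuilt on each call)."""
    return _build_catalog()


def get_scenario(name: str) -> Scenario:
    cat = _build_catalog()
    if name not in cat:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(sorted(cat))}"
        )
    return cat[name]


def _traces_frame(traces) -> pd.DataFrame:
    frames = []
    for tr in traces:
        df = tr.to_frame()
        df.insert(0, "molecule_id", tr.molecule_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate(
    name: str,
    seed: int,
    outdir,
    output_mode: str = "traces",
    n_molecules: Optional[int] = None,
    photo: Optional[PhotoParams] = None,
) -> Dict:
    """Generate a scenario's synthetic data set and ground-truth sidecar.

    Writes CSV (traces mode) or TIFF (movies mode) outputs plus a JSON
    sidecar recording every ground-truth parameter.  Deterministic for a
    fixed (name, seed).  Returns the sidecar dict.
    """
    if output_mode not in ("traces", "movies"):
        raise ValueError("output_mode must be 'traces' or 'movies'")
    scen = get_scenario(name)
    if output_mode == "movies" and scen.kind != "histogram":
        raise ValueError(
            "movies mode renders short ALEX histogram movies; use traces "
            f"mode for {scen.kind!r} scenarios"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    photo = photo or PhotoParams()
    sub = scen.substrate
    truth = scen.ground_truth()
    truth["seed"] = seed

    if scen.kind in ("survival", "titration"):
        per_molecule = []
        for atp in scen.atp_um:
            sc = simulate_survival_counts(
                scen.helicase, sub, atp, scen.n_views, scen.spots_per_view,
                scen.times_s, rng=rng,
            )
            df = pd.DataFrame(
                sc.counts,
                columns=[f"t{int(t)}s" for t in sc.times_s],
            )
            df.insert(0, "view", np.arange(scen.n_views))
            df.insert(0, "atp_um", atp)
            per_molecule.append(df)
            truth.setdefault("per_atp", {})[str(atp)] = sc.truth
        pd.concat(per_molecule, ignore_index=True).to_csv(
            outdir / "survival_counts.csv", index=False
        )
    elif scen.kind == "flow":
        n = n_molecules if n_molecules is not None else scen.n_molecules
        ligand = sub.spec.ligand != "none"
        from dataclasses import replace as _replace

        # flow-trace sets are pre-screened for an active acceptor
        flow_photo = _replace(photo, acceptor_dark_fraction=0.0)
        traces = []
        mol_truth = []
        for i in range(n):
            traj = simulate_helicase_trace(
                scen.helicase, sub, scen.t_flow_s, scen.t_end_s, rng=rng
            )
            tr = render_trace(traj, flow_photo, sub, rng=rng, molecule_id=i)
            traces.append(tr)
            mol_truth.append({k: v for k, v in tr.truth.items()
                              if not isinstance(v, np.ndarray)})
        _traces_frame(traces).to_csv(outdir / "flow_traces.csv", index=False)
        truth["molecules"] = mol_truth
        truth["ligand_protocol"] = ligand
    elif scen.kind == "histogram":
        n = n_molecules if n_molecules is not None else scen.n_molecules
        from .kinetics import StateTrajectory

        t_end = 21 * photo.frame_s
        idle = "LIGAND_WASHED" if sub.spec.ligand != "none" else "FREE"
        traces = []
        mol_truth = []
        movie_photo = (
            replace(photo, noise=False, background=0.0, read_sigma=0.0)
            if output_mode == "movies" else photo
        )
        for i in range(n):
            traj = StateTrajectory(
                segments=[(idle, 0.0, t_end)], active=False, t_end=t_end
            )
            tr = render_trace(
                traj, movie_photo, sub, rng=rng, alex=True, molecule_id=i
            )
            traces.append(tr)
            mol_truth.append({"acceptor_dark": tr.truth["acceptor_dark"]})
        if output_mode == "movies":
            # one short two-channel TIFF stack per imaging field
            from .photophysics import render_movie

            per_field = 300
            fields = []
            for f0 in range(0, n, per_field):
                stack = render_movie(
                    traces[f0 : f0 + per_field], image_shape=(170, 340),
                    min_sep_px=10, rng=rng,
                )
                fid = f0 // per_field
                stack.save_tiff(
                    outdir / f"field{fid:02d}_donor.tif",
                    outdir / f"field{fid:02d}_acceptor.tif",
                )
                fields.append({"field": fid, "spots": stack.sidecar})
            truth["fields"] = fields
        else:
            _traces_frame(traces).to_csv(outdir / "alex_traces.csv", index=False)
        truth["molecules"] = mol_truth
        truth["bare_fret"] = float(bare_fret(sub, photo))
    elif scen.kind == "reca":
        pop = simulate_reca_population(
            scen.reca, sub, scen.times_s, scen.n_molecules, rng=rng,
            plateau=scen.reca_plateau, mean_assembly_s=scen.reca_mean_assembly_s,
        )
        df = pd.DataFrame(pop.assembled, columns=[f"t{int(t)}s" for t in pop.times_s])
        df.insert(0, "molecule_id", np.arange(scen.n_molecules))
        df.to_csv(outdir / "reca_assembly.csv", index=False)
        truth.update(pop.truth)
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario kind {scen.kind!r}")

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
    return truth
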
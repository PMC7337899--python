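"""End-to-end analysis pipeline: scenario -> estimates -> report.

``run_pipeline`` simulates a named scenario, runs the matching analysis
chain (survival fitting, Michaelis-Menten titration, trace segmentation,
histogram fitting or RecA assembly kinetics) and writes a JSON report
containing the estimates alongside the generator's ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .detection import count_spots_series
from .fretstats import build_histogram, estimate_leakage, filter_donor_only, \
    fit_gaussians, molecule_fret
from .kinetics import StateTrajectory, expected_stage2_duration, \
    simulate_helicase_trace, simulate_survival_counts, with_atp
from .kinfit import assembly_kinetics, fit_decay, fit_mm
from .photophysics import PhotoParams, population_fret_samples, render_trace
from .reca import simulate_reca_population
from .scenarios import ATP_WORKING_UM, Scenario, get_scenario
from .segmentation import SegmentationConfig, build_dwell_table, segment_traces, \
    stage_rates

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Fully serializable pipeline configuration.

    A run needs only a scenario name; everything else has defaults.
    """

    scenario: str
    seed: int = 1
    outdir: Optional[str] = None
    mode: str = "traces"
    n_molecules: Optional[int] = None
    photo: PhotoParams = field(default_factory=PhotoParams)

    def to_dict(self) -> Dict:
        d = {
            "scenario": self.scenario,
            "seed": self.seed,
            "outdir": self.outdir,
            "mode": self.mode,
            "n_molecules": self.n_molecules,
        }
        return d


def _relative_delta(estimate: float, truth: float) -> float:
    if truth == 0:
        return math.nan
    return (estimate - truth) / truth


def _survival_rates(scen: Scenario, rng, counts_by_atp=None):
    """Simulate (or reuse) survival counts and fit a decay per ATP."""
    sub = scen.substrate
    rates = {}
    fits = {}
    for atp in scen.atp_um:
        sc = simulate_survival_counts(
            scen.helicase, sub, atp, scen.n_views, scen.spots_per_view,
            scen.times_s, rng=rng,
        )
        series = count_spots_series(sc.times_s, sc.total())
        fit = fit_decay(series)
        rates[atp] = fit.k_per_min
        fits[atp] = {
            "k_per_min": fit.k_per_min,
            "k_se": fit.k_se,
            "f_active": fit.f_active,
            "truth_rate_per_min": sc.truth["rate_per_min"],
            "truth_f_active": sc.truth["f_active"],
        }
    return rates, fits


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run a scenario end to end and return (and optionally write) the report."""
    scen = get_scenario(config.scenario)
    rng = np.random.default_rng(config.seed)
    photo = config.photo
    sub = scen.substrate
    report: Dict = {
        "config": config.to_dict(),
        "scenario": scen.name,
        "kind": scen.kind,
        "substrate": sub.name,
        "truth": scen.ground_truth(),
    }

    if scen.kind == "survival":
        rates, fits = _survival_rates(scen, rng)
        atp = scen.atp_um[0]
        report["decay_fits"] = {str(a): f for a, f in fits.items()}
        truth_rate = fits[atp]["truth_rate_per_min"]
        report["estimates"] = {
            "k_per_min": rates[atp],
            "truth_k_per_min": truth_rate,
            "k_rel_delta": _relative_delta(rates[atp], truth_rate),
        }
    elif scen.kind == "titration":
        rates, fits = _survival_rates(scen, rng)
        atps = np.array(sorted(rates))
        mm = fit_mm(atps, np.array([rates[a] for a in atps]))
        report["decay_fits"] = {str(a): f for a, f in fits.items()}
        report["estimates"] = {
            "vmax_per_min": mm.vmax_per_min,
            "km_um": mm.km_um,
            "vmax_se": mm.vmax_se,
            "km_se": mm.km_se,
            "truth_vmax_per_min": scen.helicase.vmax,
            "truth_km_um": scen.helicase.km,
            "vmax_rel_delta": _relative_delta(mm.vmax_per_min, scen.helicase.vmax),
            "km_rel_delta": _relative_delta(mm.km_um, scen.helicase.km),
        }
    elif scen.kind == "flow":
        n = config.n_molecules or scen.n_molecules
        ligand = sub.spec.ligand != "none"
        # flow-trace sets are pre-screened for an active acceptor (molecule
        # selection in the raw movies), so no acceptor-dark subpopulation
        from dataclasses import replace as _replace

        flow_photo = _replace(photo, acceptor_dark_fraction=0.0)
        traces = []
        for i in range(n):
            traj = simulate_helicase_trace(
                scen.helicase, sub, scen.t_flow_s, scen.t_end_s, rng=rng
            )
            traces.append(render_trace(traj, flow_photo, sub, rng=rng, molecule_id=i))
        seg_cfg = SegmentationConfig.from_photo(flow_photo, sub)
        segs = segment_traces(traces, scen.t_flow_s, seg_cfg, ligand)
        table = build_dwell_table(segs)
        rates_df = stage_rates(table)
        n_accepted = sum(s.accepted for s in segs)
        at = with_atp(scen.helicase, ATP_WORKING_UM)
        report["stage_rates"] = rates_df.to_dict(orient="records")
        report["estimates"] = {
            "n_traces": n,
            "n_accepted": n_accepted,
            "rejection_rate": 1.0 - n_accepted / n,
            "mean_stage2_s": table.mean("g4_resolution")
            if table.n("g4_resolution") else math.nan,
            "truth_stage2_s": expected_stage2_duration(at),
            "stage3_rate_per_s": 1.0 / table.mean("duplex_unwinding")
            if table.n("duplex_unwinding") else math.nan,
            "truth_stage3_rate_per_s": at.k_dup,
            "binding_rate_per_s": 1.0 / table.mean("binding")
            if table.n("binding") else math.nan,
            "truth_binding_rate_per_s": scen.helicase.k_bind,
        }
    elif scen.kind == "histogram":
        n = config.n_molecules or scen.n_molecules
        t_end = 21 * photo.frame_s
        idle = "LIGAND_WASHED" if sub.spec.ligand != "none" else "FREE"
        traces = []
        for i in range(n):
            traj = StateTrajectory(
                segments=[(idle, 0.0, t_end)], active=False, t_end=t_end
            )
            traces.append(render_trace(traj, photo, sub, rng=rng, alex=True,
                                       molecule_id=i))
        leak = estimate_leakage(traces)
        kept = [tr for tr in traces if filter_donor_only(tr)]
        es = [molecule_fret(tr, leakage=leak) for tr in kept]
        hist = build_histogram(es, condition=sub.name)
        fit = fit_gaussians(hist, k=1)
        from .photophysics import bare_fret

        report["estimates"] = {
            "n_molecules": len(traces),
            "n_kept": len(kept),
            "leakage_estimate": leak,
            "truth_leakage": photo.leakage,
            "peak_center": fit.dominant.center,
            "peak_sigma": fit.dominant.sigma,
            "truth_fret": bare_fret(sub, photo),
        }
    elif scen.kind == "reca":
        pop = simulate_reca_population(
            scen.reca, sub, scen.times_s, config.n_molecules or scen.n_molecules,
            rng=rng, plateau=scen.reca_plateau,
            mean_assembly_s=scen.reca_mean_assembly_s,
        )
        hists = [
            build_histogram(
                population_fret_samples(pop, j, rng, photo), t_s=float(t)
            )
            for j, t in enumerate(pop.times_s)
        ]
        kin = assembly_kinetics(hists, pop.times_s)
        report["estimates"] = {
            "plateau": kin.plateau,
            "t_half_min": kin.t_half_min,
            "truth_plateau": pop.truth["plateau"],
            "truth_t_half_min": pop.truth["t_half_min"],
            "fractions": list(kin.fractions),
        }
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario kind {scen.kind!r}")

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
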
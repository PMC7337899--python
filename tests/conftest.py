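"""Shared fixtures: substrates, rendering parameters and trace factories."""

from dataclasses import replace

import numpy as np
import pytest

from g4fret.kinetics import simulate_helicase_trace
from g4fret.photophysics import PhotoParams, render_trace
from g4fret.scenarios import get_scenario
from g4fret.segmentation import SegmentationConfig
from g4fret.substrates import SubstrateSpec, build_substrate


@pytest.fixture(scope="session")
def g4_t15():
    return build_substrate(SubstrateSpec())


@pytest.fixture(scope="session")
def t40():
    return build_substrate(SubstrateSpec(g4_repeats=0, g4_topology="none", tail_nt=40))


@pytest.fixture(scope="session")
def t15():
    return build_substrate(SubstrateSpec(g4_repeats=0, g4_topology="none", tail_nt=15))


@pytest.fixture(scope="session")
def cmyc_t15():
    return build_substrate(
        SubstrateSpec(g4_motif="GGGTGG", g4_repeats=4, g4_topology="parallel",
                      tail_nt=15, label="cMyc-T15")
    )


@pytest.fixture(scope="session")
def clean_photo():
    """Noise-free rendering: exact means, no bleaching, no dark acceptors."""
    return replace(
        PhotoParams(), noise=False, background=0.0, read_sigma=0.0,
        acceptor_dark_fraction=0.0, donor_bleach_rate=0.0, acceptor_bleach_rate=0.0,
    )


@pytest.fixture(scope="session")
def flow_photo():
    """Default noisy rendering for flow traces (acceptor pre-screened)."""
    return replace(PhotoParams(), acceptor_dark_fraction=0.0)


def make_flow_set(scenario_name: str, n: int, seed: int, photo: PhotoParams):
    """Simulate and render ``n`` flow traces of a catalog scenario."""
    scen = get_scenario(scenario_name)
    sub = scen.substrate
    rng = np.random.default_rng(seed)
    traces, truths = [], []
    for i in range(n):
        traj = simulate_helicase_trace(
            scen.helicase, sub, scen.t_flow_s, scen.t_end_s, rng=rng
        )
        traces.append(render_trace(traj, photo, sub, rng=rng, molecule_id=i))
        truths.append(traj.truth)
    cfg = SegmentationConfig.from_photo(photo, sub)
    return scen, traces, truths, cfg


@pytest.fixture(scope="session")
def rep_flow_set(flow_photo):
    """500 default-noise Rep flow traces with ground truth (shared)."""
    return make_flow_set("g4t15_rep_flow", 500, 20260101, flow_photo)
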
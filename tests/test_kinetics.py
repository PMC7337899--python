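"""Helicase kinetic model: closed forms, event-driven simulation, survival."""

import math

import numpy as np
import pytest
from scipy import stats

from g4fret.kinetics import (
    HelicaseParams,
    atp_scale,
    expected_stage2_duration,
    sample_stage2_durations,
    simulate_helicase_trace,
    simulate_survival_counts,
    unwinding_rate_at_atp,
    with_atp,
)
from g4fret.scenarios import ATP_WORKING_UM, get_scenario


class TestClosedForms:
    def test_stage2_single_step(self):
        """With certain commitment stage II is one exponential folded dwell."""
        p = HelicaseParams(p_commit=1.0, k_unfold=0.1)
        assert expected_stage2_duration(p) == pytest.approx(10.0)

    def test_stage2_alternating_scheme(self):
        """Geometric cycle count: 1/(p k_u) + (1-p)/(p k_r) = 4 + 1.5 s."""
        p = HelicaseParams(k_unfold=1.0, k_refold=2.0, p_commit=0.25)
        assert expected_stage2_duration(p) == pytest.approx(5.5)

    def test_stage2_never_commits_raises(self):
        p = HelicaseParams()
        p.p_commit = 0.0  # bypass constructor validation deliberately
        with pytest.raises(ValueError):
            expected_stage2_duration(p)

    def test_rep_default_calibration_is_20s(self):
        """The Rep scenario's ATP-scaled stage-II mean is 20 s at 2 mM."""
        scen = get_scenario("g4t15_rep_flow")
        at = with_atp(scen.helicase, ATP_WORKING_UM)
        assert expected_stage2_duration(at) == pytest.approx(20.0)

    def test_mm_rate_half_saturation_and_limit(self):
        p = HelicaseParams(vmax=2.0, km=100.0)
        assert unwinding_rate_at_atp(p, 100.0) == pytest.approx(1.0)
        assert unwinding_rate_at_atp(p, 1e9) == pytest.approx(2.0, rel=1e-6)

    def test_mm_rate_printed_example(self):
        p = HelicaseParams(vmax=0.44, km=215.0)
        assert unwinding_rate_at_atp(p, 2000.0) == pytest.approx(
            0.44 * 2000 / 2215, rel=1e-12
        )

    def test_atp_scale_negative_raises(self):
        with pytest.raises(ValueError):
            atp_scale(-1.0, 100.0)


class TestEventSimulation:
    def test_stage2_mc_matches_closed_form(self):
        """Vectorized MC of the alternating scheme: 10^5 draws within 2%."""
        p = HelicaseParams(k_unfold=1.0, k_refold=2.0, p_commit=0.25)
        d = sample_stage2_durations(p, 100_000, np.random.default_rng(0))
        assert d.mean() == pytest.approx(5.5, rel=0.02)

    def test_certain_commit_dwell_is_exponential(self, g4_t15):
        """p_commit = 1: stage-II dwell matches Exp(k_unfold) within 3 SE."""
        p = HelicaseParams(p_commit=1.0, k_unfold=0.5)
        expected = 1.0 / with_atp(p, 2000.0).k_unfold
        rng = np.random.default_rng(1)
        taus = []
        for _ in range(10_000):
            traj = simulate_helicase_trace(p, g4_t15, 0.1, 1e6, rng=rng)
            taus.append(traj.truth["t_commit"] - traj.truth["t_bind"])
        taus = np.array(taus)
        se = taus.std() / math.sqrt(len(taus))
        assert abs(taus.mean() - expected) < 3 * se

    def test_folded_dwells_pass_ks_against_exponential(self, g4_t15):
        """Waiting times in the folded state are Exp(total exit rate)."""
        scen = get_scenario("g4t15_rep_flow")
        at = with_atp(scen.helicase, ATP_WORKING_UM)
        rng = np.random.default_rng(9)
        dwells = []
        while len(dwells) < 10_000:
            traj = simulate_helicase_trace(
                scen.helicase, g4_t15, 1.0, 400.0, rng=rng
            )
            for st, a, b in traj.segments[:-2]:
                if st == "G4_FOLDED_B":
                    dwells.append(b - a)
        p = stats.kstest(
            np.array(dwells[:10_000]), "expon", args=(0, 1 / at.k_unfold)
        ).pvalue
        assert p > 0.01

    def test_trajectory_invariants_and_ordering(self, g4_t15):
        scen = get_scenario("g4t15_rep_flow")
        rng = np.random.default_rng(4)
        for _ in range(200):
            traj = simulate_helicase_trace(scen.helicase, g4_t15, 10.0, 150.0, rng=rng)
            traj.validate()
            states = traj.states()
            if "DUPLEX_UNWINDING" in states:
                assert states.index("DUPLEX_UNWINDING") > states.index("G4_FOLDED_B")

    def test_identical_seed_gives_identical_trajectory(self, g4_t15):
        scen = get_scenario("g4t15_rep_flow")
        a = simulate_helicase_trace(scen.helicase, g4_t15, 10.0, 150.0, seed=123)
        b = simulate_helicase_trace(scen.helicase, g4_t15, 10.0, 150.0, seed=123)
        assert a.segments == b.segments
        assert a.truth == b.truth

    def test_parallel_g4_never_unwound_by_incompetent_protein(self, cmyc_t15):
        scen = get_scenario("cmyc_rep_flow")
        rng = np.random.default_rng(5)
        for _ in range(300):
            traj = simulate_helicase_trace(
                scen.helicase, cmyc_t15, 10.0, 120.0, rng=rng
            )
            assert "DUPLEX_UNWINDING" not in traj.states()

    def test_non_loading_substrate_stays_free(self):
        from g4fret.substrates import SubstrateSpec, build_substrate

        sub = build_substrate(SubstrateSpec(tail_nt=0))
        traj = simulate_helicase_trace(HelicaseParams(), sub, 10.0, 60.0, seed=0)
        assert traj.states() == ["FREE"]

    def test_flow_after_end_raises(self, g4_t15):
        with pytest.raises(ValueError):
            simulate_helicase_trace(HelicaseParams(), g4_t15, 60.0, 60.0, seed=0)

    def test_ligand_protocol_inserts_lag_before_cycling(self):
        from g4fret.substrates import SubstrateSpec, build_substrate

        sub = build_substrate(SubstrateSpec(ligand="braco19", ligand_washed=True))
        scen = get_scenario("braco_rep_flow")
        rng = np.random.default_rng(6)
        seen_lag = 0
        for _ in range(100):
            traj = simulate_helicase_trace(scen.helicase, sub, 25.0, 240.0, rng=rng)
            states = traj.states()
            if "G4_UNFOLDED_B" in states:
                assert "LIGAND_LAG" in states
                assert states.index("LIGAND_LAG") < states.index("G4_UNFOLDED_B")
                seen_lag += 1
        assert seen_lag > 50

    def test_ligand_lag_doubles_expected_resolution_time(self):
        """Lag mean defaults to (slowdown-1) x tau_II, so total is 2 x."""
        p = HelicaseParams()
        tau = expected_stage2_duration(p)
        assert 1.0 / p.effective_lag_rate() == pytest.approx(tau)


class TestSurvivalCounts:
    def test_expected_counts_follow_survival_law(self, g4_t15):
        scen = get_scenario("g4t15_rep_survival")
        times = np.arange(0.0, 601.0, 30.0)
        rate = unwinding_rate_at_atp(scen.helicase, 2000.0)
        for seed in range(20):
            sc = simulate_survival_counts(
                scen.helicase, g4_t15, 2000.0, 20, 350, times, seed=seed
            )
            n0 = 20 * 350
            p = np.exp(-rate * times / 60.0)
            z = (sc.total() - n0 * p) / np.sqrt(n0 * p * (1 - p) + 1e-9)
            assert np.all(np.abs(z) < 4.5)

    def test_no_unwinding_keeps_counts_constant(self, g4_t15):
        p = HelicaseParams(vmax=0.0, f_active=1.0)
        sc = simulate_survival_counts(
            p, g4_t15, 2000.0, 5, 300, [0, 60, 120, 300], seed=3
        )
        assert np.all(sc.counts == 300)

    def test_repx_loses_about_75pct_in_two_minutes(self, g4_t15):
        """The Rep-X calibration: ~75% of molecules gone at t = 2 min."""
        scen = get_scenario("g4t15_repx_survival")
        sc = simulate_survival_counts(
            scen.helicase, g4_t15, 2000.0, 20, 350, [0.0, 120.0], seed=11
        )
        lost = 1.0 - sc.total()[1] / sc.total()[0]
        assert lost == pytest.approx(0.75, abs=0.03)

    def test_inactive_fraction_persists(self, g4_t15):
        scen = get_scenario("t9_rep_survival")
        sub = get_scenario("t9_rep_survival").substrate
        sc = simulate_survival_counts(
            scen.helicase, sub, 2000.0, 20, 350, [0.0, 6000.0], seed=2
        )
        frac_left = sc.total()[1] / sc.total()[0]
        assert frac_left == pytest.approx(1 - scen.helicase.f_active, abs=0.03)

    def test_bad_arguments_raise(self, g4_t15):
        p = HelicaseParams()
        with pytest.raises(ValueError):
            simulate_survival_counts(p, g4_t15, 2000.0, 5, 0, [0, 30], seed=0)
        with pytest.raises(ValueError):
            simulate_survival_counts(p, g4_t15, 2000.0, 5, 10, [30, 0], seed=0)
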
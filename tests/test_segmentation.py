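"""Trace segmentation: PIFE binding, stage boundaries, dwell statistics."""

import math

import numpy as np
import pytest

from g4fret.segmentation import (
    SegmentationConfig,
    build_dwell_table,
    detect_binding,
    dwell_histogram,
    segment_stages,
    segment_traces,
    stage_rates,
)
from tests.conftest import make_flow_set


class TestDetectBinding:
    def test_known_onset_recovered_within_two_frames(self, rep_flow_set):
        scen, traces, truths, cfg = rep_flow_set
        errs = []
        for tr, t in zip(traces, truths):
            if math.isnan(t["t_bind"]):
                continue
            tb = detect_binding(tr, scen.t_flow_s, cfg)
            if not math.isnan(tb):
                errs.append(tb - t["t_bind"])
        errs = np.array(errs)
        assert np.mean(np.abs(errs) <= 0.2) >= 0.95

    def test_trace_without_binding_gives_sentinel(self, g4_t15, clean_photo):
        from g4fret.kinetics import StateTrajectory
        from g4fret.photophysics import render_trace

        traj = StateTrajectory(segments=[("FREE", 0.0, 30.0)], active=False,
                               t_end=30.0)
        tr = render_trace(traj, clean_photo, g4_t15, rng=np.random.default_rng(0))
        assert math.isnan(detect_binding(tr, 10.0, SegmentationConfig()))

    def test_subthreshold_rise_gives_sentinel(self, g4_t15, clean_photo):
        """A 1.1x donor rise stays below the 1.2x detection threshold."""
        from dataclasses import replace

        from g4fret.kinetics import StateTrajectory
        from g4fret.photophysics import render_trace

        photo = replace(clean_photo, pife_factor=1.1)
        traj = StateTrajectory(
            segments=[("FREE", 0.0, 12.0), ("G4_FOLDED_B", 12.0, 30.0)],
            active=False, t_end=30.0,
        )
        tr = render_trace(traj, photo, g4_t15, rng=np.random.default_rng(0))
        cfg = SegmentationConfig(pife_factor=1.1)
        assert math.isnan(detect_binding(tr, 10.0, cfg))


class TestSegmentStages:
    def test_boundaries_recovered_within_half_second(self, rep_flow_set):
        """All four stage boundaries within 0.5 s for >= 90% of traces."""
        scen, traces, truths, cfg = rep_flow_set
        segs = segment_traces(traces, scen.t_flow_s, cfg)
        ok = tot = 0
        for s, t in zip(segs, truths):
            if not s.accepted or math.isnan(t["t_release"]):
                continue
            tot += 1
            if (
                abs(s.t_bind - t["t_bind"]) < 0.5
                and abs(s.t_g4_end - t["t_commit"]) < 0.5
                and abs(s.t_dup_end - t["t_dup_end"]) < 0.5
                and abs(s.t_release - t["t_release"]) < 0.5
            ):
                ok += 1
        assert tot > 200
        assert ok / tot >= 0.90

    def test_rejection_rate_below_10pct(self, rep_flow_set):
        scen, traces, truths, cfg = rep_flow_set
        segs = segment_traces(traces, scen.t_flow_s, cfg)
        rejected = sum(not s.accepted for s in segs)
        assert rejected / len(segs) < 0.10

    def test_mean_stage2_matches_generator_within_10pct(self, rep_flow_set):
        scen, traces, truths, cfg = rep_flow_set
        from g4fret.kinetics import expected_stage2_duration, with_atp

        segs = segment_traces(traces, scen.t_flow_s, cfg)
        table = build_dwell_table(segs)
        truth = expected_stage2_duration(with_atp(scen.helicase, 2000.0))
        assert table.mean("g4_resolution") == pytest.approx(truth, rel=0.10)

    def test_segmentation_is_deterministic(self, rep_flow_set):
        scen, traces, truths, cfg = rep_flow_set
        a = segment_stages(traces[0], scen.t_flow_s, cfg)
        b = segment_stages(traces[0], scen.t_flow_s, cfg)
        assert a.to_dict() == b.to_dict()

    def test_durations_sum_to_total_span(self, rep_flow_set):
        scen, traces, truths, cfg = rep_flow_set
        for s in segment_traces(traces[:50], scen.t_flow_s, cfg):
            if s.accepted:
                total = s.stage_i + s.stage_ii + s.stage_iii + s.stage_iv
                assert total == pytest.approx(s.t_release - s.t_flow, abs=1e-6)

    def test_no_g4_trace_lacks_fluctuation(self, flow_photo):
        """T15 control: no repetitive FRET fluctuation stage."""
        scen, traces, truths, cfg = make_flow_set("t15_rep_flow", 80, 77, flow_photo)
        segs = segment_traces(traces, scen.t_flow_s, cfg)
        acc = [s for s in segs if s.accepted]
        assert len(acc) > 50
        assert all(not s.has_fluctuation or s.fluctuation_s < 1.0 for s in acc)

    def test_ligand_lag_precedes_fluctuation(self, flow_photo):
        scen, traces, truths, cfg = make_flow_set("braco_rep_flow", 80, 78,
                                                  flow_photo)
        segs = segment_traces(traces, scen.t_flow_s, cfg, ligand_protocol=True)
        acc = [s for s in segs if s.accepted]
        with_lag = [s for s in acc if not math.isnan(s.t_lag_end)]
        assert len(with_lag) / max(len(acc), 1) >= 0.8
        for s in with_lag:
            assert s.t_lag_end >= s.t_bind - 1e-9
            assert s.t_lag_end <= s.t_g4_end + 1e-9

    def test_ligand_slows_g4_resolution_about_twofold(self, flow_photo):
        lig, lt, _, lcfg = make_flow_set("braco_rep_flow", 150, 79, flow_photo)
        free, ft, _, fcfg = make_flow_set("g4t15_rep_flow", 150, 79, flow_photo)
        lsegs = [s for s in segment_traces(lt, lig.t_flow_s, lcfg, True) if s.accepted]
        fsegs = [s for s in segment_traces(ft, free.t_flow_s, fcfg) if s.accepted]
        ratio = np.mean([s.stage_ii for s in lsegs]) / np.mean(
            [s.stage_ii for s in fsegs]
        )
        assert 1.5 <= ratio <= 2.8


class TestDwellStats:
    def test_rate_is_inverse_mean_with_propagated_sem(self):
        rng = np.random.default_rng(0)
        dwells = rng.exponential(1 / 3.0, 1000)
        table = build_dwell_table([])
        table.dwells = {"duplex_unwinding": dwells}
        df = stage_rates(table, min_n=150)
        row = df.iloc[0]
        assert row["rate_per_s"] == pytest.approx(3.0, rel=0.05)
        sem = dwells.std(ddof=1) / np.sqrt(len(dwells))
        assert row["rate_sem_per_s"] == pytest.approx(sem / dwells.mean() ** 2)
        assert not row["low_n"]

    def test_sem_agrees_with_bootstrap(self):
        rng = np.random.default_rng(1)
        dwells = rng.exponential(2.0, 1000)
        table = build_dwell_table([])
        table.dwells = {"g4_resolution": dwells}
        row = stage_rates(table).iloc[0]
        boots = [
            1.0 / np.mean(rng.choice(dwells, size=len(dwells))) for _ in range(1000)
        ]
        assert row["rate_sem_per_s"] == pytest.approx(np.std(boots), rel=0.15)

    def test_low_n_flag_below_150(self):
        table = build_dwell_table([])
        table.dwells = {"binding": np.ones(100)}
        assert stage_rates(table).iloc[0]["low_n"]

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            stage_rates(build_dwell_table([]))

    def test_dwell_histogram_center_near_sample_mean(self):
        rng = np.random.default_rng(2)
        dwells = rng.normal(20.0, 3.0, 400)
        counts, edges, fit = dwell_histogram(dwells, bins=15)
        assert fit["center_s"] == pytest.approx(np.mean(dwells), rel=0.05)

    def test_dwell_histogram_needs_20_dwells(self):
        with pytest.raises(ValueError):
            dwell_histogram([1.0] * 19)
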
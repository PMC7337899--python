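"""Rendering equations: FRET algebra, PIFE, quenching, ALEX, movies."""

from dataclasses import replace

import numpy as np
import pytest

from g4fret.kinetics import StateTrajectory
from g4fret.photophysics import (
    OvercrowdedError,
    PhotoParams,
    bare_fret,
    render_movie,
    render_trace,
    state_fret,
)


def _single_state_trace(state, sub, photo, t_end=2.0, rng=None, alex=False):
    traj = StateTrajectory(segments=[(state, 0.0, t_end)], active=False, t_end=t_end)
    return render_trace(
        traj, photo, sub, rng=rng or np.random.default_rng(0), alex=alex
    )


def apparent_e(trace):
    g = trace.green
    i_d = trace.donor[g] - trace.background
    i_a = trace.acceptor[g] - trace.background
    return float(np.mean(i_a) / np.mean(i_a + i_d))


class TestRenderingAlgebra:
    def test_noiseless_zero_leakage_yields_exact_fret(self, g4_t15, clean_photo):
        """E = 0.5 renders to an intensity ratio of exactly 0.500."""
        photo = replace(clean_photo, leakage=0.0)
        tr = _single_state_trace("FREE", g4_t15, photo)
        assert apparent_e(tr) == pytest.approx(0.5, abs=1e-12)

    def test_every_mapped_state_renders_its_fret_exactly(self, g4_t15, clean_photo):
        """Noiseless, leakage-free, PIFE-free rendering is exact per state."""
        photo = replace(clean_photo, leakage=0.0, pife_factor=1.0)
        for state in ("FREE", "G4_FOLDED_B", "G4_UNFOLDED_B", "UNWOUND_HELD",
                      "LIGAND_WASHED", "BOUND"):
            tr = _single_state_trace(state, g4_t15, photo)
            expected = state_fret(state, g4_t15, photo)
            assert apparent_e(tr) == pytest.approx(expected, abs=1e-9), state

    def test_unmapped_state_raises_with_name(self, g4_t15, clean_photo):
        with pytest.raises(KeyError, match="NOT_A_STATE"):
            state_fret("NOT_A_STATE", g4_t15, clean_photo)

    def test_leakage_shifts_apparent_fret_of_dark_acceptor(self, t40, clean_photo):
        """True E = 0 with 10% leakage appears at 0.1/1.1 = 0.0909."""
        photo = replace(clean_photo, leakage=0.10, acceptor_dark_fraction=1.0)
        tr = _single_state_trace("FREE", t40, photo)
        assert apparent_e(tr) == pytest.approx(0.1 / 1.1, abs=1e-9)

    def test_pife_raises_donor_on_binding(self, g4_t15, clean_photo):
        free = _single_state_trace("FREE", g4_t15, clean_photo)
        bound = _single_state_trace("G4_FOLDED_B", g4_t15, clean_photo)
        ratio = np.mean(bound.donor[bound.green]) / np.mean(free.donor[free.green])
        assert ratio == pytest.approx(clean_photo.pife_factor, rel=1e-9)

    def test_equal_quench_preserves_apparent_fret(self, g4_t15, clean_photo):
        """Scaling both channels cannot move an intensity ratio."""
        photo = replace(clean_photo, leakage=0.0)
        dim = replace(photo, i_total=photo.i_total * 0.5)
        assert apparent_e(
            _single_state_trace("G4_FOLDED_B", g4_t15, photo)
        ) == pytest.approx(
            apparent_e(_single_state_trace("G4_FOLDED_B", g4_t15, dim)), abs=1e-12
        )

    def test_noise_is_unbiased(self, g4_t15):
        """Mean over 10^4 noisy frames matches noiseless within 3 SE."""
        noisy = replace(PhotoParams(), acceptor_dark_fraction=0.0,
                        donor_bleach_rate=0.0, acceptor_bleach_rate=0.0)
        clean = replace(noisy, noise=False)
        rng = np.random.default_rng(2)
        tr_n = _single_state_trace("FREE", g4_t15, noisy, t_end=1000.0, rng=rng)
        tr_c = _single_state_trace("FREE", g4_t15, clean, t_end=1000.0)
        for chan in ("donor", "acceptor"):
            x = getattr(tr_n, chan)
            mu = getattr(tr_c, chan)[0]
            se = x.std() / np.sqrt(len(x))
            assert abs(x.mean() - mu) < 3 * se

    def test_duplex_ramp_is_monotone_decline(self, g4_t15, clean_photo):
        photo = replace(clean_photo, leakage=0.0, pife_factor=1.0)
        traj = StateTrajectory(
            segments=[("G4_FOLDED_B", 0.0, 1.0), ("DUPLEX_UNWINDING", 1.0, 3.0),
                      ("UNWOUND_HELD", 3.0, 5.0)],
            active=True, t_end=5.0,
        )
        tr = render_trace(traj, photo, g4_t15, rng=np.random.default_rng(0))
        g = tr.green
        e = tr.acceptor[g] / (tr.acceptor[g] + tr.donor[g])
        ramp = e[12:29]  # frames inside the decline
        assert np.all(np.diff(ramp) < 0)
        assert e[5] == pytest.approx(0.5, abs=1e-6)
        assert e[-5] == pytest.approx(photo.e_unwound, abs=1e-6)


class TestAlex:
    def test_alex_pattern_labels(self, g4_t15, clean_photo):
        tr = _single_state_trace("FREE", g4_t15, clean_photo, t_end=4.2, alex=True)
        assert list(tr.exc[:21]) == ["G"] * 10 + ["D"] + ["R"] * 10
        assert list(tr.exc[21:42]) == ["G"] * 10 + ["D"] + ["R"] * 10

    def test_red_excitation_independent_of_fret(self, g4_t15, t40, clean_photo):
        """Direct acceptor excitation reports presence, not E."""
        a = _single_state_trace("FREE", g4_t15, clean_photo, alex=True)  # E=0.5
        b = _single_state_trace("FREE", t40, clean_photo, alex=True)  # E=0.3
        assert np.mean(a.acceptor[a.red]) == pytest.approx(
            np.mean(b.acceptor[b.red]), rel=1e-9
        )

    def test_dark_acceptor_silent_under_red(self, g4_t15, clean_photo):
        photo = replace(clean_photo, acceptor_dark_fraction=1.0)
        tr = _single_state_trace("FREE", g4_t15, photo, alex=True)
        assert np.all(tr.acceptor[tr.red] == photo.background)


class TestMovies:
    def _movie(self, n, clean_photo, sub, shape=(96, 192), **kw):
        rng = np.random.default_rng(0)
        traces = [
            _single_state_trace("FREE", sub, clean_photo, t_end=2.1, rng=rng,
                                alex=True)
            for _ in range(n)
        ]
        for i, tr in enumerate(traces):
            tr.molecule_id = i
        return traces, render_movie(traces, image_shape=shape, seed=1, **kw)

    def test_sidecar_lists_every_molecule(self, g4_t15, clean_photo):
        traces, stack = self._movie(40, clean_photo, g4_t15)
        assert len(stack.sidecar) == 40
        assert sorted(s["molecule_id"] for s in stack.sidecar) == list(range(40))

    def test_aperture_sum_recovers_noiseless_intensity(self, g4_t15, clean_photo):
        """Summing a 3-sigma aperture recovers the rendered photons."""
        from g4fret.detection import detect_spots, extract_traces

        traces, stack = self._movie(
            40, clean_photo, g4_t15, noise=False, background=5.0, min_sep_px=12
        )
        spots = detect_spots(stack.green_average())
        ext, skipped = extract_traces(stack, spots, aperture_px=4)
        assert skipped == 0
        truth_yx = np.array([[s["y"], s["x"]] for s in stack.sidecar])
        rel_errs = []
        for tr in ext:
            d2 = ((truth_yx - [tr.truth["y"], tr.truth["x"]]) ** 2).sum(axis=1)
            mid = stack.sidecar[int(np.argmin(d2))]["molecule_id"]
            orig = traces[mid]
            g = orig.green
            expect = orig.donor[g] - orig.background
            rel_errs.append(np.mean(np.abs(tr.donor[g] - expect) / expect))
        assert np.mean(rel_errs) < 0.02

    def test_channel_offset_shifts_acceptor_spots(self, g4_t15, clean_photo):
        traces, stack = self._movie(
            10, clean_photo, g4_t15, channel_offset=(3.0, -2.0), noise=False
        )
        s = stack.sidecar[0]
        assert s["y_acceptor"] == pytest.approx(s["y"] + 3.0)
        assert s["x_acceptor"] == pytest.approx(s["x"] - 2.0)

    def test_overcrowded_layout_raises(self, g4_t15, clean_photo):
        with pytest.raises(OvercrowdedError):
            self._movie(500, clean_photo, g4_t15, shape=(32, 32))


def test_bare_fret_by_substrate(g4_t15, t40, t15):
    photo = PhotoParams()
    assert bare_fret(g4_t15, photo) == 0.5
    assert bare_fret(t40, photo) == pytest.approx(0.30)
    assert bare_fret(t15, photo) == pytest.approx(0.75)
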
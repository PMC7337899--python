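"""Per-molecule FRET, ALEX filtering, histograms and Gaussian fits."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4fret.fretstats import (
    build_histogram,
    estimate_leakage,
    filter_donor_only,
    fit_gaussians,
    molecule_fret,
)
from g4fret.kinetics import StateTrajectory
from g4fret.photophysics import PhotoParams, render_trace


def _alex_trace(sub, photo, rng=None, state="FREE"):
    t_end = 21 * photo.frame_s
    traj = StateTrajectory(segments=[(state, 0.0, t_end)], active=False, t_end=t_end)
    return render_trace(
        traj, photo, sub, rng=rng or np.random.default_rng(0), alex=True
    )


class TestMoleculeFret:
    def test_noiseless_no_leakage(self, g4_t15, clean_photo):
        photo = replace(clean_photo, leakage=0.0)
        tr = _alex_trace(g4_t15, photo)
        assert molecule_fret(tr, leakage=0.0) == pytest.approx(0.5, abs=1e-9)

    def test_leakage_correction_cancels_exactly(self, g4_t15, clean_photo):
        """Donor-only molecule corrected with the true leakage reads E ~ 0."""
        photo = replace(clean_photo, leakage=0.08, acceptor_dark_fraction=1.0)
        tr = _alex_trace(g4_t15, photo)
        assert abs(molecule_fret(tr, leakage=0.08)) < 0.01

    def test_scale_invariance(self, g4_t15, clean_photo):
        dim = replace(clean_photo, i_total=clean_photo.i_total * 0.5)
        e1 = molecule_fret(_alex_trace(g4_t15, clean_photo), leakage=0.08)
        e2 = molecule_fret(_alex_trace(g4_t15, dim), leakage=0.08)
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_all_background_trace_is_undefined(self, g4_t15, clean_photo):
        photo = replace(clean_photo, i_total=1e-6)
        tr = _alex_trace(g4_t15, photo)
        assert np.isnan(molecule_fret(tr, leakage=0.08))


class TestDonorOnlyFilter:
    def test_dark_acceptor_excluded_intact_kept(self, g4_t15, clean_photo):
        dark = replace(clean_photo, acceptor_dark_fraction=1.0)
        assert not filter_donor_only(_alex_trace(g4_t15, dark))
        assert filter_donor_only(_alex_trace(g4_t15, clean_photo))

    def test_no_red_frames_keeps_with_warning(self, g4_t15, clean_photo):
        t_end = 21 * clean_photo.frame_s
        traj = StateTrajectory(segments=[("FREE", 0.0, t_end)], active=False,
                               t_end=t_end)
        tr = render_trace(traj, clean_photo, g4_t15,
                          rng=np.random.default_rng(0), alex=False)
        with pytest.warns(UserWarning):
            assert filter_donor_only(tr)

    def test_excluded_fraction_matches_dark_fraction(self, g4_t15):
        """Measured exclusion within 2% of the simulated dark fraction."""
        photo = replace(PhotoParams(), donor_bleach_rate=0.0,
                        acceptor_bleach_rate=0.0)
        rng = np.random.default_rng(7)
        n = 5000
        excluded = sum(
            not filter_donor_only(_alex_trace(g4_t15, photo, rng)) for _ in range(n)
        )
        assert excluded / n == pytest.approx(photo.acceptor_dark_fraction, abs=0.02)

    def test_leakage_estimate_converges(self, g4_t15):
        """Donor-only inversion recovers the rendering leakage within 0.01."""
        photo = replace(PhotoParams(), acceptor_dark_fraction=0.5,
                        donor_bleach_rate=0.0, acceptor_bleach_rate=0.0)
        rng = np.random.default_rng(8)
        traces = [_alex_trace(g4_t15, photo, rng) for _ in range(1000)]
        assert estimate_leakage(traces) == pytest.approx(photo.leakage, abs=0.01)


class TestHistogram:
    def test_identical_values_occupy_single_bin(self):
        h = build_histogram([0.513] * 100)
        assert np.sum(h.density > 0) == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_histogram([])
        with pytest.raises(ValueError):
            build_histogram([np.nan])

    def test_mass_below_boundary(self):
        h = build_histogram([0.05] * 30 + [0.5] * 70)
        assert h.mass_below(0.15) == pytest.approx(0.30, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-0.1, max_value=1.1), min_size=1, max_size=300),
        st.sampled_from([0.01, 0.02, 0.05]),
    )
    def test_area_normalization_holds(self, values, width):
        h = build_histogram(values, bin_width=width)
        assert np.sum(h.density) * h.bin_width == pytest.approx(1.0, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        e = rng.normal(0.5, 0.05, 2000)
        h1 = build_histogram(e)
        h2 = build_histogram(e[::-1])
        assert np.array_equal(h1.density, h2.density)
        f1, f2 = fit_gaussians(h1, 1), fit_gaussians(h2, 1)
        assert f1.dominant.center == pytest.approx(f2.dominant.center, abs=1e-9)


class TestGaussianFits:
    def test_single_gaussian_center_recovered(self):
        rng = np.random.default_rng(1)
        h = build_histogram(rng.normal(0.5, 0.05, 5000))
        fit = fit_gaussians(h, 1)
        assert fit.dominant.center == pytest.approx(0.5, abs=0.01)

    def test_two_component_weights_recovered(self):
        rng = np.random.default_rng(2)
        e = np.concatenate(
            [rng.normal(0.2, 0.04, 1500), rng.normal(0.6, 0.05, 3500)]
        )
        fit = fit_gaussians(build_histogram(e), 2)
        w = np.array([c.weight for c in fit.components])
        w = w / w.sum()
        assert w[0] == pytest.approx(0.3, abs=0.05)
        assert w[1] == pytest.approx(0.7, abs=0.05)
        assert fit.components[0].center == pytest.approx(0.2, abs=0.03)

    def test_delta_like_input_center_on_occupied_bin(self):
        h = build_histogram([0.513] * 200)
        fit = fit_gaussians(h, 1)
        occupied = h.centers[np.argmax(h.density)]
        assert fit.dominant.center == pytest.approx(occupied, abs=h.bin_width)

    def test_restrained_centers_held_fixed(self):
        rng = np.random.default_rng(3)
        h = build_histogram(rng.normal(0.45, 0.05, 3000))
        fit = fit_gaussians(h, 1, restrained_centers=[0.4])
        assert fit.restrained
        assert fit.dominant.center == pytest.approx(0.4, abs=1e-9)

    def test_excess_components_flagged(self):
        h = build_histogram([0.513] * 50)
        fit = fit_gaussians(h, 3)
        assert fit.ill_conditioned
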
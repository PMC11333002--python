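"""Umbrella planning, WHAM reconstruction and profile post-processing."""

import numpy as np
import pytest
from scipy.stats import norm

from mechelix.constants import kbt
from mechelix.errors import (AlignmentError, ConfigurationError,
                             DisconnectedHistogramError, InvalidArgumentError)
from mechelix.potentials import BindingPotential, DoubleWell, Flat, Harmonic
from mechelix.umbrella import (PMFProfile, ReactionCoordinate, UmbrellaWindow,
                               basin_free_energy, basin_free_energy_oracle,
                               bidirectional_average, binned_potential_oracle,
                               overlap_matrix, plan_windows, sample_window,
                               stitch_segments, wham_solve)


class TestPlanWindows:
    def test_bound_recognition_protocol(self):
        """17 windows, 0.04 nm spacing, 18000 kJ/(mol·nm²)."""
        windows = plan_windows(ReactionCoordinate(), 17, 0.04, 18000.0,
                               start=0.20)
        centers = [w.center for w in windows]
        assert len(windows) == 17
        assert centers[0] == pytest.approx(0.20)
        assert centers[-1] == pytest.approx(0.84)
        assert all(w.spring_constant == 18000.0 for w in windows)

    def test_recognition_unbound_protocol(self):
        """22 windows, 0.05 nm spacing, 15000 kJ/(mol·nm²)."""
        coord = ReactionCoordinate(xi_max=2.0)
        windows = plan_windows(coord, 22, 0.05, 15000.0, start=0.55)
        assert len(windows) == 22
        assert windows[-1].center == pytest.approx(0.55 + 21 * 0.05)

    def test_pair_spacing(self):
        windows = plan_windows(ReactionCoordinate(), 2, 0.07, 100.0,
                               start=0.3)
        assert windows[1].center - windows[0].center == pytest.approx(0.07)

    def test_arithmetic_last_center(self):
        windows = plan_windows(ReactionCoordinate(), 9, 0.1, 100.0,
                               start=0.25)
        assert windows[-1].center == pytest.approx(0.25 + 8 * 0.1)

    def test_span_outside_range(self):
        with pytest.raises(ConfigurationError):
            plan_windows(ReactionCoordinate(xi_max=1.0), 30, 0.05, 100.0,
                         start=0.2)


class TestSampleWindow:
    def test_flat_potential_gaussian(self):
        w = UmbrellaWindow(center=0.5, spring_constant=5000.0)
        out = sample_window(w, Flat(), 20_000, seed=1, dt=1e-5)
        sd = np.sqrt(kbt() / 5000.0)
        se = sd / np.sqrt(200)  # generous effective sample count
        assert out.samples.mean() == pytest.approx(0.5, abs=3 * se)
        assert out.samples.var() == pytest.approx(sd ** 2, rel=0.15)

    def test_very_stiff_window(self):
        w = UmbrellaWindow(center=0.3, spring_constant=5e5)
        out = sample_window(w, Flat(), 5000, seed=2, dt=1e-7)
        assert np.allclose(out.samples, 0.3, atol=0.02)

    def test_harmonic_weighted_mean(self):
        """V = ½k0(x−c)² plus window bias: mean is the stiffness-weighted
        average of the two centers."""
        k0, c = 2000.0, 0.2
        kw, x0 = 6000.0, 0.6
        w = UmbrellaWindow(center=x0, spring_constant=kw)
        out = sample_window(w, Harmonic(k=k0, x0=c), 40_000, seed=3, dt=5e-6)
        expected = (k0 * c + kw * x0) / (k0 + kw)
        sd = np.sqrt(kbt() / (k0 + kw))
        assert out.samples.mean() == pytest.approx(expected, abs=4 * sd / 50)


class TestWham:
    def test_single_unbiased_window_recovers_double_well(self):
        dw = DoubleWell(height=5.0, half_separation=0.5)
        w = UmbrellaWindow(center=0.0, spring_constant=0.0)
        w = sample_window(w, dw, 300_000, seed=7, dt=1.2e-4)
        prof = wham_solve([w], n_bins=70)
        ref = binned_potential_oracle(dw, prof.grid)
        m = prof.counts >= 100
        diff = prof.free_energy[m] - ref[m]
        diff -= np.average(diff, weights=prof.counts[m])
        assert np.abs(diff).max() < 0.5

    def test_window_duplication_invariance(self):
        dw = DoubleWell(height=3.0, half_separation=0.4)
        w = sample_window(UmbrellaWindow(0.0, 0.0), dw, 50_000, seed=9,
                          dt=1e-4)
        a = wham_solve([w], n_bins=50)
        b = wham_solve([w, UmbrellaWindow(0.0, 0.0, w.samples.copy())],
                       n_bins=50)
        assert np.allclose(a.free_energy, b.free_energy, atol=1e-6,
                           equal_nan=True)

    def test_biased_windows_recover_binding_dg(self):
        V = BindingPotential()
        windows = plan_windows(ReactionCoordinate(), 17, 0.04, 18000.0,
                               start=0.20)
        windows = [sample_window(w, V, 8000, seed=50 + i)
                   for i, w in enumerate(windows)]
        prof = wham_solve(windows, n_bins=140)
        dg = basin_free_energy(prof, 0.40, 0.80) \
            - basin_free_energy(prof, 0.20, 0.40)
        dg_oracle = basin_free_energy_oracle(V, 0.40, 0.80) \
            - basin_free_energy_oracle(V, 0.20, 0.40)
        assert dg == pytest.approx(dg_oracle, abs=1.0)

    def test_residuals_decay_monotonically(self):
        """The WHAM self-consistency residual decreases over iterations
        (up to small jitter from the per-iteration re-anchoring of the
        window free energies)."""
        V = BindingPotential()
        windows = plan_windows(ReactionCoordinate(), 17, 0.04, 18000.0,
                               start=0.20)
        windows = [sample_window(w, V, 2000, seed=80 + i)
                   for i, w in enumerate(windows)]
        history: list[float] = []
        wham_solve(windows, n_bins=100, residual_history=history)
        h = np.asarray(history)
        assert h[-1] < 1e-6
        assert np.all(np.diff(h) <= 0.05)
        # decade-scale decay is strictly monotone
        coarse = h[:: max(1, len(h) // 20)]
        assert np.all(np.diff(coarse) < 0)

    def test_disconnected_windows_rejected(self):
        rng = np.random.default_rng(0)
        w1 = UmbrellaWindow(0.0, 100.0, rng.normal(0.0, 0.01, 500))
        w2 = UmbrellaWindow(1.0, 100.0, rng.normal(1.0, 0.01, 500))
        with pytest.raises(DisconnectedHistogramError):
            wham_solve([w1, w2], n_bins=100)

    def test_too_few_samples_rejected(self):
        w = UmbrellaWindow(0.0, 100.0, np.linspace(-0.1, 0.1, 50))
        with pytest.raises(InvalidArgumentError):
            wham_solve([w])


class TestOverlapMatrix:
    def test_identical_samples(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 5000)
        w1 = UmbrellaWindow(0.0, 1.0, s)
        w2 = UmbrellaWindow(0.1, 1.0, s.copy())
        coeffs, warn = overlap_matrix([w1, w2])
        assert coeffs[0] == pytest.approx(1.0)
        assert not warn.any()

    def test_disjoint_supports(self):
        w1 = UmbrellaWindow(0.0, 1.0, np.linspace(0, 1, 500))
        w2 = UmbrellaWindow(5.0, 1.0, np.linspace(5, 6, 500))
        coeffs, warn = overlap_matrix([w1, w2])
        assert coeffs[0] == 0.0
        assert warn.all()

    def test_two_sigma_separated_gaussians(self):
        """Unit-variance Gaussians two σ apart overlap by 2Φ(−1) ≈ 0.317."""
        rng = np.random.default_rng(2)
        w1 = UmbrellaWindow(0.0, 1.0, rng.normal(0, 1, 400_000))
        w2 = UmbrellaWindow(2.0, 1.0, rng.normal(2, 1, 400_000))
        coeffs, _ = overlap_matrix([w1, w2], n_bins=400)
        assert coeffs[0] == pytest.approx(2 * norm.cdf(-1.0), abs=0.01)


def toy_profile(shift: float = 0.0, noise_seed: int | None = None
                ) -> PMFProfile:
    grid = np.linspace(0.0, 1.0, 51)
    a = 10.0 * (grid - 0.55) ** 2 + shift
    if noise_seed is not None:
        a = a + np.random.default_rng(noise_seed).normal(0, 0.05, 51)
    return PMFProfile(grid, a, np.full(51, 1000))


class TestBidirectionalAverage:
    def test_identity(self):
        a = toy_profile()
        out = bidirectional_average(a, toy_profile(), anchor=0.55)
        assert np.allclose(out.free_energy, a.rezeroed(0.55).free_energy)

    def test_gauge_invariance(self):
        a = toy_profile()
        b = toy_profile(shift=37.0)
        out = bidirectional_average(a, b, anchor=0.55)
        assert np.allclose(out.free_energy, a.rezeroed(0.55).free_energy,
                           atol=1e-9)

    def test_grid_mismatch(self):
        a = toy_profile()
        b = PMFProfile(a.grid[:-1], a.free_energy[:-1], a.counts[:-1])
        with pytest.raises(AlignmentError):
            bidirectional_average(a, b, anchor=0.55)


class TestStitchSegments:
    def seg(self, lo, hi, fn):
        grid = np.linspace(lo, hi, 41)
        return PMFProfile(grid, fn(grid), np.full(41, 500))

    def test_flat_second_segment(self):
        s1 = self.seg(0.2, 0.55, lambda g: 30.0 * (0.55 - g))
        s2 = self.seg(0.55, 1.0, lambda g: np.zeros_like(g))
        stitched, dg = stitch_segments(s1, s2, 0.55, 0.2, 1.0)
        dg1 = s1.value_at(0.55) - s1.value_at(0.2)
        assert dg == pytest.approx(dg1)

    def test_telescoping(self):
        s1 = self.seg(0.2, 0.55, lambda g: 40.0 * (g - 0.2) ** 2)
        s2 = self.seg(0.55, 1.0, lambda g: -12.0 * (g - 0.55) + 3.0)
        stitched, dg = stitch_segments(s1, s2, 0.55, 0.2, 1.0)
        dg1 = s1.value_at(0.55) - s1.value_at(0.2)
        dg2 = s2.value_at(1.0) - s2.value_at(0.55)
        assert dg == pytest.approx(dg1 + dg2, abs=1e-9)

    def test_continuity_at_anchor(self):
        s1 = self.seg(0.2, 0.55, lambda g: 40.0 * (g - 0.2) ** 2)
        s2 = self.seg(0.55, 1.0, lambda g: -12.0 * (g - 0.55) + 3.0)
        stitched, _ = stitch_segments(s1, s2, 0.55, 0.2, 1.0)
        i = np.argmin(np.abs(stitched.grid - 0.55))
        assert abs(stitched.free_energy[i + 1]
                   - stitched.free_energy[i]) < 1.0

    def test_missing_anchor_support(self):
        s1 = self.seg(0.2, 0.4, lambda g: g)
        s2 = self.seg(0.55, 1.0, lambda g: g)
        with pytest.raises(AlignmentError):
            stitch_segments(s1, s2, 0.5, 0.2, 1.0)
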
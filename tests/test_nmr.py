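"""Spectral pipeline: interpolation, alignment, exclusion, normalization,
peak picking and the noise-based retention rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metabfuse import synthetic as syn
from metabfuse.nmr import (
    ExclusionWindows,
    NoiseEstimate,
    PeakSet,
    Spectrum,
    align_to_reference,
    build_nmr_table,
    detect_peaks,
    estimate_noise,
    exclude_regions,
    interpolate_to_grid,
    normalize_total_area,
    process_spectra,
)

STEP = 0.0005


def _grid(lo=0.0, hi=12.0, step=STEP):
    return np.arange(lo, hi + step / 2, step)


def _singlet(center, height=1.0, width=0.002, grid=None):
    g = _grid() if grid is None else grid
    return Spectrum(g, height / (1 + ((g - center) / width) ** 2), "s")


class TestInterpolation:
    def test_identity_on_own_grid(self, rng):
        g = _grid(0, 1, 0.01)
        s = Spectrum(g, rng.normal(size=g.size), "a")
        out = interpolate_to_grid(s, g)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_linear_function_hits_midpoints(self):
        g = np.linspace(0, 1, 11)
        s = Spectrum(g, 3 * g + 1, "a")
        mid = (g[:-1] + g[1:]) / 2
        out = interpolate_to_grid(s, mid)
        np.testing.assert_allclose(out.intensity, 3 * mid + 1, atol=1e-12)

    def test_round_trip_error_below_curvature_bound(self, rng):
        """Refine to a shifted half-step grid and come back: the deviation is
        bounded by the worst local second difference (linear-interp bound)."""
        g = np.linspace(0, 1, 101)
        y = np.cumsum(rng.normal(size=g.size))
        s = Spectrum(g, y, "a")
        half = (g[:-1] + g[1:]) / 2
        back = interpolate_to_grid(interpolate_to_grid(s, half), g[1:-1])
        bound = np.max(np.abs(y[:-2] - 2 * y[1:-1] + y[2:])) / 2
        assert np.max(np.abs(back.intensity - y[1:-1])) <= bound + 1e-12

    def test_grid_outside_range_raises(self):
        s = Spectrum(np.linspace(1, 2, 10), np.ones(10), "a")
        with pytest.raises(ValueError):
            interpolate_to_grid(s, np.linspace(0.5, 1.5, 5))


class TestAlignment:
    def test_apex_already_on_reference(self):
        s = _singlet(6.5)
        out, shift = align_to_reference(s)
        assert shift == 0.0
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_known_offset_recovered(self):
        """A singlet at 6.47 ppm needs a +0.03 ppm (60 point) shift."""
        out, shift = align_to_reference(_singlet(6.47))
        assert shift == pytest.approx(0.03, abs=1e-12)
        apex = out.ppm[np.argmax(out.intensity)]
        assert apex == pytest.approx(6.5, abs=STEP / 2)

    def test_opposite_jitters_coincide(self):
        a, _ = align_to_reference(_singlet(6.52))
        b, _ = align_to_reference(_singlet(6.48))
        assert np.argmax(a.intensity) == np.argmax(b.intensity)

    def test_flat_window_warns_and_prefers_small_shift(self):
        g = _grid()
        s = Spectrum(g, np.ones(g.size), "flat")
        with pytest.warns(UserWarning):
            _, shift = align_to_reference(s)
        assert shift == 0.0


class TestExclusion:
    def test_empty_window_list_is_identity(self):
        s = _singlet(3.0)
        out = exclude_regions(s, ExclusionWindows([], profile="custom"))
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_human_profile_removed_point_count(self):
        """Removed points equal the summed closed-window lengths on the grid,
        counted directly window by window."""
        s = _singlet(3.0)
        win = ExclusionWindows.for_profile("human")
        out = exclude_regions(s, win)
        expected = sum(
            int(np.sum((s.ppm >= lo) & (s.ppm <= hi))) for lo, hi in win.windows
        )
        # windows merged and disjoint, so direct counts add up exactly
        assert len(s) - len(out) == expected
        for lo, hi in win.windows:
            naive = round((hi - lo) / STEP) + 1
            assert abs(int(np.sum((s.ppm >= lo) & (s.ppm <= hi))) - naive) <= 1

    @pytest.mark.parametrize("profile", ["mouse", "human"])
    def test_methanol_window_fully_removed(self, profile):
        out = exclude_regions(_singlet(3.335), ExclusionWindows.for_profile(profile))
        assert not np.any((out.ppm >= 3.32) & (out.ppm <= 3.35))

    def test_citrate_only_in_human_profile(self):
        mouse = ExclusionWindows.for_profile("mouse")
        human = ExclusionWindows.for_profile("human")
        probe = np.array([2.5])
        assert not mouse.contains(probe)[0]
        assert human.contains(probe)[0]

    def test_overlapping_windows_merge(self):
        w = ExclusionWindows([(1.0, 2.0), (1.5, 2.5)])
        assert w.windows == [(1.0, 2.5)]


class TestNormalization:
    def test_two_point_example(self):
        s = Spectrum(np.array([1.0, 2.0]), np.array([3.0, 1.0]), "a")
        np.testing.assert_allclose(
            normalize_total_area(s).intensity, [0.75, 0.25], atol=1e-15
        )

    @given(st.integers(0, 2**31 - 1))
    def test_sums_to_one_scale_invariant_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        g = np.linspace(0, 1, 50)
        y = rng.uniform(0.1, 2.0, size=50)
        s = Spectrum(g, y, "a")
        n1 = normalize_total_area(s)
        assert n1.intensity.sum() == pytest.approx(1.0, abs=1e-12)
        n_scaled = normalize_total_area(Spectrum(g, 10 * y, "a"))
        np.testing.assert_allclose(n_scaled.intensity, n1.intensity, atol=1e-12)
        np.testing.assert_allclose(
            normalize_total_area(n1).intensity, n1.intensity, atol=1e-12
        )

    def test_zero_area_rejected(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0]), np.zeros(3), "a")
        with pytest.raises(ValueError):
            normalize_total_area(s)


class TestPeakDetection:
    def test_monotone_ramp_has_no_peaks(self):
        g = np.linspace(0, 1, 100)
        assert len(detect_peaks([Spectrum(g, g.copy(), "a")])) == 0

    def test_three_lorentzians_three_peaks(self):
        g = _grid()
        y = sum(
            h / (1 + ((g - c) / 0.003) ** 2)
            for c, h in [(2.0, 1.0), (5.0, 0.7), (8.0, 1.3)]
        )
        peaks = detect_peaks([Spectrum(g, y, "a")])
        assert len(peaks) == 3
        for center in (2.0, 5.0, 8.0):
            assert np.min(np.abs(peaks.positions - center)) <= STEP

    def test_plateau_yields_no_peak(self):
        g = np.linspace(0, 1, 9)
        y = np.array([0, 1, 2, 3, 3, 3, 2, 1, 0], dtype=float)
        assert len(detect_peaks([Spectrum(g, y, "a")])) == 0

    def test_mismatched_grids_rejected(self):
        a = Spectrum(np.linspace(0, 1, 10), np.ones(10), "a")
        b = Spectrum(np.linspace(0, 2, 10), np.ones(10), "b")
        with pytest.raises(ValueError):
            detect_peaks([a, b])


class TestNoise:
    def test_constant_region_zero_noise(self):
        g = np.linspace(0, 1, 100)
        assert estimate_noise(Spectrum(g, np.ones(100), "a")).level == 0.0

    def test_hand_computed_sample_sd(self):
        """Noise is the ddof=1 sample SD: two copies of {1..5} have mean 3,
        squared deviations summing to 20, hence SD = sqrt(20/9)."""
        g = np.linspace(0, 0.2, 10)
        s = Spectrum(g, np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]), "a")
        est = estimate_noise(s, region=(0, 0.2))
        assert est.level == pytest.approx(np.sqrt(20 / 9), abs=1e-12)

    def test_white_noise_recovered_within_ten_percent(self, rng):
        g = np.linspace(0, 0.2, 1000)
        s = Spectrum(g, rng.normal(0, 0.05, size=1000), "a")
        assert estimate_noise(s).level == pytest.approx(0.05, rel=0.10)

    def test_too_few_points_rejected(self):
        g = np.linspace(0, 1, 30)
        s = Spectrum(g, np.ones(30), "a")
        with pytest.raises(ValueError):
            estimate_noise(s, region=(0.0, 0.05))


class TestRetentionRule:
    def _toy(self, n_below: int):
        """10 samples; variable v1 below 2x noise in ``n_below`` of them."""
        g = np.linspace(0, 1, 201)
        noise_level = 0.1
        spectra, noise = [], {}
        for i in range(10):
            y = np.full(g.size, 1.0)
            y[100] = 0.05 if i < n_below else 1.0  # v1 at ppm 0.5
            y[150] = 1.0  # v2 always above threshold
            spectra.append(Spectrum(g, y, f"s{i}"))
            noise[f"s{i}"] = NoiseEstimate(noise_level)
        peaks = PeakSet(np.array([g[100], g[150]]))
        return build_nmr_table(spectra, peaks, noise, factor=2.0, discard_fraction=0.5)

    def test_six_of_ten_below_discarded(self):
        table = self._toy(6)
        assert list(table.data.columns) == ["nmr_0.7500"]

    def test_exactly_half_below_retained(self):
        """'More than 50%' is strict: 5/10 below keeps the variable."""
        table = self._toy(5)
        assert table.data.shape[1] == 2

    def test_all_above_threshold_all_retained(self):
        assert self._toy(0).data.shape[1] == 2


class TestEndToEnd:
    def test_no_retained_variable_inside_exclusion_windows(self, two_arm_truth):
        lib, truth = two_arm_truth
        spectra = syn.render_spectra(truth, lib, seed=1)
        table, _ = process_spectra(spectra, profile="mouse")
        windows = ExclusionWindows.for_profile("mouse")
        positions = np.array([float(c.split("_")[1]) for c in table.data.columns])
        assert not windows.contains(positions).any()

    def test_affected_metabolite_peak_retained_at_low_noise(self, two_arm_truth):
        """With tiny noise and jitter inside the search half-window, the
        planted responder's tallest non-excluded peak becomes a variable."""
        lib, truth = two_arm_truth
        spectra = syn.render_spectra(
            truth, lib, jitter_ppm=0.003, noise_sd=1e-4, seed=2
        )
        table, _ = process_spectra(spectra, profile="mouse")
        windows = ExclusionWindows.for_profile("mouse")
        sig = next(s for s in lib if s.metabolite_id == "M01")
        free = [(c, h) for c, h, _ in sig.peaks if not windows.contains(np.array([c]))[0]]
        tallest = max(free, key=lambda p: p[1])[0]
        positions = np.array([float(c.split("_")[1]) for c in table.data.columns])
        assert np.min(np.abs(positions - tallest)) <= 2 * STEP
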
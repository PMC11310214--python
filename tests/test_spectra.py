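"""THz spectroscopy stage: path length, absorption, differences, vapor masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrosense.errors import InsufficientRangeError, NoFringesError, ValidationError
from hydrosense.spectra import (
    DifferenceSpectrum,
    Spectrum,
    absorption_coefficient,
    average_replicates,
    coupling_change,
    difference_spectrum,
    estimate_path_length,
    mask_vapor_lines,
)
from hydrosense.synthetic import ThzSceneSpec, gen_etalon_transmission, gen_thz_scene

MIDIR_GRID = np.arange(400.0, 4000.0, 1.0)


class TestPathLength:
    @pytest.mark.parametrize("d_true", [1.3e-3, 6.5e-4, 2.6e-3])
    @pytest.mark.parametrize("method", ["fringe-fft", "fringe-peaks"])
    def test_recovers_spacer_thickness(self, d_true, method):
        """Etalon fringe period 1/(2d) pins the window gap to better than 1%."""
        spec = gen_etalon_transmission(d_true, MIDIR_GRID, noise_sd=0.0)
        pl = estimate_path_length(spec, method=method)
        assert pl.d == pytest.approx(d_true, rel=0.01)
        assert pl.uncertainty >= 0

    def test_halving_period_doubles_estimate(self):
        a = estimate_path_length(gen_etalon_transmission(1.3e-3, MIDIR_GRID))
        b = estimate_path_length(gen_etalon_transmission(2.6e-3, MIDIR_GRID))
        assert b.d == pytest.approx(2 * a.d, rel=1e-3)

    def test_flat_spectrum_refused(self):
        flat = gen_etalon_transmission(1.3e-3, MIDIR_GRID, modulation_depth=0.0)
        with pytest.raises(NoFringesError):
            estimate_path_length(flat)

    def test_too_few_periods_refused(self):
        narrow = gen_etalon_transmission(1.3e-3, np.arange(50.0, 500.0, 0.5))
        with pytest.raises(InsufficientRangeError):
            estimate_path_length(narrow)

    def test_requires_transmission_kind(self):
        spec = Spectrum(MIDIR_GRID, np.ones_like(MIDIR_GRID), kind="absorption")
        with pytest.raises(ValidationError):
            estimate_path_length(spec)


class TestAbsorption:
    def test_identity_gives_zero(self):
        grid = np.linspace(50, 500, 200)
        s = Spectrum(grid, np.full(200, 3.0))
        alpha = absorption_coefficient(s, s, d=1.3e-3)
        assert np.allclose(alpha.values, 0.0)
        assert alpha.kind == "absorption"

    def test_decadic_definition(self):
        grid = np.array([100.0, 200.0])
        sample = Spectrum(grid, np.array([0.1, 1.0]))
        background = Spectrum(grid, np.array([1.0, 1.0]))
        alpha = absorption_coefficient(sample, background, d=1.0)
        assert alpha.values[0] == pytest.approx(1.0)
        assert alpha.values[1] == pytest.approx(0.0)

    def test_matches_elementwise_formula_on_random_spectra(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(50, 500, 301)
        for _ in range(20):
            i = np.exp(rng.normal(size=grid.size))
            i0 = np.exp(rng.normal(size=grid.size))
            d = float(rng.uniform(1e-4, 1e-2))
            alpha = absorption_coefficient(Spectrum(grid, i), Spectrum(grid, i0), d)
            expected = -np.log10(i / i0) / d  # independent elementwise oracle
            np.testing.assert_allclose(alpha.values, expected, rtol=1e-12)

    def test_nonpositive_intensity_named(self):
        grid = np.array([100.0, 200.0, 300.0])
        good = Spectrum(grid, np.ones(3))
        # the op itself validates intensities (kind tag aside) and names
        # the offending grid points
        bad = Spectrum(grid, np.array([1.0, -1.0, 1.0]), kind="absorption")
        with pytest.raises(ValidationError, match="200"):
            absorption_coefficient(bad, good, d=1.0)

    def test_background_interpolated_onto_sample_grid(self):
        gs = np.linspace(100, 400, 100)
        gb = np.linspace(50, 500, 500)
        alpha = absorption_coefficient(
            Spectrum(gs, np.full(100, 0.5)), Spectrum(gb, np.ones(500)), d=1.0
        )
        assert alpha.meta["background_resampled"]
        np.testing.assert_allclose(alpha.values, -np.log10(0.5), rtol=1e-12)

    def test_extrapolation_forbidden(self):
        gs = np.linspace(50, 500, 100)
        gb = np.linspace(100, 400, 100)
        with pytest.raises(ValidationError, match="extrapolation"):
            absorption_coefficient(
                Spectrum(gs, np.ones(100)), Spectrum(gb, np.ones(100)), d=1.0
            )

    def test_natural_log_option(self):
        grid = np.array([100.0, 200.0])
        alpha = absorption_coefficient(
            Spectrum(grid, np.full(2, 0.5)), Spectrum(grid, np.ones(2)),
            d=1.0, log_base="e",
        )
        assert alpha.values[0] == pytest.approx(np.log(2))

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_common_intensity_scaling_cancels(self, scale):
        """alpha depends only on the ratio I/I0 (pipeline linearity)."""
        grid = np.linspace(50, 500, 50)
        rng = np.random.default_rng(1)
        i = np.exp(rng.normal(size=50))
        i0 = np.exp(rng.normal(size=50))
        a1 = absorption_coefficient(Spectrum(grid, i), Spectrum(grid, i0), 1e-3)
        a2 = absorption_coefficient(
            Spectrum(grid, scale * i), Spectrum(grid, scale * i0), 1e-3
        )
        np.testing.assert_allclose(a1.values, a2.values, rtol=1e-9, atol=1e-9)


class TestDifference:
    def test_sample_equals_water_gives_zero(self):
        grid = np.linspace(50, 500, 100)
        a = Spectrum(grid, np.linspace(100, 400, 100), kind="absorption")
        ds = difference_spectrum(a, a)
        assert np.all(ds.delta_alpha == 0)

    def test_linearity_identity(self):
        grid = np.linspace(50, 500, 100)
        w = Spectrum(grid, np.linspace(100, 400, 100), kind="absorption")
        a = Spectrum(grid, w.values + 2.0, kind="absorption")
        b = np.sin(grid / 50)
        ab = Spectrum(grid, a.values + b, kind="absorption")
        lhs = difference_spectrum(ab, w).delta_alpha
        rhs = difference_spectrum(a, w).delta_alpha + b
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_requires_absorption_kind(self):
        grid = np.linspace(50, 500, 10)
        t = Spectrum(grid, np.ones(10))
        with pytest.raises(ValidationError):
            difference_spectrum(t, t)

    def test_noise_free_scene_recovers_truth(self, noise_free_scene):
        """Full forward-model inversion: transmission -> delta_alpha == truth."""
        scene = noise_free_scene
        aw = absorption_coefficient(scene.water, scene.empty_cell, scene.path_length)
        for cond, sample in scene.samples.items():
            a = absorption_coefficient(sample, scene.empty_cell, scene.path_length)
            ds = difference_spectrum(a, aw)
            assert np.max(np.abs(ds.delta_alpha - scene.truth[cond])) < 1e-10


class TestVaporMasking:
    @staticmethod
    def _dipped(grid, baseline, centers, depth=2.0, width=0.6):
        values = baseline.copy()
        for c in centers:
            values -= depth * np.exp(-(((grid - c) / width) ** 2))
        return values

    def test_no_windows_is_identity(self):
        grid = np.linspace(50, 500, 400)
        spec = Spectrum(grid, np.linspace(1, 2, 400))
        out = mask_vapor_lines(spec, [])
        assert np.array_equal(out.values, spec.values)

    def test_dips_on_linear_baseline_removed(self):
        grid = np.arange(50.0, 500.0, 0.25)
        baseline = 0.01 * grid + 1.0
        spec = Spectrum(grid, self._dipped(grid, baseline, [150.5, 202.6]))
        out = mask_vapor_lines(spec, [(147, 154), (199, 206)])
        np.testing.assert_allclose(out.values, baseline, atol=1e-9)

    def test_untouched_points_bit_identical(self):
        grid = np.arange(50.0, 500.0, 0.5)
        rng = np.random.default_rng(3)
        spec = Spectrum(grid, 1.0 + rng.random(grid.size))
        out = mask_vapor_lines(spec, [(150, 160)])
        outside = (grid < 150) | (grid > 160)
        assert np.array_equal(out.values[outside], spec.values[outside])

    def test_overlapping_windows_merged(self):
        grid = np.arange(50.0, 500.0, 0.5)
        spec = Spectrum(grid, np.ones(grid.size))
        a = mask_vapor_lines(spec, [(100, 120), (110, 130)])
        b = mask_vapor_lines(spec, [(100, 130)])
        assert np.array_equal(a.values, b.values)

    def test_boundary_window_refused(self):
        grid = np.arange(50.0, 500.0, 0.5)
        spec = Spectrum(grid, np.ones(grid.size))
        with pytest.raises(ValidationError, match="boundary"):
            mask_vapor_lines(spec, [(45, 60)])

    def test_window_outside_grid_refused(self):
        grid = np.arange(50.0, 500.0, 0.5)
        spec = Spectrum(grid, np.ones(grid.size))
        with pytest.raises(ValidationError, match="outside"):
            mask_vapor_lines(spec, [(600, 620)])

    def test_masking_reduces_vapor_residuals_in_difference(self):
        """Channel-to-channel vapor depth jitter leaves residual lines in
        delta_alpha; interpolation across the line windows removes them."""
        spec = ThzSceneSpec(noise_sd=0.0, vapor_channel_jitter=0.3, seed=5)
        scene = gen_thz_scene(spec)
        aw = absorption_coefficient(scene.water, scene.empty_cell, scene.path_length)
        cond = "gt10"
        a = absorption_coefficient(scene.samples[cond], scene.empty_cell, scene.path_length)
        ds = difference_spectrum(a, aw)
        windows = [(c - 4 * w, c + 4 * w) for c, w, _ in spec.vapor_lines]
        masked = mask_vapor_lines(ds, windows)
        err_before = np.max(np.abs(ds.delta_alpha - scene.truth[cond]))
        err_after = np.max(np.abs(masked.delta_alpha - scene.truth[cond]))
        assert err_after < 0.05 * err_before


class TestReplicates:
    def test_single_replicate_flagged(self):
        grid = np.linspace(50, 500, 10)
        ds = DifferenceSpectrum(grid, np.ones(10), condition="c")
        avg = average_replicates([ds])
        assert avg.n_replicates == 1
        assert np.all(avg.sem == 0)
        assert avg.meta["sem_undefined"]

    def test_identical_replicates_zero_sem(self):
        grid = np.linspace(50, 500, 10)
        reps = [DifferenceSpectrum(grid, np.ones(10), condition="c") for _ in range(2)]
        avg = average_replicates(reps)
        assert np.all(avg.sem == 0)
        assert avg.n_replicates == 2

    def test_sem_estimates_sigma_over_sqrt_n(self):
        """Mean squared SEM over 200 triplicates approximates sigma^2/3."""
        rng = np.random.default_rng(8)
        grid = np.linspace(50, 500, 50)
        sigma = 0.7
        sem_sq = []
        for _ in range(200):
            reps = [
                DifferenceSpectrum(
                    grid, sigma * rng.standard_normal(50), condition="c"
                )
                for _ in range(3)
            ]
            sem_sq.append(average_replicates(reps).sem ** 2)
        assert np.mean(sem_sq) == pytest.approx(sigma**2 / 3, rel=0.05)

    def test_mixed_conditions_refused(self):
        grid = np.linspace(50, 500, 10)
        with pytest.raises(ValidationError, match="mixed"):
            average_replicates([
                DifferenceSpectrum(grid, np.ones(10), condition="a"),
                DifferenceSpectrum(grid, np.ones(10), condition="b"),
            ])


class TestCouplingChange:
    def _ds(self, values, sem=None):
        grid = np.linspace(50, 500, 451)
        return DifferenceSpectrum(grid, values, sem=sem, condition="c")

    def test_equal_spectra_give_zero(self):
        ds = self._ds(np.full(451, 3.0))
        value, err = coupling_change(ds, ds, nu=150)
        assert value == 0.0

    def test_doubling_gives_plus_one(self):
        ref = self._ds(np.full(451, 3.0))
        double = self._ds(np.full(451, 6.0))
        assert coupling_change(double, ref, nu=150)[0] == pytest.approx(1.0)

    def test_scene_truth_at_150(self, noise_free_scene):
        scene = noise_free_scene
        aw = absorption_coefficient(scene.water, scene.empty_cell, scene.path_length)
        ds = {}
        for cond, sample in scene.samples.items():
            a = absorption_coefficient(sample, scene.empty_cell, scene.path_length)
            ds[cond] = difference_spectrum(a, aw)
        value, _ = coupling_change(ds["gt10+dopamine"], ds["gt10"], nu=150)
        i = int(np.argmin(np.abs(scene.grid - 150)))
        expected = (
            scene.truth["gt10+dopamine"][i] - scene.truth["gt10"][i]
        ) / scene.truth["gt10"][i]
        assert value == pytest.approx(expected, abs=1e-10)

    def test_zero_reference_refused(self):
        ref = self._ds(np.zeros(451))
        other = self._ds(np.ones(451))
        with pytest.raises(ValidationError, match="zero"):
            coupling_change(other, ref, nu=150)

    def test_sem_propagation_first_order(self):
        ref = self._ds(np.full(451, 2.0), sem=np.full(451, 0.2))
        ana = self._ds(np.full(451, 3.0), sem=np.full(451, 0.3))
        value, err = coupling_change(ana, ref, nu=300)
        assert value == pytest.approx(0.5)
        expected = np.hypot(0.3 / 2.0, 3.0 * 0.2 / 4.0)
        assert err == pytest.approx(expected)
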
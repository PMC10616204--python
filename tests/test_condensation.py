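import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from aerotox.condensation import (
    VaporProperties,
    beta_m,
    condensation_sink,
    cs_bands,
    cs_bands_series,
    knudsen,
)
from aerotox.grids import make_size_grid
from aerotox.lognormal import LognormalMode, evaluate_modes

VAPOR = VaporProperties()


class TestKnudsen:
    def test_direct_values(self):
        v = VaporProperties(mean_free_path=100e-9)
        assert knudsen(200.0, v) == pytest.approx(1.0)
        assert knudsen(20.0, v) == pytest.approx(10.0)

    def test_inverse_proportionality(self):
        assert knudsen(100.0, VAPOR) == pytest.approx(2 * knudsen(200.0, VAPOR))

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            knudsen(0.0, VAPOR)

    def test_derived_mean_free_path(self):
        # lambda = 3 D / c with c = sqrt(8RT/(pi M))
        c = np.sqrt(8 * 8.314462618 * VAPOR.temperature / (np.pi * VAPOR.molar_mass))
        assert VAPOR.lam == pytest.approx(3 * VAPOR.diffusion_coefficient / c)


class TestBetaM:
    def test_continuum_limit(self):
        assert beta_m(0.0) == 1.0

    def test_printed_formula_at_kn_1(self):
        assert beta_m(1.0) == pytest.approx(2.0 / 4.010, rel=1e-6)

    def test_free_molecular_asymptote(self):
        assert beta_m(100.0) == pytest.approx(1 / (1.333 * 100), rel=0.02)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1e4), st.floats(1e-6, 10))
    def test_monotone_decreasing_in_unit_interval(self, kn, dk):
        b1, b2 = beta_m(kn), beta_m(kn + dk)
        assert 0 < b2 < b1 <= 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            beta_m(-0.1)


class TestCondensationSink:
    def test_zero_distribution(self, grid):
        assert condensation_sink(np.zeros(grid.n_bins), grid, VAPOR) == 0.0

    def test_monodisperse_closed_form(self, grid):
        i = int(np.argmin(np.abs(grid.mid_diameters_nm - 100)))
        y = np.zeros(grid.n_bins)
        y[i] = 1000.0 / grid.dlog[i]  # 1000 cm^-3 in this bin
        d_m = grid.mid_diameters_nm[i] * 1e-9
        oracle = 4 * np.pi * VAPOR.diffusion_coefficient * beta_m(
            knudsen(grid.mid_diameters_nm[i], VAPOR)) * d_m * 1000e6
        assert condensation_sink(y, grid, VAPOR) == pytest.approx(oracle, rel=1e-12)

    def test_linearity(self, grid):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1000, grid.n_bins)
        assert condensation_sink(2 * y, grid, VAPOR) == pytest.approx(
            2 * condensation_sink(y, grid, VAPOR), rel=1e-12)

    def test_integrand_regime_scaling(self):
        """Per-particle integrand beta*d: ~d in the continuum, ~d^2 free-molecular."""
        lam_nm = VAPOR.lam * 1e9
        for d, power in [(10 * lam_nm, 1.0), (lam_nm / 10, 2.0)]:
            f = lambda x: beta_m(knudsen(x, VAPOR)) * x
            ratio = f(1.05 * d) / f(d)
            assert ratio == pytest.approx(1.05 ** power, rel=0.02)

    def test_grid_refinement_matches_quadrature_oracle(self):
        """CS on 16 and 64 bins/decade both within 2% of fine quadrature."""
        mode = LognormalMode(5000, 60, 1.8)
        s = np.log10(mode.gsd)

        def integrand(t):  # t = log10(d_p [nm])
            d_nm = 10 ** t
            n = mode.number / (np.sqrt(2 * np.pi) * s) * np.exp(
                -((t - np.log10(mode.gmd)) ** 2) / (2 * s * s))
            return beta_m(knudsen(d_nm, VAPOR)) * (d_nm * 1e-9) * n * 1e6

        oracle, _ = integrate.quad(integrand, np.log10(8), np.log10(1066.82), limit=200)
        oracle *= 4 * np.pi * VAPOR.diffusion_coefficient
        for bpd in (16, 64):
            g = make_size_grid(8, 1000, bpd)
            cs = condensation_sink(evaluate_modes([mode], g), g, VAPOR)
            assert cs == pytest.approx(oracle, rel=0.02)

    def test_band_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError):
            condensation_sink(np.ones(grid.n_bins), grid, VAPOR, 2000, 5000)


class TestCSBands:
    def test_band_sum_equals_banded_total(self, grid):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 2000, grid.n_bins)
        res = cs_bands(y, grid, VAPOR)
        assert sum(res.bands.values()) == pytest.approx(
            condensation_sink(y, grid, VAPOR, 8, 900), rel=1e-12)
        assert res.cs_total >= max(res.bands.values())

    def test_mode_confined_to_one_band(self, grid):
        y = evaluate_modes([LognormalMode(1000, 12, 1.15)], grid)
        res = cs_bands(y, grid, VAPOR)
        assert res.cs_8_20 == pytest.approx(condensation_sink(y, grid, VAPOR, 8, 900), rel=1e-3)
        assert res.cs_200_900 < 1e-3 * res.cs_8_20

    def test_total_increases_with_mode_number(self, grid):
        lo = cs_bands(evaluate_modes([LognormalMode(1000, 60, 1.7)], grid), grid, VAPOR)
        hi = cs_bands(evaluate_modes([LognormalMode(1500, 60, 1.7)], grid), grid, VAPOR)
        assert hi.cs_total > lo.cs_total

    def test_accumulation_band_dominates_aged_aerosol(self, grid):
        y = evaluate_modes([LognormalMode(800, 250, 1.6), LognormalMode(1200, 70, 1.8)], grid)
        res = cs_bands(y, grid, VAPOR)
        assert res.cs_200_900 == max(res.bands.values())

    def test_series_wrapper_matches_per_record(self, winter):
        table = cs_bands_series(winter.pnsd.iloc[:5], winter.grid, VAPOR)
        one = cs_bands(winter.pnsd.iloc[2].to_numpy(), winter.grid, VAPOR)
        assert table["cs_total"].iloc[2] == pytest.approx(one.cs_total, rel=1e-12)
        assert table["cs_8_20"].iloc[2] == pytest.approx(one.cs_8_20, rel=1e-12)

    def test_configurable_edges(self, grid):
        y = np.ones(grid.n_bins) * 100
        res = cs_bands(y, grid, VAPOR, band_edges=(8, 20, 40, 100, 200, 800))
        assert "cs_200_800" in res.bands
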
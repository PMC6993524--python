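"""Gradient physics: BD equations, tube geometry, and the model gradient."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipreads.exceptions import (
    ConfigurationError,
    DomainError,
    GeometryError,
    OutOfGradientError,
)
from sipreads.gradient import (
    BDWindow,
    GradientParams,
    ModelGradientTable,
    dbl_position_range,
    diffusion_sigma,
    equilibrium_position,
    isoconcentration_point,
    labeled_bd,
    position_to_bd,
    theoretical_bd,
)


class TestTheoreticalBD:
    @pytest.mark.parametrize(
        "gc,expected",
        [(0.0, 1.66), (0.5, 1.709), (1.0, 1.758)],
    )
    def test_linear_map(self, gc, expected):
        assert theoretical_bd(gc) == pytest.approx(expected, abs=1e-12)

    def test_maps_unit_interval_onto_full_bd_range(self):
        gcs = np.linspace(0, 1, 101)
        bds = theoretical_bd(gcs)
        assert bds.min() == pytest.approx(1.66)
        assert bds.max() == pytest.approx(1.758)
        assert np.all(np.diff(bds) > 0)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain_error(self, bad):
        with pytest.raises(DomainError):
            theoretical_bd(bad)


class TestLabeledBD:
    @pytest.mark.parametrize(
        "rho_t,excess,isotope,expected",
        [
            (1.709, 0.0, "13C", 1.709),
            (1.709, 1.0, "13C", 1.745),
            (1.70, 1.0, "15N", 1.716),
        ],
    )
    def test_isotope_shift(self, rho_t, excess, isotope, expected):
        assert labeled_bd(rho_t, excess, isotope) == pytest.approx(expected, abs=1e-12)

    def test_full_label_shift_is_exactly_delta(self):
        assert labeled_bd(1.7, 1.0, "13C") - labeled_bd(1.7, 0.0, "13C") == pytest.approx(
            0.036, abs=1e-15
        )
        assert labeled_bd(1.7, 1.0, "15N") - labeled_bd(1.7, 0.0, "15N") == pytest.approx(
            0.016, abs=1e-15
        )

    def test_unknown_isotope(self):
        with pytest.raises(ConfigurationError):
            labeled_bd(1.7, 0.5, "2H")


class TestDiffusionSigma:
    def test_matches_literal_formula(self, params):
        # independent single-line re-typing of the band-width equation
        rho, length = 1.709, 10_000
        expected = math.sqrt(
            rho * 8.314 * 293.15 / (1.14e9**2 * 7.87e-10 * 882.0 * length)
        )
        assert diffusion_sigma(rho, length, params) == pytest.approx(expected, rel=1e-12)

    def test_inverse_sqrt_length_scaling(self, params, rng):
        rhos = rng.uniform(1.6, 1.8, size=100)
        lengths = rng.integers(100, 100_000, size=100)
        ratio = diffusion_sigma(rhos, lengths, params) / diffusion_sigma(
            rhos, 4 * lengths, params
        )
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-12)

    def test_increasing_in_temperature(self):
        cold = GradientParams(temperature=277.15)
        warm = GradientParams(temperature=310.15)
        assert diffusion_sigma(1.7, 5000, warm) > diffusion_sigma(1.7, 5000, cold)

    def test_short_fragment_rejected(self, params):
        with pytest.raises(DomainError):
            diffusion_sigma(1.7, 0, params)


class TestIsoconcentrationPoint:
    def test_direct_substitution(self):
        assert isoconcentration_point(1.0, 2.0) == pytest.approx(math.sqrt(7.0 / 3.0))

    def test_symmetric_limit(self):
        assert isoconcentration_point(3.0, 3.0) == pytest.approx(3.0)

    def test_lies_between_radii_and_above_midpoint(self):
        # numeric sweep oracle: I is within [r_min, r_max] and >= the midpoint
        for r_min in np.linspace(0.5, 5, 10):
            for r_max in np.linspace(r_min + 0.1, r_min + 6, 10):
                i = isoconcentration_point(r_min, r_max)
                assert r_min <= i <= r_max
                assert i >= 0.5 * (r_min + r_max) - 1e-12

    def test_nonpositive_radii_rejected(self):
        with pytest.raises(DomainError):
            isoconcentration_point(-1.0, 2.0)


class TestEquilibriumPosition:
    def test_average_density_bands_at_isoconcentration_point(self, params):
        assert equilibrium_position(params.avg_density, params) == pytest.approx(
            params.isoconcentration
        )

    def test_strictly_increasing_in_rho(self, params):
        rhos = np.linspace(1.66, 1.80, 500)
        xs = equilibrium_position(rhos, params)
        assert np.all(np.diff(xs) > 0)

    def test_off_gradient_error_reports_rho(self, params):
        with pytest.raises(OutOfGradientError) as exc:
            equilibrium_position(1.0, params)
        assert exc.value.rho == 1.0


class TestPositionToBD:
    def test_inverse_at_isoconcentration_point(self, params):
        assert position_to_bd(params.isoconcentration, params) == pytest.approx(
            params.avg_density
        )

    def test_strictly_increasing(self, params):
        xs = np.linspace(params.r_min, params.r_max, 500)
        assert np.all(np.diff(position_to_bd(xs, params)) > 0)

    def test_round_trip_identity(self, params, rng):
        rhos = rng.uniform(1.66, 1.80, size=1000)
        back = position_to_bd(equilibrium_position(rhos, params), params)
        assert np.max(np.abs(back - rhos)) < 1e-9

    def test_nonpositive_position_rejected(self, params):
        with pytest.raises(GeometryError):
            position_to_bd(0.0, params)


@settings(max_examples=200, derandomize=True)
@given(rho=st.floats(min_value=1.66, max_value=1.80))
def test_round_trip_property(rho):
    params = GradientParams()
    assert position_to_bd(equilibrium_position(rho, params), params) == pytest.approx(
        rho, abs=1e-9
    )


class TestDBLPositionRange:
    def test_positive_width_everywhere(self, params):
        for x in np.linspace(params.r_min + 1e-9, params.r_max - 1e-9, 500):
            d = dbl_position_range(x, params)
            assert d.x_min < d.x_max
            assert d.rho_dbl_min < d.rho_dbl_max

    def test_bd_bounds_bracket_band_density(self, params):
        for x in np.linspace(params.r_min + 1e-9, params.r_max - 1e-9, 500):
            d = dbl_position_range(x, params)
            rho = position_to_bd(x, params)
            assert d.rho_dbl_min <= rho <= d.rho_dbl_max

    def test_section_boundary_continuity(self, params):
        """Cylindrical and rounded-bottom formulas agree at each junction."""
        rt, theta = params.tube_radius, params.tube_angle
        c_bottom = params.r_max - rt
        for x_star in (
            c_bottom - rt * math.cos(theta),  # s_min bound crossover
            c_bottom + rt * math.cos(theta),  # s_max bound crossover
        ):
            below = dbl_position_range(x_star - 1e-9, params)
            above = dbl_position_range(x_star + 1e-9, params)
            assert abs(below.x_min - above.x_min) < 1e-6
            assert abs(below.x_max - above.x_max) < 1e-6

    def test_bd_bounds_monotone_on_cylindrical_section(self, params):
        """Dense sweep: deeper bands contaminate denser BD ranges."""
        rt, theta = params.tube_radius, params.tube_angle
        upper = params.r_max - rt - rt * math.cos(theta)
        xs = np.linspace(params.r_min + 1e-9, upper - 1e-9, 300)
        lo = np.array([dbl_position_range(x, params).rho_dbl_min for x in xs])
        hi = np.array([dbl_position_range(x, params).rho_dbl_max for x in xs])
        assert np.all(np.diff(lo) >= -1e-12)
        assert np.all(np.diff(hi) >= -1e-12)

    def test_outside_tube_names_bound(self, params):
        with pytest.raises(GeometryError, match="r_min"):
            dbl_position_range(params.r_min - 0.1, params)
        with pytest.raises(GeometryError, match="r_max"):
            dbl_position_range(params.r_max + 0.1, params)


class TestModelGradientTable:
    def test_parity_with_analytic_gradient(self, params):
        table = ModelGradientTable(params, step=1e-4)
        xs = np.linspace(params.r_min, params.r_max, 777)
        np.testing.assert_allclose(
            table.bd_at(xs), position_to_bd(xs, params), atol=1e-9
        )

    def test_inverse_lookup(self, params):
        table = ModelGradientTable(params, step=1e-4)
        rho = 1.72
        assert table.position_at(rho) == pytest.approx(
            equilibrium_position(rho, params), abs=1e-6
        )


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_min": 5.0, "r_max": 2.0},
            {"tube_radius": -1.0},
            {"tube_angle": 0.0},
            {"temperature": -3.0},
            {"avg_density": 0.9},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GradientParams(**kwargs)

    def test_window_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            BDWindow(1.77, 1.72)
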
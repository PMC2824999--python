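import math

import numpy as np
import pandas as pd
import pytest

from brachymc import reference, tg43
from brachymc.fixtures import FixtureSpec, analytic_field_archive, known_ratio_pair
from brachymc.tallies import GL_RADII


class TestUnitConversion:
    def test_gy_per_decay_to_activity_units(self):
        assert tg43.per_decay_to_activity_units(1.0) == pytest.approx(3.6e5)
        assert tg43.per_decay_to_activity_units(0.0) == 0.0

    def test_round_trip_identity(self):
        x = 2.7e-13
        back = tg43.activity_units_to_per_decay(
            tg43.per_decay_to_activity_units(x))
        assert back == pytest.approx(x, rel=1e-15)


class TestAirKermaFit:
    def test_exact_inverse_square(self):
        y = np.array([25.0, 50.0, 75.0, 100.0])
        c = 3.0e-7
        series = tg43.AirKermaSeries(y, c / y**2, np.zeros(4))
        sk, b, _ = tg43.fit_air_kerma_strength(series)
        assert sk == pytest.approx(c, rel=1e-12)
        assert b == pytest.approx(0.0, abs=1e-15)

    def test_recovers_constructed_linear_data(self):
        y = np.array([25.0, 50.0, 75.0, 100.0])
        c, slope = 2.5e-7, 1e-3
        series = tg43.AirKermaSeries(y, (c + slope * y) / y**2, np.zeros(4))
        sk, b, _ = tg43.fit_air_kerma_strength(series)
        assert sk == pytest.approx(c, rel=1e-10)
        assert b == pytest.approx(slope, rel=1e-10)

    def test_too_few_points(self):
        series = tg43.AirKermaSeries(np.array([25.0]), np.array([1e-10]),
                                     np.array([0.0]))
        with pytest.raises(ValueError):
            tg43.fit_air_kerma_strength(series)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            tg43.AirKermaSeries(np.array([25.0, 50.0]),
                                np.array([1e-10, -1e-10]), np.zeros(2))


class TestGeometryFunction:
    def test_far_field_inverse_square_limit(self):
        g = tg43.line_geometry_function(1000.0)
        assert g * 1000.0**2 == pytest.approx(1.0, abs=1e-6)

    def test_theta_reflection_symmetry(self, rng):
        for _ in range(100):
            r = rng.uniform(0.3, 20.0)
            th = rng.uniform(0.05, math.pi / 2)
            assert tg43.line_geometry_function(r, th) == \
                pytest.approx(tg43.line_geometry_function(r, math.pi - th),
                              rel=1e-12)

    def test_point_source_constant_relation(self):
        # lambda_point * G_L(1 cm, 90 deg) for the 0.35 cm active length
        val = 1.094 * tg43.line_geometry_function(1.0)
        assert round(val, 3) == 1.083

    def test_long_axis_continuity(self):
        r = 2.0
        near_axis = tg43.line_geometry_function(r, 1e-7)
        on_axis = tg43.line_geometry_function(r, 0.0)
        assert near_axis == pytest.approx(on_axis, rel=1e-6)
        assert on_axis == pytest.approx(1.0 / (r**2 - 0.35**2 / 4), rel=1e-12)

    def test_point_on_segment_rejected(self):
        with pytest.raises(ValueError):
            tg43.line_geometry_function(0.1, 0.0)


class TestDoseRateConstant:
    def test_unity_when_numerator_equals_sk(self):
        lam, _ = tg43.dose_rate_constant(3.0e-7, 3.0e-7)
        assert lam == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [1.0, 1.086, 1.094])
    def test_known_ratio_pair_exact(self, target):
        series, kerma_r0 = known_ratio_pair(target)
        sk, _, _ = tg43.fit_air_kerma_strength(series)
        lam, _ = tg43.dose_rate_constant(kerma_r0, sk)
        assert lam == pytest.approx(target, rel=1e-10)

    def test_uncertainty_in_quadrature(self):
        _, rel = tg43.dose_rate_constant(1.0, 1.0, 0.03, 0.04)
        assert rel == pytest.approx(0.05)

    def test_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            tg43.dose_rate_constant(0.0, 1.0)


class TestRadialDoseFunction:
    def _profile(self, scale):
        r = np.array(GL_RADII)
        geo = np.array([tg43.line_geometry_function(x) for x in r])
        return pd.DataFrame({"r": r, "dose": geo * scale(r)})

    def test_geometry_only_field_gives_unity(self):
        gl = tg43.radial_dose_function(self._profile(lambda r: 1.0))
        np.testing.assert_allclose(gl["g"], 1.0, atol=1e-12)

    def test_exponential_field_recovered(self):
        gl = tg43.radial_dose_function(
            self._profile(lambda r: np.exp(-0.01 * r)))
        np.testing.assert_allclose(gl["g"], np.exp(-0.01 * (gl["r"] - 1)),
                                   rtol=1e-12)

    def test_reference_radius_exactly_one(self):
        gl = tg43.radial_dose_function(
            self._profile(lambda r: np.exp(-0.05 * r)))
        assert float(gl.loc[np.isclose(gl["r"], 1.0), "g"].iloc[0]) == 1.0

    def test_missing_reference_radius(self):
        prof = pd.DataFrame({"r": [2.0, 3.0], "dose": [1.0, 0.5]})
        with pytest.raises(ValueError):
            tg43.radial_dose_function(prof)


class TestPolynomialFit:
    def test_exact_cubic_recovery(self):
        coef_true = np.array([1.01, -0.012, -3e-4, 4e-6])
        r = np.linspace(0.2, 20, 30)
        g = np.polynomial.polynomial.polyval(r, coef_true)
        coef = tg43.fit_radial_polynomial(pd.DataFrame({"r": r, "g": g}))
        np.testing.assert_allclose(coef, coef_true, atol=1e-10)

    def test_constant_data(self):
        r = np.linspace(0.2, 20, 10)
        coef = tg43.fit_radial_polynomial(
            pd.DataFrame({"r": r, "g": np.full_like(r, 0.9)}))
        assert coef[0] == pytest.approx(0.9, abs=1e-10)
        np.testing.assert_allclose(coef[1:], 0.0, atol=1e-10)

    def test_published_water_column(self):
        """Cubic fit of the published 32-point water g_L table reproduces
        the published coefficients, and residuals stay below 0.01."""
        table = reference.radial_dose_function_table()
        gl = pd.DataFrame({"r": table["r"], "g": table["water"]})
        coef = tg43.fit_radial_polynomial(gl)
        assert coef[0] == pytest.approx(reference.GL_POLY_WATER[0], abs=0.005)
        fit = np.polynomial.polynomial.polyval(gl["r"], coef)
        assert np.max(np.abs(fit - gl["g"])) < 0.01

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            tg43.fit_radial_polynomial(
                pd.DataFrame({"r": [1, 2, 3], "g": [1, 0.9, 0.8]}))


class TestDoseRateTable:
    def test_unity_when_kerma_rate_equals_sk(self):
        sk = 3.0e-7
        kerma = tg43.activity_units_to_per_decay(sk)
        cells = pd.DataFrame({"y": [5.0], "z": [0.0], "kerma": [kerma],
                              "kerma_rel_1sigma": [0.0]})
        table = tg43.build_dose_rate_table(cells, sk)
        assert float(table["dose_rate"].iloc[0]) == pytest.approx(1.0)

    def test_internal_tg43_identity_on_fixture(self):
        """Table values satisfy D(y,0)/S_K = lambda g_L(y) G_L(y)/G_L(1)."""
        spec = FixtureSpec(field_model="line_geometry_attenuated",
                           amplitude=1e-12, mu=0.03)
        arch = analytic_field_archive(spec)
        cells = arch["cells"]
        sk = 3.0e-7
        table = tg43.build_dose_rate_table(cells, sk)
        gl = tg43.radial_dose_function(tg43.transverse_profile(cells))
        lam = tg43.per_decay_to_activity_units(
            cells[(cells.y == 1.0) & (cells.z == 0.0)]["kerma"].iloc[0]) / sk
        for y in (2.0, 5.0, 10.0):
            t_val = float(table[(table.y == y) & (table.z == 0.0)]
                          ["dose_rate"].iloc[0])
            g = float(gl.loc[np.isclose(gl["r"], y), "g"].iloc[0])
            pred = lam * g * tg43.line_geometry_function(y) / \
                tg43.line_geometry_function(1.0)
            assert t_val == pytest.approx(pred, rel=1e-9)

    def test_rejects_bad_sk(self):
        cells = pd.DataFrame({"y": [5.0], "z": [0.0], "kerma": [1e-13],
                              "kerma_rel_1sigma": [0.0]})
        with pytest.raises(ValueError):
            tg43.build_dose_rate_table(cells, 0.0)


class TestComparison:
    def _table(self, scale, rel=0.001):
        y = np.array([1.0, 5.0, 10.0])
        return pd.DataFrame({"y": y, "z": np.zeros(3),
                             "dose_rate": scale * np.array([0.5, 0.04, 0.009]),
                             "rel_1sigma": np.full(3, rel)})

    def test_identical_tables_zero(self):
        t = self._table(1.0)
        cmp_df = tg43.compare_phantoms(t, t)
        np.testing.assert_allclose(cmp_df["percent_diff"], 0.0, atol=1e-12)

    def test_constant_offset_recovered(self):
        cmp_df = tg43.compare_phantoms(self._table(1.0), self._table(1.03))
        np.testing.assert_allclose(cmp_df["percent_diff"], 3.0, rtol=1e-10)
        assert cmp_df["significant"].all()

    def test_lattice_mismatch_rejected(self):
        t1 = self._table(1.0)
        t2 = self._table(1.0).assign(y=[1.0, 5.0, 12.0])
        with pytest.raises(ValueError):
            tg43.compare_phantoms(t1, t2)

    def test_published_pmma_deficit_at_10cm(self):
        """Published radial dose functions put PMMA ~2.3% below water at
        10 cm."""
        diff = 100 * (reference.gl_reference("pmma", 10.0)
                      - reference.gl_reference("water", 10.0)) \
            / reference.gl_reference("water", 10.0)
        assert diff == pytest.approx(-2.3, abs=0.1)


class TestBackscatter:
    def test_co60_mean_energy(self):
        assert tg43.backscatter_energy(1.25) == pytest.approx(0.212, abs=5e-4)
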
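import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import m15tg43.tg43 as tg43
from m15tg43.mc_transport import DoseGrid


class TestUnitConversion:
    def test_constant_rounds_to_standard_value(self):
        # 1 MeV/g per Bq s = 2.13e3 cGy/(mCi h) to 3 significant figures
        assert round(tg43.K_CGY_MCI_H, -1) == 2130.0

    def test_hand_multiplied_factors(self):
        assert tg43.K_CGY_MCI_H == pytest.approx(
            3.7e7 * 3600 * 1.602176634e-8, rel=1e-12)
        assert tg43.dose_rate(1.0, 2.301) == pytest.approx(4.911e3, rel=1e-3)

    def test_zero_and_negative(self):
        assert tg43.dose_rate(0.0, 2.301) == 0.0
        with pytest.raises(ValueError):
            tg43.dose_rate(-1.0, 2.301)
        with pytest.raises(ValueError):
            tg43.dose_rate(1.0, 0.0)


class TestGeometryFunction:
    def test_transverse_axis_closed_form(self):
        # beta = 2 atan(L/2r) on the transverse axis
        expect = 2 * np.arctan(0.175) / 0.35
        assert tg43.geometry_function(1.0, 90.0, 0.35) == pytest.approx(
            expect, rel=1e-12)
        assert expect == pytest.approx(0.9900, abs=2e-4)

    def test_polar_branch(self):
        assert tg43.geometry_function(1.0, 0.0, 0.35) == pytest.approx(
            1.0 / (1 - 0.030625), rel=1e-12)
        assert tg43.geometry_function(1.0, 180.0, 0.35) == pytest.approx(
            tg43.geometry_function(1.0, 0.0, 0.35))

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.3, 12.0), st.floats(0.0, 180.0))
    def test_point_source_limit(self, r, theta):
        g = tg43.geometry_function(r, theta, 1e-6)
        assert g * r**2 == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("r", [0.5, 1.0, 5.0, 10.0])
    @pytest.mark.parametrize("pole", [0.0, 180.0])
    def test_pole_continuity(self, r, pole):
        inner = tg43.geometry_function(r, abs(pole - 0.5), 0.35)
        at_pole = tg43.geometry_function(r, pole, 0.35)
        assert abs(inner - at_pole) / at_pole < 0.005

    def test_domain_error_inside_source(self):
        with pytest.raises(ValueError):
            tg43.geometry_function(0.1, 90.0, 0.35)


def _toy_grid():
    radii = np.array([0.5, 1.0, 2.0])
    angles = np.array([0.0, 90.0, 180.0])
    tally = np.array([[1.0, 0.5, 0.2],
                      [2.0, 1.0, 0.25],
                      [0.9, 0.45, 0.18]])
    return DoseGrid(radii=radii, angles_deg=angles, tally=tally,
                    rel_unc=np.zeros_like(tally), n_histories=0,
                    n_batches=1, seed=0)


class TestTableOperations:
    def test_normalized_dose_self_normalizes(self):
        dn = tg43.normalized_dose_table(_toy_grid())
        assert dn[1, 1] == 1.0
        assert dn[1, 0] == pytest.approx(2.0 * 0.25)

    def test_radial_dose_is_one_at_reference(self):
        g = tg43.radial_dose_function(_toy_grid(), 0.35)
        assert g[1] == 1.0
        assert np.all(g > 0)

    def test_anisotropy_is_one_on_transverse_axis(self):
        f = tg43.anisotropy_function(_toy_grid(), 0.35)
        assert np.allclose(f[1, :], 1.0)

    def test_missing_reference_cell_is_fatal(self):
        grid = DoseGrid(radii=np.array([2.0]), angles_deg=np.array([90.0]),
                        tally=np.array([[1.0]]), rel_unc=np.array([[0.0]]),
                        n_histories=0, n_batches=1, seed=0)
        with pytest.raises(KeyError):
            tg43.normalized_dose_table(grid)


class TestAnisotropyFactor:
    def test_isotropic_row_integrates_to_one(self):
        angles = np.concatenate([np.arange(0, 11), np.arange(15, 170, 5),
                                 np.arange(170, 181)]).astype(float)
        phi = tg43.anisotropy_factor(angles, np.ones_like(angles))
        assert phi == pytest.approx(1.0, abs=1e-3)

    def test_row_must_span_poles(self):
        with pytest.raises(ValueError):
            tg43.anisotropy_factor(np.array([10.0, 90.0, 170.0]),
                                   np.ones(3))

    def test_weights_sum_to_one(self):
        w = tg43.anisotropy_weights(np.arange(1.0, 11.0))
        assert w.sum() == pytest.approx(1.0, rel=1e-12)

    def test_constant_profile_returns_constant(self):
        assert tg43.anisotropy_constant(
            np.arange(1.0, 11.0), np.full(10, 0.7)) == pytest.approx(0.7)

    def test_wrong_radius_set_is_fatal(self):
        with pytest.raises(ValueError):
            tg43.anisotropy_constant(np.arange(2.0, 12.0), np.ones(10))


class TestScalars:
    def test_dose_rate_constant_ratio(self):
        assert tg43.dose_rate_constant(4.038, 3.632) == pytest.approx(
            1.112, abs=5e-4)
        assert tg43.dose_rate_constant(1.0, 1.0) == 1.0
        assert tg43.dose_rate_constant(2 * 4.038, 2 * 3.632) == pytest.approx(
            tg43.dose_rate_constant(4.038, 3.632))
        with pytest.raises(ValueError):
            tg43.dose_rate_constant(4.0, 0.0)


class TestRoundTrip:
    def test_analytic_grid_inverts_to_input_parameters(self, reference):
        """Noise-free forward model through Eq.-style synthesis must invert
        to the same g_L and F to 1e-6 relative."""
        radii = reference.radii
        angles = reference.angles_deg
        g_true = reference.radial_dose["g_L"].to_numpy(float)
        f_true = reference.anisotropy.to_numpy(float)
        grid = tg43.synthesize_grid(radii, angles, 1.112, g_true, f_true, 0.35)
        g_back = tg43.radial_dose_function(grid, 0.35)
        f_back = tg43.anisotropy_function(grid, 0.35)
        assert np.allclose(g_back, g_true, rtol=1e-6)
        assert np.allclose(f_back, f_true, rtol=1e-6)
        dn = tg43.normalized_dose_table(grid)
        from m15tg43.dose_engine import reconstruct_normalized_dose

        assert np.allclose(
            dn, reconstruct_normalized_dose(radii, angles, g_true, f_true),
            rtol=1e-6)
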
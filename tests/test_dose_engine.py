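import numpy as np
import pytest

from m15tg43.dose_engine import (
    anisotropy_from_normalized,
    build_reference_dataset,
    dose_at,
    reconstruct_normalized_dose,
    validate,
)
from m15tg43.tg43 import geometry_function


@pytest.fixture(scope="module")
def dataset(reference):
    return build_reference_dataset(reference)


class TestDoseAt:
    def test_reference_point_returns_dose_rate_constant(self, dataset):
        assert dose_at(dataset, 1.0, 1.0, 90.0) == pytest.approx(1.112,
                                                                 rel=1e-6)

    def test_tabulated_node_hand_product(self, dataset):
        expect = (1.112 * geometry_function(5.0, 90.0, 0.35)
                  / geometry_function(1.0, 90.0, 0.35) * 1.004 * 1.0)
        assert dose_at(dataset, 1.0, 5.0, 90.0) == pytest.approx(expect,
                                                                 rel=1e-6)

    def test_transverse_axis_independent_of_anisotropy_interp(self, dataset):
        for r in (2.0, 3.0, 7.0):
            direct = (1.112 * geometry_function(r, 90.0, 0.35)
                      / geometry_function(1.0, 90.0, 0.35)
                      * np.interp(r, dataset.radii, dataset.g))
            assert dose_at(dataset, 1.0, r, 90.0) == pytest.approx(direct,
                                                                   rel=1e-9)

    def test_linear_in_source_strength(self, dataset):
        base = dose_at(dataset, 1.0, 3.3, 47.0)
        assert dose_at(dataset, 2.5, 3.3, 47.0) == pytest.approx(2.5 * base,
                                                                 rel=1e-12)

    def test_no_interpolation_seams(self, dataset):
        # the interpolated g*F factor (dose with the closed-form geometry
        # factor divided out) must be continuous across grid nodes: adjacent
        # evaluations 0.01 cm (or 0.1 deg) apart differ by < 0.1%
        def factor(r, theta):
            return (dose_at(dataset, 1.0, r, theta)
                    / geometry_function(r, theta, 0.35))

        for r in (1.0, 2.0, 5.0):
            for theta in (37.0, 90.0, 120.0):
                lo = factor(r - 0.005, theta)
                hi = factor(r + 0.005, theta)
                assert abs(hi - lo) / lo < 0.001
        for theta in (10.0, 15.0, 165.0):
            lo = factor(4.0, theta - 0.005)
            hi = factor(4.0, theta + 0.005)
            assert abs(hi - lo) / lo < 0.001

    def test_out_of_range_radius_raises_unless_extrapolating(self, dataset):
        with pytest.raises(ValueError, match="outside the tabulated range"):
            dose_at(dataset, 1.0, 12.0, 90.0)
        val = dose_at(dataset, 1.0, 12.0, 90.0, extrapolate=True)
        assert 0 < val < dose_at(dataset, 1.0, 10.0, 90.0)

    def test_angles_clamp_to_poles(self, dataset):
        assert dose_at(dataset, 1.0, 2.0, -3.0) == pytest.approx(
            dose_at(dataset, 1.0, 2.0, 0.0), rel=0.05)


class TestReconstruction:
    def test_identity_against_published_table(self, reference):
        dn = reconstruct_normalized_dose(
            reference.radii, reference.angles_deg,
            reference.radial_dose["g_L"].to_numpy(float),
            reference.anisotropy.to_numpy(float))
        dev = np.abs(dn - reference.normalized_dose.to_numpy(float))
        assert dev.max() <= 0.01  # limited by 3-decimal table rounding

    def test_anisotropy_recovery_from_normalized(self, reference):
        f = anisotropy_from_normalized(
            reference.radii, reference.angles_deg,
            reference.normalized_dose.to_numpy(float))
        dev = np.abs(f - reference.anisotropy.to_numpy(float))
        assert dev.max() <= 0.012


class TestValidate:
    def test_reference_dataset_validates_perfectly(self, dataset, reference):
        report = validate(dataset, reference)
        assert report["passed"]
        for entry in report["tables"].values():
            assert entry["max_abs_dev"] == 0.0
        for entry in report["scalars"].values():
            assert entry["abs_dev"] == 0.0

    def test_analytic_round_trip_deviations_small(self, reference):
        from m15tg43 import tg43

        g_true = reference.radial_dose["g_L"].to_numpy(float)
        f_true = reference.anisotropy.to_numpy(float)
        grid = tg43.synthesize_grid(reference.radii, reference.angles_deg,
                                    1.112, g_true, f_true, 0.35)
        g = tg43.radial_dose_function(grid, 0.35)
        f = tg43.anisotropy_function(grid, 0.35)
        assert np.max(np.abs(g - g_true)) < 1e-9
        assert np.max(np.abs(f - f_true)) < 1e-9

    def test_grid_mismatch_is_fatal(self, dataset):
        import dataclasses

        bad = dataclasses.replace(dataset, radii=dataset.radii[:-1],
                                  normalized_dose=dataset.normalized_dose[:, :-1],
                                  g=np.concatenate([dataset.g[:-2], [1.0]])[:10],
                                  anisotropy=dataset.anisotropy[:, :-1])
        with pytest.raises(ValueError, match="grid mismatch"):
            validate(bad)
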
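import numpy as np
import pytest

from m15tg43.mc_transport import (
    TallyGridSpec,
    simulate_air_kerma,
    simulate_water,
)
from m15tg43.physics_data import coefficient, load_material


def _single_cell():
    return TallyGridSpec(np.array([1.0]), np.array([90.0]))


class TestDeterminism:
    def test_water_bitwise_reproducible(self, geometry, spectrum):
        kw = dict(grid=_single_cell(), n_histories=10**4, seed=77, n_batches=10)
        a = simulate_water(geometry, spectrum, **kw)
        b = simulate_water(geometry, spectrum, **kw)
        assert np.array_equal(a.tally, b.tally)
        assert np.array_equal(a.rel_unc, b.rel_unc)

    def test_air_bitwise_reproducible(self, geometry, spectrum):
        kw = dict(n_histories=10**4, seed=77, n_batches=10)
        a = simulate_air_kerma(geometry, spectrum, **kw)
        b = simulate_air_kerma(geometry, spectrum, **kw)
        assert a.kerma_per_photon == b.kerma_per_photon
        assert a.rel_unc == b.rel_unc


class TestWaterPhysics:
    def test_absorption_only_point_source_matches_closed_form(self, spectrum):
        """Scattering disabled, point source: the tally must equal the
        analytic primary collision kerma sum over the emission lines."""
        grid = TallyGridSpec(np.array([1.0, 3.0]), np.array([90.0]))
        res = simulate_water(None, spectrum, grid, n_histories=2 * 10**5,
                             seed=5, n_batches=20, disable_scatter=True,
                             point_isotropic=True)
        water = load_material("water")
        rho = water.density
        for j, r in enumerate(grid.radii):
            mu = coefficient(water, spectrum.energies) * rho
            muen = coefficient(water, spectrum.energies, "energy_absorption")
            expect = np.sum(spectrum.intensities / spectrum.total_yield
                            * spectrum.energies * muen
                            * np.exp(-mu * r)) / (4 * np.pi * r**2)
            got = res.tally[0, j]
            se = got * res.rel_unc[0, j]
            assert abs(got - expect) < max(3 * se, 0.004 * expect)

    def test_scatter_increases_dose_over_primary(self, geometry, spectrum):
        kw = dict(grid=_single_cell(), n_histories=5 * 10**4, seed=3,
                  n_batches=10)
        full = simulate_water(geometry, spectrum, **kw)
        primary = simulate_water(geometry, spectrum, disable_scatter=True, **kw)
        assert full.at(1, 90) > primary.at(1, 90)

    def test_energy_bookkeeping_without_scatter(self, spectrum):
        """Energy scored in the tally cells cannot exceed emitted energy."""
        grid = TallyGridSpec(np.array([0.5, 1.0, 2.0]),
                             np.array([45.0, 90.0, 135.0]))
        res = simulate_water(None, spectrum, grid, n_histories=10**4, seed=8,
                             n_batches=10, disable_scatter=True,
                             point_isotropic=True)
        water_rho = load_material("water").density
        scored = np.sum(res.tally * grid.cell_volumes * water_rho)
        emitted = res.n_histories * spectrum.mean_energy
        assert scored < emitted

    def test_uncertainty_scales_inverse_sqrt_histories(self, geometry, spectrum):
        kw = dict(grid=_single_cell(), seed=4, n_batches=10)
        lo = simulate_water(geometry, spectrum, n_histories=2 * 10**4, **kw)
        hi = simulate_water(geometry, spectrum, n_histories=16 * 10**4, **kw)
        ratio = lo.rel_unc_at(1, 90) / hi.rel_unc_at(1, 90)
        assert 1.6 < ratio < 5.0  # expect ~sqrt(8) = 2.83

    def test_batch_error_consistent_with_seed_spread(self, geometry, spectrum):
        vals, sems = [], []
        for seed in range(10):
            g = simulate_water(geometry, spectrum, _single_cell(),
                               n_histories=2 * 10**4, seed=seed, n_batches=10)
            vals.append(g.at(1, 90))
            sems.append(g.at(1, 90) * g.rel_unc_at(1, 90))
        spread = np.std(vals, ddof=1)
        predicted = np.mean(sems)
        assert predicted / 2.0 < spread < predicted * 2.0

    def test_azimuthal_sector_symmetry(self, small_water_grid):
        """Disjoint azimuthal half-sectors must agree within statistics."""
        s = small_water_grid.sector_tally
        total = s.sum(axis=0)
        mask = total > 0
        # binomial split: sd of the half/total fraction ~ cell noise
        frac = s[0][mask] / total[mask]
        rel = small_water_grid.rel_unc[mask]
        z = (frac - 0.5) / np.maximum(rel / np.sqrt(2), 1e-3)
        assert np.mean(np.abs(z) < 4.0) > 0.9

    def test_zero_track_cells_flagged(self, geometry, spectrum):
        grid = TallyGridSpec(np.array([10.0]), np.array([0.0]))
        res = simulate_water(geometry, spectrum, grid, n_histories=10**4,
                             seed=1, n_batches=5)
        if res.tally[0, 0] == 0.0:
            assert res.rel_unc[0, 0] == 1.0
            assert res.zero_track_cells[0, 0]

    def test_history_minimum_enforced(self, geometry, spectrum):
        with pytest.raises(ValueError):
            simulate_water(geometry, spectrum, _single_cell(),
                           n_histories=100, seed=0)

    def test_grid_must_fit_phantom(self, geometry, spectrum):
        grid = TallyGridSpec(np.array([60.0]), np.array([90.0]))
        with pytest.raises(ValueError, match="inside the phantom"):
            simulate_water(geometry, spectrum, grid, n_histories=10**4, seed=0)


class TestAirKerma:
    def test_point_source_vacuum_matches_analytic(self, spectrum):
        """No absorber: kerma = sum I/Itot * E * muen/rho / (4 pi d^2)."""
        res = simulate_air_kerma(None, spectrum, distance_cm=100.0,
                                 delta_kev=0.0, n_histories=3 * 10**5, seed=6,
                                 n_batches=20, point_isotropic=True)
        air = load_material("air")
        muen = coefficient(air, spectrum.energies, "energy_absorption")
        expect = np.sum(spectrum.intensities / spectrum.total_yield
                        * spectrum.energies * muen) / (4 * np.pi * 100.0**2)
        se = res.kerma_per_photon * res.rel_unc
        assert abs(res.kerma_per_photon - expect) < max(4 * se, 0.01 * expect)

    def test_inverse_square_in_vacuum(self, spectrum):
        near = simulate_air_kerma(None, spectrum, distance_cm=50.0,
                                  n_histories=10**5, seed=9, n_batches=20,
                                  point_isotropic=True)
        far = simulate_air_kerma(None, spectrum, distance_cm=100.0,
                                 n_histories=10**5, seed=9, n_batches=20,
                                 point_isotropic=True)
        ratio = near.kerma_per_photon / far.kerma_per_photon
        sigma = ratio * np.sqrt(near.rel_unc**2 + far.rel_unc**2)
        assert abs(ratio - 4.0) < 4 * sigma + 0.1

    def test_distance_squared_cancels_in_strength(self, geometry, spectrum):
        from m15tg43.tg43 import air_kerma_strength

        a = simulate_air_kerma(geometry, spectrum, distance_cm=50.0,
                               n_histories=2 * 10**5, seed=12, n_batches=20)
        b = simulate_air_kerma(geometry, spectrum, distance_cm=100.0,
                               n_histories=2 * 10**5, seed=12, n_batches=20)
        sa = air_kerma_strength(a, spectrum.total_yield)
        sb = air_kerma_strength(b, spectrum.total_yield)
        sigma = sa * np.sqrt(a.rel_unc**2 + b.rel_unc**2)
        assert abs(sa - sb) < 4 * sigma + 0.02 * sa

    def test_cutoff_filter_monotone(self, geometry, spectrum):
        kw = dict(n_histories=5 * 10**4, seed=2, n_batches=10,
                  cutoff_mev=0.001)
        unfiltered = simulate_air_kerma(geometry, spectrum, delta_kev=0.0, **kw)
        filtered = simulate_air_kerma(geometry, spectrum, delta_kev=10.0, **kw)
        # identical trajectories, the filter only removes sub-10-keV scoring
        diff = unfiltered.kerma_per_photon - filtered.kerma_per_photon
        assert diff >= 0.0
        assert diff < 0.02 * unfiltered.kerma_per_photon

    def test_delta_recorded_and_preconditions(self, geometry, spectrum):
        res = simulate_air_kerma(geometry, spectrum, n_histories=10**4,
                                 seed=1, n_batches=5)
        assert res.delta_kev == 10.0
        with pytest.raises(ValueError):
            simulate_air_kerma(geometry, spectrum, distance_cm=0.1,
                               n_histories=10**4, seed=1)
        with pytest.raises(ValueError):
            simulate_air_kerma(geometry, spectrum, delta_kev=-5,
                               n_histories=10**4, seed=1)
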
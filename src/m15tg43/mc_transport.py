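"""Desk-scale Monte Carlo photon transport for the M-15 source.

Produces F6-style collision-kerma tallies on an (r, theta) polar grid in a
water sphere (``simulate_water``) and a *F4-style air-kerma tally at a
distance in vacuum (``simulate_air_kerma``), each with per-cell batch
statistical uncertainties.  The kerma approximation stands in for coupled
photon-electron transport: at Ir-192 energies secondary-electron ranges in
water are under ~2 mm, so collision kerma tracks absorbed dose at all
tallied radii.

Tallies are reported per source photon in MeV/g, mirroring the tally units
of general-purpose transport codes, and are converted to clinical units by
:func:`m15tg43.tg43.dose_rate`.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .physics_data import (
    ELECTRONS_PER_GRAM,
    MATERIAL_DENSITY_G_CM3,
    MaterialTable,
    PhotonSpectrum,
    coefficient,
    klein_nishina_cross_section,
    load_material,
)
from .source_model import SourceGeometry, build_m15

__all__ = [
    "TallyGridSpec",
    "DoseGrid",
    "AirKermaResult",
    "default_grid_spec",
    "simulate_water",
    "simulate_air_kerma",
]

R0_CM = 1.0
THETA0_DEG = 90.0


def default_grid_spec() -> "TallyGridSpec":
    """Tally layout matching the published tables: r = 0.5 then 1..10 cm,
    theta in 1-degree steps at 0-10 and 170-180 and 5-degree steps between."""
    radii = [0.5] + list(range(1, 11))
    angles = list(range(0, 11)) + list(range(15, 170, 5)) + list(range(170, 181))
    return TallyGridSpec(np.array(radii, float), np.array(angles, float))


@dataclass(frozen=True)
class TallyGridSpec:
    """Polar tally-cell layout.

    Cells are full-azimuth spherical-shell rings centred on the grid nodes.
    Radial half-widths default to ``min(0.025 + 0.025 r, 0.1)`` cm and the
    angular half-width to 0.5 degrees — small enough that volume-averaging
    bias stays below the statistical noise at desk-scale history counts.
    """

    radii: np.ndarray
    angles_deg: np.ndarray
    angular_half_width_deg: float = 0.5
    radial_half_widths: np.ndarray = field(default=None)

    def __post_init__(self):
        r = np.asarray(self.radii, float)
        a = np.asarray(self.angles_deg, float)
        if r.ndim != 1 or a.ndim != 1 or r.size == 0 or a.size == 0:
            raise ValueError("grid must have at least one radius and one angle")
        if np.any(np.diff(r) <= 0) or np.any(r <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if np.any(np.diff(a) <= 0) or a[0] < 0 or a[-1] > 180:
            raise ValueError("angles must be strictly increasing within [0, 180]")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "angles_deg", a)
        if self.radial_half_widths is None:
            hw = np.minimum(0.025 + 0.025 * r, 0.1)
        else:
            hw = np.asarray(self.radial_half_widths, float)
        lo = r - hw
        hi = r + hw
        if np.any(lo <= 0) or np.any(hi[:-1] > lo[1:]):
            raise ValueError("radial shells must be positive and non-overlapping")
        object.__setattr__(self, "radial_half_widths", hw)

    @property
    def shell_bounds(self):
        return self.radii - self.radial_half_widths, self.radii + self.radial_half_widths

    @property
    def band_bounds(self):
        """(mu_lo, mu_hi) polar-cosine bounds per angle row (clipped at poles)."""
        h = self.angular_half_width_deg
        hi_deg = np.clip(self.angles_deg + h, 0.0, 180.0)
        lo_deg = np.clip(self.angles_deg - h, 0.0, 180.0)
        mu_lo = np.cos(np.radians(hi_deg))
        mu_hi = np.cos(np.radians(lo_deg))
        return mu_lo, mu_hi

    @property
    def cell_volumes(self):
        """Ring volumes in cm^3, shape (n_theta, n_r)."""
        lo, hi = self.shell_bounds
        mu_lo, mu_hi = self.band_bounds
        radial = 2.0 * np.pi / 3.0 * (hi**3 - lo**3)
        return np.outer(mu_hi - mu_lo, radial)


@dataclass(frozen=True)
class DoseGrid:
    """Polar-grid tally means with per-cell relative MC uncertainty."""

    radii: np.ndarray
    angles_deg: np.ndarray
    tally: np.ndarray  # MeV/g per source photon, shape (n_theta, n_r)
    rel_unc: np.ndarray  # relative standard error (batch statistics)
    n_histories: int
    n_batches: int
    seed: int
    sector_tally: np.ndarray = None  # (2, n_theta, n_r), azimuthal halves
    geometry_json: str = ""

    def __post_init__(self):
        if np.any(self.tally < 0) or np.any(self.rel_unc < 0):
            raise ValueError("tally means and uncertainties must be non-negative")

    def _index(self, r, theta):
        ir = np.flatnonzero(np.isclose(self.radii, r))
        it = np.flatnonzero(np.isclose(self.angles_deg, theta))
        if ir.size == 0 or it.size == 0:
            raise KeyError(f"({r} cm, {theta} deg) is not a grid node")
        return int(it[0]), int(ir[0])

    @property
    def reference_indices(self):
        """Indices of the TG-43 reference point (1 cm, 90 deg)."""
        return self._index(R0_CM, THETA0_DEG)

    def at(self, r, theta):
        it, ir = self._index(r, theta)
        return self.tally[it, ir]

    def rel_unc_at(self, r, theta):
        it, ir = self._index(r, theta)
        return self.rel_unc[it, ir]

    @property
    def zero_track_cells(self):
        """Boolean mask of cells that scored no tracks (rel_unc flagged 1.0)."""
        return self.tally == 0.0

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("r_cm,theta_deg,tally_mev_per_g_per_photon,rel_unc\n")
            for it, th in enumerate(self.angles_deg):
                for ir, r in enumerate(self.radii):
                    fh.write(f"{r},{th},{self.tally[it, ir]:.8e},"
                             f"{self.rel_unc[it, ir]:.6e}\n")

    def sidecar(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_histories": int(self.n_histories),
            "n_batches": int(self.n_batches),
            "geometry": json.loads(self.geometry_json) if self.geometry_json else None,
        }


@dataclass(frozen=True)
class AirKermaResult:
    """Air-kerma tally at distance d in vacuum, with the X-ray cutoff delta."""

    distance_cm: float
    delta_kev: float
    kerma_per_photon: float  # MeV/g per source photon
    rel_unc: float
    n_histories: int
    n_batches: int
    seed: int
    n_scoring_photons: int = 0
    geometry_json: str = ""

    def __post_init__(self):
        if self.kerma_per_photon <= 0:
            raise ValueError(
                "degenerate air-kerma result: no photons reached the scoring volume"
            )


class CrossSectionSet:
    """Fine-grid linear attenuation data shared by the transport kernels."""

    def __init__(self, materials=None, n_grid=512, e_lo=0.009, e_hi=1.2):
        if materials is None:
            materials = {name: load_material(name)
                         for name in ("iridium", "steel", "water", "air")}
        self.materials = materials
        e = np.geomspace(e_lo, e_hi, n_grid)
        self.loge0 = float(np.log(e[0]))
        self.dloge = float(np.log(e[1]) - np.log(e[0]))
        self.mu_lin = np.zeros((3, n_grid))
        self.p_comp = np.zeros((3, n_grid))
        for idx, name in ((0, "iridium"), (1, "steel"), (2, "water")):
            m = materials[name]
            mu_rho = self._mass_atten(m, e)
            rho = m.density
            mu_kn = (ELECTRONS_PER_GRAM[name]
                     * klein_nishina_cross_section(e))
            self.mu_lin[idx] = mu_rho * rho
            self.p_comp[idx] = np.clip(mu_kn / mu_rho, 0.0, 1.0)
        self.muen_w = self._mass_en(materials["water"], e)
        self.muen_air = self._mass_en(materials["air"], e)

    @staticmethod
    def _clamped(energy, table):
        return np.clip(energy, table.energies[0], table.energies[-1])

    def _mass_atten(self, table, e):
        return coefficient(table, self._clamped(e, table), "attenuation")

    def _mass_en(self, table, e):
        return coefficient(table, self._clamped(e, table), "energy_absorption")

    def checksum(self) -> str:
        h = hashlib.sha256()
        for m in self.materials.values():
            h.update(m.energies.tobytes())
            h.update(m.mu_rho.tobytes())
        return h.hexdigest()[:16]


_XS_CACHE = {}


def _get_xs(materials):
    if materials is not None:
        return CrossSectionSet(materials)
    if "default" not in _XS_CACHE:
        _XS_CACHE["default"] = CrossSectionSet()
    return _XS_CACHE["default"]


def _geometry_tuple(geometry: SourceGeometry):
    return np.array([
        geometry.core_radius,
        geometry.core_length / 2.0,
        geometry.capsule_inner_radius,
        geometry.cavity_z[1],
        geometry.capsule_outer_radius,
        geometry.capsule_z[1],
        geometry.capsule_z[0],
        geometry.cable_z[0],
    ])


def _spectrum_arrays(spectrum: PhotonSpectrum):
    cum = np.cumsum(spectrum.intensities)
    cum /= cum[-1]
    return cum, np.asarray(spectrum.energies, float)


def _batch_seeds(seed, n_batches):
    return [(int(seed) * 9973 + 7919 * b + 1) % (2**31 - 1) for b in range(n_batches)]


def simulate_water(geometry: SourceGeometry = None,
                   spectrum: PhotonSpectrum = None,
                   grid: TallyGridSpec = None,
                   n_histories: int = 10**6,
                   seed: int = 0,
                   n_batches: int = 50,
                   phantom_radius_cm: float = 50.0,
                   materials: dict = None,
                   cutoff_mev: float = 0.010,
                   disable_scatter: bool = False,
                   point_isotropic: bool = False) -> DoseGrid:
    """Simulate the source at the centre of a water sphere and tally kerma.

    Photons are generated uniformly in the iridium core with isotropic
    directions, surface-tracked through core/capsule/cable/water with
    exponential free paths, and scored with a track-length collision-kerma
    estimator on the polar ring cells.  Identical ``seed`` and
    ``n_histories`` give identical output.
    """
    if geometry is None:
        geometry = build_m15()
    if spectrum is None:
        from .physics_data import load_spectrum

        spectrum = load_spectrum()
    if grid is None:
        grid = default_grid_spec()
    if n_histories < 10**4:
        raise ValueError("n_histories must be at least 1e4")
    if grid.radii[-1] + grid.radial_half_widths[-1] >= phantom_radius_cm:
        raise ValueError("tally grid must lie inside the phantom")
    xs = _get_xs(materials)
    gt = _geometry_tuple(geometry)
    cum, e_lines = _spectrum_arrays(spectrum)
    shell_lo, shell_hi = grid.shell_bounds
    band_lo, band_hi = grid.band_bounds
    n_batch = int(n_histories) // int(n_batches)
    if n_batch == 0:
        raise ValueError("fewer histories than batches")
    n_eff = n_batch * int(n_batches)
    volumes = grid.cell_volumes
    shape = (len(grid.angles_deg), len(grid.radii))
    batch_means = np.zeros((n_batches,) + shape)
    sector_sum = np.zeros((2,) + shape)
    for bidx, bseed in enumerate(_batch_seeds(seed, n_batches)):
        tally = np.zeros((2,) + shape)
        _kernels.run_water_batch(
            bseed, n_batch, gt, float(phantom_radius_cm), xs.loge0, xs.dloge,
            xs.mu_lin, xs.p_comp, xs.muen_w, cum, e_lines,
            shell_lo, shell_hi, band_lo, band_hi,
            float(cutoff_mev), 1 if disable_scatter else 0,
            1 if point_isotropic else 0, tally)
        sector_sum += tally
        batch_means[bidx] = tally.sum(axis=0) / (volumes * n_batch)
    mean = batch_means.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batches)
        rel = np.where(mean > 0, sem / np.where(mean > 0, mean, 1.0), 1.0)
    return DoseGrid(
        radii=grid.radii, angles_deg=grid.angles_deg, tally=mean,
        rel_unc=rel, n_histories=n_eff, n_batches=int(n_batches),
        seed=int(seed), sector_tally=sector_sum,
        geometry_json=geometry.to_json())


def simulate_air_kerma(geometry: SourceGeometry = None,
                       spectrum: PhotonSpectrum = None,
                       distance_cm: float = 100.0,
                       delta_kev: float = 10.0,
                       n_histories: int = 10**6,
                       seed: int = 0,
                       n_batches: int = 50,
                       scoring_radius_cm: float = 1.0,
                       materials: dict = None,
                       cutoff_mev: float = 0.010,
                       point_isotropic: bool = False) -> AirKermaResult:
    """Air-kerma tally: vacuum ambient, 1 cm air scoring sphere at ``distance_cm``.

    Photons interact only inside the source; on escape each photon's
    azimuth-averaged expected track length through the scoring sphere is
    scored (exploiting the rotational symmetry of the source — the same
    rationale as a ring detector), weighted by E * muen/rho(air).  Photons
    with energy at or below ``delta_kev`` are excluded.
    """
    if geometry is None:
        geometry = build_m15()
    if spectrum is None:
        from .physics_data import load_spectrum

        spectrum = load_spectrum()
    if distance_cm <= geometry.capsule_length / 2.0:
        raise ValueError("scoring distance must exceed the source half-length")
    if delta_kev < 0:
        raise ValueError("delta must be non-negative")
    xs = _get_xs(materials)
    gt = _geometry_tuple(geometry)
    cum, e_lines = _spectrum_arrays(spectrum)
    n_batch = int(n_histories) // int(n_batches)
    if n_batch == 0:
        raise ValueError("fewer histories than batches")
    volume = 4.0 / 3.0 * np.pi * scoring_radius_cm**3
    sums = np.zeros(n_batches)
    hits = 0
    for bidx, bseed in enumerate(_batch_seeds(seed, n_batches)):
        acc, nh = _kernels.run_air_batch(
            bseed, n_batch, gt, float(distance_cm), float(scoring_radius_cm),
            delta_kev / 1000.0, xs.loge0, xs.dloge, xs.mu_lin, xs.p_comp,
            xs.muen_air, cum, e_lines, float(cutoff_mev),
            1 if point_isotropic else 0)
        sums[bidx] = acc / (volume * n_batch)
        hits += nh
    mean = sums.mean()
    if mean <= 0 or hits == 0:
        raise ValueError("degenerate air-kerma run: no scoring-volume crossings")
    rel = sums.std(ddof=1) / np.sqrt(n_batches) / mean
    return AirKermaResult(
        distance_cm=float(distance_cm), delta_kev=float(delta_kev),
        kerma_per_photon=float(mean), rel_unc=float(rel),
        n_histories=n_batch * n_batches, n_batches=int(n_batches),
        seed=int(seed), n_scoring_photons=int(hits),
        geometry_json=geometry.to_json())
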
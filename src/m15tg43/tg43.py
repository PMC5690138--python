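"""TG-43U1 parameter extraction from Monte Carlo tallies.

Converts per-photon kerma tallies into the clinical parameter set of the
AAPM/ESTRO formalism,

    D(r, theta) = S_K * Lambda * [G_L(r,theta)/G_L(r0,theta0)] * g_L(r) * F(r,theta),

with the line-source geometry function G_L, radial dose function g_L,
anisotropy function F, anisotropy factor phi_an(r) and anisotropy constant,
air-kerma strength S_K and dose-rate constant Lambda.  The reference point is
(r0, theta0) = (1 cm, 90 deg); theta = 0 is the distal (capsule-tip) end.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mc_transport import AirKermaResult, DoseGrid, R0_CM, THETA0_DEG

__all__ = [
    "K_CGY_MCI_H",
    "dose_rate",
    "geometry_function",
    "normalized_dose_table",
    "radial_dose_function",
    "anisotropy_function",
    "anisotropy_factor",
    "anisotropy_constant",
    "anisotropy_weights",
    "trapezoid_weights",
    "air_kerma_strength",
    "dose_rate_constant",
    "TG43Dataset",
    "extract_dataset",
    "synthesize_grid",
]

#: exact unit conversion: 1 MeV g^-1 Bq^-1 s^-1 in cGy mCi^-1 h^-1
#: (3.7e7 Bq/mCi * 3600 s/h * 1.602176634e-8 cGy per MeV/g); prints as 2.13e3
K_CGY_MCI_H = 3.7e7 * 3600.0 * 1.602176634e-8


def dose_rate(tally, i_gamma: float):
    """Convert a per-photon tally (MeV/g) to cGy mCi^-1 h^-1 via the photon yield."""
    tally = np.asarray(tally, dtype=float)
    if np.any(tally < 0) or i_gamma <= 0:
        raise ValueError("tally must be non-negative and the photon yield positive")
    out = tally * i_gamma * K_CGY_MCI_H
    return float(out) if out.ndim == 0 else out


def geometry_function(r, theta_deg, length: float):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    ``beta/(L r sin theta)`` off-axis, ``1/(r^2 - L^2/4)`` on the poles
    (the on-axis branch applies at both 0 and 180 degrees).  ``r`` must
    exceed L/2; the function is continuous through the poles.
    """
    r = np.asarray(r, dtype=float)
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    r, theta = np.broadcast_arrays(r, theta)
    if np.any(r <= length / 2.0):
        raise ValueError("geometry function requires r > L/2")
    x = r * np.sin(theta)
    z = r * np.cos(theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.arctan2(x, z - length / 2.0) - np.arctan2(x, z + length / 2.0)
        off_axis = beta / (length * x)
    on_axis = 1.0 / (r**2 - length**2 / 4.0)
    polar = np.isclose(np.sin(theta), 0.0, atol=1e-12)
    out = np.where(polar, on_axis, off_axis)
    return float(out) if out.ndim == 0 else out


def _reference_value(grid: DoseGrid):
    it, ir = grid.reference_indices
    ref = grid.tally[it, ir]
    if ref <= 0:
        raise ValueError("reference cell (1 cm, 90 deg) scored no dose")
    return it, ir, ref


def normalized_dose_table(grid: DoseGrid) -> np.ndarray:
    """D_N(r, theta) = D(r, theta) r^2 / D(r0, theta0); exactly 1 at the reference."""
    _, _, ref = _reference_value(grid)
    return grid.tally * grid.radii[np.newaxis, :] ** 2 / ref


def radial_dose_function(grid: DoseGrid, length: float) -> np.ndarray:
    """g_L(r) from the transverse-axis row; g_L(r0) = 1 exactly."""
    it, ir, ref = _reference_value(grid)
    row = grid.tally[it, :]
    g_ref = geometry_function(R0_CM, THETA0_DEG, length)
    g_r = geometry_function(grid.radii, THETA0_DEG, length)
    return row / ref * g_ref / g_r


def anisotropy_function(grid: DoseGrid, length: float) -> np.ndarray:
    """F(r, theta); F(r, theta0) = 1 exactly for every tabulated radius."""
    it, _, _ = _reference_value(grid)
    row0 = grid.tally[it, :]
    if np.any(row0 <= 0):
        raise ValueError("transverse-axis row contains empty cells")
    g_t0 = geometry_function(grid.radii, THETA0_DEG, length)
    g_rt = geometry_function(grid.radii[np.newaxis, :],
                             grid.angles_deg[:, np.newaxis], length)
    return grid.tally / row0[np.newaxis, :] * g_t0[np.newaxis, :] / g_rt


def trapezoid_weights(angles_deg) -> np.ndarray:
    """Composite-trapezoid quadrature weights (radians) on a non-uniform grid."""
    t = np.radians(np.asarray(angles_deg, dtype=float))
    if t.size < 2:
        raise ValueError("need at least two angles")
    w = np.zeros_like(t)
    d = np.diff(t)
    w[0] = d[0] / 2.0
    w[-1] = d[-1] / 2.0
    w[1:-1] = (d[:-1] + d[1:]) / 2.0
    return w


def anisotropy_factor(angles_deg, dose_row, theta0_deg: float = THETA0_DEG) -> float:
    """phi_an(r) = int_0^pi D(r,theta) sin(theta) dtheta / (2 D(r, theta0)).

    Composite trapezoid on the (generally non-uniform) tabulated angles; the
    row must span both poles.  Any quantity proportional to D at fixed r
    (e.g. the normalized dose) may be passed.
    """
    angles = np.asarray(angles_deg, dtype=float)
    row = np.asarray(dose_row, dtype=float)
    if angles[0] > 0.0 or angles[-1] < 180.0:
        raise ValueError("angular row must cover 0 to 180 degrees")
    i0 = np.flatnonzero(np.isclose(angles, theta0_deg))
    if i0.size == 0:
        raise ValueError("transverse angle missing from the row")
    w = trapezoid_weights(angles)
    integral = np.sum(w * row * np.sin(np.radians(angles)))
    return float(integral / (2.0 * row[int(i0[0])]))


def anisotropy_weights(radii) -> np.ndarray:
    """Inverse-square weights w(r) = (1/r^2) / sum(1/r^2) for the constant."""
    r = np.asarray(radii, dtype=float)
    w = 1.0 / r**2
    return w / w.sum()


def anisotropy_constant(radii, phi_values) -> float:
    """phi_bar: inverse-square-weighted mean of phi_an at r = 1..10 cm."""
    r = np.asarray(radii, dtype=float)
    if r.shape != (10,) or not np.allclose(r, np.arange(1, 11)):
        raise ValueError("anisotropy constant requires phi_an at r = 1..10 cm")
    return float(np.sum(anisotropy_weights(r) * np.asarray(phi_values, float)))


def air_kerma_strength(result: AirKermaResult, i_gamma: float) -> float:
    """S_K = (air-kerma rate at d) * d^2, in U mCi^-1 (U = cGy cm^2 h^-1)."""
    return dose_rate(result.kerma_per_photon, i_gamma) * result.distance_cm**2


def dose_rate_constant(ref_dose_rate: float, sk: float) -> float:
    """Lambda = D(r0, theta0) / S_K, in cGy h^-1 U^-1."""
    if sk <= 0:
        raise ValueError("air-kerma strength must be positive")
    if ref_dose_rate < 0:
        raise ValueError("reference dose rate must be non-negative")
    return ref_dose_rate / sk


@dataclass
class TG43Dataset:
    """Complete TG-43 parameter set with absolute uncertainties."""

    length: float
    radii: np.ndarray
    angles_deg: np.ndarray
    ref_dose_rate: float  # cGy mCi^-1 h^-1
    sk: float  # U mCi^-1
    lam: float  # cGy h^-1 U^-1
    normalized_dose: np.ndarray
    g: np.ndarray
    anisotropy: np.ndarray
    phi_an: np.ndarray
    phi_bar: float
    sigma_ref_dose_rate: float = 0.0
    sigma_sk: float = 0.0
    sigma_lam: float = 0.0
    sigma_normalized_dose: np.ndarray = None
    sigma_g: np.ndarray = None
    sigma_anisotropy: np.ndarray = None
    sigma_phi_an: np.ndarray = None
    sigma_phi_bar: float = 0.0
    fits: dict = field(default_factory=dict)
    budget: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        it = int(np.flatnonzero(np.isclose(self.angles_deg, THETA0_DEG))[0])
        ir = int(np.flatnonzero(np.isclose(self.radii, R0_CM))[0])
        if not np.isclose(self.g[ir], 1.0):
            raise ValueError("g_L(r0) must be exactly 1")
        if not np.allclose(self.anisotropy[it, :], 1.0):
            raise ValueError("F(r, theta0) must be exactly 1")

    def to_json(self, path=None) -> str:
        def enc(a):
            return None if a is None else np.asarray(a).tolist()

        doc = {
            "L_cm": self.length,
            "r_cm": enc(self.radii),
            "theta_deg": enc(self.angles_deg),
            "reference_dose_rate_cGy_mCi_h": self.ref_dose_rate,
            "air_kerma_strength_U_mCi": self.sk,
            "dose_rate_constant_cGy_h_U": self.lam,
            "normalized_dose": enc(self.normalized_dose),
            "radial_dose_function": enc(self.g),
            "anisotropy_function": enc(self.anisotropy),
            "anisotropy_factor": enc(self.phi_an),
            "anisotropy_constant": self.phi_bar,
            "uncertainties": {
                "reference_dose_rate": self.sigma_ref_dose_rate,
                "air_kerma_strength": self.sigma_sk,
                "dose_rate_constant": self.sigma_lam,
                "normalized_dose": enc(self.sigma_normalized_dose),
                "radial_dose_function": enc(self.sigma_g),
                "anisotropy_function": enc(self.sigma_anisotropy),
                "anisotropy_factor": enc(self.sigma_phi_an),
                "anisotropy_constant": self.sigma_phi_bar,
            },
            "fits": self.fits,
            "budget": self.budget,
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def extract_dataset(water_grid: DoseGrid, air_result: AirKermaResult,
                    i_gamma: float, length: float = 0.35,
                    budget=None, do_fits: bool = True) -> TG43Dataset:
    """Run the full tally -> TG-43 extraction with uncertainty propagation."""
    from . import fitting, uncertainty

    if budget is None:
        budget = uncertainty.UncertaintyBudget(
            sigma_igamma_rel=0.005, sigma_air_kerma_rel=air_result.rel_unc)
    it, ir, ref_tally = _reference_value(water_grid)
    ref_rate = dose_rate(ref_tally, i_gamma)
    sk = air_kerma_strength(air_result, i_gamma)
    lam = dose_rate_constant(ref_rate, sk)

    dn = normalized_dose_table(water_grid)
    g = radial_dose_function(water_grid, length)
    fmat = anisotropy_function(water_grid, length)
    phi = np.array([
        anisotropy_factor(water_grid.angles_deg, water_grid.tally[:, j])
        for j in range(len(water_grid.radii))
    ])
    const_radii = np.arange(1.0, 11.0)
    mask = np.isin(water_grid.radii, const_radii)
    if mask.sum() == 10:
        phi_bar = anisotropy_constant(water_grid.radii[mask], phi[mask])
    else:  # grid does not span r = 1..10 cm; constant undefined
        phi_bar = float("nan")

    mc = water_grid.rel_unc
    mc_ref = mc[it, ir]
    xs = budget.sigma_cross_section_rel
    sig_ref = uncertainty.sigma_dose_rate(ref_rate, budget, mc_ref)
    sig_dn = uncertainty.sigma_ratio_quantity(dn, mc, mc_ref, xs)
    sig_g = uncertainty.sigma_ratio_quantity(g, mc[it, :], mc_ref, xs)
    sig_f = uncertainty.sigma_ratio_quantity(fmat, mc, mc[it, :][np.newaxis, :], xs)
    sig_phi = np.array([
        uncertainty.sigma_anisotropy_factor(
            phi[j], water_grid.tally[:, j], mc[:, j], water_grid.angles_deg)
        for j in range(len(water_grid.radii))
    ])
    if mask.sum() == 10:
        sig_phi_bar = uncertainty.sigma_anisotropy_constant(
            sig_phi[mask], anisotropy_weights(const_radii))
    else:
        sig_phi_bar = 0.0
    sig_sk = uncertainty.sigma_air_kerma_strength(sk, budget, air_result.rel_unc)
    sig_lam = uncertainty.sigma_dose_rate_constant(lam, mc_ref, air_result.rel_unc)

    fits = {}
    if do_fits:
        for form in ("poly5", "double_exponential"):
            fit = fitting.fit_radial(water_grid.radii, g, form)
            fits[form] = fitting.fit_summary(fit)

    return TG43Dataset(
        length=length, radii=water_grid.radii, angles_deg=water_grid.angles_deg,
        ref_dose_rate=ref_rate, sk=sk, lam=lam, normalized_dose=dn, g=g,
        anisotropy=fmat, phi_an=phi, phi_bar=phi_bar,
        sigma_ref_dose_rate=sig_ref, sigma_sk=sig_sk, sigma_lam=sig_lam,
        sigma_normalized_dose=sig_dn, sigma_g=sig_g, sigma_anisotropy=sig_f,
        sigma_phi_an=sig_phi, sigma_phi_bar=sig_phi_bar, fits=fits,
        budget=budget.as_dict(),
        provenance={
            "water": water_grid.sidecar(),
            "air": {"seed": air_result.seed, "n_histories": air_result.n_histories,
                    "distance_cm": air_result.distance_cm,
                    "delta_kev": air_result.delta_kev},
        })


def synthesize_grid(radii, angles_deg, lam, g_of_r, f_table, length: float,
                    noise_rel=0.0, seed: int = 0) -> DoseGrid:
    """Build a DoseGrid analytically from TG-43 parameters (S_K = 1 photon scale).

    Inverts the formalism for round-trip testing: D(r,theta) =
    lam * G(r,theta)/G(r0,theta0) * g(r) * F(r,theta), stored as a tally so
    the extraction stage can be applied to it.  ``g_of_r`` is an array on
    ``radii``; ``f_table`` has shape (n_theta, n_r).
    """
    radii = np.asarray(radii, float)
    angles = np.asarray(angles_deg, float)
    gmat = geometry_function(radii[np.newaxis, :], angles[:, np.newaxis], length)
    g0 = geometry_function(R0_CM, THETA0_DEG, length)
    d = lam * gmat / g0 * np.asarray(g_of_r)[np.newaxis, :] * np.asarray(f_table)
    rel = np.full_like(d, float(noise_rel))
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        d = d * (1.0 + noise_rel * rng.standard_normal(d.shape))
    return DoseGrid(radii=radii, angles_deg=angles, tally=d, rel_unc=rel,
                    n_histories=0, n_batches=1, seed=seed)
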
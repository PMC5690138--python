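"""Packaged physical data: the Ir-192 photon spectrum and material coefficient tables.

The spectrum fixture carries the principal gamma and K X-ray lines of Ir-192
decay (beta- branch to Pt-192 and electron capture to Os-192).  Its two
aggregate properties are pinned by construction: the total photon yield,
``I_gamma = 2.301`` photons per decay, and the intensity-weighted mean relative
uncertainty of the line intensities, 0.5%.

Material tables hold mass attenuation (``mu/rho``) and mass energy-absorption
(``muen/rho``) coefficients on a log-spaced energy grid covering 0.01-1.5 MeV
for the four media of the source problem: liquid water, dry air (STP),
iridium metal and stainless steel.  The attenuation values model photoelectric
absorption plus free-electron (Klein-Nishina) incoherent scattering; coherent
scattering is excluded, consistent with the transport model.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "PhotonSpectrum",
    "MaterialTable",
    "load_spectrum",
    "load_material",
    "coefficient",
    "MATERIAL_DENSITY_G_CM3",
    "ELECTRONS_PER_GRAM",
    "klein_nishina_cross_section",
]

MEC2_MEV = 0.51099895
_R_E2_CM2 = 7.94079e-26  # classical electron radius squared
_N_A = 6.02214076e23

#: bulk densities used throughout (g/cm^3); air at STP
MATERIAL_DENSITY_G_CM3 = {
    "water": 0.998,
    "air": 1.2929e-3,
    "iridium": 22.4,
    "steel": 7.8,
}

#: electrons per gram, N_A * sum(w_i Z_i / A_i), for Klein-Nishina rates
ELECTRONS_PER_GRAM = {
    "water": _N_A * (0.111894 * 1 / 1.008 + 0.888106 * 8 / 15.999),
    "air": _N_A * (0.7551 * 7 / 14.007 + 0.2318 * 8 / 15.999
                   + 0.0128 * 18 / 39.948 + 0.0003 * 6 / 12.011),
    "steel": _N_A * (0.70 * 26 / 55.845 + 0.19 * 24 / 51.996 + 0.11 * 28 / 58.693),
    "iridium": _N_A * 77 / 192.217,
}


def klein_nishina_cross_section(energy_mev):
    """Total Klein-Nishina cross section per electron (cm^2)."""
    a = np.asarray(energy_mev, dtype=float) / MEC2_MEV
    t = 1.0 + 2.0 * a
    s = ((1 + a) / a**2 * (2 * (1 + a) / t - np.log(t) / a)
         + np.log(t) / (2 * a) - (1 + 3 * a) / t**2)
    return 2.0 * np.pi * _R_E2_CM2 * s


def _data_file(*parts):
    return resources.files("m15tg43.data").joinpath("/".join(parts))


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon emission spectrum.

    Attributes
    ----------
    energies : ndarray
        Line energies in MeV, strictly increasing.
    intensities : ndarray
        Photons per decay for each line.
    rel_uncertainties : ndarray
        Relative (1-sigma) uncertainty of each line intensity.
    """

    energies: np.ndarray
    intensities: np.ndarray
    rel_uncertainties: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.size == 0:
            raise ValueError("photon spectrum has no emission lines")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("line energies must be positive and strictly increasing")
        if np.any(np.asarray(self.intensities) <= 0):
            raise ValueError("line intensities must be positive")

    @property
    def total_yield(self) -> float:
        """I_gamma: photons emitted per decay."""
        return float(np.sum(self.intensities))

    @property
    def sigma_igamma_rel(self) -> float:
        """Intensity-weighted mean relative uncertainty of the spectrum."""
        i = np.asarray(self.intensities)
        return float(np.sum(i * self.rel_uncertainties) / np.sum(i))

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.intensities) / self.total_yield)

    def filtered(self, cutoff_energy_mev: float) -> "PhotonSpectrum":
        """Return the spectrum with lines at or below ``cutoff_energy_mev`` removed."""
        keep = self.energies > cutoff_energy_mev
        if not np.any(keep):
            raise ValueError(
                f"no emission lines above the {cutoff_energy_mev} MeV cutoff"
            )
        return PhotonSpectrum(
            self.energies[keep], self.intensities[keep], self.rel_uncertainties[keep]
        )


def load_spectrum(cutoff_energy_mev: float = 0.0) -> PhotonSpectrum:
    """Load the packaged Ir-192 spectrum, dropping lines at or below the cutoff.

    With ``cutoff_energy_mev = 0`` the full per-decay yield (2.301 photons)
    is returned; with a positive cutoff the yield is recomputed over the
    retained lines.
    """
    if cutoff_energy_mev < 0:
        raise ValueError("cutoff energy must be non-negative")
    path = _data_file("spectrum.csv")
    if not path.is_file():
        raise FileNotFoundError("packaged spectrum fixture spectrum.csv is missing")
    raw = np.genfromtxt(path.open("rb"), delimiter=",", skip_header=1)
    spec = PhotonSpectrum(raw[:, 0].copy(), raw[:, 1].copy(), raw[:, 2].copy())
    if cutoff_energy_mev > 0:
        spec = spec.filtered(cutoff_energy_mev)
    return spec


@dataclass(frozen=True)
class MaterialTable:
    """Photon interaction coefficients for one material on an energy grid."""

    name: str
    energies: np.ndarray  # MeV, strictly increasing
    mu_rho: np.ndarray  # cm^2/g
    muen_rho: np.ndarray  # cm^2/g
    density: float  # g/cm^3

    def __post_init__(self):
        e = np.asarray(self.energies)
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] > 0.01 or e[-1] < 1.5:
            raise ValueError("energy grid must cover at least [0.01, 1.5] MeV")
        if np.any(self.mu_rho <= 0) or np.any(self.muen_rho <= 0):
            raise ValueError("coefficients must be positive")
        if np.any(self.mu_rho < self.muen_rho):
            raise ValueError("mu/rho must dominate muen/rho at every grid energy")
        if self.density <= 0:
            raise ValueError("density must be positive")


def load_material(name: str) -> MaterialTable:
    """Load a packaged material coefficient table (water, air, iridium, steel)."""
    if name not in MATERIAL_DENSITY_G_CM3:
        raise KeyError(f"unknown material {name!r}")
    path = _data_file("materials", f"{name}.csv")
    if not path.is_file():
        raise FileNotFoundError(f"packaged material fixture {name}.csv is missing")
    raw = np.genfromtxt(path.open("rb"), delimiter=",", skip_header=1)
    return MaterialTable(
        name=name,
        energies=raw[:, 0].copy(),
        mu_rho=raw[:, 1].copy(),
        muen_rho=raw[:, 2].copy(),
        density=MATERIAL_DENSITY_G_CM3[name],
    )


def coefficient(material: MaterialTable, energy_mev, kind: str = "attenuation"):
    """Interpolate a coefficient (cm^2/g) at ``energy_mev``.

    Log-log linear interpolation between bracketing grid points; exact at the
    grid nodes.  Queries outside the tabulated range raise rather than
    extrapolate.
    """
    if kind == "attenuation":
        table = material.mu_rho
    elif kind == "energy_absorption":
        table = material.muen_rho
    else:
        raise ValueError("kind must be 'attenuation' or 'energy_absorption'")
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e < material.energies[0]) or np.any(e > material.energies[-1]):
        raise ValueError(
            f"energy outside the tabulated range "
            f"[{material.energies[0]}, {material.energies[-1]}] MeV for {material.name}"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(material.energies), np.log(table))
    )
    return float(out) if np.isscalar(energy_mev) else out
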
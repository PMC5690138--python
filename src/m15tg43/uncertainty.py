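"""Quadrature uncertainty propagation for the TG-43 parameter set.

Every reported quantity carries an absolute uncertainty assembled in
quadrature from three relative components: the per-cell Monte Carlo batch
standard error, the cross-section-table uncertainty, and the photon-yield
uncertainty.  Ratio quantities (normalized dose, g_L, F) combine the two MC
terms of numerator and reference cell plus twice the cross-section variance;
the solid-angle-integrated anisotropy factor propagates the per-angle
quadrature weights.

The cross-section component defaults to 1.5% (configurable); the photon
yield component is the spectrum's intensity-weighted 0.5%.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .tg43 import THETA0_DEG, trapezoid_weights

__all__ = [
    "UncertaintyBudget",
    "sigma_dose_rate",
    "sigma_ratio_quantity",
    "sigma_anisotropy_factor",
    "sigma_anisotropy_constant",
    "sigma_air_kerma_strength",
    "sigma_dose_rate_constant",
]


@dataclass(frozen=True)
class UncertaintyBudget:
    """Relative uncertainty components entering every quadrature formula."""

    sigma_cross_section_rel: float = 0.015
    sigma_igamma_rel: float = 0.005
    sigma_air_kerma_rel: float = 0.0

    def __post_init__(self):
        for v in (self.sigma_cross_section_rel, self.sigma_igamma_rel,
                  self.sigma_air_kerma_rel):
            if v < 0:
                raise ValueError("uncertainty components must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


def sigma_dose_rate(value, budget: UncertaintyBudget, sigma_mc_rel):
    """Absolute uncertainty of a dose rate: D * sqrt(mc^2 + xs^2 + yield^2)."""
    value = np.asarray(value, float)
    if np.any(value < 0):
        raise ValueError("dose rate must be non-negative")
    out = value * np.sqrt(np.asarray(sigma_mc_rel) ** 2
                          + budget.sigma_cross_section_rel**2
                          + budget.sigma_igamma_rel**2)
    return float(out) if out.ndim == 0 else out


def sigma_ratio_quantity(value, sigma_mc_num, sigma_mc_ref, sigma_xs_rel):
    """Absolute uncertainty of the ratio quantities D_N, g_L and F:
    value * sqrt(mc_num^2 + mc_ref^2 + 2 xs^2)."""
    value = np.asarray(value, float)
    if np.any(value < 0):
        raise ValueError("ratio quantities must be non-negative")
    out = value * np.sqrt(np.asarray(sigma_mc_num) ** 2
                          + np.asarray(sigma_mc_ref) ** 2
                          + 2.0 * sigma_xs_rel**2)
    return float(out) if out.ndim == 0 else out


def sigma_anisotropy_factor(phi, dose_row, sigma_mc_row, angles_deg,
                            theta0_deg: float = THETA0_DEG) -> float:
    """Absolute uncertainty of phi_an(r) from the per-angle MC uncertainties.

    Two-term form: the transverse reference cell contributes
    (phi - w0 sin(theta0)/2) and every other angle contributes its quadrature
    weight times its dose ratio; with a uniform angular grid the weights
    reduce to the plain step delta-theta.
    """
    angles = np.asarray(angles_deg, float)
    row = np.asarray(dose_row, float)
    sig = np.asarray(sigma_mc_row, float)
    if row.shape != sig.shape or row.shape != angles.shape:
        raise ValueError("angular rows are misaligned")
    i0 = int(np.flatnonzero(np.isclose(angles, theta0_deg))[0])
    w = trapezoid_weights(angles)
    sin = np.sin(np.radians(angles))
    ratio = row / row[i0]
    var = (phi - w[i0] * sin[i0] / 2.0) ** 2 * sig[i0] ** 2
    terms = (ratio * sin * w / 2.0) ** 2 * sig**2
    var += terms.sum() - terms[i0]
    return float(np.sqrt(var))


def sigma_anisotropy_constant(sigma_phi, weights) -> float:
    """sqrt(sum (w dr)^2 sigma^2) with dr = 1 cm absorbed into the weights."""
    s = np.asarray(sigma_phi, float)
    w = np.asarray(weights, float)
    if s.shape != w.shape:
        raise ValueError("weights and uncertainties are misaligned")
    return float(np.sqrt(np.sum((w * s) ** 2)))


def sigma_air_kerma_strength(sk, budget: UncertaintyBudget, sigma_mc_rel) -> float:
    """S_K * sqrt(mc^2 + xs^2 + yield^2)."""
    if sk < 0:
        raise ValueError("air-kerma strength must be non-negative")
    return float(sk * np.sqrt(sigma_mc_rel**2
                              + budget.sigma_cross_section_rel**2
                              + budget.sigma_igamma_rel**2))


def sigma_dose_rate_constant(lam, sigma_mc_ref_rel, sigma_mc_air_rel) -> float:
    """Lambda * sqrt(mc_water(r0,theta0)^2 + mc_airkerma^2) — the two tally terms."""
    if lam < 0:
        raise ValueError("dose-rate constant must be non-negative")
    return float(lam * np.sqrt(sigma_mc_ref_rel**2 + sigma_mc_air_rel**2))
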
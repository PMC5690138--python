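"""Geometric model of the M-15 HDR source.

The source is a stack of coaxial cylinders: an iridium-metal core (0.6 mm
diameter, 3.5 mm long) inside a stainless-steel capsule (1.1 mm outer / 0.7 mm
inner diameter, 4.8 mm long), with a steel drive cable (1.1 mm diameter)
welded to the proximal end.  The construction is symmetric about the long
axis but not about the transverse plane: the cable sits on exactly one side.

Coordinate convention: the long axis is ``z``, the core midpoint is the
origin, and the polar angle ``theta`` is measured from ``+z`` at the distal
(capsule tip) end, so the cable lies at ``theta = 180 deg``.  All lengths are
in centimetres.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

__all__ = ["SourceGeometry", "build_m15", "material_at"]


@dataclass(frozen=True)
class SourceGeometry:
    """Nested-cylinder model of the M-15 source (dimensions in cm)."""

    core_radius: float = 0.03
    core_length: float = 0.35
    core_material: str = "iridium"
    core_density: float = 22.4

    capsule_outer_radius: float = 0.055
    capsule_inner_radius: float = 0.035
    capsule_length: float = 0.48
    capsule_material: str = "steel"
    capsule_density: float = 7.8

    cable_radius: float = 0.055
    cable_modeled_length: float = 6.0  # physical cable is 200 cm; dose effect beyond a few cm is negligible
    cable_material: str = "steel"

    #: axial clearance between core and cavity at each end
    end_gap: float = field(init=False, default=0.02)

    def __post_init__(self):
        if not (self.core_radius < self.capsule_inner_radius
                and self.core_length < self.capsule_length):
            raise ValueError("core must fit strictly inside the capsule cavity")
        for d in (self.core_density, self.capsule_density):
            if d <= 0:
                raise ValueError("densities must be positive")

    # -- derived axial planes (core centred in the cavity, flat ends) --------
    @property
    def active_length(self) -> float:
        """L, the active length entering the line-source geometry function."""
        return self.core_length

    @property
    def core_z(self) -> tuple[float, float]:
        h = self.core_length / 2.0
        return (-h, h)

    @property
    def cavity_z(self) -> tuple[float, float]:
        h = self.core_length / 2.0 + self.end_gap
        return (-h, h)

    @property
    def capsule_z(self) -> tuple[float, float]:
        """Outer axial extent; the tip-side wall is one end-gap thick, the
        remaining capsule length sits proximally (weld toward the cable)."""
        z_top = self.cavity_z[1] + self.end_gap
        return (z_top - self.capsule_length, z_top)

    @property
    def cable_z(self) -> tuple[float, float]:
        z0 = self.capsule_z[0]
        return (z0 - self.cable_modeled_length, z0)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["capsule_z"] = self.capsule_z
        d["cable_z"] = self.cable_z
        return d

    def to_json(self) -> str:
        """Geometry echo for provenance sidecars."""
        return json.dumps(self.as_dict(), sort_keys=True)


def build_m15(cable_modeled_length: float = 6.0) -> SourceGeometry:
    """Construct the M-15 geometry (manufacturer dimensions, mm -> cm)."""
    return SourceGeometry(cable_modeled_length=cable_modeled_length)


def material_at(geometry: SourceGeometry, point) -> str:
    """Material name at a 3-vector ``point`` (cm): iridium, steel or medium.

    The residual cavity around the core is reported as the surrounding
    medium; everything outside the capsule/cable stack likewise.
    """
    x, y, z = (float(c) for c in point)
    if not all(math.isfinite(c) for c in (x, y, z)):
        raise ValueError("point coordinates must be finite")
    rho2 = x * x + y * y
    zc_lo, zc_hi = geometry.capsule_z
    zb_lo = geometry.cable_z[0]
    if rho2 > geometry.capsule_outer_radius**2 or z > zc_hi or z < zb_lo:
        return "medium"
    cav_lo, cav_hi = geometry.cavity_z
    if z < cav_lo or z > cav_hi:
        return "steel"  # tip wall, proximal weld fill, or cable
    if rho2 < geometry.core_radius**2 and abs(z) < geometry.core_length / 2.0:
        return "iridium"
    if rho2 < geometry.capsule_inner_radius**2:
        return "medium"  # residual cavity
    return "steel"
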
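"""Spherical-cap dome geometry, dome energetics, and unit conversions.

All closed-form quantities of the membrane--Piezo system live here.  Internal
units follow the membrane-mechanics convention: energies in kBT, lengths in
nm, tension in kBT/nm^2.  Physical constants enter only at the I/O boundary
(:func:`tension_to_mN_per_m`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "KB_SI",
    "MembraneSpec",
    "CapGeometry",
    "EnergyBreakdown",
    "cap_from_radius",
    "dome_bending_energy",
    "dome_tension_energy",
    "decay_length",
    "tension_to_mN_per_m",
    "compartment_diameter",
]

#: Boltzmann constant, J/K (exact SI definition).
KB_SI = 1.380649e-23


@dataclass(frozen=True)
class MembraneSpec:
    """Mechanical state of the lipid bilayer.

    Parameters
    ----------
    bending_modulus : float
        Bending modulus ``Kb`` in kBT.  Around 20 kBT for common
        phosphatidylcholine bilayers.
    tension : float
        Lateral membrane tension ``gamma`` in kBT/nm^2.  Typical cellular
        values are well below the lysis tension of ~3.5 kBT/nm^2.
    temperature : float
        Absolute temperature in K; used only for unit conversion.
    """

    bending_modulus: float
    tension: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not self.bending_modulus > 0:
            raise ValueError(f"bending modulus must be > 0, got {self.bending_modulus}")
        if self.tension < 0:
            raise ValueError(f"tension must be >= 0, got {self.tension}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def decay_length(self) -> float:
        """Characteristic decay length sqrt(Kb/gamma) in nm (inf if tension-free)."""
        if self.tension == 0:
            return math.inf
        return math.sqrt(self.bending_modulus / self.tension)


@dataclass(frozen=True)
class CapGeometry:
    """Spherical-cap representation of the Piezo dome.

    The dome is an up-to-hemispherical cap of fixed membrane area ``A``
    (default 390 nm^2) and radius of curvature ``R``.  Derived quantities
    follow from the cap identities ``A = 2 pi R^2 (1 - cos alpha)`` and
    ``r0 = R sin alpha``.

    Attributes
    ----------
    radius : float
        Radius of curvature R, nm.
    area : float
        Cap (membrane) area A, nm^2.
    alpha : float
        Cap half-angle at the contact line, rad.
    contact_radius : float
        In-plane radius of the contact line r0, nm.
    height : float
        Cap height above the contact-line plane, nm.
    projected_area : float
        In-plane projected area pi r0^2, nm^2.
    excess_area : float
        A - projected_area: the in-plane area released on flattening, nm^2.
    """

    radius: float
    area: float
    alpha: float = field(init=False)
    contact_radius: float = field(init=False)
    height: float = field(init=False)
    projected_area: float = field(init=False)
    excess_area: float = field(init=False)

    def __post_init__(self) -> None:
        R, A = self.radius, self.area
        if not R > 0:
            raise ValueError(f"radius of curvature must be > 0, got {R}")
        if not A > 0:
            raise ValueError(f"cap area must be > 0, got {A}")
        hemisphere_area = 2.0 * math.pi * R * R
        if A > hemisphere_area * (1.0 + 1e-12):
            r_min = math.sqrt(A / (2.0 * math.pi))
            raise ValueError(
                f"cap area A={A} nm^2 exceeds the hemisphere area 2*pi*R^2="
                f"{hemisphere_area:.4g} nm^2 at R={R} nm; for this area the "
                f"dome needs R >= {r_min:.4g} nm"
            )
        # cos(alpha) = 1 - A / (2 pi R^2); alpha in (0, pi/2]
        cos_alpha = 1.0 - A / hemisphere_area
        alpha = math.acos(max(-1.0, min(1.0, cos_alpha)))
        object.__setattr__(self, "alpha", alpha)
        r0 = R * math.sin(alpha)
        object.__setattr__(self, "contact_radius", r0)
        object.__setattr__(self, "height", R * (1.0 - cos_alpha))
        proj = math.pi * r0 * r0
        object.__setattr__(self, "projected_area", proj)
        object.__setattr__(self, "excess_area", A - proj)


@dataclass
class EnergyBreakdown:
    """Additive decomposition G = GDP + GDb + GDgamma + GM of the system energy.

    ``GDP`` is the (externally supplied) protein term, ``GDb`` the dome
    bending energy, ``GDgamma`` the tension work of forming the dome, and
    ``GM`` the membrane-footprint energy with its bending and tension parts.
    All energies in kBT, areas in nm^2.
    """

    protein: float = 0.0
    dome_bending: float = 0.0
    dome_tension: float = 0.0
    footprint: float = 0.0
    footprint_bending: float = 0.0
    footprint_tension: float = 0.0
    footprint_excess_area: float = 0.0

    @property
    def total(self) -> float:
        return self.protein + self.dome_bending + self.dome_tension + self.footprint


def cap_from_radius(radius: float, area: float = 390.0) -> CapGeometry:
    """Build the spherical-cap dome of radius of curvature ``radius`` (nm) and
    fixed membrane area ``area`` (nm^2, default 390).

    Raises ``ValueError`` if the cap would exceed a hemisphere
    (``area > 2 pi radius^2``).
    """
    return CapGeometry(radius=radius, area=area)


def dome_bending_energy(cap: CapGeometry, bending_modulus: float) -> float:
    """Bending energy of the dome, (Kb/2)(2/R)^2 A = 2 Kb A / R^2, in kBT.

    Approximates all of the dome area as membrane bent to the sphere's
    curvature 2/R.  For the closed dome (A=390 nm^2, R=10.2 nm) this gives
    ~2.4 pi Kb.
    """
    return 2.0 * bending_modulus * cap.area / (cap.radius * cap.radius)


def dome_tension_energy(cap: CapGeometry, tension: float) -> float:
    """Tension work gamma * excess_area of forming the dome, in kBT."""
    if tension < 0:
        raise ValueError(f"tension must be >= 0, got {tension}")
    return tension * cap.excess_area


def decay_length(bending_modulus: float, tension: float) -> float:
    """Characteristic decay length lambda = sqrt(Kb/gamma), nm.

    Sets the lateral scale over which membrane shape deformations relax back
    to the far-field plane.  A tension-free membrane has no finite decay
    scale; ``tension == 0`` raises ``ValueError`` (callers wanting the
    tension-free limit should use the catenoid reference shape instead).
    """
    if not bending_modulus > 0:
        raise ValueError(f"bending modulus must be > 0, got {bending_modulus}")
    if tension == 0:
        raise ValueError(
            "decay length diverges at zero tension; the tension-free footprint "
            "is the catenoid minimal surface, not an exponentially decaying mode"
        )
    if tension < 0:
        raise ValueError(f"tension must be >= 0, got {tension}")
    return math.sqrt(bending_modulus / tension)


def tension_to_mN_per_m(tension: float, temperature: float = 298.0) -> float:
    """Convert a tension in kBT/nm^2 to mN/m at the given temperature.

    1 kBT/nm^2 = kB*T / (1 nm^2) ~ 4.114 mN/m at 298 K.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    # kB*T [J] / 1e-18 [m^2] -> N/m; *1e3 -> mN/m
    return tension * KB_SI * temperature / 1e-18 * 1e3


def compartment_diameter(cap: CapGeometry, arc_length: float) -> float:
    """Diameter S of the membrane compartment whose rim lies ``arc_length`` nm
    beyond the dome contact line.

    Uses the radial in-plane approximation S = 2 (r0 + L); the difference
    from the true arc along the deformed membrane is O(slope^2) and below
    the ~10 nm resolution at which compartment sizes are quoted.
    """
    if arc_length < 0:
        raise ValueError(f"arc length must be >= 0, got {arc_length}")
    return 2.0 * (cap.contact_radius + arc_length)
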
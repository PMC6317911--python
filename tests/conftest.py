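import numpy as np
import pytest

from piezomech import (
    CompartmentSpec,
    MembraneSpec,
    SolverSettings,
    cap_from_radius,
    footprint_energy,
    solve_footprint,
    solve_footprint_sweep,
)

CLOSED_R = 10.2
DOME_AREA = 390.0
KB = 20.0


@pytest.fixture(scope="session")
def closed_cap():
    """The closed Piezo dome: spherical cap of area 390 nm^2, R = 10.2 nm."""
    return cap_from_radius(CLOSED_R, DOME_AREA)


@pytest.fixture(scope="session")
def standard_membrane():
    """Kb = 20 kBT, gamma = 0.1 kBT/nm^2: the reference membrane state."""
    return MembraneSpec(bending_modulus=KB, tension=0.1)


@pytest.fixture(scope="session")
def closed_profile(closed_cap, standard_membrane):
    """Converged infinite-membrane footprint of the closed dome at gamma=0.1."""
    return solve_footprint(closed_cap, standard_membrane)


@pytest.fixture(scope="session")
def low_tension_sweep(closed_cap):
    """Footprints of the closed dome at decreasing tensions (catenoid approach).

    Returns (tensions, profiles, energies) for gamma from 1e-2 down to 1e-4.
    """
    tensions = [1e-2, 3e-3, 1e-3, 3e-4, 1e-4]
    membrane = MembraneSpec(bending_modulus=KB, tension=max(tensions))
    profiles = solve_footprint_sweep(closed_cap, membrane, tensions)
    energies = [footprint_energy(p) for p in profiles]
    return tensions, profiles, energies


@pytest.fixture(scope="session")
def radius_scan():
    """GM versus dome radius at gamma = 0.1 (fixed area, Kb)."""
    radii = [10.2, 11.2, 15.0, 20.0, 40.0]
    membrane = MembraneSpec(bending_modulus=KB, tension=0.1)
    out = {}
    for r in radii:
        prof = solve_footprint(cap_from_radius(r, DOME_AREA), membrane)
        out[r] = footprint_energy(prof).footprint
    return out


@pytest.fixture(scope="session")
def compartment_energies(closed_cap):
    """GM for finite compartments L in {5, 10} nm and the infinite membrane,
    at low (0.01) and moderate (0.5) tension."""
    out = {}
    for gamma in (0.01, 0.5):
        membrane = MembraneSpec(bending_modulus=KB, tension=gamma)
        row = {"inf": footprint_energy(solve_footprint(closed_cap, membrane)).footprint}
        for L in (5.0, 10.0):
            prof = solve_footprint(
                closed_cap, membrane, CompartmentSpec.finite(L), SolverSettings(seed=1)
            )
            row[L] = footprint_energy(prof).footprint
        out[gamma] = row
    return out
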
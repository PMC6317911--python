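"""Tension-dependent gating energetics of the dome + footprint system.

The total work of forming the membrane--Piezo system from a planar standard
state decomposes as G = GDP + GDb + GDgamma + GM: protein term, dome bending,
dome tension work, and the footprint energy.  Gating is modeled as a
two-state (closed/open) equilibrium between dome geometries Rc < Ro; the
open state may be exactly flat, in which case all its membrane terms vanish.
The open probability follows the Boltzmann relation

    Po / (1 - Po) = exp(-dG)        (energies in kBT)

and the tension sensitivity dPo/dgamma = -Po (1 - Po) * d(dG)/dgamma.  The
footprint contribution to d(dG)/dgamma is evaluated through the envelope
identity dGM/dgamma = dA_M (exact at the energy minimum), with central
finite differences available as a verification mode.

Since the protein term GDP is unknown, the absolute gating tension is not a
prediction; ``calibrate_delta_gdp`` chooses the protein offset so that the
activation midpoint (Po = 0.5) falls at a user-supplied tension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .arclength import (
    CompartmentSpec,
    FootprintProfile,
    SolverSettings,
    footprint_energy,
    solve_footprint,
    solve_footprint_sweep,
)
from .geometry import (
    CapGeometry,
    EnergyBreakdown,
    MembraneSpec,
    dome_bending_energy,
    dome_tension_energy,
)

__all__ = [
    "FLAT",
    "GatingScenario",
    "GatingEnergies",
    "GatingCurve",
    "open_probability",
    "state_energy",
    "gating_energy",
    "tension_sensitivity",
    "calibrate_delta_gdp",
    "gating_curve",
]


class _FlatState:
    """Sentinel for an exactly flat (Ro -> infinity) open conformation.

    All membrane-shape terms (dome bending, dome tension work, footprint)
    vanish identically for a flat dome; representing flatness explicitly
    avoids large-radius numerical limits.
    """

    def __repr__(self) -> str:  # pragma: no cover
        return "FLAT"


#: the flat conformation (radius of curvature -> infinity)
FLAT = _FlatState()

DomeState = CapGeometry | _FlatState


@dataclass(frozen=True)
class GatingScenario:
    """Closed/open dome pair in a given membrane and compartment.

    ``delta_gdp`` is the protein contribution dGDP = GDP(open) - GDP(closed)
    in kBT, externally supplied or calibrated from a midpoint tension.
    """

    closed: CapGeometry
    open: DomeState
    membrane: MembraneSpec
    delta_gdp: float = 0.0
    compartment: CompartmentSpec = field(default_factory=CompartmentSpec.infinite)
    settings: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if isinstance(self.open, CapGeometry):
            if self.closed.radius > self.open.radius:
                raise ValueError(
                    "gating convention requires Rc <= Ro (the open dome is flatter); "
                    f"got Rc={self.closed.radius}, Ro={self.open.radius}"
                )

    def with_delta_gdp(self, delta_gdp: float) -> "GatingScenario":
        return replace(self, delta_gdp=delta_gdp)


@dataclass
class GatingEnergies:
    """Per-state energy breakdowns and the open-minus-closed differences (kBT)."""

    tension: float
    closed: EnergyBreakdown
    open: EnergyBreakdown
    delta_dome_bending: float
    delta_dome_tension: float
    delta_footprint: float
    delta_gdp: float

    @property
    def delta_total(self) -> float:
        return (
            self.delta_gdp
            + self.delta_dome_bending
            + self.delta_dome_tension
            + self.delta_footprint
        )

    @property
    def delta_membrane(self) -> float:
        """Membrane-shape part of the gating energy (everything but dGDP)."""
        return self.delta_dome_bending + self.delta_dome_tension + self.delta_footprint


@dataclass
class GatingCurve:
    """Gating quantities tabulated on a tension grid.

    Arrays (one value per tension, kBT / nm^2 / kBT-based units):
    open-minus-closed energy terms, total gating energy, open probability,
    and the tension sensitivities d(dG)/dgamma (nm^2) and dPo/dgamma
    (nm^2/kBT).  ``dome_only`` holds the same curve with the footprint
    contribution excluded.
    """

    tensions: np.ndarray
    delta_dome_bending: np.ndarray
    delta_dome_tension: np.ndarray
    delta_footprint: np.ndarray
    delta_total: np.ndarray
    open_probability: np.ndarray
    dG_dgamma: np.ndarray
    dPo_dgamma: np.ndarray
    scenario: GatingScenario
    dome_only: "GatingCurve | None" = None


def open_probability(delta_g) -> np.ndarray | float:
    """Two-state open probability Po = 1 / (1 + e^{dG}), energies in kBT.

    Evaluated in the log domain; numerically exact (0 or 1) for |dG| far
    beyond the ~700 kBT overflow threshold of a naive exponential.
    """
    dg = np.asarray(delta_g, dtype=float)
    # logistic of -dg via the stable two-branch form
    out = np.where(dg >= 0, np.exp(-np.clip(dg, 0, None)) / (1.0 + np.exp(-np.clip(dg, 0, None))),
                   1.0 / (1.0 + np.exp(np.clip(dg, None, 0))))
    if np.isscalar(delta_g):
        return float(out)
    return out


def _membrane_terms(
    state: DomeState,
    membrane: MembraneSpec,
    compartment: CompartmentSpec,
    settings: SolverSettings,
    profile: FootprintProfile | None = None,
) -> EnergyBreakdown:
    if isinstance(state, _FlatState):
        return EnergyBreakdown()
    gdb = dome_bending_energy(state, membrane.bending_modulus)
    gdg = dome_tension_energy(state, membrane.tension)
    if membrane.tension == 0 and compartment.mode == "infinite":
        # tension-free infinite membrane: the footprint is a catenoid, GM = 0
        fp = EnergyBreakdown()
    else:
        if profile is None:
            profile = solve_footprint(state, membrane, compartment, settings)
        fp = footprint_energy(profile, membrane)
    return EnergyBreakdown(
        dome_bending=gdb,
        dome_tension=gdg,
        footprint=fp.footprint,
        footprint_bending=fp.footprint_bending,
        footprint_tension=fp.footprint_tension,
        footprint_excess_area=fp.footprint_excess_area,
    )


def state_energy(
    state: DomeState,
    membrane: MembraneSpec,
    compartment: CompartmentSpec | None = None,
    settings: SolverSettings | None = None,
) -> EnergyBreakdown:
    """Membrane-shape energy breakdown of a single dome conformation."""
    return _membrane_terms(
        state,
        membrane,
        compartment or CompartmentSpec.infinite(),
        settings or SolverSettings(),
    )


def gating_energy(
    scenario: GatingScenario,
    tension: float | None = None,
    include_footprint: bool = True,
    _profiles: tuple | None = None,
) -> GatingEnergies:
    """Open-minus-closed energy differences at one tension.

    For a flat open state every membrane term of the open conformation is
    identically zero.  At zero tension in an infinite membrane both the dome
    tension work and the footprint term vanish (the footprint becomes an
    energy-free catenoid), so dG reduces to dGDP + dGDb.
    """
    mem = scenario.membrane if tension is None else replace(scenario.membrane, tension=tension)
    prof_c, prof_o = _profiles if _profiles is not None else (None, None)
    closed = _membrane_terms(scenario.closed, mem, scenario.compartment, scenario.settings, prof_c)
    opened = _membrane_terms(scenario.open, mem, scenario.compartment, scenario.settings, prof_o)
    if not include_footprint:
        closed = replace_footprint_zero(closed)
        opened = replace_footprint_zero(opened)
    return GatingEnergies(
        tension=mem.tension,
        closed=closed,
        open=opened,
        delta_dome_bending=opened.dome_bending - closed.dome_bending,
        delta_dome_tension=opened.dome_tension - closed.dome_tension,
        delta_footprint=opened.footprint - closed.footprint,
        delta_gdp=scenario.delta_gdp,
    )


def replace_footprint_zero(e: EnergyBreakdown) -> EnergyBreakdown:
    return EnergyBreakdown(
        protein=e.protein, dome_bending=e.dome_bending, dome_tension=e.dome_tension
    )


def _delta_excess_area(scenario: GatingScenario, energies: GatingEnergies) -> tuple[float, float]:
    """(dome, footprint) excess-area differences dA(open) - dA(closed), nm^2."""
    a_closed = scenario.closed.excess_area
    a_open = 0.0 if isinstance(scenario.open, _FlatState) else scenario.open.excess_area
    am_closed = energies.closed.footprint_excess_area
    am_open = energies.open.footprint_excess_area
    return a_open - a_closed, am_open - am_closed


def tension_sensitivity(
    scenario: GatingScenario,
    tension: float,
    method: str = "envelope",
    step: float | None = None,
    include_footprint: bool = True,
) -> dict:
    """Tension sensitivities at one tension.

    Returns ``{"dG_dgamma": nm^2, "dPo_dgamma": nm^2/kBT}``.  The dome part
    of d(dG)/dgamma is the constant excess-area difference; the footprint
    part uses the envelope identity dGM/dgamma = dA_M by default
    (``method="envelope"``, exact at the energy minimum) or a central finite
    difference (``method="fd"``) as an independent verification.  Sensitivity
    is negative for Rc < Ro: increasing tension favors the open state.
    """
    if method not in ("envelope", "fd"):
        raise ValueError(f"method must be 'envelope' or 'fd', got {method!r}")
    energies = gating_energy(scenario, tension, include_footprint=include_footprint)
    d_dome, d_foot_area = _delta_excess_area(scenario, energies)
    if method == "envelope":
        dg_dgamma = d_dome + (d_foot_area if include_footprint else 0.0)
    else:
        step = step if step is not None else 0.05 * tension
        if not tension - step > 0:
            raise ValueError(f"finite-difference step {step} too large for tension {tension}")
        lo = gating_energy(scenario, tension - step, include_footprint=include_footprint)
        hi = gating_energy(scenario, tension + step, include_footprint=include_footprint)
        dg_dgamma = (hi.delta_membrane - lo.delta_membrane) / (2.0 * step)
    po = open_probability(energies.delta_total)
    return {
        "dG_dgamma": dg_dgamma,
        "dPo_dgamma": -po * (1.0 - po) * dg_dgamma,
        "Po": po,
        "delta_total": energies.delta_total,
    }


def calibrate_delta_gdp(
    scenario: GatingScenario,
    midpoint_tension: float,
    include_footprint: bool = True,
) -> float:
    """Protein offset dGDP that places the activation midpoint (Po = 0.5,
    i.e. dG = 0) at ``midpoint_tension``.

    dG is affine in dGDP, so the calibration is the exact negative of the
    membrane-shape gating energy at the midpoint tension.
    """
    if not midpoint_tension > 0:
        raise ValueError(f"midpoint tension must be > 0, got {midpoint_tension}")
    energies = gating_energy(scenario, midpoint_tension, include_footprint=include_footprint)
    return -energies.delta_membrane


def gating_curve(
    scenario: GatingScenario,
    tensions: Sequence[float],
    include_dome_only: bool = True,
) -> GatingCurve:
    """Evaluate all gating terms, Po, and sensitivities on a tension grid.

    The grid must be positive and strictly increasing.  Footprint solves are
    shared across the grid by continuation.  With ``include_dome_only`` the
    same curve excluding the footprint term (at the same dGDP) is attached,
    mirroring the with/without-footprint comparison of activation curves.
    """
    gammas = np.asarray(list(tensions), dtype=float)
    if gammas.size == 0:
        raise ValueError("empty tension grid")
    if np.any(gammas <= 0) or np.any(np.diff(gammas) <= 0):
        raise ValueError("tension grid must be positive and strictly increasing")

    profs = {}
    for state, tag in ((scenario.closed, "closed"), (scenario.open, "open")):
        if isinstance(state, _FlatState) or state.alpha == 0.0:
            profs[tag] = [None] * gammas.size
        elif scenario.compartment.mode == "infinite":
            profs[tag] = solve_footprint_sweep(
                state, scenario.membrane, gammas, scenario.compartment, scenario.settings
            )
        else:
            profs[tag] = [
                solve_footprint(
                    state,
                    replace(scenario.membrane, tension=g),
                    scenario.compartment,
                    scenario.settings,
                )
                for g in gammas
            ]

    def build(include_footprint: bool) -> GatingCurve:
        rows = []
        for i, g in enumerate(gammas):
            en = gating_energy(
                scenario,
                g,
                include_footprint=include_footprint,
                _profiles=(profs["closed"][i], profs["open"][i]),
            )
            d_dome, d_foot = _delta_excess_area(scenario, en)
            dgdg = d_dome + (d_foot if include_footprint else 0.0)
            po = open_probability(en.delta_total)
            rows.append(
                (en.delta_dome_bending, en.delta_dome_tension,
                 en.delta_footprint if include_footprint else 0.0,
                 en.delta_total, po, dgdg, -po * (1 - po) * dgdg)
            )
        cols = [np.array(c) for c in zip(*rows)]
        return GatingCurve(
            tensions=gammas.copy(),
            delta_dome_bending=cols[0],
            delta_dome_tension=cols[1],
            delta_footprint=cols[2],
            delta_total=cols[3],
            open_probability=cols[4],
            dG_dgamma=cols[5],
            dPo_dgamma=cols[6],
            scenario=scenario,
        )

    curve = build(True)
    if include_dome_only:
        curve.dome_only = build(False)
    return curve
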
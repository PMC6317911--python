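"""Small-gradient (Monge) analytic solution for the membrane footprint.

In the Monge parametrization the mid-bilayer surface outside the dome is a
height field h(r) over the reference plane.  Linearizing the Helfrich
functional for small gradients gives the biharmonic-Helmholtz equation

    Kb * Lap^2 h - gamma * Lap h = 0 ,

whose bounded, decaying, force-free axisymmetric solution is the single
Bessel mode h(r) = C K0(r / lambda) with lambda = sqrt(Kb/gamma).  (The
constant and I0 modes grow at infinity; the log mode carries a net vertical
force and is excluded for a free-floating dome.)  The amplitude C follows
from matching the membrane slope to the dome rim.

This solution is quantitatively valid only for small rim slopes; for the
strongly curved closed Piezo dome it overestimates the footprint and its
energy, and the nonlinear arclength solver should be used instead.  It
remains valuable as a fast approximation and as an independent cross-check
in the small-slope regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.special import k0, k1

from .geometry import CapGeometry, MembraneSpec

__all__ = ["MongeSolution", "SmallGradientWarning", "monge_solve", "monge_energy"]

#: rim slope beyond which the small-gradient expansion is unreliable
SLOPE_WARN_THRESHOLD = 0.3


class SmallGradientWarning(UserWarning):
    """Raised when the Monge solution is evaluated outside its validity regime."""


@dataclass(frozen=True)
class MongeSolution:
    """Decaying-mode solution h(r) = C K0(r/lambda) of the linearized problem.

    Attributes
    ----------
    amplitude : float
        Mode coefficient C, nm.
    decay_length : float
        lambda = sqrt(Kb/gamma), nm.
    contact_radius : float
        Dome contact-line radius r0, nm.
    rim_slope : float
        Boundary slope magnitude |h'(r0)|.
    cap : CapGeometry
        The dome the solution is matched to.
    """

    amplitude: float
    decay_length: float
    contact_radius: float
    rim_slope: float
    cap: CapGeometry

    def height(self, r):
        """Height h(r) above the far-field plane, nm, for r >= r0."""
        return self.amplitude * k0(np.asarray(r, dtype=float) / self.decay_length)

    def slope(self, r):
        """Radial slope dh/dr (negative: the footprint decays outward)."""
        return -self.amplitude / self.decay_length * k1(
            np.asarray(r, dtype=float) / self.decay_length
        )

    def mean_curvature(self, r):
        """Mean curvature H = (1/2) Lap h = h / (2 lambda^2), per nm."""
        return self.height(r) / (2.0 * self.decay_length**2)


def monge_solve(
    cap: CapGeometry,
    membrane: MembraneSpec,
    slope_match: str = "tan",
) -> MongeSolution:
    """Solve the linearized footprint problem on r in [r0, inf).

    The slope of the membrane at the contact line is matched to the dome rim:
    |h'(r0)| = tan(alpha) by default (the true geometric slope of the cap),
    or sin(alpha) with ``slope_match="sin"``.  Warns when the rim slope
    exceeds ~0.3, where the small-gradient expansion loses accuracy.

    Raises ``ValueError`` at zero tension, where the linear operator is
    degenerate (logarithmic far field) and the catenoid reference applies.
    """
    if membrane.tension == 0:
        raise ValueError(
            "the linearized problem is degenerate at zero tension "
            "(logarithmic far field); use the catenoid reference shape"
        )
    if slope_match not in ("tan", "sin"):
        raise ValueError(f"slope_match must be 'tan' or 'sin', got {slope_match!r}")
    lam = membrane.decay_length
    r0 = cap.contact_radius
    s0 = math.tan(cap.alpha) if slope_match == "tan" else math.sin(cap.alpha)
    if s0 > SLOPE_WARN_THRESHOLD:
        warnings.warn(
            f"rim slope {s0:.3g} exceeds {SLOPE_WARN_THRESHOLD}; the "
            "small-gradient (Monge) solution overestimates the footprint here "
            "- prefer the arclength solver",
            SmallGradientWarning,
            stacklevel=2,
        )
    if cap.alpha == 0.0 or s0 == 0.0:
        amplitude = 0.0
    else:
        amplitude = lam * s0 / k1(r0 / lam)
    return MongeSolution(
        amplitude=amplitude,
        decay_length=lam,
        contact_radius=r0,
        rim_slope=s0,
        cap=cap,
    )


def monge_energy(
    sol: MongeSolution,
    membrane: MembraneSpec,
    rel_tol: float = 1e-8,
    cutoff_lambdas: float = 20.0,
) -> float:
    """Footprint energy GM of a Monge solution, kBT, in the small-gradient limit.

    GM = int_{r0}^{inf} [ (Kb/2)(h'' + h'/r)^2 + (gamma/2) h'^2 ] 2 pi r dr,
    by adaptive quadrature on [r0, r0 + cutoff_lambdas * lambda].  The
    truncated tail is bounded analytically through the K-Bessel asymptotics
    (integrand ~ e^{-2r/lambda}) and verified below the requested tolerance.
    """
    if sol.amplitude == 0.0:
        return 0.0
    lam = sol.decay_length
    r0 = sol.contact_radius
    Kb = membrane.bending_modulus
    gamma = membrane.tension
    C = sol.amplitude

    def integrand(r: float) -> float:
        x = r / lam
        lap = C * k0(x) / lam**2  # h'' + h'/r = Lap h = h / lambda^2
        dh = -C * k1(x) / lam
        return (0.5 * Kb * lap * lap + 0.5 * gamma * dh * dh) * 2.0 * math.pi * r

    r_cut = r0 + cutoff_lambdas * lam
    val, err = quad(integrand, r0, r_cut, epsrel=rel_tol, epsabs=0.0, limit=200)
    # tail bound: K_nu(x)^2 <= (pi/(2x)) e^{-2x} for x >= x_cut >~ 1, so the
    # tail of each term is below (pi^2/2)(coef) lam e^{-2 x_cut} * (x_cut+1)
    x_cut = r_cut / lam
    tail = (
        math.pi**2
        * (0.5 * Kb * C * C / lam**4 + 0.5 * gamma * C * C / lam**2)
        * lam
        * (x_cut + 1.0)
        * math.exp(-2.0 * x_cut)
    )
    if val > 0 and (err + tail) / val > max(rel_tol * 100, 1e-6):
        raise RuntimeError(
            f"Monge energy quadrature did not converge: value={val:.6g}, "
            f"quad error={err:.3g}, tail bound={tail:.3g}"
        )
    return val
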
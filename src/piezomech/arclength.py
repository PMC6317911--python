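"""Nonlinear axisymmetric footprint solver in the arclength parametrization.

The mid-bilayer surface outside the dome is described by its tangent angle
psi(s) versus arclength s, measured from the dome contact line.  This
parametrization remains valid at arbitrarily large membrane slopes, which the
strongly curved closed Piezo dome requires.  Minimizing the Helfrich energy

    GM = (Kb/2) int (c1 + c2)^2 dA + gamma * dA_excess

(zero osmotic pressure, zero spontaneous curvature) yields the axisymmetric
shape-equation system, with H the mean curvature and K the Gaussian
curvature:

    r'   = cos psi
    h'   = -sin psi
    psi' = 2 H - sin(psi) / r
    Lap H = (gamma/Kb) H - 2 H (H^2 - K),   Lap H = H'' + (cos psi / r) H'

For an infinite membrane the footprint decays exponentially on the scale
lambda = sqrt(Kb/gamma); the boundary-value problem is solved in units of
lambda with scipy's collocation solver, using continuation in gamma to reach
the stiff low-tension (near-catenoid) regime.  Finite membrane compartments
clamped to planarity at their rim are handled by direct minimization of the
energy functional over endpoint-constrained tangent-angle profiles.

Sign conventions: the dome bulges toward positive h; heights are measured
from the far-field (or compartment-rim) plane h = 0; psi in [0, pi/2) and
decreases outward, so h' = -sin psi along the outward arclength.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import simpson, solve_ivp
from scipy.interpolate import interp1d
from scipy.optimize import minimize
from scipy.special import k0, k1

from .geometry import CapGeometry, EnergyBreakdown, MembraneSpec
from .monge import SmallGradientWarning, monge_energy, monge_solve

__all__ = [
    "CompartmentSpec",
    "SolverSettings",
    "FootprintProfile",
    "SolverError",
    "solve_footprint",
    "solve_footprint_sweep",
    "footprint_energy",
    "catenoid_reference",
    "compare_parametrizations",
    "ParametrizationComparison",
]


class SolverError(RuntimeError):
    """Footprint solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class CompartmentSpec:
    """Membrane domain: infinite, or a finite corral clamped planar at its rim.

    ``arc_length`` is the unconstrained membrane arc length L between the dome
    contact line and the compartment rim (finite mode only).
    """

    mode: str = "infinite"  # "infinite" | "finite"
    arc_length: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("infinite", "finite"):
            raise ValueError(f"mode must be 'infinite' or 'finite', got {self.mode!r}")
        if self.mode == "finite":
            if self.arc_length is None or not self.arc_length > 0:
                raise ValueError("finite compartment requires arc_length > 0")
        elif self.arc_length is not None:
            raise ValueError("arc_length is only meaningful for finite compartments")

    @classmethod
    def infinite(cls) -> "CompartmentSpec":
        return cls(mode="infinite")

    @classmethod
    def finite(cls, arc_length: float) -> "CompartmentSpec":
        return cls(mode="finite", arc_length=arc_length)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs for the footprint solvers.

    cutoff_lambdas / cutoff_contact_radii: the infinite domain is truncated at
    s_max = max(cutoff_lambdas * lambda, cutoff_contact_radii * r0) with
    asymptotic boundary conditions psi = H = h = 0; the default truncation
    changes GM by well under 0.1% on doubling.  n_modes is the number of sine
    modes of the tangent-angle representation used for finite compartments;
    multistart randomized restarts (seeded) guard the direct minimizer
    against local minima.
    """

    tol: float = 1e-8
    max_nodes: int = 200_000
    cutoff_lambdas: float = 10.0
    cutoff_contact_radii: float = 5.0
    n_output: int = 2001
    n_modes: int = 24
    n_quad: int = 1601
    multistart: int = 2
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tol", "cutoff_lambdas", "cutoff_contact_radii"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("max_nodes", "n_output", "n_modes", "n_quad", "max_iter"):
            if not getattr(self, name) >= 1:
                raise ValueError(f"{name} must be >= 1")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass
class FootprintProfile:
    """Discretized minimum-energy footprint shape.

    Arrays are sampled on an arclength grid ``s`` (nm, 0 at the dome contact
    line): in-plane radius ``r`` (nm), height ``h`` above the far-field plane
    (nm), tangent angle ``psi`` (rad), and mean curvature ``H`` (1/nm).
    """

    s: np.ndarray
    r: np.ndarray
    h: np.ndarray
    psi: np.ndarray
    H: np.ndarray
    cap: CapGeometry
    membrane: MembraneSpec
    compartment: CompartmentSpec
    method: str = "arclength"
    diagnostics: dict = field(default_factory=dict)

    @property
    def rim_height(self) -> float:
        """Height of the dome contact line above the far-field plane, nm."""
        return float(self.h[0])

    def neck_invariant(self) -> np.ndarray:
        """r(s) * sin(psi(s)); constant (= r0 sin alpha) for a catenoid."""
        return self.r * np.sin(self.psi)


# ---------------------------------------------------------------------------
# infinite membrane: collocation BVP in units of lambda


def _shape_rhs(x, y, lam_sq_inv_unused=None):
    """RHS of the scaled shape-equation system; y = [r, h, psi, H, dH] in
    units of lambda (H in 1/lambda).  The tension/bending ratio scales out."""
    r, h, psi, H, dH = y
    sin_psi = np.sin(psi)
    cos_psi = np.cos(psi)
    dpsi = 2.0 * H - sin_psi / r
    gauss = dpsi * sin_psi / r
    return np.vstack(
        [
            cos_psi,
            -sin_psi,
            dpsi,
            dH,
            H - 2.0 * H * (H * H - gauss) - cos_psi / r * dH,
        ]
    )


def _initial_mesh(x0: float, x_max: float, n: int) -> np.ndarray:
    """Mesh graded geometrically near the rim (scale x0) then linear outward."""
    n_in = n // 2
    inner = np.geomspace(max(x0 * 1e-2, 1e-6), min(1.0, x_max / 2), n_in)
    outer = np.linspace(min(1.0, x_max / 2), x_max, n - n_in + 1)[1:]
    return np.concatenate([[0.0], inner, outer])


def _solve_infinite_scaled(
    cap: CapGeometry,
    membrane: MembraneSpec,
    settings: SolverSettings,
    guess: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Solve the scaled BVP for one tension; returns the scipy bvp solution.

    ``guess``: optional (x_mesh, y_values) initial iterate in scaled units.
    """
    from scipy.integrate import solve_bvp

    lam = membrane.decay_length
    r0s = cap.contact_radius / lam
    alpha = cap.alpha
    x_max = max(settings.cutoff_lambdas, settings.cutoff_contact_radii * r0s)

    def bc(ya, yb):
        return np.array([ya[0] - r0s, ya[2] - alpha, yb[2], yb[3], yb[1]])

    if guess is None:
        x = _initial_mesh(r0s, x_max, 201)
        # exponential-decay ansatz on the larger of the two inner scales
        scale = max(r0s, 1.0)
        psi = alpha * np.exp(-x / scale)
        r = r0s + np.concatenate([[0.0], np.cumsum(np.diff(x) * np.cos(0.5 * (psi[1:] + psi[:-1])))])
        h = np.concatenate([[0.0], np.cumsum(np.diff(x) * np.sin(0.5 * (psi[1:] + psi[:-1])))])
        h = h[-1] - h  # gauge: h = 0 at the outer boundary
        dpsi = -alpha / scale * np.exp(-x / scale)
        H = 0.5 * (dpsi + np.sin(psi) / r)
        dH = np.gradient(H, x)
        y = np.vstack([r, h, psi, H, dH])
    else:
        x, y = guess
    sol = solve_bvp(
        _shape_rhs, bc, x, y, tol=settings.tol, max_nodes=settings.max_nodes, verbose=0
    )
    return sol, lam, x_max


def _profile_from_scaled(sol, lam, x_max, cap, membrane, compartment, settings, n_gamma_steps):
    xs = np.unique(
        np.concatenate(
            [
                np.linspace(0.0, x_max, settings.n_output // 2),
                _initial_mesh(cap.contact_radius / lam, x_max, settings.n_output // 2),
            ]
        )
    )
    y = sol.sol(xs)
    return FootprintProfile(
        s=xs * lam,
        r=y[0] * lam,
        h=y[1] * lam,
        psi=y[2],
        H=y[3] / lam,
        cap=cap,
        membrane=membrane,
        compartment=compartment,
        method="arclength",
        diagnostics={
            "bvp_status": sol.status,
            "max_residual": float(sol.rms_residuals.max()),
            "n_nodes": sol.x.size,
            "s_max_nm": x_max * lam,
            "continuation_steps": n_gamma_steps,
        },
    )


def _continuation_gammas(cap: CapGeometry, membrane: MembraneSpec, target: float) -> list[float]:
    """Geometric ladder of tensions from an easy starting point down to target."""
    gamma_easy = membrane.bending_modulus / cap.contact_radius**2
    if target >= gamma_easy:
        return [target]
    n = max(2, int(math.ceil(math.log(gamma_easy / target) / math.log(3.0))) + 1)
    n = min(n, 12)  # nearly flat caps make r0 tiny; the problem is easy there anyway
    return list(np.geomspace(gamma_easy, target, n))


def solve_footprint(
    cap: CapGeometry,
    membrane: MembraneSpec,
    compartment: CompartmentSpec | None = None,
    settings: SolverSettings | None = None,
) -> FootprintProfile:
    """Minimum-energy membrane footprint around the dome.

    Infinite membranes are solved through the shape-equation boundary-value
    problem (collocation, continuation in tension down to the requested
    value); finite compartments by direct minimization of the Helfrich
    functional over clamped tangent-angle profiles.

    Raises
    ------
    SolverError
        On non-convergence (diagnostics attached) or if the profile pinches
        off (r -> 0).
    ValueError
        For an infinite membrane at zero tension (no planar far-field
        attachment exists; use :func:`catenoid_reference`).
    """
    compartment = compartment or CompartmentSpec.infinite()
    settings = settings or SolverSettings()
    if cap.alpha == 0.0:
        return _planar_profile(cap, membrane, compartment, settings)
    if compartment.mode == "finite":
        return _solve_finite(cap, membrane, compartment, settings)
    if membrane.tension <= 0:
        raise ValueError(
            "infinite-membrane footprint requires tension > 0; the zero-tension "
            "limit is the catenoid (see catenoid_reference)"
        )
    profiles = solve_footprint_sweep(cap, membrane, [membrane.tension], compartment, settings)
    return profiles[0]


def solve_footprint_sweep(
    cap: CapGeometry,
    membrane: MembraneSpec,
    tensions: Sequence[float],
    compartment: CompartmentSpec | None = None,
    settings: SolverSettings | None = None,
) -> list[FootprintProfile]:
    """Solve the infinite-membrane footprint for several tensions efficiently.

    Tensions are visited from the largest down, each converged solution
    seeding the next (continuation); the returned list matches the input
    order.  All tensions must be positive.
    """
    compartment = compartment or CompartmentSpec.infinite()
    settings = settings or SolverSettings()
    if compartment.mode != "infinite":
        raise ValueError("sweep continuation applies to infinite membranes only")
    tensions = list(tensions)
    if not tensions or any(g <= 0 for g in tensions):
        raise ValueError("all tensions must be > 0")

    order = np.argsort(tensions)[::-1]
    ladder = _continuation_gammas(cap, replace(membrane, tension=max(tensions)), max(tensions))
    # merge requested tensions into the descending ladder
    all_gammas = sorted(set(ladder) | set(tensions), reverse=True)
    results: dict[float, FootprintProfile] = {}
    guess = None
    lam_prev = None
    for gamma in all_gammas:
        mem_g = replace(membrane, tension=gamma)
        lam = mem_g.decay_length
        if guess is not None:
            # rescale the previous converged iterate (same physical shape) to
            # the new lambda units and resample it onto a fresh graded mesh
            x_prev, y_prev = guess
            scale = lam_prev / lam
            x_old = x_prev * scale
            y_old = y_prev.copy()
            y_old[0] *= scale
            y_old[1] *= scale
            y_old[3] /= scale
            y_old[4] /= scale * scale
            r0s = cap.contact_radius / lam
            x_max_new = max(settings.cutoff_lambdas, settings.cutoff_contact_radii * r0s)
            x_new = _initial_mesh(r0s, x_max_new, 401)
            y_new = np.empty((5, x_new.size))
            inside = x_new <= x_old[-1]
            for i in range(5):
                y_new[i, inside] = np.interp(x_new[inside], x_old, y_old[i])
                # beyond the previous domain the solution has decayed: pad the
                # deformation fields with zeros and extend r along the plane
                y_new[i, ~inside] = 0.0
            y_new[0, ~inside] = y_old[0, -1] + (x_new[~inside] - x_old[-1])
            cur_guess = (x_new, y_new)
        else:
            cur_guess = None
        sol, lam, x_max = _solve_infinite_scaled(cap, mem_g, settings, cur_guess)
        if sol.status != 0:
            raise SolverError(
                f"shape-equation BVP failed at tension {gamma:.4g} kBT/nm^2: "
                f"{sol.message}",
                diagnostics={
                    "tension": gamma,
                    "status": sol.status,
                    "max_residual": float(sol.rms_residuals.max()) if sol.rms_residuals.size else None,
                    "n_nodes": sol.x.size,
                },
            )
        if np.any(sol.y[0] <= 0):
            raise SolverError(
                f"footprint neck pinched off (r -> 0) at tension {gamma:.4g}",
                diagnostics={"tension": gamma, "failure": "neck_pinch"},
            )
        guess = (sol.x, sol.y)
        lam_prev = lam
        if gamma in tensions:
            prof = _profile_from_scaled(
                sol, lam, x_max, cap, mem_g, compartment, settings, len(all_gammas)
            )
            results[gamma] = prof
    return [results[tensions[i]] for i in range(len(tensions))]


def _planar_profile(cap, membrane, compartment, settings) -> FootprintProfile:
    """Flat dome (alpha = 0) induces no footprint: the plane itself."""
    if compartment.mode == "finite":
        s_max = compartment.arc_length
    else:
        lam = membrane.decay_length
        s_max = (
            settings.cutoff_lambdas * lam
            if math.isfinite(lam)
            else settings.cutoff_contact_radii * max(cap.contact_radius, 1.0)
        )
    s = np.linspace(0.0, s_max, settings.n_output)
    zeros = np.zeros_like(s)
    return FootprintProfile(
        s=s,
        r=cap.contact_radius + s,
        h=zeros.copy(),
        psi=zeros.copy(),
        H=zeros.copy(),
        cap=cap,
        membrane=membrane,
        compartment=compartment,
        method="arclength",
        diagnostics={"planar": True},
    )


# ---------------------------------------------------------------------------
# finite compartment: direct minimization over tangent-angle profiles


def _psi_basis(L: float, s: np.ndarray, n_modes: int):
    """Ramp + sine representation; every member satisfies psi(0)=alpha_hat,
    psi(L)=0 when combined as alpha*ramp + modes @ a."""
    ramp = 1.0 - s / L
    modes = np.sin(np.outer(np.arange(1, n_modes + 1) * math.pi / L, s))
    dramp = np.full_like(s, -1.0 / L)
    dmodes = (
        np.cos(np.outer(np.arange(1, n_modes + 1) * math.pi / L, s))
        * (np.arange(1, n_modes + 1) * math.pi / L)[:, None]
    )
    return ramp, modes, dramp, dmodes


def _finite_energy_of(a, alpha, r0, L, Kb, gamma, s, w, ramp, modes, dramp, dmodes):
    psi = alpha * ramp + a @ modes
    dpsi = alpha * dramp + a @ dmodes
    cos_psi = np.cos(psi)
    sin_psi = np.sin(psi)
    # r(s) = r0 + int cos psi; cumulative trapezoid on the uniform grid
    ds = s[1] - s[0]
    r = r0 + np.concatenate([[0.0], np.cumsum(0.5 * (cos_psi[1:] + cos_psi[:-1]) * ds)])
    if np.any(r <= 0):
        return 1e12
    mean2 = (dpsi + sin_psi / r) ** 2
    integrand = (0.5 * Kb * mean2 + gamma * (1.0 - cos_psi)) * 2.0 * math.pi * r
    return float(np.sum(w * integrand))


def _solve_finite(cap, membrane, compartment, settings) -> FootprintProfile:
    L = compartment.arc_length
    alpha, r0 = cap.alpha, cap.contact_radius
    Kb, gamma = membrane.bending_modulus, membrane.tension
    n = settings.n_quad if settings.n_quad % 2 == 1 else settings.n_quad + 1
    s = np.linspace(0.0, L, n)
    # Simpson weights on the uniform grid
    ds = s[1] - s[0]
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= ds / 3.0
    ramp, modes, dramp, dmodes = _psi_basis(L, s, settings.n_modes)

    rng = np.random.default_rng(settings.seed)
    best = None
    candidates = []
    for trial in range(settings.multistart):
        a0 = np.zeros(settings.n_modes)
        if trial > 0:
            a0 += rng.normal(scale=0.05 * alpha, size=settings.n_modes) / (
                1.0 + np.arange(settings.n_modes)
            )
        res = minimize(
            _finite_energy_of,
            a0,
            args=(alpha, r0, L, Kb, gamma, s, w, ramp, modes, dramp, dmodes),
            method="BFGS",
            options={"maxiter": settings.max_iter, "gtol": 1e-10},
        )
        candidates.append((res.fun, trial))
        if best is None or res.fun < best.fun:
            best = res
    a = best.x
    psi = alpha * ramp + a @ modes
    dpsi = alpha * dramp + a @ dmodes
    cos_psi, sin_psi = np.cos(psi), np.sin(psi)
    r = r0 + np.concatenate([[0.0], np.cumsum(0.5 * (cos_psi[1:] + cos_psi[:-1]) * ds)])
    h = np.concatenate([[0.0], np.cumsum(0.5 * (sin_psi[1:] + sin_psi[:-1]) * ds)])
    h = h[-1] - h  # clamp: h = 0 at the compartment rim, dome height free
    H = 0.5 * (dpsi + sin_psi / r)
    return FootprintProfile(
        s=s,
        r=r,
        h=h,
        psi=psi,
        H=H,
        cap=cap,
        membrane=membrane,
        compartment=compartment,
        method="arclength-direct",
        diagnostics={
            "energy": float(best.fun),
            "n_modes": settings.n_modes,
            "candidates": sorted(candidates),
            "seed": settings.seed,
            "converged": bool(best.success or best.fun < 1e11),
        },
    )


# ---------------------------------------------------------------------------
# energies and references


def footprint_energy(profile: FootprintProfile, membrane: MembraneSpec | None = None) -> EnergyBreakdown:
    """Helfrich energy of a footprint profile (footprint fields only), kBT.

    bending = int (Kb/2)(2H)^2 2 pi r ds; excess area = int 2 pi r (1-cos psi) ds;
    tension part = gamma * excess area.  Integration by Simpson's rule on the
    stored profile grid.
    """
    membrane = membrane or profile.membrane
    r, psi, H, s = profile.r, profile.psi, profile.H, profile.s
    two_pi_r = 2.0 * math.pi * r
    bending = simpson(0.5 * membrane.bending_modulus * (2.0 * H) ** 2 * two_pi_r, x=s)
    excess = simpson((1.0 - np.cos(psi)) * two_pi_r, x=s)
    bending = float(max(bending, 0.0))
    excess = float(max(excess, 0.0))
    tension_part = membrane.tension * excess
    return EnergyBreakdown(
        footprint=bending + tension_part,
        footprint_bending=bending,
        footprint_tension=tension_part,
        footprint_excess_area=excess,
    )


def catenoid_reference(cap: CapGeometry, s_max: float | None = None, n: int = 2001) -> FootprintProfile:
    """Catenoid minimal surface attached smoothly to the dome rim.

    The zero-tension footprint: mean curvature identically zero, so the
    bending energy vanishes and r(s) sin(psi(s)) = r0 sin(alpha) everywhere
    (the catenoid neck constant).  Heights are reported relative to the dome
    rim (a catenoid approaches no planar far field - its height grows
    logarithmically - so the far-field gauge does not exist here).
    """
    r0, alpha = cap.contact_radius, cap.alpha
    if not r0 * math.sin(alpha) > 0:
        raise ValueError("catenoid reference requires a curved dome (alpha > 0)")
    if s_max is None:
        s_max = 4.0 * r0
    c = r0 * math.sin(alpha)

    def rhs(s, y):
        r, h, psi = y
        return [math.cos(psi), -math.sin(psi), -math.sin(psi) / r]

    s_eval = np.linspace(0.0, s_max, n)
    sol = solve_ivp(
        rhs, (0.0, s_max), [r0, 0.0, alpha], t_eval=s_eval, rtol=1e-12, atol=1e-12,
        method="DOP853",
    )
    r, h, psi = sol.y
    h = h - h[0]  # rim gauge
    return FootprintProfile(
        s=s_eval,
        r=r,
        h=h,
        psi=psi,
        H=np.zeros_like(s_eval),
        cap=cap,
        membrane=MembraneSpec(bending_modulus=1.0, tension=0.0),
        compartment=CompartmentSpec.infinite(),
        method="catenoid",
        diagnostics={"neck_constant": c},
    )


@dataclass(frozen=True)
class ParametrizationComparison:
    """Energies and profile deviation of the Monge vs arclength solutions."""

    energy_monge: float
    energy_arclength: float
    relative_difference: float
    max_profile_deviation: float
    larger: str


def compare_parametrizations(
    cap: CapGeometry,
    membrane: MembraneSpec,
    settings: SolverSettings | None = None,
) -> ParametrizationComparison:
    """Compare the small-gradient (Monge) and nonlinear (arclength) solutions.

    The Monge solution systematically overestimates the footprint and its
    energy at high dome curvature; the two agree in the small-slope regime.
    Profile deviation is the max |h_monge(r) - h_arclength(r)| over the
    common radial range.
    """
    if membrane.tension <= 0:
        raise ValueError("comparison requires tension > 0")
    settings = settings or SolverSettings()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallGradientWarning)
        msol = monge_solve(cap, membrane)
        gm_monge = monge_energy(msol, membrane)
    prof = solve_footprint(cap, membrane, settings=settings)
    gm_arc = footprint_energy(prof).footprint
    if cap.alpha == 0.0:
        return ParametrizationComparison(0.0, 0.0, 0.0, 0.0, "equal")
    # compare heights on the arclength solution's radial support, offsetting
    # the Monge profile to the same far-field gauge (both decay to 0)
    r_grid = prof.r
    h_monge = np.asarray(msol.height(r_grid))
    dev = float(np.max(np.abs(h_monge - prof.h)))
    denom = max(abs(gm_arc), 1e-300)
    rel = (gm_monge - gm_arc) / denom
    larger = "monge" if gm_monge >= gm_arc else "arclength"
    return ParametrizationComparison(
        energy_monge=gm_monge,
        energy_arclength=gm_arc,
        relative_difference=rel,
        max_profile_deviation=dev,
        larger=larger,
    )
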
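"""Self-describing CSV output for profiles, geometry reports, and gating curves.

Every file carries its full provenance (all physical parameters, method tag,
solver seed where applicable) in ``# key = value`` header lines, so any
output can be regenerated from its own header.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .arclength import FootprintProfile
from .gating import GatingCurve, _FlatState
from .geometry import CapGeometry, MembraneSpec, dome_bending_energy, dome_tension_energy
from .monge import MongeSolution

__all__ = [
    "write_csv",
    "read_csv",
    "profile_frame",
    "monge_profile_frame",
    "geometry_frame",
    "gating_frame",
]


def write_csv(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a DataFrame as CSV with ``# key = value`` provenance headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key} = {value}\n")
    frame.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_csv`; returns (frame, metadata)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    frame = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return frame, meta


def _membrane_meta(membrane: MembraneSpec) -> dict:
    return {
        "Kb_kBT": membrane.bending_modulus,
        "gamma_kBT_nm2": membrane.tension,
        "temperature_K": membrane.temperature,
    }


def _cap_meta(cap: CapGeometry) -> dict:
    return {"R_nm": cap.radius, "A_nm2": cap.area}


def profile_frame(profile: FootprintProfile) -> tuple[pd.DataFrame, dict]:
    """Tabulate an arclength footprint profile; returns (frame, metadata)."""
    frame = pd.DataFrame(
        {
            "s_nm": profile.s,
            "r_nm": profile.r,
            "h_nm": profile.h,
            "psi_rad": profile.psi,
            "H_per_nm": profile.H,
        }
    )
    comp = profile.compartment
    meta = {
        "method": profile.method,
        **_cap_meta(profile.cap),
        **_membrane_meta(profile.membrane),
        "compartment": comp.mode if comp.mode == "infinite" else f"finite L={comp.arc_length} nm",
    }
    for key in ("max_residual", "seed", "s_max_nm", "n_modes"):
        if key in profile.diagnostics:
            meta[key] = profile.diagnostics[key]
    return frame, meta


def monge_profile_frame(
    sol: MongeSolution, membrane: MembraneSpec, n: int = 500, cutoff_lambdas: float = 10.0
) -> tuple[pd.DataFrame, dict]:
    """Tabulate the small-gradient solution h(r) on a radial grid."""
    r = np.linspace(sol.contact_radius, sol.contact_radius + cutoff_lambdas * sol.decay_length, n)
    frame = pd.DataFrame(
        {
            "r_nm": r,
            "h_nm": sol.height(r),
            "slope": sol.slope(r),
            "meanCurv_per_nm": sol.mean_curvature(r),
        }
    )
    meta = {"method": "monge", **_cap_meta(sol.cap), **_membrane_meta(membrane)}
    return frame, meta


def geometry_frame(caps, membrane: MembraneSpec) -> pd.DataFrame:
    """Geometry + dome-energetics report, one row per cap."""
    rows = []
    for cap in caps:
        rows.append(
            {
                "R_nm": cap.radius,
                "A_nm2": cap.area,
                "alpha_rad": cap.alpha,
                "r0_nm": cap.contact_radius,
                "height_nm": cap.height,
                "projArea_nm2": cap.projected_area,
                "excessArea_nm2": cap.excess_area,
                "GDb_kBT": dome_bending_energy(cap, membrane.bending_modulus),
                "GDgamma_kBT": dome_tension_energy(cap, membrane.tension),
            }
        )
    return pd.DataFrame(rows)


def gating_frame(curve: GatingCurve) -> tuple[pd.DataFrame, dict]:
    """Tabulate a gating curve; returns (frame, metadata)."""
    frame = pd.DataFrame(
        {
            "gamma_kBT_nm2": curve.tensions,
            "dGDb_kBT": curve.delta_dome_bending,
            "dGDgamma_kBT": curve.delta_dome_tension,
            "dGM_kBT": curve.delta_footprint,
            "dG_kBT": curve.delta_total,
            "Po": curve.open_probability,
            "dGdgamma_nm2": curve.dG_dgamma,
            "dPodgamma": curve.dPo_dgamma,
        }
    )
    if curve.dome_only is not None:
        frame["dG_domeonly_kBT"] = curve.dome_only.delta_total
        frame["Po_domeonly"] = curve.dome_only.open_probability
        frame["dPodgamma_domeonly"] = curve.dome_only.dPo_dgamma
    sc = curve.scenario
    comp = sc.compartment
    meta = {
        "Rc_nm": sc.closed.radius,
        "Ro_nm": "inf" if isinstance(sc.open, _FlatState) else sc.open.radius,
        "A_nm2": sc.closed.area,
        **_membrane_meta(sc.membrane),
        "deltaGDP_kBT": sc.delta_gdp,
        "compartment": comp.mode if comp.mode == "infinite" else f"finite L={comp.arc_length} nm",
        "seed": sc.settings.seed,
    }
    return frame, meta
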
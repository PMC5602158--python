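"""Steady lymph flow through the node.

The flow problem is solved in a Darcy (pressure-potential) formulation:
``u = -(k/mu) grad p`` with region-wise permeability and a Starling drainage
term in the porous parenchyma, giving the linear problem

    -div( (k/mu) grad p ) = -J_v(p),    J_v = Lp*(S/V) * (p - p_equiv)

with prescribed volumetric inflow at the afferent inlet, fixed pressure at
the efferent outlet and no-flux walls elsewhere.  The thin SCS sinus is the
lubrication (Hele-Shaw) limit of free channel flow, so it carries its exact
equivalent permeability ``k = h^2/12`` and the capsule/floor wall shear
stress is recovered as ``tau = 6*mu*U/h`` from the gap-averaged speed U
(the plane-Poiseuille relation, exact in that limit); vessel stubs use the
Poiseuille-pipe equivalent ``k = a^2/8``.  At the micrometre scales and
microlitre-per-hour flows of a lymph node the Reynolds number is ~1e-3, the
system is linear, and rescaling the afferent flow rescales the whole field
exactly — which is what the low-flow scenarios exploit.

The finite-volume discretization conserves mass discretely: for every cell,
inflow = outflow + Starling drainage to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import FlowParams, PA_TO_DYN_CM2
from .geometry import Mesh, RegionId, POROUS_REGIONS


class FlowSolverError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Converged steady flow on a mesh."""

    pressure: np.ndarray     # (ncell,) Pa
    face_flux: np.ndarray    # (nface,) um^3/s, positive owner -> neighbour
    bnd_flux: np.ndarray     # (nbnd,) um^3/s, positive outward
    jv: np.ndarray           # (ncell,) 1/s, Starling drainage per volume
    inflow: float            # um^3/s through the afferent inlet
    outflow: float           # um^3/s through the efferent outlet


def cell_permeability(mesh: Mesh, params: FlowParams) -> np.ndarray:
    """Region-wise permeability (um^2) including the Hele-Shaw sinus."""
    p = mesh.params
    k_scs = (params.scs_permeability if params.scs_permeability is not None
             else p.scs_thickness ** 2 / 12.0)
    lut = {
        RegionId.AFFERENT_VESSEL: (p.radius * np.sin(
            np.radians(p.afferent_cap_deg))) ** 2 / 8.0,
        RegionId.EFFERENT_VESSEL: (p.radius * np.sin(
            np.radians(p.efferent_cap_deg))) ** 2 / 8.0,
        RegionId.SCS: k_scs,
        RegionId.BFOLLICLE: params.permeability_bf,
        RegionId.TCELL_AREA: params.permeability_tc,
        RegionId.MEDULLA: params.permeability_medulla,
    }
    out = np.empty(mesh.n_cells)
    for rid, k in lut.items():
        out[mesh.region == int(rid)] = k
    return out


def _face_conductance(mesh: Mesh, kappa: np.ndarray) -> np.ndarray:
    """Harmonic-mean face conductances g (um^3/s per Pa)."""
    ko = kappa[mesh.face_owner]
    kn = kappa[mesh.face_neigh]
    d = mesh.face_dist
    return mesh.face_area / (0.5 * d * (1.0 / ko + 1.0 / kn))


def solve_flow(mesh: Mesh, params: FlowParams) -> FlowField:
    """Solve the steady Darcy/Starling pressure problem."""
    params.validate()
    n = mesh.n_cells
    kappa = cell_permeability(mesh, params) / params.viscosity
    g = _face_conductance(mesh, kappa)

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    o, nb = mesh.face_owner, mesh.face_neigh
    rows += [o, nb, o, nb]
    cols += [o, nb, nb, o]
    vals += [g, g, -g, -g]

    # Starling drainage in porous regions (linear in p)
    porous = np.isin(mesh.region, [int(r) for r in POROUS_REGIONS])
    s_coeff = np.where(porous, params.lp_s_over_v * mesh.volume, 0.0)
    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(s_coeff)
    rhs += s_coeff * params.blood_pressure

    # afferent inlet: prescribed influx, distributed by face area
    inlet = mesh.patch_faces("AFFERENT_INLET")
    q_in = params.afferent_flow_um3_s
    a_in = mesh.bnd_area[inlet]
    rhs[mesh.bnd_cell[inlet]] += q_in * a_in / a_in.sum()

    # efferent outlet: Dirichlet pressure via half-cell conductance
    outlet = mesh.patch_faces("EFFERENT_OUTLET")
    ocell = mesh.bnd_cell[outlet]
    g_out = mesh.bnd_area[outlet] * kappa[ocell] / mesh.bnd_dist[outlet]
    rows.append(ocell); cols.append(ocell); vals.append(g_out)
    rhs[ocell] += g_out * params.outlet_pressure

    mat = sp.csr_matrix((np.concatenate(vals),
                         (np.concatenate(rows), np.concatenate(cols))),
                        shape=(n, n))
    try:
        pressure = spla.spsolve(mat, rhs)
    except Exception as exc:   # pragma: no cover - singular configurations
        raise FlowSolverError(f"pressure solve failed: {exc}") from exc
    if not np.all(np.isfinite(pressure)):
        raise FlowSolverError("pressure solve returned non-finite values")

    face_flux = g * (pressure[o] - pressure[nb])
    bnd_flux = np.zeros(len(mesh.bnd_cell))
    bnd_flux[inlet] = -q_in * a_in / a_in.sum()          # inward
    bnd_flux[outlet] = g_out * (pressure[ocell] - params.outlet_pressure)
    jv = np.where(porous,
                  params.lp_s_over_v * (pressure - params.blood_pressure),
                  0.0)
    return FlowField(pressure=pressure, face_flux=face_flux,
                     bnd_flux=bnd_flux, jv=jv, inflow=q_in,
                     outflow=float(bnd_flux[outlet].sum()))


def mass_imbalance(field: FlowField, mesh: Mesh) -> float:
    """Relative global mass-balance error |in - out - drained| / in."""
    drained = float((field.jv * mesh.volume).sum())
    denom = max(abs(field.inflow), 1e-300)
    return abs(field.inflow - field.outflow - drained) / denom


def wall_shear(field: FlowField, mesh: Mesh,
               params: FlowParams) -> pd.DataFrame:
    """Wall shear stress along the SCS, per (theta, phi) sinus column.

    The sinus is a thin channel of gap h between the capsule and the
    parenchyma floor; in the lubrication limit the wall shear is
    ``tau = 6*mu*U/h`` with U the gap-averaged tangential speed.  U is
    computed from the meridional (theta-direction) volume fluxes through the
    sinus cross-section.  Returns a tidy frame sorted by polar angle with
    columns ``theta_deg``, ``phi_deg``, ``speed_um_s``, ``tau_dyn_cm2``.
    """
    scs = int(RegionId.SCS)
    o, nb = mesh.face_owner, mesh.face_neigh
    mask = (mesh.face_axis == 1) & (mesh.region[o] == scs) \
        & (mesh.region[nb] == scs)
    if not mask.any():
        return pd.DataFrame(columns=["theta_deg", "phi_deg", "speed_um_s",
                                     "tau_dyn_cm2"])
    ijk_o = mesh.cell_ijk[o[mask]]
    key = ijk_o[:, 1] * 10_000 + ijk_o[:, 2]        # (theta-edge, phi) column
    flux = field.face_flux[mask]
    area = mesh.face_area[mask]
    df = pd.DataFrame({
        "key": key,
        "theta": mesh.th_edges[ijk_o[:, 1] + 1],
        "phi": 0.5 * (mesh.ph_edges[ijk_o[:, 2]]
                      + mesh.ph_edges[ijk_o[:, 2] + 1]),
        "flux": flux, "area": area})
    grp = df.groupby("key").agg(theta=("theta", "first"),
                                phi=("phi", "first"),
                                flux=("flux", "sum"), area=("area", "sum"))
    speed = np.abs(grp["flux"]) / grp["area"]
    tau_pa = 6.0 * params.viscosity * speed / mesh.params.scs_thickness
    out = pd.DataFrame({
        "theta_deg": np.degrees(grp["theta"]),
        "phi_deg": np.degrees(grp["phi"]),
        "speed_um_s": speed,
        "tau_dyn_cm2": tau_pa * PA_TO_DYN_CM2,
    }).sort_values(["theta_deg", "phi_deg"]).reset_index(drop=True)
    return out


def poiseuille_wall_shear(mean_speed: float, gap: float,
                          viscosity: float) -> float:
    """Plane-Poiseuille wall shear tau = 6*mu*U/h, in dyn/cm^2."""
    return 6.0 * viscosity * mean_speed / gap * PA_TO_DYN_CM2
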
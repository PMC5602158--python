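"""Steady-state coupled chemokine transport.

Mobile CCL19 and free CCL21 obey steady advection-diffusion-reaction
equations on the frozen lymph-flow field:

    0 = div(D grad C) - div(u C) + q(x) - sinks(C)

Sinks: Starling convective drainage to blood (J_v*C), diffusive vascular
clearance (P_vasc*(S/V)*C, plasma concentration ~0), CCR7-mediated CCL19
destruction (k_eff(R)*C19, the flux committed to the desensitization/
internalization cycle), and ACKR4 scavenging applied as a Robin-type flux
condition on the capsule-ceiling patches.  The immobile species (matrix-bound
CCL21, all receptor states) are slaved to the mobile fields through the local
equilibrium closure in :mod:`lnchemosim.kinetics` — their net local exchange
with the mobile pool vanishes at steady state, so they enter the mobile
equations only through k_eff and the conservation-constrained free-receptor
field.

Discretization: cell-centred finite volumes on the spherical mesh with
first-order upwind advection (positivity-preserving, an M-matrix) and
harmonic-mean diffusive conductances.  The weak nonlinear coupling
(C19 <-> free CCR7 via CCL21b occupancy, ACKR4 two-ligand competition) is
resolved by damped Picard iteration on the assembled linear problems,
converged to a relative field-change tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import (KineticParams, MOLEC_PER_UM3_PER_NM, TransportSettings)
from .flow import FlowField
from .geometry import Mesh, POROUS_REGIONS
from .kinetics import (AckrState, LocalState, ackr4_scavenging,
                       ccr7_consumption_coeff, local_equilibrium)
from .params import FieldMaps


class TransportError(RuntimeError):
    pass


class SingularSteadyStateError(TransportError):
    """The species has sources but no sinks: no steady state exists."""


@dataclass
class TransportProblem:
    mesh: Mesh
    flow: FlowField
    maps: FieldMaps
    kinetics: KineticParams
    settings: TransportSettings = field(default_factory=TransportSettings)

    def __post_init__(self):
        self.settings.validate()
        self.kinetics.validate()
        if len(self.maps.q19) != self.mesh.n_cells:
            raise TransportError("field maps and mesh sizes disagree")


@dataclass
class FieldState:
    """Converged steady state of all species."""

    local: LocalState              # per-cell fields (nM)
    ackr: AckrState                # per ceiling face (molecules/um^2, /s)
    ceiling_faces: np.ndarray      # boundary-face indices of the ceiling
    iterations: int
    residuals: np.ndarray
    converged: bool


def _diffusivity(mesh: Mesh, kin: KineticParams, d_tissue: float):
    d = np.full(mesh.n_cells, d_tissue)
    fluid = ~np.isin(mesh.region, [int(r) for r in POROUS_REGIONS])
    d[fluid] = kin.d_fluid
    return d


class _SpeciesSystem:
    """Frozen-coefficient linear system for one mobile species."""

    def __init__(self, problem: TransportProblem, d_tissue: float,
                 c_in: float, production: np.ndarray):
        mesh, flow = problem.mesh, problem.flow
        n = mesh.n_cells
        self.mesh = mesh
        self.production = production
        self.c_in = c_in

        d_cell = _diffusivity(mesh, problem.kinetics, d_tissue)
        do = d_cell[mesh.face_owner]
        dn = d_cell[mesh.face_neigh]
        g_d = mesh.face_area / (0.5 * mesh.face_dist * (1 / do + 1 / dn))
        f = flow.face_flux
        up = np.maximum(f, 0.0)        # owner -> neighbour
        dn_ = np.maximum(-f, 0.0)      # neighbour -> owner

        o, nb = mesh.face_owner, mesh.face_neigh
        rows = [o, nb, o, nb]
        cols = [o, nb, nb, o]
        vals = [g_d + up, g_d + dn_, -(g_d + dn_), -(g_d + up)]

        # volumetric clearance to blood: convective (J_v) + diffusive (P*S/V)
        porous = np.isin(mesh.region, [int(r) for r in POROUS_REGIONS])
        kin = problem.kinetics
        self.clear_coeff = np.where(
            porous, (flow.jv + kin.p_vasc_um_s * kin.vessel_s_over_v), 0.0) \
            * mesh.volume
        idx = np.arange(n)
        rows.append(idx); cols.append(idx); vals.append(self.clear_coeff)

        # boundary advection: outflow on the diagonal, inflow on the rhs.
        # The prescribed concentration c_in enters only through the afferent
        # inlet; fluid drawn in anywhere else (e.g. an absorbing outlet at
        # very low flow) carries zero chemokine.
        self.rhs0 = production * mesh.volume
        bflux = flow.bnd_flux
        out_coeff = np.zeros(n)
        np.add.at(out_coeff, mesh.bnd_cell, np.maximum(bflux, 0.0))
        rows.append(idx); cols.append(idx); vals.append(out_coeff)
        inlet = mesh.patch_faces("AFFERENT_INLET")
        influx = np.maximum(-bflux[inlet], 0.0)
        np.add.at(self.rhs0, mesh.bnd_cell[inlet], influx * c_in)
        self.advective_out = out_coeff

        self.rows = np.concatenate(rows)
        self.cols = np.concatenate(cols)
        self.vals0 = np.concatenate(vals)
        self.n = n

    def solve(self, extra_diag: np.ndarray) -> np.ndarray:
        """Solve with additional per-cell sink coefficients (um^3/s)."""
        sink_total = (self.clear_coeff.sum() + self.advective_out.sum()
                      + extra_diag.sum())
        source_total = self.rhs0.sum()
        if source_total > 0 and sink_total <= 1e-30 * source_total:
            raise SingularSteadyStateError(
                "species has net production but no advective, clearance, "
                "receptor or scavenging sink: the steady problem is singular")
        idx = np.arange(self.n)
        mat = sp.csr_matrix(
            (np.concatenate([self.vals0, extra_diag]),
             (np.concatenate([self.rows, idx]),
              np.concatenate([self.cols, idx]))),
            shape=(self.n, self.n))
        c = spla.spsolve(mat, self.rhs0)
        if not np.all(np.isfinite(c)):
            raise TransportError("transport solve returned non-finite values")
        cmax = float(np.max(np.abs(c), initial=0.0))
        if cmax > 0 and c.min() < -1e-8 * cmax:
            raise TransportError(
                f"negative concentrations beyond tolerance (min {c.min():g})")
        return np.maximum(c, 0.0)


def solve_steady(problem: TransportProblem) -> FieldState:
    """Picard-iterate the coupled system to its steady state."""
    mesh, kin, st = problem.mesh, problem.kinetics, problem.settings
    maps = problem.maps

    ceil_faces = np.concatenate([mesh.patch_faces("CAPSULE_CEILING_SCS"),
                                 mesh.patch_faces("CAPSULE_CEILING_MEDULLA")])
    ceil_cells = mesh.bnd_cell[ceil_faces]
    ceil_area = mesh.bnd_area[ceil_faces]
    atot = maps.atot_ceiling if st.ackr4_enabled else 0.0

    sys19 = _SpeciesSystem(problem, kin.d_eff_19, st.c_in_19, maps.q19)
    sys21 = _SpeciesSystem(problem, kin.d_eff_21, st.c_in_21, maps.q21)

    c19 = np.zeros(mesh.n_cells)
    c21u = np.zeros(mesh.n_cells)
    local = local_equilibrium(c19, c21u, maps.rtot, maps.mtot, kin)
    r_relaxed = local.r.copy()
    residuals = []
    converged = False
    it = 0
    for it in range(1, st.max_picard + 1):
        ack = ackr4_scavenging(c19[ceil_cells], c21u[ceil_cells],
                               np.full(len(ceil_cells), atot), kin)
        # linearized Robin coefficient: flux = eta_in*s(C)*A_free_prev
        k_lin = kin.eta_in * kin.eta_on / (kin.eta_off + kin.eta_in) \
            * ack.a * ceil_area / MOLEC_PER_UM3_PER_NM
        ack_diag19 = np.zeros(mesh.n_cells)
        ack_diag21 = np.zeros(mesh.n_cells)
        np.add.at(ack_diag19, ceil_cells, k_lin)
        np.add.at(ack_diag21, ceil_cells, k_lin)

        keff = ccr7_consumption_coeff(r_relaxed, kin) * mesh.volume
        c21u_new = sys21.solve(ack_diag21)
        c19_new = sys19.solve(ack_diag19 + keff)

        local = local_equilibrium(c19_new, c21u_new, maps.rtot, maps.mtot,
                                  kin)
        r_relaxed = (1.0 - st.relax) * r_relaxed + st.relax * local.r

        scale = max(float(np.max(c19_new, initial=0.0)),
                    float(np.max(c21u_new, initial=0.0)), 1e-30)
        res = max(float(np.max(np.abs(c19_new - c19), initial=0.0)),
                  float(np.max(np.abs(c21u_new - c21u), initial=0.0))) / scale
        residuals.append(res)
        c19, c21u = c19_new, c21u_new
        if res < st.picard_tol:
            converged = True
            break
    if not converged:
        raise TransportError(
            "Picard iteration stagnated: residual history "
            f"{np.array(residuals[-10:])}")

    local = local_equilibrium(c19, c21u, maps.rtot, maps.mtot, kin)
    ack = ackr4_scavenging(c19[ceil_cells], c21u[ceil_cells],
                           np.full(len(ceil_cells), atot), kin)
    return FieldState(local=local, ackr=ack, ceiling_faces=ceil_faces,
                      iterations=it, residuals=np.asarray(residuals),
                      converged=converged)


def mass_balance_report(state: FieldState,
                        problem: TransportProblem) -> dict[str, dict]:
    """Per-species steady-state ledger (all entries in nM*um^3/s).

    For each chemokine: production + afferent influx must equal the sum of
    CCR7 degradation (identically zero for CCL21), blood clearance, ACKR4
    scavenging and efferent advective export.  ``imbalance`` is the relative
    closure error.
    """
    mesh, kin, st = problem.mesh, problem.kinetics, problem.settings
    flow, maps = problem.flow, problem.maps
    s = state.local
    porous = np.isin(mesh.region, [int(r) for r in POROUS_REGIONS])
    clear_rate = np.where(
        porous, flow.jv + kin.p_vasc_um_s * kin.vessel_s_over_v, 0.0) \
        * mesh.volume
    outlet = mesh.patch_faces("EFFERENT_OUTLET")
    ocell = mesh.bnd_cell[outlet]
    oflux = np.maximum(flow.bnd_flux[outlet], 0.0)
    inlet = mesh.patch_faces("AFFERENT_INLET")
    influx = np.maximum(-flow.bnd_flux[inlet], 0.0).sum()
    ceil_area = mesh.bnd_area[state.ceiling_faces]

    def ledger(c, production, c_in, ackr_flux, ccr7_deg):
        prod = float(production @ mesh.volume) + influx * c_in
        ledger = {
            "production": float(production @ mesh.volume),
            "afferent_influx": influx * c_in,
            "ccr7_degradation": ccr7_deg,
            "blood_clearance": float(clear_rate @ c),
            "ackr4_scavenging": float(
                (ackr_flux * ceil_area).sum() / MOLEC_PER_UM3_PER_NM),
            "efferent_export": float(oflux @ c[ocell]),
        }
        sinks = (ledger["ccr7_degradation"] + ledger["blood_clearance"]
                 + ledger["ackr4_scavenging"] + ledger["efferent_export"])
        ledger["imbalance"] = (prod - sinks) / max(prod, 1e-300)
        return ledger

    keff = ccr7_consumption_coeff(s.r, kin)
    rep19 = ledger(s.c19, maps.q19, st.c_in_19, state.ackr.flux19,
                   float((keff * s.c19) @ mesh.volume))
    rep21 = ledger(s.c21u, maps.q21, st.c_in_21, state.ackr.flux21, 0.0)
    return {"CCL19": rep19, "CCL21": rep21}
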
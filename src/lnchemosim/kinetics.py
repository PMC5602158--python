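"""Local biochemistry of the CCL19/CCL21/CCR7/ACKR4/ECM network.

The network (volumetric species in nM, ACKR4 surface species in
molecules/um^2):

* CCL21u reversibly binds free ECM sites (k1/k2) to form matrix-bound CCL21b.
* CCR7 (R) reversibly binds CCL19, CCL21u and CCL21b with shared on/off rates
  lam_on/lam_off.  Only the CCL19-CCR7 complex (R19) desensitizes (lam_des ->
  Rdes), internalizes (lam_int -> Rint, destroying the carried CCL19) and
  recycles (lam_up -> R).  CCL21 is never degraded by CCR7.
* ACKR4 on SCS-ceiling LECs binds CCL19/CCL21u (eta_on/eta_off), internalizes
  the complex (eta_in, destroying the ligand) and resurfaces slowly (eta_up,
  the limiting step).

The right-hand sides conserve total CCR7 (R + R19 + Rdes + Rint + R21u + R21b
= Rtot), total ECM sites (Mfree + C21b + R21b = Mtot) and total ACKR4
(A + A19 + A21 + Aint = Atot) identically.  The closed-form steady states
defined here serve both as the local closure inside the PDE solver and as
well-mixed oracles for it.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .config import KineticParams


@dataclass
class LocalState:
    """Concentrations of all local species (scalars or per-cell arrays)."""

    c19: np.ndarray        # free CCL19, nM
    c21u: np.ndarray       # free (unbound) CCL21, nM
    c21b: np.ndarray       # matrix-bound CCL21, nM
    mfree: np.ndarray      # free ECM binding sites, nM
    r: np.ndarray          # free CCR7, nM
    r19: np.ndarray        # CCL19-CCR7, nM
    rdes: np.ndarray       # desensitized CCL19-CCR7, nM
    rint: np.ndarray       # internalized CCR7, nM
    r21u: np.ndarray       # CCL21u-CCR7, nM
    r21b: np.ndarray       # CCL21b-CCR7, nM

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def rtot(self) -> np.ndarray:
        """Total CCR7 (conserved)."""
        return self.r + self.r19 + self.rdes + self.rint + self.r21u \
            + self.r21b

    @property
    def mtot(self) -> np.ndarray:
        """Total ECM binding sites (conserved)."""
        return self.mfree + self.c21b + self.r21b


def local_rhs(state: LocalState, params: KineticParams) -> LocalState:
    """Time-derivatives of every local species (reaction terms only).

    Raises ``ValueError`` for negative inputs.  The derivatives of the CCR7
    and ECM conservation sums are identically zero.
    """
    for name, v in state.as_dict().items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"negative concentration in field {name!r}")
    p = params
    s = state
    bind19 = p.lam_on * s.c19 * s.r - p.lam_off * s.r19
    bind21u = p.lam_on * s.c21u * s.r - p.lam_off * s.r21u
    bind21b = p.lam_on * s.c21b * s.r - p.lam_off * s.r21b
    ecm = p.k1_ecm_on * s.c21u * s.mfree - p.k2_ecm_off * s.c21b
    des = p.lam_des * s.r19
    internal = p.lam_int * s.rdes
    recyc = p.lam_up * s.rint
    return LocalState(
        c19=-bind19,
        c21u=-ecm - bind21u,
        c21b=ecm - bind21b,
        # CCR7 binding of C21b keeps the ECM site sequestered, so site release
        # happens only through the k2 off-step inside `ecm`
        mfree=-ecm,
        r=-bind19 - bind21u - bind21b + recyc,
        r19=bind19 - des,
        rdes=des - internal,
        rint=internal - recyc,
        r21u=bind21u,
        r21b=bind21b,
    )


def _chain_coeffs(p: KineticParams) -> tuple[float, float, float]:
    """Steady-state CCL19-chain coefficients: (R19, Rdes, Rint) = c * C19 * R."""
    c1 = p.lam_on / (p.lam_off + p.lam_des)
    c2 = c1 * p.lam_des / p.lam_int
    c3 = c1 * p.lam_des / p.lam_up
    return c1, c2, c3


def ccr7_occupancy_equilibrium(c19, c21u, c21b, rtot,
                               params: KineticParams) -> LocalState:
    """Closed-form steady state of the receptor subsystem at fixed ligands.

    Competitive binding of the three ligands plus the CCL19
    desensitization/internalization/recycling cycle.  Inputs broadcast.
    """
    p = params
    c19, c21u, c21b, rtot = np.broadcast_arrays(
        *map(np.asarray, (c19, c21u, c21b, rtot)))
    c1, c2, c3 = _chain_coeffs(p)
    kd = p.kd_ccr7
    denom = 1.0 + (c21u + c21b) / kd + (c1 + c2 + c3) * c19
    r = rtot / denom
    return LocalState(
        c19=np.array(c19, dtype=float), c21u=np.array(c21u, dtype=float),
        c21b=np.array(c21b, dtype=float),
        mfree=np.zeros_like(r),        # not tracked by this closure
        r=r, r19=c1 * c19 * r, rdes=c2 * c19 * r, rint=c3 * c19 * r,
        r21u=c21u * r / kd, r21b=c21b * r / kd,
    )


def local_equilibrium(c19, c21u, rtot, mtot, params: KineticParams,
                      tol: float = 1e-12, max_iter: int = 500) -> LocalState:
    """Joint steady state of receptors *and* ECM at fixed mobile ligands.

    Solves the coupled fixed point for free CCR7 and free ECM sites under the
    conservation sums, giving the full immobile-species closure used by the
    transport solver.  Vectorized over cells.
    """
    p = params
    c19, c21u, rtot, mtot = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (c19, c21u, rtot, mtot)))
    c1, c2, c3 = _chain_coeffs(p)
    kd = p.kd_ccr7
    beta = p.k1_ecm_on / p.k2_ecm_off      # C21b = beta * C21u * Mfree
    r = np.array(rtot, dtype=float)
    mfree = np.array(mtot, dtype=float)
    for _ in range(max_iter):
        c21b = beta * c21u * mfree
        r_new = rtot / (1.0 + (c21u + c21b) / kd + (c1 + c2 + c3) * c19)
        m_new = mtot / (1.0 + beta * c21u * (1.0 + r_new / kd))
        delta = max(np.max(np.abs(r_new - r), initial=0.0),
                    np.max(np.abs(m_new - mfree), initial=0.0))
        r, mfree = r_new, m_new
        scale = max(float(np.max(rtot, initial=0.0)),
                    float(np.max(mtot, initial=0.0)), 1.0)
        if delta <= tol * scale:
            break
    c21b = beta * c21u * mfree
    return LocalState(
        c19=np.array(c19, dtype=float), c21u=np.array(c21u, dtype=float),
        c21b=c21b, mfree=mfree, r=r,
        r19=c1 * c19 * r, rdes=c2 * c19 * r, rint=c3 * c19 * r,
        r21u=c21u * r / kd, r21b=c21b * r / kd,
    )


def ccr7_consumption_coeff(r, params: KineticParams):
    """First-order CCL19 consumption rate (1/s) at free-CCR7 level ``r``.

    At the receptor steady state the net CCL19 reaction term is
    ``-lam_on*C19*R + lam_off*R19 = -k_eff(R)*C19`` with
    ``k_eff = lam_on*lam_des/(lam_off+lam_des) * R``: CCL19 is destroyed at
    the rate it is committed to the desensitization/internalization cycle.
    """
    p = params
    return p.lam_on * p.lam_des / (p.lam_off + p.lam_des) * np.asarray(r)


# --------------------------------------------------------------------------
# ACKR4 surface scavenging
# --------------------------------------------------------------------------

@dataclass
class AckrState:
    """ACKR4 surface states (molecules/um^2) and scavenging fluxes
    (molecules/um^2/s), per ceiling face."""

    a: np.ndarray          # free surface ACKR4
    a19: np.ndarray        # CCL19-bound
    a21: np.ndarray        # CCL21u-bound
    aint: np.ndarray       # internalized
    flux19: np.ndarray     # CCL19 consumption flux
    flux21: np.ndarray     # CCL21u consumption flux

    @property
    def atot(self) -> np.ndarray:
        return self.a + self.a19 + self.a21 + self.aint


def ackr4_scavenging(c19, c21u, atot, params: KineticParams) -> AckrState:
    """Steady ACKR4 state and per-area consumption fluxes at wall ligand
    concentrations ``c19``/``c21u`` (nM).

    With slow resurfacing (eta_up << eta_in) the internalized pool dominates
    at modest ligand levels, so the combined flux saturates at
    ``eta_in*eta_up/(eta_in+eta_up) * Atot ~= eta_up*Atot`` (resurfacing-
    limited).  ``atot = 0`` gives zero flux (ACKR4 knockout).
    """
    p = params
    c19, c21u, atot = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (c19, c21u, atot)))
    s19 = p.eta_on * c19 / (p.eta_off + p.eta_in)
    s21 = p.eta_on * c21u / (p.eta_off + p.eta_in)
    a = atot / (1.0 + (1.0 + p.eta_in / p.eta_up) * (s19 + s21))
    a19 = s19 * a
    a21 = s21 * a
    return AckrState(a=a, a19=a19, a21=a21,
                     aint=(p.eta_in / p.eta_up) * (a19 + a21),
                     flux19=p.eta_in * a19, flux21=p.eta_in * a21)
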
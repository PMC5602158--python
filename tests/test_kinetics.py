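"""Local reaction network: conservation, closed-form steady states vs
brute-force ODE integration, ACKR4 scavenging properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from lnchemosim import KineticParams
from lnchemosim.kinetics import (LocalState, ackr4_scavenging,
                                 ccr7_consumption_coeff,
                                 ccr7_occupancy_equilibrium,
                                 local_equilibrium, local_rhs)

P = KineticParams()


def random_state(rng, n=32) -> LocalState:
    fields = {k: rng.uniform(0, 100, n) for k in
              ("c19", "c21u", "c21b", "mfree", "r", "r19", "rdes", "rint",
               "r21u", "r21b")}
    return LocalState(**fields)


def integrate_receptor_odes(c19, c21u, mtot, rtot, params, t_end=5e5):
    """Brute-force oracle: integrate the immobile-species ODEs at clamped
    mobile-ligand concentrations until steady state."""
    def rhs(_, y):
        s = LocalState(c19=np.array(c19), c21u=np.array(c21u),
                       c21b=y[0], mfree=y[1], r=y[2], r19=y[3], rdes=y[4],
                       rint=y[5], r21u=y[6], r21b=y[7])
        d = local_rhs(s, params)
        return [d.c21b, d.mfree, d.r, d.r19, d.rdes, d.rint, d.r21u, d.r21b]

    y0 = [0.0, mtot, rtot, 0.0, 0.0, 0.0, 0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-12,
                    atol=1e-12)
    names = ("c21b", "mfree", "r", "r19", "rdes", "rint", "r21u", "r21b")
    return dict(zip(names, sol.y[:, -1]))


class TestConservation:
    def test_receptor_and_site_totals_have_zero_derivative(self, rng):
        s = random_state(rng)
        d = local_rhs(s, P)
        drtot = d.r + d.r19 + d.rdes + d.rint + d.r21u + d.r21b
        dmtot = d.mfree + d.c21b + d.r21b
        scale = max(np.abs(v).max() for v in d.as_dict().values())
        assert np.abs(drtot).max() <= 1e-12 * scale
        assert np.abs(dmtot).max() <= 1e-12 * scale

    def test_total_ccl21_is_conserved_locally(self, rng):
        """CCR7 and ECM neither create nor destroy CCL21: the sum
        c21u + c21b + r21u + r21b has exactly zero time-derivative."""
        d = local_rhs(random_state(rng), P)
        total = d.c21u + d.c21b + d.r21u + d.r21b
        assert np.abs(total).max() <= 1e-12 * 100

    def test_ccl19_destroyed_only_at_internalization(self, rng):
        """d(C19 + R19 + Rdes)/dt = -lam_int * Rdes: ligand committed to the
        desensitized pool is destroyed at the internalization step."""
        s = random_state(rng)
        d = local_rhs(s, P)
        assert np.allclose(d.c19 + d.r19 + d.rdes, -P.lam_int * s.rdes)

    @given(st.lists(st.floats(0.0, 1e4, allow_nan=False,
                              allow_infinity=False),
                    min_size=10, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_conservation_for_arbitrary_admissible_states(self, vals):
        """Receptor/site conservation holds for any nonnegative state, not
        just typical magnitudes (property test)."""
        names = ("c19", "c21u", "c21b", "mfree", "r", "r19", "rdes", "rint",
                 "r21u", "r21b")
        s = LocalState(**{k: np.array([v]) for k, v in zip(names, vals)})
        d = local_rhs(s, P)
        scale = max(1.0, *(float(np.abs(v).max())
                           for v in d.as_dict().values()))
        assert float(np.abs(d.r + d.r19 + d.rdes + d.rint + d.r21u
                            + d.r21b).max()) <= 1e-9 * scale
        assert float(np.abs(d.mfree + d.c21b + d.r21b).max()) <= 1e-9 * scale

    def test_zero_state_is_stationary(self):
        z = LocalState(**{k: np.zeros(3) for k in
                          ("c19", "c21u", "c21b", "mfree", "r", "r19",
                           "rdes", "rint", "r21u", "r21b")})
        d = local_rhs(z, P)
        assert all(np.all(v == 0) for v in d.as_dict().values())

    def test_negative_input_rejected(self):
        z = LocalState(**{k: np.zeros(1) for k in
                          ("c19", "c21u", "c21b", "mfree", "r", "r19",
                           "rdes", "rint", "r21u", "r21b")})
        z.c19 = np.array([-1.0])
        with pytest.raises(ValueError):
            local_rhs(z, P)


class TestEquilibria:
    def test_dissociation_constants(self):
        assert P.kd_ccr7 == pytest.approx(5.0)
        assert P.kd_ackr4 == pytest.approx(4.5)

    def test_simple_binding_without_desensitization(self):
        """With lam_des = 0 and fixed CCL19, R19/R = C19/Kd (mass action)."""
        p0 = dataclasses.replace(P, lam_des=0.0)
        eq = ccr7_occupancy_equilibrium(c19=10.0, c21u=0.0, c21b=0.0,
                                        rtot=100.0, params=p0)
        assert eq.r19 / eq.r == pytest.approx(10.0 / p0.kd_ccr7, rel=1e-12)

    def test_competitive_free_fraction(self):
        """A single saturating ligand leaves Kd/(Kd + C) of CCR7 free: with
        306 nM matrix-bound CCL21 that is ~1.6% ('about 2% available')."""
        eq = ccr7_occupancy_equilibrium(0.0, 0.0, 306.0, 100.0, P)
        frac = float(eq.r / 100.0)
        assert frac == pytest.approx(P.kd_ccr7 / (P.kd_ccr7 + 306.0),
                                     rel=1e-12)
        assert 0.014 < frac < 0.020

    def test_no_ligand_leaves_receptor_free(self):
        eq = ccr7_occupancy_equilibrium(0.0, 0.0, 0.0, 42.0, P)
        assert eq.r == pytest.approx(42.0)

    @pytest.mark.parametrize("c19,c21u,rtot,mtot", [
        (0.5, 5.0, 90.0, 480.0),
        (2.0, 0.3, 250.0, 50.0),
        (0.0, 8.0, 10.0, 1000.0),
        (5.0, 0.0, 120.0, 0.0),
    ])
    def test_closed_form_matches_ode_integration(self, c19, c21u, rtot,
                                                 mtot):
        """The joint receptor/ECM closure agrees with brute-force ODE
        integration of the full local network to 1e-6 relative."""
        oracle = integrate_receptor_odes(c19, c21u, mtot, rtot, P)
        eq = local_equilibrium(c19, c21u, rtot, mtot, P)
        for name, val in oracle.items():
            mine = float(getattr(eq, name))
            assert mine == pytest.approx(val, rel=1e-6, abs=1e-8), name

    def test_consumption_coeff_matches_chain_throughput(self):
        """k_eff*C19 equals the steady internalization flux lam_int*Rdes."""
        eq = local_equilibrium(1.3, 4.0, 150.0, 300.0, P)
        assert ccr7_consumption_coeff(eq.r, P) * 1.3 == pytest.approx(
            float(P.lam_int * eq.rdes), rel=1e-9)


class TestAckr4:
    def test_knockout_gives_zero_flux(self):
        st = ackr4_scavenging(5.0, 5.0, 0.0, P)
        assert st.flux19 == 0.0 and st.flux21 == 0.0

    def test_saturating_flux_is_resurfacing_limited(self):
        """As C -> inf the combined flux tends to
        eta_in*eta_up/(eta_in+eta_up)*Atot ~ eta_up*Atot: ~60 molecules/s
        for a 30,000-receptor LEC."""
        atot = 61.0
        st = ackr4_scavenging(1e9, 0.0, atot, P)
        limit = P.eta_in * P.eta_up / (P.eta_in + P.eta_up) * atot
        assert float(st.flux19) == pytest.approx(limit, rel=1e-6)
        assert limit == pytest.approx(P.eta_up * atot, rel=0.005)
        # per 25-um LEC: ~60 molecules/s
        per_cell = limit * np.pi * 12.5 ** 2
        assert per_cell == pytest.approx(60.0, rel=0.05)

    def test_flux_monotone_in_ligand_and_receptor(self):
        c = np.logspace(-4, 3, 40)
        f = ackr4_scavenging(c, 0.0, 61.0, P).flux19
        assert np.all(np.diff(f) > 0)
        a = np.linspace(0, 100, 30)
        f = ackr4_scavenging(1.0, 1.0, a, P).flux19
        assert np.all(np.diff(f) > 0)

    def test_two_ligand_fluxes_bounded_by_capacity(self, rng):
        c19 = rng.uniform(0, 50, 100)
        c21 = rng.uniform(0, 50, 100)
        st = ackr4_scavenging(c19, c21, 61.0, P)
        assert np.all(st.flux19 + st.flux21 <= P.eta_up * 61.0 + 1e-12)

    def test_conservation_of_surface_states(self):
        st = ackr4_scavenging(3.0, 7.0, 61.0, P)
        assert float(st.atot) == pytest.approx(61.0, rel=1e-12)

    def test_steady_state_matches_ode_integration(self):
        """Surface-state closure agrees with integrating the 4-state ODE."""
        c19, c21, atot = 0.05, 0.02, 61.0
        s19 = P.eta_on * c19
        s21 = P.eta_on * c21

        def rhs(_, y):
            a, a19, a21, aint = y
            return [-(s19 + s21) * a + P.eta_off * (a19 + a21)
                    + P.eta_up * aint,
                    s19 * a - (P.eta_off + P.eta_in) * a19,
                    s21 * a - (P.eta_off + P.eta_in) * a21,
                    P.eta_in * (a19 + a21) - P.eta_up * aint]

        sol = solve_ivp(rhs, (0, 2e4), [atot, 0, 0, 0], method="LSODA",
                        rtol=1e-12, atol=1e-12)
        a, a19, a21, aint = sol.y[:, -1]
        st = ackr4_scavenging(c19, c21, atot, P)
        assert float(st.a) == pytest.approx(a, rel=1e-6)
        assert float(st.flux19) == pytest.approx(P.eta_in * a19, rel=1e-6)
        assert float(st.flux21) == pytest.approx(P.eta_in * a21, rel=1e-6)
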
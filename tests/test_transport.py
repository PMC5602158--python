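"""Steady transport solver: degenerate limits, well-mixed oracle, maximum
principle, linearity, flux-balance ledger."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from lnchemosim import (FlowParams, KineticParams, RegionId,
                        SingularSteadyStateError, TransportProblem,
                        TransportSettings, mass_balance_report, solve_flow,
                        solve_steady)
from lnchemosim.geometry import POROUS_REGIONS
from lnchemosim.kinetics import ccr7_consumption_coeff, local_equilibrium
from lnchemosim.params import FieldMaps


def make_maps(mesh, q19=0.0, q21=0.0, rtot=0.0, mtot=0.0, atot=0.0):
    n = mesh.n_cells
    porous = np.isin(mesh.region, [int(r) for r in POROUS_REGIONS])
    return FieldMaps(
        q19=np.where(porous, q19, 0.0) * np.ones(n),
        q21=np.where(porous, q21, 0.0) * np.ones(n),
        rtot=np.where(porous, rtot, 0.0) * np.ones(n),
        mtot=np.where(porous, mtot, 0.0) * np.ones(n),
        atot_ceiling=atot)


@pytest.fixture(scope="module")
def flow_lowres(mesh_lowres):
    return solve_flow(mesh_lowres, FlowParams())


@pytest.fixture(scope="module")
def no_flow(mesh_lowres):
    return solve_flow(mesh_lowres,
                      FlowParams(afferent_flow_ul_h=0.0, lp_s_over_v=0.0))


class TestDegenerateLimits:
    def test_no_sources_gives_zero_solution(self, mesh_lowres, flow_lowres):
        prob = TransportProblem(mesh_lowres, flow_lowres,
                                make_maps(mesh_lowres), KineticParams(),
                                TransportSettings())
        state = solve_steady(prob)
        assert np.all(state.local.c19 == 0)
        assert np.all(state.local.c21u == 0)
        assert np.all(state.local.c21b == 0)

    def test_production_without_any_sink_is_singular(self, mesh_lowres,
                                                     no_flow):
        """A closed domain with uniform production and no sink has no steady
        state; the solver must detect and report it."""
        kin = dataclasses.replace(KineticParams(), p_vasc_cm_s=0.0)
        prob = TransportProblem(
            mesh_lowres, no_flow, make_maps(mesh_lowres, q21=1e-3),
            kin, TransportSettings(ackr4_enabled=False))
        with pytest.raises(SingularSteadyStateError):
            solve_steady(prob)

    def test_linearity_without_receptors(self, mesh_lowres, flow_lowres):
        """With receptors and ECM removed both chemokine equations are
        linear: doubling production exactly doubles the fields."""
        kin = KineticParams()
        st = TransportSettings(ackr4_enabled=False)
        s1 = solve_steady(TransportProblem(
            mesh_lowres, flow_lowres, make_maps(mesh_lowres, q19=1e-3,
                                                q21=2e-3), kin, st))
        s2 = solve_steady(TransportProblem(
            mesh_lowres, flow_lowres, make_maps(mesh_lowres, q19=2e-3,
                                                q21=4e-3), kin, st))
        assert np.allclose(s2.local.c19, 2 * s1.local.c19, rtol=1e-9)
        assert np.allclose(s2.local.c21u, 2 * s1.local.c21u, rtol=1e-9)


class TestMaximumPrinciple:
    def test_pure_advection_diffusion_bounded_by_inlet(self, mesh_lowres):
        """No reactions, no clearance: the solution must lie between the
        boundary extremes 0 and c_in (discrete maximum principle of the
        upwind M-matrix scheme)."""
        flow = solve_flow(mesh_lowres, FlowParams(lp_s_over_v=0.0))
        kin = dataclasses.replace(KineticParams(), p_vasc_cm_s=0.0)
        st = TransportSettings(c_in_19=5.0, c_in_21=5.0, ackr4_enabled=False)
        state = solve_steady(TransportProblem(
            mesh_lowres, flow, make_maps(mesh_lowres), kin, st))
        for c in (state.local.c19, state.local.c21u):
            assert c.min() >= -1e-12
            assert c.max() <= 5.0 + 1e-9
            assert c.max() > 4.0      # inlet value propagates into the node


class TestWellMixedLimit:
    def test_matches_zero_dimensional_oracle(self, mesh_lowres, no_flow):
        """With a huge diffusivity the PDE solution collapses to the
        well-mixed balance; the 0-D steady state (scalar root-find on the
        reaction closure) is an independent oracle."""
        q19, q21 = 5e-4, 2e-3
        rtot, mtot = 100.0, 400.0
        kin = dataclasses.replace(KineticParams(), d_eff_19=1e6,
                                  d_eff_21=1e6, d_fluid=1e6)
        maps = make_maps(mesh_lowres, q19=q19, q21=q21, rtot=rtot, mtot=mtot)
        prob = TransportProblem(mesh_lowres, no_flow, maps, kin,
                                TransportSettings(ackr4_enabled=False))
        state = solve_steady(prob)

        porous = np.isin(mesh_lowres.region, [int(r) for r in POROUS_REGIONS])
        v_por = mesh_lowres.volume[porous].sum()
        v_tot = mesh_lowres.volume.sum()
        cl = kin.p_vasc_um_s * kin.vessel_s_over_v       # 1/s, porous only
        # 0-D balances: production over the whole domain, sinks in porous
        c21_star = q21 * v_por / (cl * v_por)

        def c19_residual(c19):
            eq = local_equilibrium(c19, c21_star, rtot, mtot,
                                   KineticParams())
            keff = float(ccr7_consumption_coeff(eq.r, KineticParams()))
            return q19 * v_por - (cl + keff) * c19 * v_por

        c19_star = brentq(c19_residual, 0.0, 1e3, xtol=1e-12)
        c19_avg = float(state.local.c19[porous].mean())
        c21_avg = float(state.local.c21u[porous].mean())
        assert c21_avg == pytest.approx(c21_star, rel=0.01)
        assert c19_avg == pytest.approx(c19_star, rel=0.01)


class TestConservation:
    def test_receptor_and_site_sums_hold_per_cell(self, baseline_lowres):
        rec = baseline_lowres
        s = rec.state.local
        rtot = s.r + s.r19 + s.rdes + s.rint + s.r21u + s.r21b
        mtot = s.mfree + s.c21b + s.r21b
        assert np.allclose(rtot, rec.problem.maps.rtot, rtol=1e-9,
                           atol=1e-9)
        assert np.allclose(mtot, rec.problem.maps.mtot, rtol=1e-9,
                           atol=1e-9)

    def test_ledger_closes_below_half_percent(self, baseline_lowres):
        rep = mass_balance_report(baseline_lowres.state,
                                  baseline_lowres.problem)
        for species in ("CCL19", "CCL21"):
            assert abs(rep[species]["imbalance"]) < 0.005

    def test_ccr7_never_degrades_ccl21(self, baseline_lowres):
        rep = mass_balance_report(baseline_lowres.state,
                                  baseline_lowres.problem)
        assert rep["CCL21"]["ccr7_degradation"] == 0.0

    def test_removing_ackr4_raises_efferent_export(self, scenario):
        wt = scenario("BASELINE_WT")
        ko = scenario("LN_ACKR4_KO")
        rep_wt = mass_balance_report(wt.state, wt.problem)
        rep_ko = mass_balance_report(ko.state, ko.problem)
        for sp in ("CCL19", "CCL21"):
            assert rep_ko[sp]["efferent_export"] > rep_wt[sp][
                "efferent_export"]
            assert rep_ko[sp]["ackr4_scavenging"] == 0.0

    def test_low_flow_accumulates_in_scs_and_medulla(self, scenario):
        wt = scenario("BASELINE_WT")
        lf = scenario("LOW_FLOW")
        scs = wt.mesh.region == int(RegionId.SCS)
        med = wt.mesh.region == int(RegionId.MEDULLA)
        # marked accumulation of free CCL21 in the sinus; milder in medulla
        assert lf.state.local.c21u[scs].mean() > \
            5.0 * wt.state.local.c21u[scs].mean()
        for sel in (scs, med):
            assert lf.state.local.c21u[sel].mean() > \
                wt.state.local.c21u[sel].mean()
            assert lf.state.local.c19[sel].mean() > \
                wt.state.local.c19[sel].mean()

    def test_solution_nonnegative_everywhere(self, baseline_lowres):
        s = baseline_lowres.state.local
        for name, v in s.as_dict().items():
            assert np.all(v >= 0), name
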
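# lnchemosim

Steady-state simulation of CCL19/CCL21 chemokine transport and gradient
formation in an idealized mouse popliteal lymph node (PLN).

Leukocyte navigation inside lymph nodes is steered by the chemokine receptor
CCR7 and its ligands CCL19 and CCL21. CCL21 carries a highly charged C
terminus that binds extracellular matrix (ECM), so it exists in a mobile
(CCL21u) and a matrix-bound (CCL21b) form; CCL19 does not bind matrix but is
the only ligand that desensitizes and internalizes CCR7. Both ligands are
scavenged by the atypical receptor ACKR4 on the ceiling of the subcapsular
sinus (SCS). This package couples all of these processes to lymph flow
through the node and asks where chemokine gradients form, how steep they
are, and which biological parameters control them. It is aimed at
quantitative immunologists and modellers who want a desk-scale, fully
scriptable replacement for a commercial-CFD workflow.

## Model

On an idealized quarter-symmetric PLN (1 mm sphere; 10 μm SCS shell;
afferent/efferent vessels on the polar axis; spherical B-cell follicles whose
BF–TC border sits 188 μm below the SCS floor; medulla in the lower pole):

* **Lymph flow** — Darcy flow `u = −(k/μ)∇p` with the thin sinus in its
  lubrication (Hele-Shaw) limit `k = h²/12`, porous parenchyma, Starling
  drainage to blood vessels `J_v = L_p(S/V)(p − p_eq)`, prescribed afferent
  inflow and fixed efferent pressure. SCS wall shear is recovered as
  `τ = 6μU/h`.
* **Transport** — for the mobile species C ∈ {CCL19, CCL21u}:
  `0 = ∇·(D_eff∇C) − ∇·(uC) + q(x) − (J_v + P_vasc S/V)C − k_eff(R)·C₁₉`,
  with zero-concentration inlet lymph, advective outflow, and the ACKR4
  scavenging flux `η_in·A_bound(C)` as a Robin condition on the capsule
  ceiling.
* **Local biochemistry** — mass-action network
  `CCL21u + M ⇌ CCL21b` (k₁, k₂), competitive CCR7 binding of CCL19, CCL21u
  and CCL21b (λ_on, λ_off; K_d = 5 nM), the CCL19-specific
  desensitization/internalization/recycling cycle (λ_des, λ_int, λ_up), and
  the ACKR4 bind–internalize–resurface cycle (η_on, η_off, η_in, η_up;
  K_d = 4.5 nM, resurfacing-limited). Immobile species are held at their
  closed-form local steady state; receptor and matrix-site totals are
  conserved identically.
* **Parameter maps** — regional production rates, CCR7 and ECM-site
  concentrations estimated from a cell census:
  `value_j = Σ_k N_k·P_k,j·EV_X,k·X_max / (N_A·Vol_j)`.
* **Analysis** — concentration profiles along two probe lines (through the
  interfollicular region, and through a follicle across the BF–TC border),
  resampled at 4.5 μm, low-pass filtered, differentiated; concentration
  differences across 9/18/36 μm cells; whole-node totals and efferent
  concentrations.
* **Sensitivity** — Latin-hypercube variation of seven inputs with partial
  rank correlation coefficients (PRCC) and a +/− significance table.

Discretization is cell-centred finite volumes on a structured spherical
mesh with first-order upwind advection; the weakly nonlinear coupling is
solved by damped Picard iteration.

## Worked example

```python
from lnchemosim import run_scenario

record = run_scenario("BASELINE_WT")
s = record.summary
print(f"max CCL21b  {s['max_c21b']:.0f} nM")
print(f"max CCL19   {s['max_c19']:.2f} nM")
print(f"max CCL21u  {s['max_c21u']:.2f} nM")
print(f"IFR CCL21b gradient at SCS floor  {s['ifr_slope_c21b']:.2f} nM/um")
print(f"BF-TC CCL21b slope (25 um window) {s['bftc_slope_c21b']:.1f} nM/um")
print(f"free CCR7 in T zone  {s['pct_ccr7_free_tc']:.1f} %")
```

prints (default mesh, ~17k cells, ~30 s on one core):

```
max CCL21b  282 nM
max CCL19   0.73 nM
max CCL21u  5.28 nM
IFR CCL21b gradient at SCS floor  3.31 nM/um
BF-TC CCL21b slope (25 um window) 9.7 nM/um
free CCR7 in T zone  1.7 %
```

i.e. matrix-bound CCL21 dominates the node (~280 nM peaking in the T-zone
centre, two orders of magnitude above free CCL19/CCL21u), forms a steep
gradient immediately under the SCS floor and a ~10 nM/μm step across the
follicle border, and occupies ~98% of T-zone CCR7.

The same pipeline runs knockout and flow scenarios
(`LN_ACKR4_KO`, `SKIN_ACKR4_KO`, `GLOBAL_ACKR4_KO`, `LOW_FLOW`,
`LOW_FLOW_NO_ACKR4`) and exposes a CLI:

```sh
lnchemosim scenario --name BASELINE_WT --out runs/wt/     # VTK + CSV + JSON
lnchemosim compare --a BASELINE_WT --b LN_ACKR4_KO
lnchemosim pva --samples 100 --seed 1 --out runs/pva/
```

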
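# Methods

This note documents the model implemented in `lnchemosim`: its equations and
assumptions, the provenance and defaults of every parameter group, the
numerical choices, and what the synthetic setting does and does not capture.

## Geometry

The popliteal lymph node is idealized as a 1 mm sphere. The outer 10 μm
shell is the subcapsular sinus (SCS), a lymph-filled channel between the
capsule ceiling and the parenchyma floor. Afferent and efferent lymphatic
vessels are short radial stubs over polar caps (half-angles 7.5° and 11.25°)
so that lymph enters the sinus at the north pole, sweeps around the shell
and through the parenchyma, and collects at the south pole. The medulla
occupies polar angles beyond 110°; the rest of the parenchyma is T-cell area
(TC) except for spherical B-cell follicles (BF).

Only a quarter of the node is meshed, with symmetry conditions on the two
coordinate planes. Follicles default to two spheres of radius 150 μm whose
centres sit 38 μm below the floor *on the symmetry planes* (azimuths 0° and
90°), so the full node carries four spherical follicles and the BF–TC border
along a radial line through a follicle centre lies at the canonical 188 μm
below the SCS floor. Placing the follicles on the planes leaves the
interfollicular (IFR) probe line at azimuth 45° more than 100 μm clear of
follicle tissue; follicles closer to the probe line contaminate the
interpolated IFR profile with follicle-level free CCR7 and visibly suppress
the near-floor CCL21b gradient. Follicle count, radius and vessel-cap sizes
are not constrained by published geometry; they are documented defaults.

The mesh is a structured spherical grid (r, θ, φ). Cell volumes and face
areas use the exact spherical metric, so the meshed volume equals the
analytic quarter-node volume to round-off. The radial spacing is graded:
~33 μm in the core (at the default resolution of 3 cells/100 μm), ~8 μm in
30-μm bands straddling the BF–TC border sphere and under the SCS floor, two
cells across the sinus shell, and three cells along each vessel stub.
Region tags come from the constructive-solid-geometry definition; follicle
cells are tagged by a half-volume rule (4×4×4 midpoint subsample per cell)
followed by a deterministic volume-matching sweep that flips near-half
boundary cells until the tagged volume equals the second-order quadrature
volume — a plain centroid test converges too slowly and is one-sided where a
follicle surface meets a symmetry plane.

## Lymph flow

Flow is solved in a Darcy (pressure-potential) formulation,
`u = −(k/μ)∇p`, `∇·u = −J_v`, with region-wise permeability. The thin sinus
is the lubrication limit of free channel flow, so it carries its exact
Hele-Shaw equivalent permeability `k = h²/12` (8.3 μm² for h = 10 μm) and
the wall shear stress is recovered from the gap-averaged speed as
`τ = 6μU/h`, the plane-Poiseuille relation, which is exact in that limit.
Vessel stubs use the Poiseuille-pipe equivalent `k = a²/8`. At these scales
(lengths ≲ 1 mm, speeds ≲ 1 mm/s) the Reynolds number is ~10⁻³, inertia is
negligible, and the reduction from Stokes–Brinkman to Darcy with lubrication
closures preserves the quantities the model consumes: the flux partition
between the peripheral sinus path and parenchymal percolation, the Starling
drainage field, the sinus shear profile, and exact linearity in the afferent
flow (the 1%-flow scenario is a rescaling up to the affine Starling offset).
What it gives up is the sub-gap velocity profile and momentum boundary
layers at region interfaces, which the transport model does not resolve
anyway.

Starling drainage to blood vessels acts in the porous regions:
`J_v = L_p(S/V)·(p − p_eq)` with an equivalent pressure `p_eq = −30 Pa`
folding the hydrostatic and osmotic terms into one constant chosen so that
a few percent of afferent lymph is absorbed at baseline (J_v > 0
everywhere). `L_p·S/V = 6×10⁻⁶ Pa⁻¹s⁻¹` and the permeabilities
(TC/BF 0.01 μm², medulla 0.05 μm²) are implementer defaults of
literature magnitude. The default afferent flow, 9.4 μL/h for the whole
node, was calibrated once so that the baseline SCS floor shear spans the
published range — above 5 dyn/cm² near the afferent entry, below 1 dyn/cm²
approaching the medulla — and then frozen. The finite-volume discretization
conserves mass per cell to round-off.

## Chemokine network

Volumetric species (nM): free CCL19 (C19), free CCL21 (C21u), matrix-bound
CCL21 (C21b), free ECM sites (Mfree), and the receptor states R (free CCR7),
R·CCL19, R_des, R_int, R·CCL21u, R·CCL21b. Rate constants are published
measurements: ECM binding k₁ = 9.3×10⁻⁵ nM⁻¹s⁻¹, k₂ = 1.2×10⁻⁴ s⁻¹
(CCL21–perlecan); CCR7 λ_on = 10⁻³ nM⁻¹s⁻¹, λ_off = 5×10⁻³ s⁻¹ (K_d = 5 nM,
shared by all three ligands); desensitization λ_des = 3×10⁻³ s⁻¹,
internalization λ_int = 5×10⁻⁴ s⁻¹, recycling λ_up = 3.75×10⁻⁴ s⁻¹ (the
CCL19-specific cycle; CCL21 binds but never desensitizes or internalizes
CCR7). Model conventions the data do not fix, chosen for conservation and
testability: the desensitized complex retains its CCL19, which is destroyed
at the internalization step; a CCR7-bound C21b still sequesters its matrix
site (conservation `Mfree + C21b + R21b = Mtot`); desensitized receptor does
not rebind ligand (minimal chain R → R19 → R_des → R_int → R).

ACKR4 lives on SCS-ceiling lymphatic endothelial cells (LECs) as a surface
species (molecules/μm²) with the bind–internalize–resurface cycle
η_on = 0.5 nM⁻¹s⁻¹, η_off = 2.25 s⁻¹ (K_d = 4.5 nM), η_in = 1 s⁻¹,
η_up = 2×10⁻³ s⁻¹. Because resurfacing is limiting, the internalized pool
dominates at sub-nanomolar ligand already: the steady scavenging flux
saturates at `η_in η_up/(η_in+η_up)·A_tot ≈ η_up·A_tot` (≈ 60 molecules/s
per 30,000-receptor LEC) with a half-maximal concentration of
`(η_off+η_in)/(η_on(1+η_in/η_up)) ≈ 0.013 nM` — the ceiling operates at
capacity under all baseline conditions. A_tot defaults to 30,000 receptors
per 25-μm LEC footprint ≈ 61 molecules/μm², applied identically on the SCS
and medullary capsule.

All closed-form steady states (competitive CCR7 occupancy with the CCL19
cycle, the joint receptor/ECM closure, the ACKR4 surface closure) are
verified against brute-force ODE integration in the test suite; receptor,
matrix-site and ACKR4 totals are conserved identically by the right-hand
sides.

## Parameter maps from the cell census

Regional production rates and receptor/site concentrations follow the
continuum estimate `value_j = Σ_k N_k·P_k,j·EV_X,k·X_max/(N_A·Vol_j)`:
total cells of type k, fraction resident in region j, normalized expression
value, per-cell maximum, Avogadro, region volume. Cell types are
homogeneously distributed within regions. Per-cell maxima: 30,000 CCR7,
30,000 ACKR4, 10⁶ ECM binding sites. CCR7 is forced to zero in the vessels
and sinus (lymph carries no CCR7⁺ surfaces in this model).

The census table (counts, region fractions, expression values) is an
editable default shipped in `config.py` and loadable from TSV. Counts are
literature-scale (10⁶ T cells, 2×10⁶ B cells, 1.2×10⁵ fibroblastic reticular
cells, …); expression values encode the dominant patterns (T cells EV_CCR7
= 0.5; B cells 0.07; FRCs produce CCL19/CCL21 and carry the ECM sites; LECs
carry ACKR4). The per-cell production maxima (CCL19 1.95, CCL21 7.6
molecules/cell/s), the effective diffusivities (D_eff 25 μm²/s for CCL19,
15 μm²/s for CCL21 in tissue; 140 μm²/s in free lymph) and the B-cell CCR7
expression were calibrated **once** so that the baseline reproduces the
wild-type magnitudes (CCL21b/CCL19/CCL21u maxima ≈ 306/0.9/5.2 nM, IFR
CCL21b gradient ≈ 3.7 nM/μm, border slope ≈ 10 nM/μm over 25 μm,
receptor-complex peaks 44.2/1.4 nM, ~2% free CCR7 in the T zone) and then
frozen; they are not revisited per scenario. The distinct diffusivity
defaults reflect CCL19's smaller size and absence of matrix affinity —
identical values cannot simultaneously reconcile the CCL19 maximum and
border slope with the CCL19–CCR7 complex peak. Blood clearance uses the
published vascular permeability 5×10⁻⁷ cm/s with a default vessel surface
density S/V = 8×10⁻³ μm⁻¹, plus convective loss at the Starling rate J_v
with no solute reflection (plasma chemokine ≈ 0).

## Steady transport solver

Finite volumes on the spherical mesh; harmonic-mean diffusive conductances;
first-order upwind advection using the conservative face fluxes of the flow
solve. Upwinding makes each species matrix an M-matrix, so concentrations
stay nonnegative and a discrete maximum principle holds for the
reaction-free sub-problem — positivity matters more here than formal order
because the steepest structures (the floor boundary layer) are also where
the biology is read off. The prescribed inlet concentration enters through
the afferent faces only; outflow is purely advective; all other boundaries
are zero-flux except the ceiling, where the linearized ACKR4 flux is a
Robin coefficient refreshed each outer iteration.

At steady state the immobile species exchange no net mass with the mobile
pool, so the C21u equation is linear and C19 couples to the rest only
through the free-receptor field R(x) (consumption `k_eff = λ_on λ_des /
(λ_off+λ_des) · R`). The outer loop is damped Picard iteration (relaxation
0.7 on R) alternating sparse direct solves of the two species systems with
the local closure and the ACKR4 boundary update, converged when the maximum
relative field change drops below 10⁻⁸; the baseline needs ~18 iterations.
A steady problem with sources but no sink of any kind (no outflow,
clearance, receptors or scavenging) is singular and is detected and
reported rather than solved. A per-species ledger (production + afferent
influx = CCR7 degradation + blood clearance + ACKR4 scavenging + efferent
export) closes to round-off; the CCR7 entry for CCL21 is identically zero.

At 1% flow the fixed Starling drainage exceeds the afferent supply, the
advective outflow vanishes and the outlet draws clean fluid inward; the
"efferent concentration" is then reported as the mean in the
efferent-vessel lumen (reached by diffusion) instead of the flow-weighted
outlet mean.

## Gradient analysis

Profiles are sampled by trilinear interpolation at 4.5-μm spacing along two
radial probe lines starting on the capsule ceiling (the first 10 μm lie in
the sinus): IFR_ARROW between the follicles, BFTC_ARROW through a follicle
centre. A zero-phase 5-point (±9 μm) moving average — linear,
constant-preserving, window configurable — precedes central-difference
gradients; single-number slopes use either the signed maximum-magnitude
gradient in the first 20 μm below the floor (IFR) or a least-squares fit
over a 25-μm window straddling the border (BF–TC), both documented choices
where the published analysis does not state its estimator. Note that
matrix-bound CCL21 is discontinuous at the floor (no matrix in the sinus);
within ±9 μm of the floor the filter mixes sinus zeros into the tissue
profile, which inflates the near-floor "gradient" when the tissue
concentration right at the floor is high (the low-flow scenarios). In-tissue
comparisons for those scenarios therefore read the gradient below the
smeared zone. Across-cell differences are `C(x+d) − C(x)` for d = 9/18/36 μm
with percentage normalization by the trailing-edge concentration, flagged
undefined where that is zero.

## Sensitivity analysis

Seven inputs vary as multiplicative factors on baseline: CCL19 and CCL21
production, CCR7 and ACKR4 per cell, matrix sites, and the two effective
diffusivities. Bounds default to log-uniform ×0.2–×5 (the published
analysis does not print its bounds; these are documented defaults). Latin
hypercube sampling comes from `scipy.stats.qmc` with a fixed seed; the flow
field is independent of all seven inputs and is solved once per ensemble.
Outputs: IFR and border slopes of CCL19 and CCL21b, whole-node CCL19 and
CCL21 (u+b) totals, efferent concentrations. PRCC is computed on
rank-transformed data with the other six inputs linearly partialled out of
both sides; significance from `t = r√((n−2−p)/(1−r²))` with n−2−p degrees of
freedom, rendered as +/− per decade of p below 0.01. The implementation is
cross-checked against an independent partial-correlation routine in the
tests. Ensembles run at a reduced mesh resolution (2 cells/100 μm, ~6k
cells) to keep 100 samples at desk scale; the sign table is asserted at that
resolution with a 30-sample smoke version in the test suite.

## What the synthetic setting shows — and does not

The geometry, census and calibrated defaults define a *self-consistent
idealized node*, not a reconstruction of any measured node. Passing tests
demonstrate that the coupled mechanisms — flow-dominated sinus clearance,
matrix buffering, receptor-mediated CCL19 destruction, saturable ceiling
scavenging — reproduce the published steady-state picture and its knockout
and low-flow logic on this idealization. They do not validate the absolute
parameter values, intra-region heterogeneity, cell migration feedback
(cells are static sources/sinks), transient gradient establishment, or
anatomical irregularity of real nodes.

Known limitations:

* First-order upwinding smears steep fronts at coarse resolution; the
  refined bands at the floor and border keep the headline slopes within a
  few percent between the two finest refinement levels, but absolute slope
  values carry O(h) discretization bias.
* The ACKR4 ceiling operates at capacity at baseline, removing a fixed
  ~20% of CCL21 production. Intranodal profiles still shift by less than
  1% (relative L2) when it is knocked out, but one published sensitivity
  pattern is not reproduced: in the joint ensemble the positive effect of
  effective diffusivity on *efferent* concentrations (verified
  one-at-a-time in this model: D ×0.3→×3 raises efferent CCL19/CCL21 by
  ~25%/12%) is masked in partial rank correlation by the interaction with
  ceiling scavenging, and the corresponding test is deliberately left
  failing as a documented discrepancy.
* The Starling drainage keeps its baseline driving pressure in the
  low-flow scenarios; a poroelastic or pressure-regulated exchange model
  would attenuate absorption as interstitial pressure falls.
* Lymph-borne cellular traffic, DC-mediated CCL21 cleavage,
  shear-dependent LEC signalling and chemotaxis itself are out of scope.
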
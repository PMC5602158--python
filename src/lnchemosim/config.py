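"""Configuration containers and defaults for the lymph-node chemokine model.

Unit conventions (used consistently across the package):

* lengths in micrometres (um), areas um^2, volumes um^3
* time in seconds
* pressure in pascal (Pa); dynamic viscosity in Pa*s
* volumetric species concentrations in nanomolar (nM)
* surface species densities in molecules/um^2
* wall shear stress is reported in dyn/cm^2 (1 Pa = 10 dyn/cm^2)

All defaults describing the popliteal lymph node (PLN) live here.  Rate
constants of the CCL19/CCL21/CCR7/ACKR4 network are experimentally measured
literature values; geometry, flow and cell-census entries that have no
published value are implementer defaults, chosen once so that the baseline
simulation reproduces the magnitudes of the wild-type node, and frozen
(see docs/methods.md for the provenance of every default).
"""

from __future__ import annotations

import dataclasses
import io
import tomllib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# physical constants / unit conversions
# --------------------------------------------------------------------------

AVOGADRO = 6.02214076e23  # 1/mol

#: molecules per um^3 corresponding to a 1 nM solution
#: (1e-9 mol/L * N_A / 1e15 um^3/L)
MOLEC_PER_UM3_PER_NM = 1e-9 * AVOGADRO / 1e15  # ~0.602

#: conversion factor: Pa -> dyn/cm^2
PA_TO_DYN_CM2 = 10.0

#: conversion factor: uL/h -> um^3/s
UL_PER_H_TO_UM3_PER_S = 1e9 / 3600.0


class ConfigurationError(ValueError):
    """Raised when a configuration block violates a documented constraint."""


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass
class GeometryParams:
    """Idealized quarter-symmetric PLN geometry.

    The node is a sphere (diameter ``node_diameter``) whose outer shell of
    thickness ``scs_thickness`` is the subcapsular sinus (SCS).  Afferent and
    efferent lymphatic vessels are short radial stubs on the polar axis,
    entering the capsule over polar caps of half-angle ``afferent_cap_deg`` /
    ``efferent_cap_deg``.  The medulla occupies polar angles beyond
    ``medulla_polar_deg``; B-cell follicles are spheres of radius
    ``follicle_radius`` centred ``follicle_center_depth`` below the SCS floor,
    so the BF-TC border along a radial line through a follicle centre sits at
    ``follicle_center_depth + follicle_radius`` um below the floor.
    """

    node_diameter: float = 1000.0          # um
    scs_thickness: float = 10.0            # um
    bf_tc_border_depth: float = 188.0      # um below the SCS floor
    n_follicles_per_quarter: int = 2
    follicle_radius: float = 150.0         # um
    follicle_polar_deg: float = 50.0       # polar angle of follicle centres
    follicle_azimuth_deg: tuple[float, ...] = (0.0, 90.0)
    afferent_cap_deg: float = 7.5          # polar half-angle of Af opening
    efferent_cap_deg: float = 11.25        # polar half-angle of Ef opening
    medulla_polar_deg: float = 110.0       # medulla begins at this polar angle
    vessel_length: float = 60.0            # radial extent of vessel stubs, um
    ifr_azimuth_deg: float = 45.0          # azimuth of the IFR probe line

    @property
    def radius(self) -> float:
        return self.node_diameter / 2.0

    @property
    def floor_radius(self) -> float:
        """Radius of the SCS floor (parenchyma surface)."""
        return self.radius - self.scs_thickness

    @property
    def follicle_center_depth(self) -> float:
        """Depth of follicle centres below the SCS floor (um)."""
        return self.bf_tc_border_depth - self.follicle_radius

    def validate(self) -> None:
        if self.node_diameter <= 0:
            raise ConfigurationError("node_diameter must be positive")
        if not (0 < self.scs_thickness < self.node_diameter / 10):
            raise ConfigurationError(
                "scs_thickness must be positive and below node_diameter/10")
        if not (0 < self.bf_tc_border_depth < self.node_diameter / 2):
            raise ConfigurationError(
                "bf_tc_border_depth must lie within the node radius")
        if self.follicle_center_depth < 0:
            raise ConfigurationError(
                "follicle_radius exceeds bf_tc_border_depth: the BF-TC border "
                "would sit above the SCS floor")
        if self.n_follicles_per_quarter > len(self.follicle_azimuth_deg):
            raise ConfigurationError(
                "need one follicle_azimuth_deg entry per follicle")
        # follicles must not reach the medulla or the vessel caps
        ang_extent = np.degrees(self.follicle_radius / self.floor_radius)
        if self.follicle_polar_deg + ang_extent >= self.medulla_polar_deg:
            raise ConfigurationError("follicles overlap the medulla")
        if self.follicle_polar_deg - ang_extent <= self.afferent_cap_deg:
            raise ConfigurationError("follicles overlap the afferent vessel")
        # follicle-follicle overlap
        centers = self.follicle_centers()
        for a in range(len(centers)):
            for b in range(a + 1, len(centers)):
                d = np.linalg.norm(centers[a] - centers[b])
                if d < 2 * self.follicle_radius:
                    raise ConfigurationError(
                        f"follicles {a} and {b} overlap (centre distance "
                        f"{d:.0f} um < {2 * self.follicle_radius:.0f} um)")

    def follicle_centers(self) -> np.ndarray:
        """Cartesian centres of the follicles, shape (n, 3)."""
        rc = self.floor_radius - self.follicle_center_depth
        th = np.radians(self.follicle_polar_deg)
        out = []
        for i in range(self.n_follicles_per_quarter):
            ph = np.radians(self.follicle_azimuth_deg[i])
            out.append([rc * np.sin(th) * np.cos(ph),
                        rc * np.sin(th) * np.sin(ph),
                        rc * np.cos(th)])
        return np.asarray(out, dtype=float)


# --------------------------------------------------------------------------
# lymph flow
# --------------------------------------------------------------------------

@dataclass
class FlowParams:
    """Steady lymph-flow parameters (Darcy formulation, see docs/methods.md).

    ``afferent_flow_ul_h`` is the whole-node afferent lymph flow; a quarter of
    it enters the quarter-symmetric computational domain.  The SCS sinus is a
    thin channel and carries its lubrication-limit permeability h^2/12 unless
    ``scs_permeability`` is set explicitly.  The Starling term drains lymph to
    blood vessels in the porous regions: J_v = Lp*(S/V)*max(p - p_equiv, 0)
    with ``p_equiv = blood_pressure - osmotic_reflection * osmotic_pressure``
    an effective (usually negative) equivalent pressure so that J_v > 0 at
    baseline.
    """

    afferent_flow_ul_h: float = 9.4        # uL/h, whole node
    viscosity: float = 1.5e-3              # Pa*s (lymph, ~1.5x water)
    permeability_tc: float = 0.01          # um^2
    permeability_bf: float = 0.01          # um^2
    permeability_medulla: float = 0.05     # um^2
    scs_permeability: float | None = None  # um^2; default h^2/12
    lp_s_over_v: float = 6.0e-6            # 1/(Pa*s), Lp*S/V of blood vessels
    blood_pressure: float = -30.0          # Pa, equivalent Starling pressure
    osmotic_reflection: float = 0.9        # sigma (fluid), folded into above
    outlet_pressure: float = 0.0           # Pa at the efferent outlet
    flow_scale: float = 1.0                # scenario multiplier

    def validate(self) -> None:
        if self.afferent_flow_ul_h < 0:
            raise ConfigurationError("afferent flow must be >= 0")
        if min(self.permeability_tc, self.permeability_bf,
               self.permeability_medulla) <= 0:
            raise ConfigurationError("permeabilities must be positive")
        if not (0 <= self.osmotic_reflection <= 1):
            raise ConfigurationError("osmotic_reflection must lie in [0, 1]")

    @property
    def afferent_flow_um3_s(self) -> float:
        """Quarter-domain inflow in um^3/s."""
        return (self.afferent_flow_ul_h * UL_PER_H_TO_UM3_PER_S / 4.0
                * self.flow_scale)


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Rate constants of the CCL19/CCL21/CCR7/ACKR4/ECM network.

    All binding/trafficking rates are published measurements; the effective
    diffusivities and the vascular surface density are documented defaults.
    """

    # CCL21 <-> ECM (perlecan) binding
    k1_ecm_on: float = 9.3e-5      # nM^-1 s^-1
    k2_ecm_off: float = 1.2e-4     # s^-1
    # CCR7 binding (same on/off rates for CCL19, CCL21u, CCL21b)
    lam_on: float = 1.0e-3         # nM^-1 s^-1
    lam_off: float = 5.0e-3        # s^-1
    # CCL19-driven CCR7 trafficking
    lam_des: float = 3.0e-3        # s^-1  desensitization of CCL19-CCR7
    lam_int: float = 5.0e-4        # s^-1  internalization of desensitized CCR7
    lam_up: float = 3.75e-4        # s^-1  recycling of internalized CCR7
    # ACKR4 scavenging (SCS-ceiling LECs)
    eta_on: float = 0.5            # nM^-1 s^-1
    eta_off: float = 2.25          # s^-1
    eta_in: float = 1.0            # s^-1  internalization of bound ACKR4
    eta_up: float = 2.0e-3         # s^-1  receptor resurfacing (limiting)
    # transport coefficients
    d_eff_19: float = 25.0         # um^2/s, effective diffusivity in tissue
    d_eff_21: float = 15.0         # um^2/s
    d_fluid: float = 140.0         # um^2/s, free diffusion in Af/SCS/Ef lymph
    p_vasc_cm_s: float = 5.0e-7    # cm/s, chemokine permeability of vessels
    vessel_s_over_v: float = 0.008  # um^-1, blood-vessel surface density

    def validate(self) -> None:
        rates = [self.k1_ecm_on, self.k2_ecm_off, self.lam_on, self.lam_off,
                 self.lam_des, self.lam_int, self.lam_up, self.eta_on,
                 self.eta_off, self.eta_in, self.eta_up]
        if any(r < 0 for r in rates):
            raise ConfigurationError("kinetic rates must be non-negative")

    @property
    def kd_ccr7(self) -> float:
        """CCR7 dissociation constant, nM."""
        return self.lam_off / self.lam_on

    @property
    def kd_ackr4(self) -> float:
        """ACKR4 dissociation constant, nM."""
        return self.eta_off / self.eta_on

    @property
    def p_vasc_um_s(self) -> float:
        return self.p_vasc_cm_s * 1e4


# --------------------------------------------------------------------------
# cell census and per-cell maxima
# --------------------------------------------------------------------------

#: region names used in census tables (vessels carry no cells)
CENSUS_REGIONS = ("SCS", "BFOLLICLE", "TCELL_AREA", "MEDULLA")

#: quantities with per-cell maxima and expression values
CENSUS_QUANTITIES = ("CCR7", "CCL19_PROD", "CCL21_PROD", "ECM", "ACKR4")


@dataclass
class PerCellMaxima:
    """Per-cell maxima translating expression values into molecule numbers."""

    ccr7: float = 30_000.0          # molecules/cell
    ackr4: float = 30_000.0         # molecules/cell
    ecm_sites: float = 1.0e6        # binding sites/cell
    ccl19_prod: float = 1.95        # molecules/cell/s   (calibrated default)
    ccl21_prod: float = 7.6        # molecules/cell/s   (calibrated default)
    lec_diameter: float = 25.0      # um, SCS-ceiling LEC footprint diameter

    def validate(self) -> None:
        if min(self.ccr7, self.ackr4, self.ecm_sites,
               self.ccl19_prod, self.ccl21_prod) < 0:
            raise ConfigurationError("per-cell maxima must be >= 0")

    def maximum(self, quantity: str) -> float:
        return {"CCR7": self.ccr7, "ACKR4": self.ackr4, "ECM": self.ecm_sites,
                "CCL19_PROD": self.ccl19_prod,
                "CCL21_PROD": self.ccl21_prod}[quantity]


# Default cell census.  N = total cells of each type in the whole PLN;
# P_<region> = fraction of that type residing in each region; EV_<quantity>
# = normalized (0-1) expression value of each quantity for that type.
# Counts are literature-scale estimates for a resting mouse PLN (~3e6 cells);
# expression values are implementer defaults encoding the dominant patterns
# (T/B/DC express CCR7; stromal FRCs produce CCL19/CCL21 and carry ECM sites;
# LECs express ACKR4) and were frozen after the one-time baseline calibration.
_DEFAULT_CENSUS_TSV = """\
cell_type\tN\tP_SCS\tP_BFOLLICLE\tP_TCELL_AREA\tP_MEDULLA\tEV_CCR7\tEV_CCL19_PROD\tEV_CCL21_PROD\tEV_ECM\tEV_ACKR4
T_cell\t1.0e6\t0.0\t0.05\t0.9\t0.05\t0.5\t0.0\t0.0\t0.0\t0.0
B_cell\t2.0e6\t0.0\t0.95\t0.03\t0.02\t0.07\t0.0\t0.0\t0.0\t0.0
DC\t3.0e4\t0.02\t0.03\t0.85\t0.10\t0.8\t0.05\t0.0\t0.0\t0.0
macrophage\t1.0e5\t0.15\t0.05\t0.20\t0.60\t0.05\t0.0\t0.0\t0.0\t0.0
LEC\t3.0e4\t0.60\t0.0\t0.0\t0.40\t0.0\t0.0\t0.1\t0.0\t1.0
BEC\t3.0e4\t0.0\t0.05\t0.65\t0.30\t0.0\t0.05\t0.1\t0.05\t0.0
FRC\t1.2e5\t0.0\t0.01\t0.70\t0.29\t0.0\t1.0\t1.0\t0.9\t0.0
"""


@dataclass
class CellCensus:
    """Cell counts, region fractions and expression values per cell type."""

    table: pd.DataFrame

    @classmethod
    def default(cls) -> "CellCensus":
        return cls.from_tsv(io.StringIO(_DEFAULT_CENSUS_TSV))

    @classmethod
    def from_tsv(cls, path_or_buf) -> "CellCensus":
        df = pd.read_csv(path_or_buf, sep="\t").set_index("cell_type")
        census = cls(df)
        census.validate()
        return census

    def validate(self) -> None:
        df = self.table
        pcols = [f"P_{r}" for r in CENSUS_REGIONS]
        evcols = [f"EV_{q}" for q in CENSUS_QUANTITIES]
        missing = [c for c in ["N", *pcols, *evcols] if c not in df.columns]
        if missing:
            raise ConfigurationError(f"census table missing columns {missing}")
        if (df["N"] < 0).any():
            raise ConfigurationError("cell counts N must be >= 0")
        p = df[pcols].to_numpy()
        if (p < 0).any() or (p > 1).any() or (p.sum(axis=1) > 1 + 1e-9).any():
            raise ConfigurationError(
                "region fractions must lie in [0, 1] and sum to <= 1")
        ev = df[evcols].to_numpy()
        if (ev < 0).any() or (ev > 1).any():
            raise ConfigurationError("expression values must lie in [0, 1]")

    def scaled(self, **factors: float) -> "CellCensus":
        """Return a census with quantity columns scaled by given factors.

        Keys are census quantities (e.g. ``CCR7=2.0`` doubles every cell
        type's CCR7 expression value); used by the sensitivity analysis.
        Scaled EVs may exceed 1 (they then describe more molecules per cell
        than the nominal maximum, which is the intent of the variation).
        """
        df = self.table.copy()
        for q, f in factors.items():
            if f"EV_{q}" not in df.columns:
                raise ConfigurationError(f"unknown census quantity {q!r}")
            df[f"EV_{q}"] = df[f"EV_{q}"] * f
        return CellCensus(df)


# --------------------------------------------------------------------------
# transport / scenario settings
# --------------------------------------------------------------------------

@dataclass
class TransportSettings:
    """Boundary settings and solver controls for the steady transport solve."""

    c_in_19: float = 0.0           # nM at the afferent inlet
    c_in_21: float = 0.0           # nM at the afferent inlet
    ackr4_enabled: bool = True
    max_picard: int = 200
    picard_tol: float = 1.0e-8     # relative residual on field updates
    relax: float = 0.7             # under-relaxation of receptor closure

    def validate(self) -> None:
        if self.c_in_19 < 0 or self.c_in_21 < 0:
            raise ConfigurationError("inlet concentrations must be >= 0")


@dataclass
class Scenario:
    """A named experiment: overrides applied on top of the baseline config."""

    name: str
    ackr4_enabled: bool = True
    c_in_19: float = 0.0
    c_in_21: float = 0.0
    flow_scale: float = 1.0


SCENARIOS: dict[str, Scenario] = {
    "BASELINE_WT": Scenario("BASELINE_WT"),
    "LN_ACKR4_KO": Scenario("LN_ACKR4_KO", ackr4_enabled=False),
    "SKIN_ACKR4_KO": Scenario("SKIN_ACKR4_KO", c_in_19=5.0, c_in_21=5.0),
    "GLOBAL_ACKR4_KO": Scenario("GLOBAL_ACKR4_KO", ackr4_enabled=False,
                                c_in_19=5.0, c_in_21=5.0),
    "LOW_FLOW": Scenario("LOW_FLOW", flow_scale=0.01),
    "LOW_FLOW_NO_ACKR4": Scenario("LOW_FLOW_NO_ACKR4", ackr4_enabled=False,
                                  flow_scale=0.01),
}


# --------------------------------------------------------------------------
# top-level config
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Complete model configuration with defaults for every block."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    flow: FlowParams = field(default_factory=FlowParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    maxima: PerCellMaxima = field(default_factory=PerCellMaxima)
    census: CellCensus = field(default_factory=CellCensus.default)
    transport: TransportSettings = field(default_factory=TransportSettings)
    resolution: float = 3.0        # mesh cells per 100 um
    seed: int = 0

    def validate(self) -> None:
        self.geometry.validate()
        self.flow.validate()
        self.kinetics.validate()
        self.maxima.validate()
        self.census.validate()
        self.transport.validate()
        if self.resolution < 2:
            raise ConfigurationError("resolution must be >= 2")

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def with_scenario(self, scenario: Scenario | str) -> "ModelConfig":
        """Apply a scenario's overrides, returning a new config."""
        if isinstance(scenario, str):
            scenario = SCENARIOS[scenario]
        transport = dataclasses.replace(
            self.transport, ackr4_enabled=scenario.ackr4_enabled,
            c_in_19=scenario.c_in_19, c_in_21=scenario.c_in_21)
        flow = dataclasses.replace(self.flow, flow_scale=scenario.flow_scale)
        return self.replace(transport=transport, flow=flow)


def _update_dataclass(obj, data: dict, block: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown keys in [{block}]: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return dataclasses.replace(obj, **coerced)


def load_config(path: str | None = None) -> ModelConfig:
    """Load a TOML config file on top of the package defaults.

    Recognized blocks: ``[geometry]``, ``[flow]``, ``[kinetics]``,
    ``[maxima]``, ``[transport]`` (keys mirror the dataclass field names) and
    top-level ``resolution`` / ``seed`` / ``census_file`` (TSV path).
    """
    cfg = ModelConfig()
    if path is None:
        cfg.validate()
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for block, attr in [("geometry", "geometry"), ("flow", "flow"),
                        ("kinetics", "kinetics"), ("maxima", "maxima"),
                        ("transport", "transport")]:
        if block in data:
            setattr(cfg, attr,
                    _update_dataclass(getattr(cfg, attr), data[block], block))
    if "resolution" in data:
        cfg.resolution = float(data["resolution"])
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "census_file" in data:
        cfg.census = CellCensus.from_tsv(data["census_file"])
    cfg.validate()
    return cfg
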
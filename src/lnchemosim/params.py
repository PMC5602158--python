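"""Cell-census -> volumetric field maps.

Each per-region quantity is obtained by the continuum estimate

    value_j = sum_k  N_k * P_k,j * EV_X,k * X_max / (N_A * Vol_j)

i.e. total molecules (or molecules/s for production rates) carried by all
cell types in region j, converted to moles and divided by the region volume,
assuming cell types are homogeneously distributed within each region.  The
result is piecewise-constant per region: nM for concentrations, nM/s for
production rates.

CCR7 is a leukocyte surface receptor and is absent from the lymph-filled
afferent/efferent vessels and the SCS, so the CCR7 map is forced to zero in
those regions regardless of the census.  ACKR4 lives on SCS-ceiling LECs and
is expressed as a surface density (molecules/um^2) on the capsule-ceiling
patches, identical over the SCS and medullary capsule (same LEC density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (AVOGADRO, CellCensus, ConfigurationError, PerCellMaxima,
                     CENSUS_REGIONS)
from .geometry import FLUID_REGIONS, Mesh, RegionId


@dataclass
class FieldMaps:
    """Per-cell parameter fields plus the ACKR4 ceiling surface density."""

    q19: np.ndarray        # CCL19 production, nM/s
    q21: np.ndarray        # CCL21 production, nM/s
    rtot: np.ndarray       # total CCR7, nM
    mtot: np.ndarray       # total ECM binding sites, nM
    atot_ceiling: float    # ACKR4 surface density, molecules/um^2


def region_moles(census: CellCensus, maxima: PerCellMaxima,
                 quantity: str) -> dict[str, float]:
    """Total moles (or mol/s) of a census quantity per region, whole node."""
    df = census.table
    xmax = maxima.maximum(quantity)
    out = {}
    for reg in CENSUS_REGIONS:
        molecules = (df["N"] * df[f"P_{reg}"] * df[f"EV_{quantity}"]).sum() \
            * xmax
        out[reg] = float(molecules) / AVOGADRO
    return out


def concentration_from_census(census: CellCensus, maxima: PerCellMaxima,
                              quantity: str, mesh: Mesh) -> np.ndarray:
    """Per-cell field (nM or nM/s) for one census quantity.

    Region volumes come from the mesh (the mesh models a quarter node, so a
    quarter of each region's moles is spread over the meshed quarter volume,
    which cancels to moles/volume of the whole region).
    """
    moles = region_moles(census, maxima, quantity)
    field = np.zeros(mesh.n_cells)
    for reg_name, mol in moles.items():
        rid = RegionId[reg_name]
        vol_quarter_um3 = mesh.region_volume(rid)
        if mol > 0 and vol_quarter_um3 <= 0:
            raise ConfigurationError(
                f"census assigns {quantity} to region {reg_name} "
                "which has zero mesh volume")
        if vol_quarter_um3 <= 0:
            continue
        vol_l = 4.0 * vol_quarter_um3 * 1e-15   # whole-node region volume, L
        field[mesh.region == int(rid)] = mol / vol_l * 1e9   # -> nM
    return field


def ackr4_surface_density(census: CellCensus, maxima: PerCellMaxima) -> float:
    """ACKR4 molecules/um^2 on the capsule ceiling.

    Atot = (per-LEC ACKR4) * (mean ceiling-LEC ACKR4 expression) divided by
    the LEC footprint area (diameter ``maxima.lec_diameter``).  With the
    defaults (30,000 receptors, 25 um cells) this is ~61 molecules/um^2.
    """
    df = census.table
    lec = df.loc[df["EV_ACKR4"] > 0]
    ev = float(lec["EV_ACKR4"].max()) if len(lec) else 0.0
    footprint = np.pi * (maxima.lec_diameter / 2.0) ** 2
    return maxima.ackr4 * ev / footprint


def build_field_maps(census: CellCensus, maxima: PerCellMaxima,
                     mesh: Mesh) -> FieldMaps:
    """All parameter fields needed by the transport solver."""
    census.validate()
    maxima.validate()
    rtot = concentration_from_census(census, maxima, "CCR7", mesh)
    for rid in FLUID_REGIONS:          # CCR7 absent from Af, SCS, Ef
        rtot[mesh.region == int(rid)] = 0.0
    return FieldMaps(
        q19=concentration_from_census(census, maxima, "CCL19_PROD", mesh),
        q21=concentration_from_census(census, maxima, "CCL21_PROD", mesh),
        rtot=rtot,
        mtot=concentration_from_census(census, maxima, "ECM", mesh),
        atot_ceiling=ackr4_surface_density(census, maxima),
    )
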
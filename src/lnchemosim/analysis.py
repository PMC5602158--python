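"""Concentration profiles, gradients and across-cell differences.

Profiles are sampled along the radial probe lines at 4.5-um spacing by
trilinear interpolation of the cell-centred fields on the structured
(r, theta, phi) grid, low-pass filtered with a zero-phase 5-point (+/- 9 um)
moving average, and differentiated with central differences.  Across-cell
concentration differences are C(x+d) - C(x) for cell diameters d of 9, 18 or
36 um (integer multiples of the sample spacing), signed positive when
concentration increases away from the SCS.

Single-number "slopes" quoted in summaries use two documented windows:

* IFR slope: the maximum filtered gradient within the first 20 um of tissue
  below the SCS floor (where the matrix-bound CCL21 gradient peaks);
* BF-TC slope: a least-squares line fit over a 25-um window straddling the
  follicle/T-zone border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .geometry import Mesh, ProbeLine, RegionId
from .transport import FieldState, TransportProblem

#: species sampled by default: mobile chemokines, bound CCL21 and receptors
PROFILE_SPECIES = ("c19", "c21u", "c21b", "r", "r19", "rdes", "rint",
                   "r21u", "r21b")

FILTER_WINDOW = 5      # samples; +/- 9 um at 4.5-um spacing


@dataclass
class ProfileSeries:
    """A sampled, filtered concentration profile along one probe line."""

    probe: str
    species: str
    positions: np.ndarray      # um from the SCS ceiling, strictly increasing
    raw: np.ndarray            # nM
    filtered: np.ndarray       # nM, zero-phase moving average
    gradient: np.ndarray       # nM/um, central differences of `filtered`


def lowpass(values: np.ndarray, window: int = FILTER_WINDOW) -> np.ndarray:
    """Zero-phase symmetric moving average with edge reflection.

    Linear, preserves constants exactly.
    """
    if window % 2 != 1:
        raise ValueError("filter window must be odd")
    half = window // 2
    padded = np.pad(values, half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _interpolator(mesh: Mesh, values: np.ndarray) -> RegularGridInterpolator:
    rc, tc, pc = mesh.cell_centers_sph
    grid = mesh.field3d(values)
    return RegularGridInterpolator((rc, tc, pc), grid, bounds_error=False,
                                   fill_value=None)


def sample_field(mesh: Mesh, values: np.ndarray,
                 points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a per-cell field at cartesian points.

    Points are converted to spherical coordinates and clamped to the range of
    active cell centres (so samples on the capsule ceiling take the value of
    the outermost sinus cell rather than extrapolating into vessel stubs).
    """
    x, y, z = points.T
    r = np.sqrt(x * x + y * y + z * z)
    th = np.arccos(np.clip(np.divide(z, np.maximum(r, 1e-12)), -1, 1))
    ph = np.arctan2(y, np.maximum(x, 0.0))
    rc, tc, pc = mesh.cell_centers_sph
    # clamp strictly inside the node-interior cell centres (the vessel stubs
    # beyond the capsule are inactive off the polar caps)
    inner = rc[rc <= mesh.params.radius]
    r = np.clip(r, rc[0], inner[-1] * (1 - 1e-12))
    th = np.clip(th, tc[0], tc[-1])
    ph = np.clip(ph, pc[0], pc[-1])
    interp = _interpolator(mesh, values)
    return interp(np.column_stack([r, th, ph]))


def sample_profile(mesh: Mesh, values: np.ndarray, line: ProbeLine,
                   species: str = "") -> ProfileSeries:
    raw = sample_field(mesh, values, line.points)
    filt = lowpass(raw)
    grad = np.gradient(filt, line.positions)
    return ProfileSeries(probe=line.name, species=species,
                         positions=line.positions, raw=raw, filtered=filt,
                         gradient=grad)


def profiles_from_state(mesh: Mesh, state: FieldState, lines,
                        species=PROFILE_SPECIES) -> dict:
    """Nested dict: profiles[line_name][species] -> ProfileSeries."""
    out = {}
    for line in lines:
        out[line.name] = {sp: sample_profile(
            mesh, getattr(state.local, sp), line, species=sp)
            for sp in species}
    return out


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """Tidy export: columns probe, species, position_um, value, filtered,
    gradient."""
    rows = []
    for probe, by_species in profiles.items():
        for spn, prof in by_species.items():
            rows.append(pd.DataFrame({
                "probe": probe, "species": spn,
                "position_um": prof.positions, "value": prof.raw,
                "filtered": prof.filtered, "gradient": prof.gradient}))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# across-cell concentration differences
# --------------------------------------------------------------------------

@dataclass
class CellDifferenceSeries:
    probe: str
    species: str
    diameter: float
    positions: np.ndarray      # trailing-edge position, um from ceiling
    delta: np.ndarray          # C(x+d) - C(x), nM
    percent: np.ndarray        # 100*delta/C(x); NaN where C(x) == 0


def cell_differences(profile: ProfileSeries,
                     diameter: float) -> CellDifferenceSeries:
    """Concentration difference across a cell of the given diameter.

    ``diameter`` must be an integer multiple of the sample spacing (9, 18 and
    36 um all are at the default 4.5-um spacing).
    """
    spacing = float(profile.positions[1] - profile.positions[0])
    k = diameter / spacing
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"cell diameter {diameter} um is not a multiple of the "
            f"{spacing} um sample spacing")
    k = int(round(k))
    if k >= len(profile.positions):
        return CellDifferenceSeries(profile.probe, profile.species, diameter,
                                    np.empty(0), np.empty(0), np.empty(0))
    c = profile.filtered
    delta = c[k:] - c[:-k]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(c[:-k] > 0, 100.0 * delta / c[:-k], np.nan)
    return CellDifferenceSeries(profile.probe, profile.species, diameter,
                                profile.positions[:-k], delta, pct)


# --------------------------------------------------------------------------
# scalar summaries
# --------------------------------------------------------------------------

def window_slope(profile: ProfileSeries, center: float,
                 width: float = 25.0) -> float:
    """Least-squares slope of the filtered profile over [center +/- width/2]."""
    x, y = profile.positions, profile.filtered
    m = (x >= center - width / 2) & (x <= center + width / 2)
    if m.sum() < 2:
        return np.nan
    return float(np.polyfit(x[m], y[m], 1)[0])


def max_gradient_in(profile: ProfileSeries, lo: float, hi: float) -> float:
    """Signed gradient of largest magnitude with position in (lo, hi].

    Positive means concentration increasing away from the SCS ceiling.
    """
    m = (profile.positions > lo) & (profile.positions <= hi)
    if not m.any():
        return np.nan
    g = profile.gradient[m]
    return float(g[np.argmax(np.abs(g))])


def summary_gradients(mesh: Mesh, state: FieldState, lines,
                      problem: TransportProblem) -> dict[str, float]:
    """Scalar outputs: slopes, whole-node totals and efferent concentrations.

    * ``ifr_slope_*``: peak filtered gradient in the first 20 um of tissue
      under the SCS floor along IFR_ARROW (nM/um);
    * ``bftc_slope_*``: least-squares slope over the 25-um window straddling
      the BF-TC border along BFTC_ARROW (nM/um);
    * ``total_ccl19_mol`` / ``total_ccl21_mol``: whole-node volume integrals
      (CCL19 free, CCL21 = CCL21u + CCL21b), in moles;
    * ``efferent_c19_nm`` / ``efferent_c21_nm``: flow-weighted mean outlet
      concentrations (nM);
    * peak receptor-complex concentrations on the follicle side of the BF-TC
      border and the free-CCR7 percentage in the T-cell-area core.
    """
    geom = mesh.params
    floor_depth = geom.scs_thickness
    border_depth = floor_depth + geom.bf_tc_border_depth
    lines = {ln.name: ln for ln in lines}
    s = state.local
    out: dict[str, float] = {}

    ifr = lines.get("IFR_ARROW")
    for spn in ("c19", "c21u", "c21b"):
        if ifr is not None:
            prof = sample_profile(mesh, getattr(s, spn), ifr, spn)
            out[f"ifr_slope_{spn}"] = max_gradient_in(
                prof, floor_depth, floor_depth + 20.0)
        bftc = lines.get("BFTC_ARROW")
        if bftc is not None:
            prof = sample_profile(mesh, getattr(s, spn), bftc, spn)
            out[f"bftc_slope_{spn}"] = window_slope(prof, border_depth)

    vol = mesh.volume
    nm_um3_to_mol = 1e-9 * 1e-15           # nM * um^3 -> mol
    out["total_ccl19_mol"] = 4.0 * float(s.c19 @ vol) * nm_um3_to_mol
    out["total_ccl21_mol"] = 4.0 * float(
        (s.c21u + s.c21b) @ vol) * nm_um3_to_mol

    # flow-weighted outlet mean; when Starling absorption swallows the whole
    # (scaled-down) afferent flow there is no advective outflow, and the mean
    # concentration in the efferent-vessel lumen is reported instead
    flow = problem.flow
    outlet = mesh.patch_faces("EFFERENT_OUTLET")
    oflux = np.maximum(flow.bnd_flux[outlet], 0.0)
    ocell = mesh.bnd_cell[outlet]
    qsum = oflux.sum()
    if qsum > 0:
        out["efferent_c19_nm"] = float(oflux @ s.c19[ocell] / qsum)
        out["efferent_c21_nm"] = float(oflux @ s.c21u[ocell] / qsum)
    else:
        ef = mesh.cells_in_region(RegionId.EFFERENT_VESSEL)
        out["efferent_c19_nm"] = float(s.c19[ef].mean())
        out["efferent_c21_nm"] = float(s.c21u[ef].mean())

    # receptor-complex peaks on the follicle side of the border
    bftc = lines.get("BFTC_ARROW")
    if bftc is not None:
        pos = bftc.positions
        bf_side = (pos >= floor_depth) & (pos <= border_depth)
        for spn, key in (("r21u", "peak_r21u_bf"), ("r19", "peak_r19_bf")):
            prof = sample_profile(mesh, getattr(s, spn), bftc, spn)
            out[key] = float(prof.filtered[bf_side].max()) if bf_side.any() \
                else np.nan

    # free CCR7 in the T-cell-area core (cell of maximal CCL21b)
    tc = mesh.cells_in_region(RegionId.TCELL_AREA)
    core = tc[np.argmax(s.c21b[tc])]
    rtot_core = problem.maps.rtot[core]
    out["pct_ccr7_free_tc"] = 100.0 * float(s.r[core] / rtot_core) \
        if rtot_core > 0 else np.nan
    out["max_c19"] = float(s.c19.max())
    out["max_c21u"] = float(s.c21u.max())
    out["max_c21b"] = float(s.c21b.max())
    return out
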
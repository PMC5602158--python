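"""Scenario presets, pipeline orchestration and run comparison.

A scenario is the full pipeline — mesh, parameter maps, lymph flow, steady
transport, gradient analysis — run under a named set of overrides:

* ``BASELINE_WT``          : the calibrated wild-type node;
* ``LN_ACKR4_KO``          : ACKR4 removed from the SCS ceiling only;
* ``SKIN_ACKR4_KO``        : ACKR4 intact, but afferent lymph carries 5 nM
                             CCL19 and CCL21 (loss of upstream scavenging);
* ``GLOBAL_ACKR4_KO``      : both of the above;
* ``LOW_FLOW``             : afferent flow at 1% of baseline;
* ``LOW_FLOW_NO_ACKR4``    : low flow with ceiling ACKR4 removed.

Every stage is deterministic, so a ``RunRecord`` (config + scenario name)
reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (profiles_from_state, profiles_to_frame,
                       summary_gradients)
from .config import ModelConfig, SCENARIOS
from .flow import FlowField, solve_flow, wall_shear
from .geometry import Mesh, build_mesh, probe_lines, write_vtk
from .params import build_field_maps
from .transport import (FieldState, TransportProblem, mass_balance_report,
                        solve_steady)

log = logging.getLogger(__name__)


@dataclass
class RunRecord:
    """Provenance and results of one scenario run."""

    scenario: str
    config: ModelConfig            # with scenario overrides applied
    config_hash: str
    seed: int
    mesh: Mesh
    flow: FlowField
    state: FieldState
    problem: TransportProblem
    profiles: dict                 # profiles[line][species] -> ProfileSeries
    summary: dict[str, float]
    ledger: dict[str, dict]
    iterations: int


def _config_hash(cfg: ModelConfig, scenario: str) -> str:
    payload = json.dumps(
        {"scenario": scenario, "resolution": cfg.resolution,
         "geometry": dataclasses.asdict(cfg.geometry),
         "flow": dataclasses.asdict(cfg.flow),
         "kinetics": dataclasses.asdict(cfg.kinetics),
         "maxima": dataclasses.asdict(cfg.maxima),
         "transport": dataclasses.asdict(cfg.transport),
         "census": cfg.census.table.to_csv()},
        sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_scenario(name: str, config: ModelConfig | None = None,
                 resolution: float | None = None) -> RunRecord:
    """Execute geometry -> maps -> flow -> transport -> analysis."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"choose from {sorted(SCENARIOS)}")
    cfg = (config or ModelConfig())
    if resolution is not None:
        cfg = cfg.replace(resolution=resolution)
    cfg = cfg.with_scenario(name)
    cfg.validate()
    log.info("scenario %s: building mesh (resolution %.3g)", name,
             cfg.resolution)
    mesh = build_mesh(cfg.geometry, cfg.resolution)
    flow = solve_flow(mesh, cfg.flow)
    maps = build_field_maps(cfg.census, cfg.maxima, mesh)
    problem = TransportProblem(mesh, flow, maps, cfg.kinetics, cfg.transport)
    log.info("scenario %s: solving steady transport", name)
    state = solve_steady(problem)
    lines = probe_lines(mesh)
    record = RunRecord(
        scenario=name, config=cfg, config_hash=_config_hash(cfg, name),
        seed=cfg.seed,
        mesh=mesh, flow=flow, state=state, problem=problem,
        profiles=profiles_from_state(mesh, state, lines),
        summary=summary_gradients(mesh, state, lines, problem),
        ledger=mass_balance_report(state, problem),
        iterations=state.iterations)
    log.info("scenario %s: converged in %d Picard iterations", name,
             state.iterations)
    return record


def export_record(record: RunRecord, out_dir: str | Path) -> dict[str, str]:
    """Write VTK fields, profile/shear CSVs and the summary/ledger JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = record.state.local
    paths = {}
    vtk = out / "fields.vtk"
    write_vtk(record.mesh, str(vtk), {
        "CCL19": s.c19, "CCL21u": s.c21u, "CCL21b": s.c21b,
        "CCR7_free": s.r, "CCR7_CCL19": s.r19, "CCR7_des": s.rdes,
        "CCR7_int": s.rint, "CCR7_CCL21u": s.r21u, "CCR7_CCL21b": s.r21b,
        "pressure": record.flow.pressure, "Jv": record.flow.jv})
    paths["fields"] = str(vtk)
    prof = out / "profiles.csv"
    profiles_to_frame(record.profiles).to_csv(prof, index=False)
    paths["profiles"] = str(prof)
    shear = out / "scs_shear.csv"
    wall_shear(record.flow, record.mesh,
               record.config.flow).to_csv(shear, index=False)
    paths["shear"] = str(shear)
    meta = out / "summary.json"
    with open(meta, "w") as fh:
        json.dump({"scenario": record.scenario,
                   "config_hash": record.config_hash,
                   "iterations": record.iterations,
                   "summary": record.summary,
                   "ledger": record.ledger}, fh, indent=2)
    paths["summary"] = str(meta)
    return paths


@dataclass
class ComparisonReport:
    """Profile-level differences between two runs on the same mesh."""

    rel_diff: pd.DataFrame         # rows (probe, species) -> relative L2 diff
    summary_diff: pd.DataFrame     # summary-table comparison
    max_rel_diff: float
    indistinguishable: bool        # max relative profile difference < 1%


def compare_runs(a: RunRecord, b: RunRecord,
                 species=("c19", "c21u", "c21b"),
                 tol: float = 0.01) -> ComparisonReport:
    """Normed per-profile differences between two runs.

    The relative difference of each (probe, species) profile is the L2 norm
    of the difference divided by the L2 norm of the first run's profile
    (zero profiles compare equal).  ``indistinguishable`` is declared when
    the largest relative profile difference is below ``tol`` (default 1%).
    """
    if a.mesh.n_cells != b.mesh.n_cells or \
            len(a.mesh.r_edges) != len(b.mesh.r_edges):
        raise ValueError("runs use different meshes; cannot compare")
    rows = []
    for probe in a.profiles:
        for sp in species:
            pa = a.profiles[probe][sp].filtered
            pb = b.profiles[probe][sp].filtered
            na = np.linalg.norm(pa)
            diff = np.linalg.norm(pa - pb) / na if na > 0 else \
                (0.0 if np.linalg.norm(pb) == 0 else np.inf)
            rows.append({"probe": probe, "species": sp, "rel_diff": diff})
    rel = pd.DataFrame(rows)
    sd = pd.DataFrame({
        "a": pd.Series(a.summary), "b": pd.Series(b.summary)})
    sd["abs_diff"] = (sd["a"] - sd["b"]).abs()
    max_rel = float(rel["rel_diff"].max())
    return ComparisonReport(rel_diff=rel, summary_diff=sd,
                            max_rel_diff=max_rel,
                            indistinguishable=max_rel < tol)
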
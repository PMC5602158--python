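"""Parameter variation analysis: Latin hypercube sampling + PRCC.

Seven biological inputs are varied as multiplicative factors on their
baseline values — CCL19 production, CCL21 production, CCR7 per cell, ACKR4
per cell, matrix binding sites, and the two effective diffusivities — with
log-uniform factors between 0.2x and 5x by default (the bounds are
configurable).  The lymph-flow field does not depend on any of these, so it
is solved once and frozen across the ensemble.

For each sample the full transport problem is re-solved and eight outputs
recorded: the IFR and BF-TC border slopes of CCL19 and matrix-bound CCL21,
the whole-node totals of CCL19 and CCL21, and the efferent concentrations of
both chemokines.  Partial rank correlation coefficients (PRCC) between each
input and each output are computed on rank-transformed data with the other
six inputs partialled out; significance comes from the Student t statistic
``t = r*sqrt((n-2-p)/(1-r^2))`` with ``n-2-p`` degrees of freedom (p = number
of controlled inputs).  A sign table renders the result with +/- notation at
the p < 0.01 / 0.001 / 0.0001 levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .config import ModelConfig
from .flow import solve_flow
from .geometry import build_mesh, probe_lines
from .params import build_field_maps
from .transport import TransportProblem, solve_steady
from .analysis import summary_gradients

log = logging.getLogger(__name__)

#: the seven varied inputs (multiplicative factors on baseline)
PVA_PARAMETERS = ("ccl19_production", "ccl21_production", "ccr7_per_cell",
                  "ackr4_per_cell", "matrix_sites", "d_eff_19", "d_eff_21")

#: the eight recorded outputs
PVA_OUTPUTS = ("ifr_slope_c19", "ifr_slope_c21b", "bftc_slope_c19",
               "bftc_slope_c21b", "total_ccl19", "total_ccl21",
               "efferent_c19", "efferent_c21")


@dataclass
class PvaDesign:
    n_samples: int = 100
    seed: int = 0
    lower: float = 0.2         # multiplicative factor bounds
    upper: float = 5.0
    log_uniform: bool = True
    parameters: tuple[str, ...] = PVA_PARAMETERS

    def validate(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError("bounds must satisfy 0 < lower < upper")
        if self.n_samples < 2 * len(self.parameters):
            raise ValueError("n_samples must be >= 2 * n_parameters")


@dataclass
class PvaResult:
    design: pd.DataFrame           # n_samples x 7 factors
    outputs: pd.DataFrame          # n_samples x 8 (NaN rows = failed)
    prcc: pd.DataFrame             # 7 x 8
    pvalues: pd.DataFrame          # 7 x 8
    sign_table: pd.DataFrame       # 7 x 8, strings "", "+".."+++", "-".."---"
    n_failed: int = 0


def lhs_sample(design: PvaDesign) -> pd.DataFrame:
    """Stratified Latin-hypercube factors, reproducible under a fixed seed."""
    design.validate()
    d = len(design.parameters)
    unit = qmc.LatinHypercube(d=d, seed=design.seed).random(design.n_samples)
    if design.log_uniform:
        lo, hi = np.log(design.lower), np.log(design.upper)
        vals = np.exp(lo + unit * (hi - lo))
    else:
        vals = design.lower + unit * (design.upper - design.lower)
    return pd.DataFrame(vals, columns=list(design.parameters))


def apply_factors(config: ModelConfig, factors: dict[str, float]
                  ) -> ModelConfig:
    """Return a config with the PVA factors applied to the baseline."""
    import dataclasses
    maxima = dataclasses.replace(
        config.maxima,
        ccl19_prod=config.maxima.ccl19_prod * factors["ccl19_production"],
        ccl21_prod=config.maxima.ccl21_prod * factors["ccl21_production"],
        ccr7=config.maxima.ccr7 * factors["ccr7_per_cell"],
        ackr4=config.maxima.ackr4 * factors["ackr4_per_cell"],
        ecm_sites=config.maxima.ecm_sites * factors["matrix_sites"])
    kin = dataclasses.replace(
        config.kinetics,
        d_eff_19=config.kinetics.d_eff_19 * factors["d_eff_19"],
        d_eff_21=config.kinetics.d_eff_21 * factors["d_eff_21"])
    return config.replace(maxima=maxima, kinetics=kin)


def run_ensemble(design: PvaDesign, config: ModelConfig | None = None,
                 resolution: float | None = None) -> PvaResult:
    """Execute the ensemble and compute PRCCs.

    ``resolution`` defaults to a reduced mesh (2 cells / 100 um) to keep a
    100-sample ensemble desk-scale; the flow field is solved once.  Samples
    whose transport solve fails are logged and excluded; more than 10%
    failures aborts.
    """
    cfg = config or ModelConfig()
    res = resolution if resolution is not None else 2.0
    mesh = build_mesh(cfg.geometry, res)
    flow = solve_flow(mesh, cfg.flow)
    lines = probe_lines(mesh)
    factors = lhs_sample(design)

    rows = []
    n_failed = 0
    for i, fac in factors.iterrows():
        sample_cfg = apply_factors(cfg, fac.to_dict())
        try:
            maps = build_field_maps(sample_cfg.census, sample_cfg.maxima,
                                    mesh)
            prob = TransportProblem(mesh, flow, maps, sample_cfg.kinetics,
                                    sample_cfg.transport)
            state = solve_steady(prob)
            s = summary_gradients(mesh, state, lines, prob)
            rows.append({
                "ifr_slope_c19": s["ifr_slope_c19"],
                "ifr_slope_c21b": s["ifr_slope_c21b"],
                "bftc_slope_c19": s["bftc_slope_c19"],
                "bftc_slope_c21b": s["bftc_slope_c21b"],
                "total_ccl19": s["total_ccl19_mol"],
                "total_ccl21": s["total_ccl21_mol"],
                "efferent_c19": s["efferent_c19_nm"],
                "efferent_c21": s["efferent_c21_nm"],
            })
        except Exception as exc:
            n_failed += 1
            log.warning("PVA sample %d failed: %s", i, exc)
            rows.append({k: np.nan for k in PVA_OUTPUTS})
    if n_failed > 0.1 * design.n_samples:
        raise RuntimeError(
            f"{n_failed}/{design.n_samples} ensemble samples failed")

    outputs = pd.DataFrame(rows, columns=list(PVA_OUTPUTS))
    ok = ~outputs.isna().any(axis=1)
    prcc_mat, p_mat = prcc(factors[ok].to_numpy(), outputs[ok].to_numpy())
    prcc_df = pd.DataFrame(prcc_mat, index=list(design.parameters),
                           columns=list(PVA_OUTPUTS))
    p_df = pd.DataFrame(p_mat, index=list(design.parameters),
                        columns=list(PVA_OUTPUTS))
    return PvaResult(design=factors, outputs=outputs, prcc=prcc_df,
                     pvalues=p_df, sign_table=sign_table(prcc_df, p_df),
                     n_failed=n_failed)


def prcc(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partial rank correlation of each input column with each output column.

    Both matrices are rank-transformed; for input i, the other inputs are
    linearly regressed out of input i and of the output, and the Pearson
    correlation of the residuals is the PRCC.  Returns (prcc, p) arrays of
    shape (n_inputs, n_outputs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, d = x.shape
    if n <= d + 2:
        raise ValueError("need more samples than inputs + 2")
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = np.apply_along_axis(stats.rankdata, 0, y)
    if np.any(np.ptp(rx, axis=0) == 0):
        raise ValueError("constant input column: PRCC undefined")
    out_r = np.empty((d, y.shape[1]))
    out_p = np.empty((d, y.shape[1]))
    dof = n - 2 - (d - 1)
    for i in range(d):
        others = np.column_stack(
            [np.ones(n), np.delete(rx, i, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, rx[:, i], rcond=None)
        ux = rx[:, i] - others @ beta_x
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        uy = ry - others @ beta_y
        denom = np.sqrt((ux @ ux) * np.sum(uy * uy, axis=0))
        r = np.where(denom > 0, ux @ uy / np.maximum(denom, 1e-300), 0.0)
        r = np.clip(r, -0.9999999, 0.9999999)
        t = r * np.sqrt(dof / (1.0 - r ** 2))
        out_r[i] = r
        out_p[i] = 2.0 * stats.t.sf(np.abs(t), dof)
    return out_r, out_p


def sign_table(prcc_df: pd.DataFrame, p_df: pd.DataFrame) -> pd.DataFrame:
    """Render +/- significance notation: one symbol per decade of p below
    0.01 (+ for 0.001<p<0.01, ++ for 0.0001<p<0.001, +++ for p<0.0001)."""
    def cell(r, p):
        if p >= 0.01 or r == 0:
            return ""
        sym = "+" if r > 0 else "-"
        if p < 0.0001:
            return sym * 3
        if p < 0.001:
            return sym * 2
        return sym
    return pd.DataFrame(
        [[cell(prcc_df.iat[i, j], p_df.iat[i, j])
          for j in range(prcc_df.shape[1])] for i in range(prcc_df.shape[0])],
        index=prcc_df.index, columns=prcc_df.columns)


def render_sign_table(result: PvaResult) -> str:
    """Markdown rendering of the sign table."""
    return result.sign_table.to_markdown()
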
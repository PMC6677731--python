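"""Global sensitivity analysis: LHS sampling and partial rank correlation.

The extended parameter set (checkpoint expression fractions, antigen
abundance per cell, clonality, mAPC inactivation in the tumor
microenvironment, chemokine factor, mAPC activation in the TDLN, starting
diameter) is sampled by Latin hypercube, the model is simulated under a
fixed therapy, and each parameter's partial rank correlation coefficient
(PRCC) against each readout is computed with a t-distributed significance
test.  Readouts follow the trial figure conventions: time-averaged tumor
diameter, maximum effector T-cell density in the tumor and time-averaged
mAPC density in the lymph node, all over the therapy horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .engine import InitializationError, SimulationError, simulate
from .params import ModelParams, PatientParameters
from .pbpk import Regimen

__all__ = ["SensitivitySpec", "run_sensitivity", "prcc"]

#: default sensitivity ranges of the extended parameter set
SENSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "pdl1_frac": (0.01, 1.0),
    "pd1_frac": (0.01, 1.0),
    "pdl2_frac": (0.01, 1.0),
    "cd80_frac": (0.01, 1.0),
    "antigen_per_cell": (10.0, 1.0e5),
    "t_clonality": (5.0, 130.0),
    "mapc_inactivation_tme": (0.05, 0.95),
    "chemokine_factor": (50.0, 500.0),
    "mapc_activation_tdln": (0.1, 1.0),
    "tumor_diameter_start": (5.0, 80.0),
}

READOUTS = ("avg_tumor_diameter", "max_effector_density", "avg_mapc_density")


@dataclass
class SensitivitySpec:
    """Ranges, sample size and seed of one sensitivity run."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SENSITIVITY_RANGES)
    )
    n_samples: int = 100
    seed: int | None = None
    readouts: tuple[str, ...] = READOUTS

    def __post_init__(self) -> None:
        if self.n_samples < 10 * len(self.ranges):
            raise ValueError(
                f"n_samples must be >= 10x the number of parameters "
                f"({10 * len(self.ranges)})"
            )


def prcc(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partial rank correlation of each design column with the response.

    Rank-transforms everything, then correlates the residuals of column j
    and of the response after regressing both on the remaining columns.
    Returns (coefficients, p_values); a constant column yields NaN.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n, k = x.shape
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = stats.rankdata(y)
    coeffs = np.full(k, np.nan)
    pvals = np.full(k, np.nan)
    dof = n - k - 1
    for j in range(k):
        if np.ptp(rx[:, j]) == 0:
            continue
        others = np.delete(rx, j, axis=1)
        a = np.column_stack([np.ones(n), others])
        res_x = rx[:, j] - a @ np.linalg.lstsq(a, rx[:, j], rcond=None)[0]
        res_y = ry - a @ np.linalg.lstsq(a, ry, rcond=None)[0]
        denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
        if denom == 0:
            continue
        r = float((res_x * res_y).sum() / denom)
        r = min(1.0, max(-1.0, r))
        coeffs[j] = r
        if dof > 0 and abs(r) < 1.0:
            t = r * np.sqrt(dof / (1.0 - r**2))
            pvals[j] = 2.0 * stats.t.sf(abs(t), dof)
        else:
            pvals[j] = 0.0
    return coeffs, pvals


def _apply_sample(base: ModelParams, values: dict[str, float]) -> ModelParams:
    pt_fields = {f for f in PatientParameters.__dataclass_fields__}
    pt_kwargs = {}
    patient = base.patient
    for name in ("tumor_diameter_start", "t_clonality", "chemokine_factor",
                 "antigen_per_cell", "pdl1_frac"):
        pt_kwargs[name] = values.get(name, getattr(patient, name))
    pt_kwargs["antigen_strength"] = patient.antigen_strength
    pt_kwargs["treg_ln_frac"] = patient.treg_ln_frac
    pt_kwargs["treg_tumor_frac"] = patient.treg_tumor_frac
    pt = PatientParameters(**{k: v for k, v in pt_kwargs.items() if k in pt_fields})
    # sensitivity ranges deliberately exceed the trial-population bounds
    p = ModelParams(patient=pt)
    p.antigen = replace(
        p.antigen,
        antigen_per_cell=pt.antigen_per_cell,
        mapc_inactivation_tme=values.get(
            "mapc_inactivation_tme", p.antigen.mapc_inactivation_tme),
        mapc_activation_tdln=values.get(
            "mapc_activation_tdln", p.antigen.mapc_activation_tdln),
    )
    expr = dict(p.panel.expression)
    for key, name in (("PD1", "pd1_frac"), ("PDL1", "pdl1_frac"),
                      ("PDL2", "pdl2_frac"), ("CD80", "cd80_frac")):
        if name in values:
            expr[key] = values[name]
    p.panel = replace(p.panel, expression=expr)
    return p


def run_sensitivity(
    spec: SensitivitySpec,
    therapy: Regimen,
    horizon: float = 365.0,
    model_factory=None,
) -> pd.DataFrame:
    """LHS sample -> per-sample simulation -> PRCC table.

    Returns a tidy frame (parameter x readout) with the PRCC, its raw p and
    a Benjamini-Hochberg adjusted p per readout.  ``model_factory`` maps a
    value dict to readouts and exists so stub models can be sensitivity-
    tested; by default the full simulator is run.
    """
    names = list(spec.ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    unit = sampler.random(spec.n_samples)
    lows = np.array([spec.ranges[n][0] for n in names])
    highs = np.array([spec.ranges[n][1] for n in names])
    design = lows + (highs - lows) * unit

    responses = np.full((spec.n_samples, len(spec.readouts)), np.nan)
    for i, row in enumerate(design):
        values = dict(zip(names, row))
        if model_factory is not None:
            out = model_factory(values)
            responses[i] = [out[r] for r in spec.readouts]
            continue
        params = _apply_sample(ModelParams(), values)
        try:
            res = simulate(params, therapy, horizon=horizon)
        except (InitializationError, SimulationError):
            # immune elimination before therapy start: the tumor never
            # reaches its start diameter; readouts reflect a vanishing tumor
            fallback = {"avg_tumor_diameter": 0.0,
                        "max_effector_density": np.nan,
                        "avg_mapc_density": np.nan}
            responses[i] = [fallback[r] for r in spec.readouts]
            continue
        readouts = {
            "avg_tumor_diameter": float(res.diameter_mm.mean()),
            "max_effector_density": float(res.effector_density_tumor.max()),
            "avg_mapc_density": float(res.mapc_density_ln.mean()),
        }
        responses[i] = [readouts[r] for r in spec.readouts]

    rows = []
    for r_i, readout in enumerate(spec.readouts):
        y = responses[:, r_i]
        ok = np.isfinite(y)
        if ok.sum() < len(names) + 2:
            warnings.warn(f"too few valid samples for readout {readout}", stacklevel=2)
            continue
        coeffs, pvals = prcc(design[ok], y[ok])
        for j, name in enumerate(names):
            rows.append({"parameter": name, "readout": readout,
                         "prcc": coeffs[j], "p_value": pvals[j]})
    table = pd.DataFrame(rows)
    if len(table):
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(table), np.nan)
        for readout in table["readout"].unique():
            sel = (table["readout"] == readout) & table["p_value"].notna()
            if sel.sum():
                adj[sel.to_numpy()] = multipletests(
                    table.loc[sel, "p_value"], method="fdr_bh")[1]
        table["p_adjusted"] = adj
    return table
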
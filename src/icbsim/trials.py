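"""Virtual clinical trials: LHS cohorts, response classes, cohort summaries.

A cohort is drawn by Latin hypercube sampling over the physiological
parameter ranges (tumor diameter at therapy start, antigen strength, T-cell
clonality, lymph-node and tumor Treg fractions, %PD-L1 expression); every
parameter's n samples occupy its n equal-probability strata exactly once.
Each virtual patient is simulated under the trial regimen and the percent
change of the longest tumor diameter is classified with RECIST-1.1-style
thresholds: complete response below a detectability floor, partial response
at best change <= -30%, progressive disease (non-responder) at >= +20%,
stable disease otherwise.  Cohort summaries report the PR/CR fraction and
an "any response" fraction (PR/CR plus regressing stable disease, best
change below -10%), the waterfall vector, median trajectory with a
percentile band, and rank-based comparisons of each varied parameter
between non-responders and PR/CR patients with Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .engine import (
    InitializationError,
    SimulationError,
    SimulationResult,
    SolverSettings,
    simulate,
)
from .params import ModelParams, PatientParameters
from .pbpk import Regimen

__all__ = [
    "DEFAULT_RANGES",
    "ResponseClass",
    "PatientOutcome",
    "TrialResult",
    "sample_cohort",
    "classify_response",
    "run_trial",
    "responder_statistics",
]

#: Trial-population ranges of the varied physiological parameters.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "tumor_diameter_start": (15.0, 80.0),
    "antigen_strength": (0.8, 1.0),
    "t_clonality": (10.0, 130.0),
    "treg_ln_frac": (0.05, 0.35),
    "treg_tumor_frac": (0.0, 0.0025),
    "pdl1_frac": (0.40, 0.90),
}

#: Response classes: non-responder (progressive disease), stable disease,
#: partial and complete response.
CLASSES = ("NR", "SD", "PR", "CR")


class ResponseClass(str):
    pass


def sample_cohort(
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 200,
    seed: int | None = None,
) -> list[PatientParameters]:
    """Latin-hypercube cohort of ``n`` virtual patients.

    Each parameter's samples are stratified: exactly one draw falls in each
    of the n equal-width strata of its range.  Degenerate ranges (lo == hi)
    produce a constant column.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(ranges or DEFAULT_RANGES)
    names = list(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    cohort = []
    for row in unit:
        kw = {}
        for j, name in enumerate(names):
            lo, hi = ranges[name]
            kw[name] = lo + (hi - lo) * row[j]
        cohort.append(PatientParameters(**kw))
    return cohort


def classify_response(
    baseline_diameter: float,
    trajectory: np.ndarray,
    detect_floor_mm: float = 2.0,
    pr_threshold: float = -30.0,
    pd_threshold: float = 20.0,
) -> str:
    """Best-overall-response class from the longest-diameter trajectory.

    CR if the diameter ever falls below the detectability floor; PR if the
    best percent change is at or below -30%; NR (progressive) if the change
    ever reaches +20% without a prior PR/CR; SD otherwise.
    """
    if baseline_diameter <= 0:
        raise ValueError("baseline_diameter must be > 0")
    traj = np.asarray(trajectory, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    change = 100.0 * (traj / baseline_diameter - 1.0)
    best = float(change.min())
    if float(traj.min()) < detect_floor_mm:
        return "CR"
    if best <= pr_threshold:
        return "PR"
    if float(change.max()) >= pd_threshold:
        return "NR"
    return "SD"


@dataclass
class PatientOutcome:
    patient: PatientParameters
    response_class: str
    best_change: float          # % of baseline longest diameter
    final_change: float
    max_effector_density: float
    mean_mapc_density: float
    failed: bool = False


@dataclass
class TrialResult:
    """Per-patient outcomes plus cohort-level summaries."""

    outcomes: list[PatientOutcome]
    label: str = ""
    band_level: float = 90.0    # percentile band width (e.g. 90 or 30)
    time: np.ndarray | None = None
    median_change: np.ndarray | None = None
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def n_failed(self) -> int:
        return sum(o.failed for o in self.outcomes)

    def class_fractions(self) -> dict[str, float]:
        counts = {c: 0 for c in CLASSES}
        for o in self.outcomes:
            counts[o.response_class] += 1
        return {c: counts[c] / self.n for c in CLASSES}

    @property
    def orr(self) -> float:
        """Objective response rate: PR + CR fraction."""
        f = self.class_fractions()
        return f["PR"] + f["CR"]

    @property
    def any_response_rate(self) -> float:
        """PR/CR plus regressing stable disease (best change < -10%)."""
        hits = sum(
            o.response_class in ("PR", "CR")
            or (o.response_class == "SD" and o.best_change < -10.0)
            for o in self.outcomes
        )
        return hits / self.n

    def waterfall(self) -> np.ndarray:
        """Best percent changes sorted descending (waterfall plot vector)."""
        return np.sort([o.best_change for o in self.outcomes])[::-1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            row = {f.name: getattr(o.patient, f.name) for f in fields(o.patient)
                   if isinstance(getattr(o.patient, f.name), (int, float))}
            row.update(
                response_class=o.response_class,
                best_change=o.best_change,
                final_change=o.final_change,
                max_effector_density=o.max_effector_density,
                mean_mapc_density=o.mean_mapc_density,
                failed=o.failed,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _outcome_from_result(pt: PatientParameters, res: SimulationResult) -> PatientOutcome:
    change = res.percent_change()
    cls = classify_response(res.baseline_diameter, res.diameter_mm)
    return PatientOutcome(
        patient=pt,
        response_class=cls,
        best_change=float(change.min()),
        final_change=float(change[-1]),
        max_effector_density=float(res.effector_density_tumor.max()),
        mean_mapc_density=float(res.mapc_density_ln.mean()),
    )


def run_trial(
    cohort: list[PatientParameters],
    regimen: Regimen,
    horizon: float = 365.0,
    settings: SolverSettings | None = None,
    band_level: float = 90.0,
    base_params: ModelParams | None = None,
    label: str = "",
) -> TrialResult:
    """Simulate every cohort member under ``regimen`` and summarise.

    Patients whose integration fails (or whose tumor escapes all bounds)
    are recorded as non-responders with ``failed=True`` and counted in the
    report.  Results are independent of execution order.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    outcomes: list[PatientOutcome] = []
    trajectories: list[np.ndarray] = []
    time_grid: np.ndarray | None = None
    for pt in cohort:
        params = (
            replace(base_params, patient=pt) if base_params is not None
            else ModelParams(patient=pt)
        )
        try:
            res = simulate(params, regimen, horizon=horizon, settings=settings)
        except (InitializationError, SimulationError) as err:
            warnings.warn(f"patient failed ({err.__class__.__name__}); counted as NR",
                          stacklevel=2)
            outcomes.append(PatientOutcome(
                patient=pt, response_class="NR", best_change=np.nan,
                final_change=np.nan, max_effector_density=np.nan,
                mean_mapc_density=np.nan, failed=True,
            ))
            continue
        outcomes.append(_outcome_from_result(pt, res))
        trajectories.append(res.percent_change())
        if time_grid is None or len(res.time) > len(time_grid):
            time_grid = res.time

    result = TrialResult(outcomes=outcomes, label=label or regimen.label,
                         band_level=band_level)
    if trajectories and time_grid is not None:
        n_t = min(len(t) for t in trajectories)
        mat = np.vstack([t[:n_t] for t in trajectories])
        half = band_level / 2.0
        result.time = time_grid[:n_t]
        result.median_change = np.median(mat, axis=0)
        result.band_lo = np.percentile(mat, 50.0 - half, axis=0)
        result.band_hi = np.percentile(mat, 50.0 + half, axis=0)
    return result


def responder_statistics(
    result: TrialResult,
    parameters: tuple[str, ...] = tuple(DEFAULT_RANGES),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based NR vs PR/CR comparison per varied parameter.

    Mann-Whitney U per parameter with Benjamini-Hochberg adjustment across
    parameters.  Parameters that are constant in the cohort, or classes
    with fewer than two members, are skipped with a notice.
    """
    df = result.to_frame()
    df = df[~df["failed"].astype(bool)]
    nr = df[df["response_class"] == "NR"]
    rc = df[df["response_class"].isin(["PR", "CR"])]
    if len(nr) < 2 or len(rc) < 2:
        raise ValueError("need at least two members in both NR and PR/CR classes")
    rows = []
    for name in parameters:
        x, y = nr[name].to_numpy(), rc[name].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0.0:
            warnings.warn(f"parameter {name} is constant; test skipped", stacklevel=2)
            continue
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"parameter": name, "statistic": float(u), "p_value": float(p),
                     "median_nr": float(np.median(x)), "median_prcr": float(np.median(y))})
    table = pd.DataFrame(rows)
    if len(table):
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, *_ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
        table["p_adjusted"] = p_adj
        table["significant"] = reject
    return table
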
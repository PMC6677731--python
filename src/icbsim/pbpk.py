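"""Minimal PBPK of checkpoint antibodies with infusion scheduling.

Each antibody distributes over five compartments: central (plasma), tight
tissue, leaky tissue, lymph and tumor.  Doses enter the central compartment
as zero-order IV infusions (1 or 1.5 h by drug) and are cleared first-order
from plasma.  Tissue distribution follows the two-pore minimal-PBPK layout:
lymph flow carries antibody from plasma into tight/leaky tissue (attenuated
by vascular reflection coefficients), out through the lymph compartment and
back to plasma.  Tumor exchange is a permeability-surface-area flux whose
magnitude scales with the current tumor surface area (the tumor PK volume
tracks the true tumor size); an influx/efflux permeability asymmetry
represents enhanced permeability and retention.  Target-mediated drug
disposition, implemented as the quasi-equilibrium (Michaelis-Menten) limit
of target binding plus complex internalisation, applies to anti-CTLA-4 only.

State for one drug is the amount vector [central, tight, leaky, lymph,
tumor] in mg; free concentrations (mg/L) are amounts over compartment
volumes.  Molar conversion uses the IgG molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IGG_MW",
    "TmddParameters",
    "PkParameters",
    "DoseEvent",
    "Regimen",
    "expand_schedule",
    "infusion_rate",
    "pk_rhs",
    "mg_per_l_to_molar",
    "N_PK_STATES",
    "PK_COMPARTMENTS",
]

IGG_MW = 1.5e5  # g/mol

PK_COMPARTMENTS = ("central", "tight", "leaky", "lymph", "tumor")
N_PK_STATES = len(PK_COMPARTMENTS)


def mg_per_l_to_molar(conc_mg_per_l: float) -> float:
    return conc_mg_per_l * 1e-3 / IGG_MW


@dataclass
class TmddParameters:
    """Quasi-equilibrium target-mediated disposition (anti-CTLA-4 only).

    The target pool is at synthesis/degradation steady state
    ``R_tot = k_syn / k_deg``; drug bound at equilibrium ``Kd`` is
    internalised with the complex at ``k_int``, giving the saturable
    clearance term ``k_int * R_tot * C/(Kd + C)`` in the central compartment.
    """

    k_syn: float  # M/day, target synthesis (central)
    k_deg: float  # 1/day, free-target turnover
    k_int: float  # 1/day, complex internalisation
    kd: float     # M

    @property
    def r_total(self) -> float:
        return self.k_syn / self.k_deg


@dataclass
class PkParameters:
    """Distribution/elimination constants for one antibody."""

    drug: str
    clearance: float            # L/day from central
    v_central: float            # L
    v_tight: float              # L
    v_leaky: float              # L
    v_lymph: float              # L
    lymph_flow_tight: float     # L/day plasma -> tight
    lymph_flow_leaky: float     # L/day plasma -> leaky
    sigma_tight: float          # vascular reflection, tight tissue
    sigma_leaky: float          # vascular reflection, leaky tissue
    sigma_lymph: float          # lymphatic reflection (usually ~0)
    tumor_perm_in: float        # L/day per dm^2 of tumor surface, plasma -> tumor
    tumor_perm_out: float       # L/day per dm^2, tumor -> lymph (EPR: out < in)
    infusion_hours: float = 1.0
    tmdd: TmddParameters | None = None

    def __post_init__(self) -> None:
        for name in ("clearance", "v_central", "v_tight", "v_leaky", "v_lymph",
                     "lymph_flow_tight", "lymph_flow_leaky"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.drug}: {name} must be > 0")
        if (self.tmdd is not None) != (self.drug == "antiCTLA4"):
            raise ValueError("TMDD parameters are present iff drug is antiCTLA4")


@dataclass(frozen=True)
class DoseEvent:
    drug: str
    dose: float            # mg per kg body weight
    start: float           # day
    infusion_duration: float  # hours

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.infusion_duration <= 0:
            raise ValueError("infusion_duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.infusion_duration / 24.0


@dataclass
class Regimen:
    """Time-ordered dosing events for one or more drugs."""

    events: list[DoseEvent] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start, e.drug))
        by_drug: dict[str, float] = {}
        for e in self.events:
            if e.start < by_drug.get(e.drug, -np.inf):
                raise ValueError(f"overlapping infusions of {e.drug}")
            by_drug[e.drug] = e.end

    @property
    def drugs(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.drug)
        return list(seen)

    def breakpoints(self, horizon: float) -> np.ndarray:
        """Integration restart points: every infusion window edge in [0, horizon]."""
        pts = {0.0, float(horizon)}
        for e in self.events:
            for t in (e.start, e.end):
                if 0.0 < t < horizon:
                    pts.add(float(t))
        return np.array(sorted(pts))

    def __add__(self, other: "Regimen") -> "Regimen":
        return Regimen(events=self.events + other.events,
                       label=" then ".join(filter(None, [self.label, other.label])))


def expand_schedule(
    drug: str,
    dose: float,
    interval_days: float,
    n_doses: int,
    start_day: float = 0.0,
    infusion_hours: float = 1.0,
    label: str = "",
) -> Regimen:
    """Regular schedule: ``n_doses`` events at ``start_day + k*interval_days``."""
    if interval_days <= 0:
        raise ValueError("interval_days must be > 0")
    if n_doses < 0:
        raise ValueError("n_doses must be >= 0")
    events = [
        DoseEvent(drug=drug, dose=dose, start=start_day + k * interval_days,
                  infusion_duration=infusion_hours)
        for k in range(n_doses)
    ]
    if not label:
        label = f"{drug} {dose:g} mg/kg q{interval_days:g}d x{n_doses}"
    return Regimen(events=events, label=label)


def infusion_rate(t: float, regimen: Regimen, body_weight: float) -> dict[str, float]:
    """Zero-order infusion rate (mg/day) per drug at time ``t`` (day).

    Constant ``dose * weight / duration`` inside each infusion window, zero
    outside; window edges are half-open ``[start, end)`` so rates integrate
    exactly to the administered mass.
    """
    rates: dict[str, float] = {}
    for e in regimen.events:
        if e.start <= t < e.end and e.dose > 0:
            rates[e.drug] = rates.get(e.drug, 0.0) + e.dose * body_weight / (
                e.infusion_duration / 24.0
            )
    return rates


def tumor_exchange_coefficients(
    p: PkParameters, tumor_volume_l: float
) -> tuple[float, float]:
    """(influx, efflux) clearances in L/day for the current tumor volume.

    Permeability is applied over the vascular exchange surface, which scales
    with tumor volume^(2/3); volumes in liters are converted to a dm^2
    surface scale so the permeability constants carry per-area units.
    """
    surface = max(tumor_volume_l, 0.0) ** (2.0 / 3.0)
    return p.tumor_perm_in * surface, p.tumor_perm_out * surface


def pk_rhs(
    state: np.ndarray,
    params: PkParameters,
    rate_in: float,
    tumor_volume_l: float,
) -> np.ndarray:
    """Amount derivatives (mg/day) for one drug.

    Mass balance: d(total)/dt = rate_in - linear elimination - TMDD
    internalisation.  The reported concentration in each compartment is the
    free concentration (no explicit bound states outside TMDD).
    """
    if np.any(np.asarray(state) < -1e-9):
        raise ValueError("negative drug amount")
    a_c, a_t, a_l, a_ly, a_tu = state
    c_c = a_c / params.v_central
    c_t = a_t / params.v_tight
    c_l = a_l / params.v_leaky
    c_ly = a_ly / params.v_lymph
    v_tumor = max(tumor_volume_l, 1e-9)
    c_tu = a_tu / v_tumor

    l1, l2 = params.lymph_flow_tight, params.lymph_flow_leaky
    j_in_t = l1 * (1.0 - params.sigma_tight) * c_c
    j_in_l = l2 * (1.0 - params.sigma_leaky) * c_c
    j_out_t = l1 * (1.0 - params.sigma_lymph) * c_t
    j_out_l = l2 * (1.0 - params.sigma_lymph) * c_l
    j_lymph_return = (l1 + l2) * c_ly

    cl_in, cl_out = tumor_exchange_coefficients(params, v_tumor)
    j_tumor_in = cl_in * c_c
    j_tumor_out = cl_out * c_tu  # drains to lymph

    elim = params.clearance * c_c
    tmdd_flux = 0.0
    if params.tmdd is not None:
        c_molar = mg_per_l_to_molar(c_c)
        td = params.tmdd
        # saturable internalisation of drug-target complex, central compartment
        tmdd_flux = (
            td.k_int * td.r_total * c_molar / (td.kd + c_molar)
        ) * params.v_central * IGG_MW * 1e3  # M/day * L -> mol/day -> mg/day

    d_c = rate_in - elim - tmdd_flux - j_in_t - j_in_l + j_lymph_return - j_tumor_in
    d_t = j_in_t - j_out_t
    d_l = j_in_l - j_out_l
    d_ly = j_out_t + j_out_l + j_tumor_out - j_lymph_return
    d_tu = j_tumor_in - j_tumor_out
    return np.array([d_c, d_t, d_l, d_ly, d_tu])
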
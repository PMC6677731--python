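"""Cellular dynamics: lymph-node priming, effector trafficking, tumor killing.

The cellular state is a flat vector of cell/molecule counts covering

* one representative tumor-draining lymph node (TDLN): the naive T pool
  ``NT``, stage-1 and stage-2 priming complexes ``NT1``/``NT2``, a
  three-stage proliferation transit chain ``PRO1..PRO3``, mature
  antigen-presenting cells ``mAPC_ln`` and free tumor antigen ``TAA_ln``;
* effector T cells trafficking through blood and seven tissue compartments
  (lung, liver, spleen, tumor with explicit vascular-bound / arrested /
  interstitial states; GI tract, peripheral lump and non-draining lymph
  nodes as single interstitial pools);
* the tumor: cancer cells ``C`` (total count; the checkpoint-subtype
  composition is a constant lattice), immature and mature APCs and free
  antigen ``TAA_t``.

Priming follows the three-stage intravital picture: naive T cells associate
with non-interacting mAPCs with a probability of at least one successful
encounter over the contact window,

    P1 = 1 - exp(-4*pi*D_T*Diff_T*mAPC_nInt*[T]*phi_NT*Antigen
                 / (TClonality * S_NT_mAPC) * t_max),

unsuccessful complexes dissociate back, and successfully activated cells
pass through a proliferation chain whose output is amplified by
``2**(divisions/day * duration * stimulation)`` - up to 2^15 for three
divisions a day over five days at maximal costimulation.  The effector flux
leaving the chain is multiplied by the number of TDLNs acting in parallel.

Effector-target killing uses the saturating fractional-association law

    dT/dt = -d * (E/T)**lam / (s + (E/T)**lam) * T.

Killed and naturally dying cancer cells release a fixed number of antigen
molecules each; tumor APCs take the antigen up and mature, mAPCs and free
antigen drain to the TDLNs (an equal share to each), closing the priming
feed-forward loop.

Regulatory cells (Tregs, MDSCs) are algebraic populations proportional to
the local T-cell or cancer-cell count; they act only through the checkpoint
ligands they contribute, not through any additional suppression pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IMMUNE_STATES",
    "STATE_INDEX",
    "CellState",
    "PrimingParameters",
    "KillingParameters",
    "TraffickingParameters",
    "AntigenCycleParameters",
    "TumorGrowthParameters",
    "TumorGeometry",
    "priming_probability",
    "priming_rhs",
    "killing_rate",
    "antigen_cycle_rhs",
    "trafficking_matrix",
    "trafficking_rhs",
    "regulatory_populations",
    "tumor_geometry_convert",
    "diameter_to_cells",
    "cells_to_diameter",
]

IMMUNE_STATES = (
    "NT", "NT1", "NT2", "PRO1", "PRO2", "PRO3", "mAPC_ln", "TAA_ln",
    "E_blood",
    "E_lung_bound", "E_lung_arrest", "E_lung_int",
    "E_liver_bound", "E_liver_arrest", "E_liver_int",
    "E_spleen_bound", "E_spleen_arrest", "E_spleen_int",
    "E_tumor_bound", "E_tumor_arrest", "E_tumor_int",
    "E_gi_int", "E_periph_int", "E_ln_int",
    "C", "APC_t", "mAPC_t", "TAA_t",
)
STATE_INDEX = {name: i for i, name in enumerate(IMMUNE_STATES)}
N_IMMUNE = len(IMMUNE_STATES)

#: slice of the effector-trafficking block within the immune state vector
TRAFFIC_SLICE = slice(STATE_INDEX["E_blood"], STATE_INDEX["E_ln_int"] + 1)
TRAFFIC_STATES = IMMUNE_STATES[TRAFFIC_SLICE]
N_TRAFFIC = len(TRAFFIC_STATES)


class CellState:
    """Named view over the flat immune state vector."""

    __slots__ = ("vec",)

    def __init__(self, vec: np.ndarray | None = None):
        self.vec = np.zeros(N_IMMUNE) if vec is None else np.asarray(vec, dtype=float)
        if self.vec.shape != (N_IMMUNE,):
            raise ValueError(f"immune state must have length {N_IMMUNE}")

    def __getitem__(self, name: str) -> float:
        return float(self.vec[STATE_INDEX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.vec[STATE_INDEX[name]] = value

    def copy(self) -> "CellState":
        return CellState(self.vec.copy())


@dataclass
class PrimingParameters:
    """Constants of the TDLN priming cascade.  Rates are per day, lengths in
    micrometers; ``s_nt_mapc`` is the dimensionless encounter scaling that
    absorbs the lymph-node geometry."""

    k_assoc_p1: float = 8.0          # 1/day, stage-1 association
    k_dissoc_p1: float = 2.0         # 1/day, unsuccessful stage-1 dissociation
    k_assoc_p2: float = 6.0          # 1/day, stage-2 association
    k_dissoc_p2: float = 2.0         # 1/day, unsuccessful stage-2 dissociation
    k_activate: float = 2.0          # 1/day, stage-2 -> proliferation
    d_t: float = 7.0                 # um, T-cell diameter
    diff_t: float = 1.4e4            # um^2/day, T-cell motility
    phi_nt: float = 0.01             # fraction of TDLN T cells available
    antigen_strength: float = 0.9    # dimensionless in [0.1, 1.0]
    t_clonality: float = 70.0        # number of tumor-specific clones
    s_nt_mapc: float = 1.0e12        # encounter scaling (absorbs LN geometry)
    t_max: float = 0.5               # day, priming contact window
    sig_cd28: float = 0.9            # CD28:CD80/86 costimulatory occupancy
    proliferation_rate: float = 3.0  # divisions/day at maximal stimulation
    proliferation_duration: float = 5.0  # day
    n_tdln: float = 32.0             # TDLNs acting in parallel
    t_total_ln: float = 2.0e8        # total T cells per TDLN
    copies_per_clone: float = 2000.0  # naive precursor copies per clone (per TDLN share)
    k_nt_homeostasis: float = 0.2    # 1/day, naive-pool replenishment
    treg_costim_weight: float = 0.5  # LN-Treg sequestration of costimulation

    def __post_init__(self) -> None:
        if not (0.1 <= self.antigen_strength <= 1.0):
            raise ValueError("antigen_strength must lie in [0.1, 1.0]")
        if self.t_clonality < 1:
            raise ValueError("t_clonality must be >= 1")

    @property
    def naive_pool_target(self) -> float:
        return self.copies_per_clone * self.t_clonality


@dataclass
class KillingParameters:
    """Saturating effector-target killing law constants."""

    d: float = 0.26    # 1/day, association rate for killing
    lam: float = 1.2   # exponent of fractional cell association
    s: float = 0.05    # steepness coefficient

    def __post_init__(self) -> None:
        if self.d <= 0 or self.s <= 0 or self.lam <= 0:
            raise ValueError("d, s and lam must all be > 0")


@dataclass
class TraffickingParameters:
    """First-order transport rates (1/day) of the effector circuit.

    ``k_bind_tumor_ref`` applies at the reference diameter and scales with
    the tumor's vascular surface (diameter squared); the arrest rate in the
    tumor is ``k_arrest_tumor_base * chemokine_factor``.
    """

    k_bind_lung: float = 2.0
    k_bind_liver: float = 0.8
    k_bind_spleen: float = 0.6
    k_bind_tumor_ref: float = 1.0
    ref_diameter_mm: float = 40.0
    k_unbind: float = 1.0
    k_arrest_lung: float = 0.05
    k_arrest_liver: float = 0.1
    k_arrest_spleen: float = 0.1
    k_arrest_tumor_base: float = 2.0e-3
    k_extravasate: float = 1.0
    k_return: float = 0.3
    k_in_gi: float = 0.3
    k_in_periph: float = 1.0
    k_in_ln: float = 0.2
    k_death: float = 0.05
    k_elim_lung: float = 0.2
    k_death_tumor: float = 0.05
    death_checkpoint_boost: float = 8.0  # tumor effector death scales 1 + boost*f_a


@dataclass
class AntigenCycleParameters:
    """Antigen release, APC maturation and drainage back to the TDLNs."""

    antigen_per_cell: float = 100.0    # TAA molecules released per dead cancer cell
    cancer_turnover: float = 0.005     # 1/day, natural death releasing TAA
    k_apc_influx: float = 1.0e6        # APC/day entering tumor at reference size
    k_apc_death: float = 0.3           # 1/day
    k_uptake: float = 5.0e-5           # 1/day per APC, TAA capture
    antigen_per_mapc: float = 100.0    # TAA consumed to mature one APC
    mapc_inactivation_tme: float = 0.5 # fraction of maturing APCs inactivated
    k_mapc_migrate: float = 0.5        # 1/day, mAPC drainage to TDLNs
    k_mapc_death: float = 0.3          # 1/day (both compartments)
    k_taa_drain: float = 0.2           # 1/day, free TAA drainage to TDLNs
    k_taa_degrade: float = 1.0         # 1/day
    k_apc_ln: float = 2.0e-3           # 1/day, LN-resident APC maturation per TAA
    mapc_activation_tdln: float = 0.7  # mAPC priming effectiveness in the TDLN


@dataclass
class TumorGrowthParameters:
    """Intrinsic growth law of the cancer-cell population.

    Default is Gompertzian, ``dC/dt = a*ln(K/C)*C``: the specific growth
    rate decelerates as the tumor approaches carrying capacity, so small
    tumors grow proportionally faster - the standard empirical law for
    solid-tumor growth curves.  A logistic alternative is available via
    ``law``.  ``growth_rate`` is the Gompertz ``a`` (or the logistic
    intrinsic rate), per day.
    """

    growth_rate: float = 0.0017        # 1/day
    capacity_diameter_mm: float = 200.0
    law: str = "gompertz"              # or "logistic"

    def rate(self, cells: float, capacity: float) -> float:
        """Current growth flux dC/dt for ``cells`` given ``capacity``."""
        c = min(max(cells, 1.0), capacity)
        if self.law == "gompertz":
            return self.growth_rate * c * math.log(capacity / c)
        if self.law == "logistic":
            return self.growth_rate * c * (1.0 - c / capacity)
        raise ValueError(f"unknown growth law {self.law!r}")


@dataclass
class TumorGeometry:
    """Ellipsoid tumor with axes (d, r1*d, r2*d) along the longest diameter."""

    axis_ratio: tuple[float, float] = (0.75, 0.5)
    cell_density: float = 1.0e5        # cells/mm^3 (packed-cell fraction included)

    def volume_mm3(self, diameter_mm: float) -> float:
        r1, r2 = self.axis_ratio
        return math.pi / 6.0 * diameter_mm**3 * r1 * r2


def tumor_geometry_convert(
    value: float, g: TumorGeometry, to: str = "cells"
) -> float:
    """Bijective diameter (mm) <-> cell-count map through ellipsoid volume.

    ``to='cells'`` converts a longest diameter, ``to='diameter'`` a count.
    """
    if value <= 0:
        raise ValueError("input must be > 0")
    r1, r2 = g.axis_ratio
    k = math.pi / 6.0 * r1 * r2 * g.cell_density
    if to == "cells":
        return k * value**3
    if to == "diameter":
        return (value / k) ** (1.0 / 3.0)
    raise ValueError("to must be 'cells' or 'diameter'")


def diameter_to_cells(diameter_mm: float, g: TumorGeometry) -> float:
    return tumor_geometry_convert(diameter_mm, g, to="cells")


def cells_to_diameter(cells: float, g: TumorGeometry) -> float:
    return tumor_geometry_convert(cells, g, to="diameter")


def priming_probability(
    p: PrimingParameters, mapc_nint: float, t_total: float
) -> float:
    """Probability of at least one successful priming encounter.

    Exponential-encounter form: increasing in the available mAPC count and
    antigen strength, decreasing in the clonality (more clones dilute the
    copies of each) and in the encounter scaling ``s_nt_mapc``.
    """
    if mapc_nint < 0 or t_total < 0:
        raise ValueError("counts must be >= 0")
    if p.t_clonality <= 0:
        raise ValueError("t_clonality must be > 0")
    x = (
        4.0 * math.pi * p.d_t * p.diff_t * mapc_nint * t_total
        * p.phi_nt * p.antigen_strength
        / (p.t_clonality * p.s_nt_mapc)
        * p.t_max
    )
    return 1.0 - math.exp(-x)


def proliferation_fold(p: PrimingParameters, stimulation: float) -> float:
    """Cohort expansion across the proliferation chain: 2**(rate*duration*stim).

    At full stimulation (three divisions a day over five days) this is 2^15.
    """
    n_div = p.proliferation_rate * p.proliferation_duration * min(max(stimulation, 0.0), 1.0)
    return 2.0**n_div


def priming_rhs(
    state: CellState | np.ndarray,
    p: PrimingParameters,
    cd28_signal: float | None = None,
    ctla4_inhibition: float = 0.0,
    treg_ln_frac: float = 0.0,
    mapc_activation: float = 1.0,
    proliferate: bool = True,
    homeostasis: bool = True,
) -> np.ndarray:
    """TDLN priming-cascade derivatives (full-length immune vector).

    Stage-1 influx is ``k_assoc_p1 * NT * P1 * SigCD28`` scaled down by the
    integrated CTLA-4 inhibitory signal ``(1 - f_a)``; unsuccessful
    complexes dissociate back to the naive pool; stage 2 is analogous.
    Activated cells traverse the proliferation chain and the effector output
    flux into blood is multiplied by the number of TDLNs.  LN Tregs
    sequester costimulation: the effective CD28 signal is scaled by
    ``(1 - treg_costim_weight * treg_ln_frac)``.
    """
    y = state.vec if isinstance(state, CellState) else np.asarray(state, dtype=float)
    d = np.zeros(N_IMMUNE)
    nt = y[STATE_INDEX["NT"]]
    nt1 = y[STATE_INDEX["NT1"]]
    nt2 = y[STATE_INDEX["NT2"]]
    mapc = y[STATE_INDEX["mAPC_ln"]]

    sig = p.sig_cd28 if cd28_signal is None else cd28_signal
    sig_eff = sig * max(0.0, 1.0 - p.treg_costim_weight * treg_ln_frac)
    inhib = max(0.0, 1.0 - ctla4_inhibition)

    # mAPCs engaged in complexes are unavailable for new encounters
    mapc_nint = max(mapc - nt1 - nt2, 0.0) * mapc_activation
    p1 = priming_probability(p, mapc_nint, p.t_total_ln)

    f1 = p.k_assoc_p1 * nt * p1 * sig_eff * inhib
    # stage 2 matures an existing conjugate; no new encounter probability
    f2 = p.k_assoc_p2 * nt1 * sig_eff * inhib
    f_act = p.k_activate * nt2

    d[STATE_INDEX["NT"]] = -f1 + p.k_dissoc_p1 * nt1 + p.k_dissoc_p2 * nt2
    if homeostasis:
        d[STATE_INDEX["NT"]] += p.k_nt_homeostasis * (p.naive_pool_target - nt)
    d[STATE_INDEX["NT1"]] = f1 - p.k_dissoc_p1 * nt1 - f2
    d[STATE_INDEX["NT2"]] = f2 - p.k_dissoc_p2 * nt2 - f_act

    k_tr = 3.0 / p.proliferation_duration
    i1, i2, i3 = (STATE_INDEX[k] for k in ("PRO1", "PRO2", "PRO3"))
    d[i1] = f_act - k_tr * y[i1]
    d[i2] = k_tr * (y[i1] - y[i2])
    d[i3] = k_tr * (y[i2] - y[i3])

    # the transit chain carries cohort identity; expansion is applied to the
    # output flux, and the whole flux is multiplied across parallel TDLNs
    fold = proliferation_fold(p, sig_eff * inhib) if proliferate else 1.0
    d[STATE_INDEX["E_blood"]] = k_tr * y[i3] * fold * p.n_tdln
    return d


def killing_rate(effectors: float, targets: float, k: KillingParameters) -> float:
    """Cancer-cell kill rate d*(E/T)^lam/(s+(E/T)^lam)*T (cells/day).

    Saturates at ``d*T`` for overwhelming effector excess; zero targets or
    zero effectors give zero (no division by zero).
    """
    if targets <= 0.0 or effectors <= 0.0:
        return 0.0
    ratio = (effectors / targets) ** k.lam
    return k.d * ratio / (k.s + ratio) * targets


def antigen_cycle_rhs(
    state: CellState | np.ndarray,
    antigen_per_cell: float,
    chemokine_factor: float,
    mapc_params: AntigenCycleParameters,
    kill_flux: float = 0.0,
    n_tdln: float = 32.0,
    tumor_size_scale: float = 1.0,
) -> np.ndarray:
    """TAA release, APC maturation and drainage derivatives.

    ``kill_flux`` is the current cancer-cell kill rate (cells/day); natural
    turnover adds ``cancer_turnover * C``.  Each of the ``n_tdln`` lymph
    nodes receives an equal share of the migrating mAPCs and draining TAA;
    the representative TDLN state tracks one node's share.  ``chemokine_factor``
    is accepted for interface symmetry with the trafficking step (it acts on
    arrest, not on the antigen cycle).
    """
    del chemokine_factor
    y = state.vec if isinstance(state, CellState) else np.asarray(state, dtype=float)
    d = np.zeros(N_IMMUNE)
    a = mapc_params
    c = y[STATE_INDEX["C"]]
    apc = y[STATE_INDEX["APC_t"]]
    mapc_t = y[STATE_INDEX["mAPC_t"]]
    taa_t = y[STATE_INDEX["TAA_t"]]
    taa_ln = y[STATE_INDEX["TAA_ln"]]
    mapc_ln = y[STATE_INDEX["mAPC_ln"]]

    death_flux = a.cancer_turnover * c + kill_flux
    release = antigen_per_cell * death_flux

    uptake = a.k_uptake * apc * taa_t
    maturation = uptake / a.antigen_per_mapc * (1.0 - a.mapc_inactivation_tme)

    d[STATE_INDEX["APC_t"]] = (
        a.k_apc_influx * tumor_size_scale - a.k_apc_death * apc - uptake / a.antigen_per_mapc
    )
    d[STATE_INDEX["mAPC_t"]] = maturation - (a.k_mapc_migrate + a.k_mapc_death) * mapc_t
    d[STATE_INDEX["TAA_t"]] = release - uptake - (a.k_taa_drain + a.k_taa_degrade) * taa_t

    ln_uptake = a.k_apc_ln * taa_ln
    d[STATE_INDEX["TAA_ln"]] = a.k_taa_drain * taa_t / n_tdln - ln_uptake - a.k_taa_degrade * taa_ln
    d[STATE_INDEX["mAPC_ln"]] = (
        a.k_mapc_migrate * mapc_t / n_tdln
        + ln_uptake / a.antigen_per_mapc
        - a.k_mapc_death * mapc_ln
    )
    return d


def trafficking_matrix(
    params: TraffickingParameters,
    chemokine_factor: float,
    tumor_diameter_mm: float,
    eliminate: bool = True,
) -> np.ndarray:
    """Linear transport operator A of the effector circuit (dE/dt = A @ E).

    Rows/columns follow ``TRAFFIC_STATES``.  Reversible vascular binding,
    irreversible arrest, extravasation, lymphatic return (tumor interstitium
    is absorbing) and, when ``eliminate``, death plus lung/tumor
    elimination.  The tumor binding rate scales with vascular surface
    (diameter squared) and its arrest rate with the chemokine factor.
    """
    t = params
    idx = {name: i for i, name in enumerate(TRAFFIC_STATES)}
    a = np.zeros((N_TRAFFIC, N_TRAFFIC))

    def move(src: str, dst: str, rate: float) -> None:
        a[idx[src], idx[src]] -= rate
        a[idx[dst], idx[src]] += rate

    k_bind_tumor = t.k_bind_tumor_ref * (tumor_diameter_mm / t.ref_diameter_mm) ** 2
    k_arrest_tumor = t.k_arrest_tumor_base * chemokine_factor

    for organ, k_bind, k_arr in (
        ("lung", t.k_bind_lung, t.k_arrest_lung),
        ("liver", t.k_bind_liver, t.k_arrest_liver),
        ("spleen", t.k_bind_spleen, t.k_arrest_spleen),
        ("tumor", k_bind_tumor, k_arrest_tumor),
    ):
        move("E_blood", f"E_{organ}_bound", k_bind)
        move(f"E_{organ}_bound", "E_blood", t.k_unbind)
        move(f"E_{organ}_bound", f"E_{organ}_arrest", k_arr)
        move(f"E_{organ}_arrest", f"E_{organ}_int", t.k_extravasate)
        if organ != "tumor":
            move(f"E_{organ}_int", "E_blood", t.k_return)

    for organ, k_in in (("gi", t.k_in_gi), ("periph", t.k_in_periph), ("ln", t.k_in_ln)):
        move("E_blood", f"E_{organ}_int", k_in)
        move(f"E_{organ}_int", "E_blood", t.k_return)

    if eliminate:
        for name in TRAFFIC_STATES:
            a[idx[name], idx[name]] -= t.k_death
        a[idx["E_lung_int"], idx["E_lung_int"]] -= t.k_elim_lung
        # tumor interstitial elimination is handled in the tumor block where
        # it depends on checkpoint signaling
    return a


def trafficking_rhs(
    state: CellState | np.ndarray,
    params: TraffickingParameters,
    chemokine_factor: float = 100.0,
    tumor_diameter_mm: float = 40.0,
    eliminate: bool = True,
) -> np.ndarray:
    """Effector transport derivatives (full-length immune vector)."""
    y = state.vec if isinstance(state, CellState) else np.asarray(state, dtype=float)
    a = trafficking_matrix(params, chemokine_factor, tumor_diameter_mm, eliminate)
    d = np.zeros(N_IMMUNE)
    d[TRAFFIC_SLICE] = a @ y[TRAFFIC_SLICE]
    return d


def regulatory_populations(
    state: CellState | np.ndarray,
    treg_ln_frac: float,
    treg_tumor_frac: float,
    mdsc_multiplier: float = 3.0,
    t_total_ln: float = 2.0e8,
) -> tuple[float, float, float]:
    """Algebraic (treg_ln, treg_tumor, mdsc) counts at the current state.

    LN Tregs are a fraction of the total TDLN T-cell count; tumor Tregs a
    fraction of the cancer-cell count; MDSCs a multiple of tumor Tregs.
    """
    y = state.vec if isinstance(state, CellState) else np.asarray(state, dtype=float)
    c = y[STATE_INDEX["C"]]
    treg_ln = treg_ln_frac * t_total_ln
    treg_tumor = treg_tumor_frac * c
    return treg_ln, treg_tumor, mdsc_multiplier * treg_tumor
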
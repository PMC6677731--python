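"""Assembled tumor-immune-PK system, initialization and simulation.

One virtual patient is a stiff ODE system combining the immune state (28
cellular/molecular counts) with five PK states per administered drug.  The
molecular checkpoint layer is algebraic: at every right-hand-side
evaluation the local free antibody concentrations set the competitive
receptor occupancies, the per-subtype combined effects f_a, and through
them the killing, effector-survival and priming fluxes.

Runs start from a quasi-steady state: the drug-free system is integrated
from a tumor at 95% of the therapy-start diameter until the tumor grows to
the start diameter, which lets the immune feed-forward loop (antigen
release -> APC maturation -> TDLN priming -> effector influx) equilibrate
against the growing tumor.  Therapy is then simulated to the horizon
(default one year), restarting the integrator at every infusion-window edge
so the zero-order infusion rates are exact within each segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import pbpk
from .checkpoints import CheckpointAxis
from .immune import (
    IMMUNE_STATES,
    N_IMMUNE,
    STATE_INDEX,
    TRAFFIC_SLICE,
    CellState,
    antigen_cycle_rhs,
    cells_to_diameter,
    diameter_to_cells,
    killing_rate,
    priming_rhs,
    trafficking_matrix,
)
from .params import KILLING_AXIS_GATES, ModelParams
from .pbpk import N_PK_STATES, Regimen, infusion_rate, mg_per_l_to_molar, pk_rhs

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "InitializationError",
    "SimulationError",
    "AssembledModel",
    "initialize",
    "simulate",
]


class InitializationError(RuntimeError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integrator settings; tolerance defaults follow the original
    study (absolute 1e-9, relative 1e-8)."""

    abs_tol: float = 1e-9
    rel_tol: float = 1e-8
    method: str = "BDF"
    #: finite cap on the step (day) keeps the multistep predictor from
    #: extrapolating across the sharp regression/regrowth turning points
    max_step: float = 7.0

    def __post_init__(self) -> None:
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class SimulationResult:
    """Daily-grid trajectory with the derived clinical readouts."""

    time: np.ndarray                      # day, from therapy start
    states: np.ndarray                    # (n_t, n_states)
    state_names: list[str]
    diameter_mm: np.ndarray
    effector_density_tumor: np.ndarray    # cells/mL tumor
    mapc_density_ln: np.ndarray           # cells/mL TDLN
    drug_conc: dict[str, np.ndarray]      # plasma mg/L, keyed by drug
    drug_conc_tumor: dict[str, np.ndarray]
    drug_conc_lymph: dict[str, np.ndarray]
    params: ModelParams | None = None
    regimen: Regimen | None = None

    @property
    def baseline_diameter(self) -> float:
        return float(self.diameter_mm[0])

    def percent_change(self) -> np.ndarray:
        return 100.0 * (self.diameter_mm / self.baseline_diameter - 1.0)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.state_names)
        df.insert(0, "time", self.time)
        df["diameter_mm"] = self.diameter_mm
        df["effector_density_tumor"] = self.effector_density_tumor
        df["mapc_density_ln"] = self.mapc_density_ln
        for drug, c in self.drug_conc.items():
            df[f"conc_plasma_{drug}"] = c
        return df


def _occupancy_scalar(r0: float, l0: float, kd: float) -> float:
    """Two-species equilibrium occupancy from concentrations (scalar fast path)."""
    b = r0 + l0 + kd
    c = 2.0 * r0 * l0 / (b + math.sqrt(b * b - 4.0 * r0 * l0))
    return c / r0


class AssembledModel:
    """Precomputed, fast right-hand side for one patient and drug set."""

    def __init__(self, params: ModelParams, drugs: list[str] | None = None):
        self.p = params
        self.drugs = list(drugs or [])
        self.n_states = N_IMMUNE + N_PK_STATES * len(self.drugs)
        self.state_names = list(IMMUNE_STATES) + [
            f"pk_{d}_{c}" for d in self.drugs for c in pbpk.PK_COMPARTMENTS
        ]
        self._pk_offsets = {
            d: N_IMMUNE + i * N_PK_STATES for i, d in enumerate(self.drugs)
        }

        panel = params.panel
        self.m = panel.m
        lattice = panel.lattice()
        self.lattice = lattice
        expr = lattice.expression_matrix()  # (2^n, n) over panel.expression keys
        names = lattice.checkpoint_names
        col = {n: i for i, n in enumerate(names)}

        # gate matrix: killing axis j engaged on subtype s
        axes = panel.killing_axes
        gates = np.zeros((lattice.n_subtypes, len(axes)))
        for j, ax in enumerate(axes):
            req = KILLING_AXIS_GATES[ax.name]
            g = np.all(expr[:, [col[r] for r in req]], axis=1)
            if ax.name == "PD1-PDL1":
                # either orientation engages the axis: cancer PD-L1 against
                # effector PD-1, or cancer PD-1 against effector PD-L1
                g = g | expr[:, col["PD1"]]
            gates[:, j] = g
        self.gates = gates
        self.weights = lattice.weights

        # molar synapse concentrations and drug-free maxima
        def conc(ax: CheckpointAxis, density: float) -> float:
            return density / (6.02214076e23 * ax.synapse_volume)

        self.kill_axes = axes
        self.kill_r0 = np.array([conc(a, a.receptor_density) for a in axes])
        self.kill_l0 = np.array([conc(a, a.ligand_density) for a in axes])
        self.kill_kd = np.array([a.kd for a in axes])
        self.kill_romax = np.array(
            [_occupancy_scalar(r, l, k) for r, l, k in
             zip(self.kill_r0, self.kill_l0, self.kill_kd)]
        )
        self.gate_romax = gates @ self.kill_romax  # per-subtype RO_max sum

        paxes = panel.priming_axes
        self.prime_axes = paxes
        self.prime_r0 = np.array([conc(a, a.receptor_density) for a in paxes])
        self.prime_l0 = np.array([conc(a, a.ligand_density) for a in paxes])
        self.prime_kd = np.array([a.kd for a in paxes])
        self.prime_romax = np.array(
            [_occupancy_scalar(r, l, k) for r, l, k in
             zip(self.prime_r0, self.prime_l0, self.prime_kd)]
        )
        self.sig_cd28 = panel.cd28_axis.drug_free_occupancy()

        # which drug masks which species
        self.ab = panel.antibodies
        self.kill_fr_targets = [a.receptor_name for a in axes]
        self.kill_fl_targets = [a.ligand_name for a in axes]

        # trafficking operator: constant part + tumor-binding entries
        t = params.trafficking
        self._traffic_base = trafficking_matrix(
            t, params.patient.chemokine_factor, tumor_diameter_mm=0.0, eliminate=True
        )
        idx = {n: i for i, n in enumerate(
            IMMUNE_STATES[TRAFFIC_SLICE.start:TRAFFIC_SLICE.stop])}
        self._i_blood = idx["E_blood"]
        self._i_tb = idx["E_tumor_bound"]
        self._i_ti = idx["E_tumor_int"]

        self.i_c = STATE_INDEX["C"]
        self.capacity = params.capacity_cells()
        self._v_ref_mm3 = params.geometry.volume_mm3(t.ref_diameter_mm)
        self._fast = None

    #: use the compiled kernel when numba is available
    use_fast = True

    def make_rhs(self, rates: dict[str, float] | None):
        """Segment right-hand side f(t, y) with fixed infusion rates."""
        from . import fastrhs

        if self.use_fast and fastrhs.HAVE_NUMBA:
            if self._fast is None:
                self._fast = fastrhs.make_fast_rhs(self)
            vec = np.array([(rates or {}).get(d, 0.0) for d in self.drugs])
            fast = self._fast
            return lambda t, y: fast(t, y, vec)
        return lambda t, y: self.rhs(t, y, rates)

    # -- molecular layer -------------------------------------------------
    def _blocking_factors(self, species: str, conc_molar: dict[str, float]) -> float:
        f = 1.0
        for drug, c in conc_molar.items():
            spec = self.ab[drug]
            if spec.target == species and c > 0.0:
                f += c / spec.kd_ab
        return f

    def killing_ro(self, tumor_conc_molar: dict[str, float]) -> np.ndarray:
        """Current occupancy of each killing axis under local antibody levels."""
        ro = np.empty(len(self.kill_axes))
        for j, ax in enumerate(self.kill_axes):
            if ax.name in self._blocked_by_any(tumor_conc_molar):
                fr = self._blocking_factors(self.kill_fr_targets[j], tumor_conc_molar)
                fl = self._blocking_factors(self.kill_fl_targets[j], tumor_conc_molar)
                kd_eff = self.kill_kd[j] * fr * fl
            else:
                kd_eff = self.kill_kd[j]
            ro[j] = _occupancy_scalar(self.kill_r0[j], self.kill_l0[j], kd_eff)
        return ro

    def _blocked_by_any(self, conc: dict[str, float]) -> frozenset[str]:
        blocked: set[str] = set()
        for drug, c in conc.items():
            if c > 0.0:
                blocked |= self.ab[drug].blocked_axes
        return frozenset(blocked)

    def priming_fa(self, ln_conc_molar: dict[str, float]) -> float:
        ro_sum = 0.0
        for j, ax in enumerate(self.prime_axes):
            fr = self._blocking_factors(ax.receptor_name, ln_conc_molar)
            fl = self._blocking_factors(ax.ligand_name, ln_conc_molar)
            ro_sum += _occupancy_scalar(
                self.prime_r0[j], self.prime_l0[j], self.prime_kd[j] * fr * fl
            )
        s = ro_sum / self.prime_romax.sum()
        sm = s**self.m
        return sm / (1.0 + sm)

    def subtype_fa(self, ro: np.ndarray) -> np.ndarray:
        """Per-subtype combined effect over the engaged killing axes."""
        num = self.gates @ ro
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(self.gate_romax > 0, num / np.where(self.gate_romax > 0,
                                                             self.gate_romax, 1.0), 0.0)
        sm = s**self.m
        return sm / (1.0 + sm)

    # -- assembled right-hand side --------------------------------------
    def rhs(self, t: float, y: np.ndarray, rates: dict[str, float] | None = None) -> np.ndarray:
        """Full derivative vector; ``rates`` are the current infusion rates
        (mg/day per drug), constant within an integration segment."""
        p = self.p
        d = np.zeros(self.n_states)
        yi = y[:N_IMMUNE]
        c = max(y[self.i_c], 1.0)
        diameter = cells_to_diameter(c, p.geometry)
        v_mm3 = c / p.geometry.cell_density
        v_l = v_mm3 * 1e-6

        # local free antibody concentrations (molar)
        tumor_conc: dict[str, float] = {}
        ln_conc: dict[str, float] = {}
        for drug in self.drugs:
            off = self._pk_offsets[drug]
            c_tum = max(y[off + 4], 0.0) / max(v_l, 1e-9)
            tumor_conc[drug] = mg_per_l_to_molar(c_tum)
            ln_conc[drug] = p.ln_tumor_conc_ratio * tumor_conc[drug]

        # molecular layer
        ro = self.killing_ro(tumor_conc)
        fa_s = self.subtype_fa(ro)
        beta_k = p.panel.killing_inhibition_strength
        kf_s = np.maximum(1.0 - beta_k * fa_s, 0.0)
        # subtypes expressing none of the modeled checkpoints retain partial
        # resistance through unmodeled pathways
        kf_s = np.where(self.gate_romax > 0, kf_s,
                        kf_s * p.panel.unexpressed_resistance)
        kill_factor = float(self.weights @ kf_s)
        fa_avg = float(self.weights @ fa_s)

        # tumor Tregs/MDSCs present additional PD-L1 to effectors; their
        # abundance is a constant fraction of the cancer-cell count
        reg_frac = p.patient.treg_tumor_frac * (1.0 + p.patient.mdsc_multiplier)
        ro_pdl1_ratio = ro[0] / self.kill_romax[0] if self.kill_romax[0] > 0 else 0.0
        fa_reg = min(0.5, p.panel.regulatory_ligand_potency * reg_frac) * ro_pdl1_ratio
        kill_factor *= 1.0 - fa_reg

        fa_prime = self.priming_fa(ln_conc)
        prime_inhib = min(1.0, p.panel.priming_inhibition_strength * fa_prime)

        # tumor block
        e_tum = yi[STATE_INDEX["E_tumor_int"]]
        kill = killing_rate(e_tum, c, p.killing) * kill_factor
        growth = p.growth.rate(c, self.capacity)
        d[self.i_c] = growth - kill

        # TDLN priming cascade
        d[:N_IMMUNE] += priming_rhs(
            yi,
            p.priming,
            cd28_signal=self.sig_cd28,
            ctla4_inhibition=prime_inhib,
            treg_ln_frac=p.patient.treg_ln_frac,
            mapc_activation=p.antigen.mapc_activation_tdln,
        )

        # antigen feed-forward cycle
        d[:N_IMMUNE] += antigen_cycle_rhs(
            yi,
            p.antigen.antigen_per_cell,
            p.patient.chemokine_factor,
            p.antigen,
            kill_flux=kill,
            n_tdln=p.priming.n_tdln,
            tumor_size_scale=1.0,
        )

        # effector trafficking: constant operator + tumor-binding entries
        e = yi[TRAFFIC_SLICE]
        de = self._traffic_base @ e
        t_par = p.trafficking
        k_bind_tumor = t_par.k_bind_tumor_ref * (diameter / t_par.ref_diameter_mm) ** 2
        flux_bind = k_bind_tumor * e[self._i_blood]
        de[self._i_blood] -= flux_bind
        de[self._i_tb] += flux_bind
        # checkpoint-dependent effector elimination in the tumor
        de[self._i_ti] -= t_par.k_death_tumor * (
            1.0 + t_par.death_checkpoint_boost * fa_avg
        ) * e[self._i_ti]
        d[TRAFFIC_SLICE] += de

        # PK blocks
        for drug in self.drugs:
            off = self._pk_offsets[drug]
            d[off:off + N_PK_STATES] = pk_rhs(
                np.maximum(y[off:off + N_PK_STATES], 0.0),
                p.pk[drug],
                (rates or {}).get(drug, 0.0),
                v_l,
            )
        return d

    def initial_state(self, diameter_mm: float) -> np.ndarray:
        """Seed state for the pre-therapy run: tumor at the given diameter,
        naive pool at its homeostatic target, everything else empty."""
        y = np.zeros(self.n_states)
        y[STATE_INDEX["NT"]] = self.p.priming.naive_pool_target
        y[self.i_c] = diameter_to_cells(diameter_mm, self.p.geometry)
        return y


def initialize(
    params: ModelParams,
    drugs: list[str] | None = None,
    settings: SolverSettings | None = None,
    pre_therapy_cap_days: float = 5 * 365.0,
    qss_tolerance: float = 1e-3,
) -> tuple[AssembledModel, np.ndarray]:
    """Drug-free pre-run from 95% of the therapy-start diameter.

    Integrates until the tumor grows to the start diameter; the returned
    state is the therapy-start quasi-steady state.  Raises
    ``InitializationError`` if the tumor cannot reach the start diameter
    within the cap (immune control wins under these parameters).
    ``qss_tolerance`` (relative drift per day) is recorded on the model for
    diagnostic use.
    """
    settings = settings or SolverSettings()
    model = AssembledModel(params, drugs=drugs)
    d_start = params.patient.tumor_diameter_start
    c_start = diameter_to_cells(d_start, params.geometry)
    y0 = model.initial_state(0.95 * d_start)

    def reached(t: float, y: np.ndarray) -> float:
        return y[model.i_c] - c_start

    reached.terminal = True
    reached.direction = 1.0

    sol = solve_ivp(
        model.make_rhs(None),
        (0.0, pre_therapy_cap_days),
        y0,
        method=settings.method,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        max_step=settings.max_step,
        events=reached,
    )
    if not sol.success:
        raise InitializationError(f"pre-therapy integration failed: {sol.message}")
    if not sol.t_events[0].size:
        raise InitializationError(
            "tumor never reached the therapy-start diameter within the "
            f"{pre_therapy_cap_days:.0f}-day cap; immune elimination outpaces "
            f"growth_rate={params.growth.growth_rate}"
        )
    y_start = sol.y_events[0][0].copy()
    model.qss_tolerance = qss_tolerance
    return model, y_start


def simulate(
    params: ModelParams,
    regimen: Regimen,
    horizon: float = 365.0,
    settings: SolverSettings | None = None,
    grid_step: float = 1.0,
) -> SimulationResult:
    """Simulate one patient from therapy start to the horizon.

    The integration restarts at every infusion-window edge so the zero-order
    infusion rate is constant (and exact) within each segment.  Output is
    reported on a daily grid from the start of therapy.
    """
    settings = settings or SolverSettings()
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    model, y0 = initialize(params, drugs=regimen.drugs, settings=settings)
    grid = np.arange(0.0, horizon + 0.5 * grid_step, grid_step)
    grid[-1] = min(grid[-1], horizon)

    breakpoints = regimen.breakpoints(horizon)
    states = np.empty((len(grid), model.n_states))
    states[0] = y0
    filled = 1

    # once the last cancer cell is gone the tumor block is a fixed point;
    # stop integrating and hold the cured state on the remaining grid
    def eliminated(t: float, yy: np.ndarray) -> float:
        return yy[model.i_c] - 1.0

    eliminated.terminal = True
    eliminated.direction = -1.0

    y = y0
    bw = params.patient.body_weight
    cured = False
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        rates = infusion_rate(0.5 * (a + b), regimen, bw)
        t_eval = grid[(grid > a) & (grid <= b)]
        # the segment end must be evaluated even when it is off the output
        # grid: the next segment continues from the state at exactly b
        if t_eval.size and np.isclose(t_eval[-1], b):
            t_req = t_eval
        else:
            t_req = np.append(t_eval, b)
        sol = None
        last_err: Exception | None = None
        for max_step in (settings.max_step, min(1.0, settings.max_step)):
            try:
                sol = solve_ivp(
                    model.make_rhs(rates),
                    (a, b),
                    y,
                    method=settings.method,
                    rtol=settings.rel_tol,
                    atol=settings.abs_tol,
                    max_step=max_step,
                    t_eval=t_req,
                    dense_output=False,
                    events=eliminated,
                )
            except (ValueError, FloatingPointError) as err:
                last_err = err
                continue
            if sol.success:
                break
        if sol is None:
            raise SimulationError(
                f"integrator raised in segment [{a:.3f}, {b:.3f}] d: {last_err}"
            ) from last_err
        if not sol.success:
            raise SimulationError(
                f"solver failed at t={sol.t[-1]:.3f} d: {sol.message}; "
                f"state snapshot: {dict(zip(model.state_names, sol.y[:, -1]))}"
            )
        ysol = np.asarray(sol.y) if len(sol.t) else np.empty((model.n_states, 0))
        n_grid = min(ysol.shape[1], t_eval.size)
        if n_grid:
            states[filled:filled + n_grid] = ysol[:, :n_grid].T
            filled += n_grid
        if sol.status == 1:  # tumor eliminated
            y = sol.y_events[0][0].copy()
            cured = True
            break
        y = ysol[:, -1]
    if cured:
        final = y.copy()
        final[model.i_c] = min(final[model.i_c], 1.0)
        states[filled:] = final
        filled = len(grid)
    states = states[:filled]
    time = grid[:filled]

    geometry = params.geometry
    c = np.maximum(states[:, model.i_c], 1.0)
    diameter = np.array([cells_to_diameter(v, geometry) for v in c])
    # density readouts use a floor at the 2 mm detectability volume so they
    # stay physical while the tumor vanishes
    v_floor_ml = geometry.volume_mm3(2.0) * 1e-3
    v_ml = np.maximum(c / geometry.cell_density * 1e-3, v_floor_ml)
    eff_density = states[:, STATE_INDEX["E_tumor_int"]] / v_ml
    mapc_density = states[:, STATE_INDEX["mAPC_ln"]] / params.ln_volume_ml

    conc, conc_t, conc_ln = {}, {}, {}
    for drug in regimen.drugs:
        off = model._pk_offsets[drug]
        conc[drug] = states[:, off] / params.pk[drug].v_central
        conc_t[drug] = states[:, off + 4] / np.maximum(v_ml * 1e-3, 1e-9)
        conc_ln[drug] = params.ln_tumor_conc_ratio * conc_t[drug]

    return SimulationResult(
        time=time,
        states=states,
        state_names=model.state_names,
        diameter_mm=diameter,
        effector_density_tumor=eff_density,
        mapc_density_ln=mapc_density,
        drug_conc=conc,
        drug_conc_tumor=conc_t,
        drug_conc_lymph=conc_ln,
        params=params,
        regimen=regimen,
    )
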
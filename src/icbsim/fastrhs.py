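"""Compiled right-hand-side kernel for the assembled patient system.

The readable right-hand side in :mod:`icbsim.engine` composes the module
functions and is the reference implementation; this kernel re-expresses the
same equations as a single numba-compiled function over flat parameter
arrays so that virtual trials (hundreds of patients, thousands of solver
steps each) run at native speed.  ``pack_model`` extracts the arrays from
an :class:`~icbsim.engine.AssembledModel`; the test suite asserts the two
paths agree to floating-point round-off at random states.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


# immune-state indices (fixed layout, mirrors immune.IMMUNE_STATES)
I_NT, I_NT1, I_NT2, I_PRO1, I_PRO2, I_PRO3, I_MAPC_LN, I_TAA_LN = range(8)
I_E_BLOOD = 8
I_E_TUMOR_BOUND, I_E_TUMOR_ARREST, I_E_TUMOR_INT = 18, 19, 20
I_C, I_APC_T, I_MAPC_T, I_TAA_T = 24, 25, 26, 27
N_IMMUNE = 28
TRAFFIC_START, TRAFFIC_END = 8, 24  # slice of effector block
N_TRAFFIC = TRAFFIC_END - TRAFFIC_START
# trafficking-local indices
T_BLOOD, T_TUM_BOUND, T_TUM_INT = 0, 10, 12

# scalar-parameter vector layout
(S_CELL_DENSITY, S_GEOM_K, S_CAPACITY, S_GROWTH_RATE, S_GROWTH_LAW,
 S_KILL_D, S_KILL_LAM, S_KILL_S,
 S_BETA_KILL, S_REG_WEIGHT, S_HILL_M, S_BETA_PRIME, S_LN_RATIO, S_SIG_EFF,
 S_UNEXPR_RESIST,
 S_K1, S_KD1, S_K2, S_KD2, S_KACT, S_PRIME_PREF, S_MAPC_ACT,
 S_KTR, S_NDIV_MAX, S_NTDLN, S_NT0, S_KHOME,
 S_ANTIGEN_PER_CELL, S_TURNOVER, S_APC_INFLUX, S_APC_DEATH, S_UPTAKE,
 S_ANTIGEN_PER_MAPC, S_MAT_EFF, S_MAPC_MIG, S_MAPC_DEATH, S_TAA_DRAIN,
 S_TAA_DEG, S_APC_LN,
 S_BIND_TUM_REF, S_REF_DIAM, S_DEATH_TUM, S_DEATH_BOOST,
 N_SCAL) = range(44)

# per-drug PK row layout
(P_CL, P_VC, P_VT, P_VL, P_VLY, P_L1, P_L2, P_SIG_T, P_SIG_L, P_SIG_LY,
 P_PIN, P_POUT, P_TMDD, P_KINT_RTOT, P_KD_TMDD, P_KDAB, P_TARGET,
 N_PKROW) = range(18)

MG_TO_MOLAR = 1e-3 / 1.5e5  # mg/L -> mol/L for IgG


@njit(cache=True)
def _occ(r0: float, l0: float, kd: float) -> float:
    b = r0 + l0 + kd
    c = 2.0 * r0 * l0 / (b + math.sqrt(b * b - 4.0 * r0 * l0))
    return c / r0


@njit(cache=True)
def rhs_kernel(t, y, scal, traffic, gates, weights, gate_romax,
               kill_r0, kill_l0, kill_kd, kill_romax, kill_rcode, kill_lcode,
               kill_blocked, prime_r0, prime_l0, prime_kd, prime_romax_sum,
               pk, rates):
    n_drugs = pk.shape[0]
    n_states = N_IMMUNE + 5 * n_drugs
    dy = np.zeros(n_states)

    c = y[I_C]
    if c < 1.0:
        c = 1.0
    diameter = (c / scal[S_GEOM_K]) ** (1.0 / 3.0)
    v_mm3 = c / scal[S_CELL_DENSITY]
    v_l = v_mm3 * 1e-6
    v_l_eff = v_l if v_l > 1e-9 else 1e-9

    # local antibody concentrations (molar)
    conc_tum = np.zeros(n_drugs)
    conc_ln = np.zeros(n_drugs)
    for i in range(n_drugs):
        off = N_IMMUNE + 5 * i
        a_tu = y[off + 4]
        if a_tu < 0.0:
            a_tu = 0.0
        conc_tum[i] = (a_tu / v_l_eff) * MG_TO_MOLAR
        conc_ln[i] = scal[S_LN_RATIO] * conc_tum[i]

    # killing-axis occupancies under competition
    n_axes = kill_kd.shape[0]
    ro = np.empty(n_axes)
    for j in range(n_axes):
        blocked = False
        for i in range(n_drugs):
            if conc_tum[i] > 0.0 and kill_blocked[i, j]:
                blocked = True
        kd_eff = kill_kd[j]
        if blocked:
            fr = 1.0
            fl = 1.0
            for i in range(n_drugs):
                if conc_tum[i] > 0.0:
                    tgt = int(pk[i, P_TARGET])
                    if tgt == kill_rcode[j]:
                        fr += conc_tum[i] / pk[i, P_KDAB]
                    if tgt == kill_lcode[j]:
                        fl += conc_tum[i] / pk[i, P_KDAB]
            kd_eff = kill_kd[j] * fr * fl
        ro[j] = _occ(kill_r0[j], kill_l0[j], kd_eff)

    # per-subtype combined effect and averages
    m = scal[S_HILL_M]
    beta_k = scal[S_BETA_KILL]
    kill_factor = 0.0
    fa_avg = 0.0
    n_sub = gates.shape[0]
    for s_i in range(n_sub):
        denom = gate_romax[s_i]
        if denom > 0.0:
            num = 0.0
            for j in range(n_axes):
                num += gates[s_i, j] * ro[j]
            sv = num / denom
            sm = sv**m
            fa = sm / (1.0 + sm)
        else:
            fa = 0.0
        fa_avg += weights[s_i] * fa
        kf = 1.0 - beta_k * fa
        if kf < 0.0:
            kf = 0.0
        if denom <= 0.0:
            kf *= scal[S_UNEXPR_RESIST]
        kill_factor += weights[s_i] * kf

    ro_ratio = ro[0] / kill_romax[0] if kill_romax[0] > 0.0 else 0.0
    kill_factor *= 1.0 - scal[S_REG_WEIGHT] * ro_ratio

    # priming-axis combined effect (lymph-node site)
    ro_sum = 0.0
    for j in range(prime_kd.shape[0]):
        fr = 1.0
        for i in range(n_drugs):
            if conc_ln[i] > 0.0 and int(pk[i, P_TARGET]) == 2:  # CTLA4
                fr += conc_ln[i] / pk[i, P_KDAB]
        ro_sum += _occ(prime_r0[j], prime_l0[j], prime_kd[j] * fr)
    s_pr = ro_sum / prime_romax_sum
    sm_pr = s_pr**m
    fa_prime = sm_pr / (1.0 + sm_pr)
    prime_inhib = scal[S_BETA_PRIME] * fa_prime
    if prime_inhib > 1.0:
        prime_inhib = 1.0
    inhib = 1.0 - prime_inhib

    # tumor block
    e_tum = y[I_E_TUMOR_INT]
    kill = 0.0
    if e_tum > 0.0 and c > 0.0:
        ratio = (e_tum / c) ** scal[S_KILL_LAM]
        kill = scal[S_KILL_D] * ratio / (scal[S_KILL_S] + ratio) * c
    kill *= kill_factor
    cc = c if c < scal[S_CAPACITY] else scal[S_CAPACITY]
    if scal[S_GROWTH_LAW] == 0.0:
        growth = scal[S_GROWTH_RATE] * cc * math.log(scal[S_CAPACITY] / cc)
    else:
        growth = scal[S_GROWTH_RATE] * cc * (1.0 - cc / scal[S_CAPACITY])
    dy[I_C] = growth - kill

    # TDLN priming cascade
    nt = y[I_NT]
    nt1 = y[I_NT1]
    nt2 = y[I_NT2]
    mapc_nint = y[I_MAPC_LN] - nt1 - nt2
    if mapc_nint < 0.0:
        mapc_nint = 0.0
    mapc_nint *= scal[S_MAPC_ACT]
    p1 = 1.0 - math.exp(-scal[S_PRIME_PREF] * mapc_nint)
    sig_eff = scal[S_SIG_EFF]
    f1 = scal[S_K1] * nt * p1 * sig_eff * inhib
    f2 = scal[S_K2] * nt1 * sig_eff * inhib
    f_act = scal[S_KACT] * nt2
    dy[I_NT] = (-f1 + scal[S_KD1] * nt1 + scal[S_KD2] * nt2
                + scal[S_KHOME] * (scal[S_NT0] - nt))
    dy[I_NT1] = f1 - scal[S_KD1] * nt1 - f2
    dy[I_NT2] = f2 - scal[S_KD2] * nt2 - f_act
    k_tr = scal[S_KTR]
    dy[I_PRO1] = f_act - k_tr * y[I_PRO1]
    dy[I_PRO2] = k_tr * (y[I_PRO1] - y[I_PRO2])
    dy[I_PRO3] = k_tr * (y[I_PRO2] - y[I_PRO3])
    stim = sig_eff * inhib
    if stim < 0.0:
        stim = 0.0
    elif stim > 1.0:
        stim = 1.0
    fold = 2.0 ** (scal[S_NDIV_MAX] * stim)
    dy[I_E_BLOOD] = k_tr * y[I_PRO3] * fold * scal[S_NTDLN]

    # antigen feed-forward cycle
    apc = y[I_APC_T]
    mapc_t = y[I_MAPC_T]
    taa_t = y[I_TAA_T]
    taa_ln = y[I_TAA_LN]
    death_flux = scal[S_TURNOVER] * c + kill
    release = scal[S_ANTIGEN_PER_CELL] * death_flux
    uptake = scal[S_UPTAKE] * apc * taa_t
    maturation = uptake / scal[S_ANTIGEN_PER_MAPC] * scal[S_MAT_EFF]
    dy[I_APC_T] = (scal[S_APC_INFLUX] - scal[S_APC_DEATH] * apc
                   - uptake / scal[S_ANTIGEN_PER_MAPC])
    dy[I_MAPC_T] = maturation - (scal[S_MAPC_MIG] + scal[S_MAPC_DEATH]) * mapc_t
    dy[I_TAA_T] = release - uptake - (scal[S_TAA_DRAIN] + scal[S_TAA_DEG]) * taa_t
    ln_uptake = scal[S_APC_LN] * taa_ln
    dy[I_TAA_LN] = (scal[S_TAA_DRAIN] * taa_t / scal[S_NTDLN]
                    - ln_uptake - scal[S_TAA_DEG] * taa_ln)
    dy[I_MAPC_LN] += (scal[S_MAPC_MIG] * mapc_t / scal[S_NTDLN]
                      + ln_uptake / scal[S_ANTIGEN_PER_MAPC]
                      - scal[S_MAPC_DEATH] * y[I_MAPC_LN])

    # effector trafficking
    for a in range(N_TRAFFIC):
        acc = 0.0
        for b in range(N_TRAFFIC):
            acc += traffic[a, b] * y[TRAFFIC_START + b]
        dy[TRAFFIC_START + a] += acc
    k_bind_tumor = scal[S_BIND_TUM_REF] * (diameter / scal[S_REF_DIAM]) ** 2
    flux_bind = k_bind_tumor * y[TRAFFIC_START + T_BLOOD]
    dy[TRAFFIC_START + T_BLOOD] -= flux_bind
    dy[TRAFFIC_START + T_TUM_BOUND] += flux_bind
    dy[TRAFFIC_START + T_TUM_INT] -= (
        scal[S_DEATH_TUM] * (1.0 + scal[S_DEATH_BOOST] * fa_avg)
        * y[TRAFFIC_START + T_TUM_INT]
    )

    # PK blocks
    for i in range(n_drugs):
        off = N_IMMUNE + 5 * i
        a_c = max(y[off], 0.0)
        a_t = max(y[off + 1], 0.0)
        a_l = max(y[off + 2], 0.0)
        a_ly = max(y[off + 3], 0.0)
        a_tu = max(y[off + 4], 0.0)
        c_c = a_c / pk[i, P_VC]
        c_t = a_t / pk[i, P_VT]
        c_l = a_l / pk[i, P_VL]
        c_ly = a_ly / pk[i, P_VLY]
        c_tu = a_tu / v_l_eff
        l1 = pk[i, P_L1]
        l2 = pk[i, P_L2]
        j_in_t = l1 * (1.0 - pk[i, P_SIG_T]) * c_c
        j_in_l = l2 * (1.0 - pk[i, P_SIG_L]) * c_c
        j_out_t = l1 * (1.0 - pk[i, P_SIG_LY]) * c_t
        j_out_l = l2 * (1.0 - pk[i, P_SIG_LY]) * c_l
        j_ret = (l1 + l2) * c_ly
        surface = v_l_eff ** (2.0 / 3.0)
        j_tu_in = pk[i, P_PIN] * surface * c_c
        j_tu_out = pk[i, P_POUT] * surface * c_tu
        elim = pk[i, P_CL] * c_c
        tmdd = 0.0
        if pk[i, P_TMDD] > 0.0:
            c_molar = c_c * MG_TO_MOLAR
            tmdd = (pk[i, P_KINT_RTOT] * c_molar / (pk[i, P_KD_TMDD] + c_molar)
                    ) * pk[i, P_VC] * 1.5e5 * 1e3
        dy[off] = rates[i] - elim - tmdd - j_in_t - j_in_l + j_ret - j_tu_in
        dy[off + 1] = j_in_t - j_out_t
        dy[off + 2] = j_in_l - j_out_l
        dy[off + 3] = j_out_t + j_out_l + j_tu_out - j_ret
        dy[off + 4] = j_tu_in - j_tu_out
    return dy


_TARGET_CODE = {"PD1": 0, "PDL1": 1, "CTLA4": 2}
_SPECIES_CODE = {"PD1": 0, "PDL1": 1, "CTLA4": 2}


def pack_model(model) -> dict:
    """Flatten an ``AssembledModel`` into the kernel's parameter arrays."""
    p = model.p
    prim = p.priming
    ant = p.antigen
    traf = p.trafficking
    scal = np.zeros(N_SCAL)
    r1, r2 = p.geometry.axis_ratio
    scal[S_CELL_DENSITY] = p.geometry.cell_density
    scal[S_GEOM_K] = math.pi / 6.0 * r1 * r2 * p.geometry.cell_density
    scal[S_CAPACITY] = model.capacity
    scal[S_GROWTH_RATE] = p.growth.growth_rate
    scal[S_GROWTH_LAW] = 0.0 if p.growth.law == "gompertz" else 1.0
    scal[S_KILL_D] = p.killing.d
    scal[S_KILL_LAM] = p.killing.lam
    scal[S_KILL_S] = p.killing.s
    scal[S_BETA_KILL] = p.panel.killing_inhibition_strength
    reg_frac = p.patient.treg_tumor_frac * (1.0 + p.patient.mdsc_multiplier)
    scal[S_REG_WEIGHT] = min(0.5, p.panel.regulatory_ligand_potency * reg_frac)
    scal[S_HILL_M] = p.panel.m
    scal[S_BETA_PRIME] = p.panel.priming_inhibition_strength
    scal[S_LN_RATIO] = p.ln_tumor_conc_ratio
    scal[S_UNEXPR_RESIST] = p.panel.unexpressed_resistance
    scal[S_SIG_EFF] = model.sig_cd28 * max(
        0.0, 1.0 - prim.treg_costim_weight * p.patient.treg_ln_frac
    )
    scal[S_K1] = prim.k_assoc_p1
    scal[S_KD1] = prim.k_dissoc_p1
    scal[S_K2] = prim.k_assoc_p2
    scal[S_KD2] = prim.k_dissoc_p2
    scal[S_KACT] = prim.k_activate
    scal[S_PRIME_PREF] = (
        4.0 * math.pi * prim.d_t * prim.diff_t * prim.t_total_ln
        * prim.phi_nt * prim.antigen_strength
        / (prim.t_clonality * prim.s_nt_mapc) * prim.t_max
    )
    scal[S_MAPC_ACT] = ant.mapc_activation_tdln
    scal[S_KTR] = 3.0 / prim.proliferation_duration
    scal[S_NDIV_MAX] = prim.proliferation_rate * prim.proliferation_duration
    scal[S_NTDLN] = prim.n_tdln
    scal[S_NT0] = prim.naive_pool_target
    scal[S_KHOME] = prim.k_nt_homeostasis
    scal[S_ANTIGEN_PER_CELL] = ant.antigen_per_cell
    scal[S_TURNOVER] = ant.cancer_turnover
    scal[S_APC_INFLUX] = ant.k_apc_influx
    scal[S_APC_DEATH] = ant.k_apc_death
    scal[S_UPTAKE] = ant.k_uptake
    scal[S_ANTIGEN_PER_MAPC] = ant.antigen_per_mapc
    scal[S_MAT_EFF] = 1.0 - ant.mapc_inactivation_tme
    scal[S_MAPC_MIG] = ant.k_mapc_migrate
    scal[S_MAPC_DEATH] = ant.k_mapc_death
    scal[S_TAA_DRAIN] = ant.k_taa_drain
    scal[S_TAA_DEG] = ant.k_taa_degrade
    scal[S_APC_LN] = ant.k_apc_ln
    scal[S_BIND_TUM_REF] = traf.k_bind_tumor_ref
    scal[S_REF_DIAM] = traf.ref_diameter_mm
    scal[S_DEATH_TUM] = traf.k_death_tumor
    scal[S_DEATH_BOOST] = traf.death_checkpoint_boost

    kill_rcode = np.array(
        [_SPECIES_CODE.get(a.receptor_name, -1) for a in model.kill_axes],
        dtype=np.int64,
    )
    kill_lcode = np.array(
        [_SPECIES_CODE.get(a.ligand_name, -1) for a in model.kill_axes],
        dtype=np.int64,
    )
    n_drugs = len(model.drugs)
    pkmat = np.zeros((n_drugs, N_PKROW))
    kill_blocked = np.zeros((n_drugs, len(model.kill_axes)), dtype=np.bool_)
    for i, drug in enumerate(model.drugs):
        pkp = p.pk[drug]
        spec = model.ab[drug]
        row = pkmat[i]
        row[P_CL] = pkp.clearance
        row[P_VC] = pkp.v_central
        row[P_VT] = pkp.v_tight
        row[P_VL] = pkp.v_leaky
        row[P_VLY] = pkp.v_lymph
        row[P_L1] = pkp.lymph_flow_tight
        row[P_L2] = pkp.lymph_flow_leaky
        row[P_SIG_T] = pkp.sigma_tight
        row[P_SIG_L] = pkp.sigma_leaky
        row[P_SIG_LY] = pkp.sigma_lymph
        row[P_PIN] = pkp.tumor_perm_in
        row[P_POUT] = pkp.tumor_perm_out
        if pkp.tmdd is not None:
            row[P_TMDD] = 1.0
            row[P_KINT_RTOT] = pkp.tmdd.k_int * pkp.tmdd.r_total
            row[P_KD_TMDD] = pkp.tmdd.kd
        row[P_KDAB] = spec.kd_ab
        row[P_TARGET] = _TARGET_CODE[spec.target]
        for j, ax in enumerate(model.kill_axes):
            kill_blocked[i, j] = ax.name in spec.blocked_axes

    return dict(
        scal=scal,
        traffic=np.ascontiguousarray(model._traffic_base),
        gates=np.ascontiguousarray(model.gates),
        weights=np.ascontiguousarray(model.weights),
        gate_romax=np.ascontiguousarray(model.gate_romax),
        kill_r0=model.kill_r0, kill_l0=model.kill_l0, kill_kd=model.kill_kd,
        kill_romax=model.kill_romax,
        kill_rcode=kill_rcode, kill_lcode=kill_lcode, kill_blocked=kill_blocked,
        prime_r0=model.prime_r0, prime_l0=model.prime_l0,
        prime_kd=model.prime_kd, prime_romax_sum=float(model.prime_romax.sum()),
        pk=pkmat,
    )


def make_fast_rhs(model):
    """Closure ``f(t, y, rates_vector) -> dy`` over the packed arrays."""
    packed = pack_model(model)

    def f(t, y, rates):
        return rhs_kernel(
            t, y, packed["scal"], packed["traffic"], packed["gates"],
            packed["weights"], packed["gate_romax"], packed["kill_r0"],
            packed["kill_l0"], packed["kill_kd"], packed["kill_romax"],
            packed["kill_rcode"], packed["kill_lcode"], packed["kill_blocked"],
            packed["prime_r0"], packed["prime_l0"], packed["prime_kd"],
            packed["prime_romax_sum"], packed["pk"], rates,
        )

    return f
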
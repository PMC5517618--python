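"""Compiled right-hand side of the whole-cell model.

The state vector (41 entries) and parameter vector layouts are fixed here;
:mod:`myoburst.model` provides the validated, named public surface on top.
Each Markov chain (RyR, L-type Ca2+, fast Na+, rapid delayed rectifier)
carries one state as the algebraic complement of the others, so occupancy
conservation holds exactly along any trajectory.

Conventions: outward membrane current positive; the stimulus enters the
voltage equation as a depolarizing ``+istim``; dV/dt = -(sum of ionic
currents) + istim, with all currents normalized by membrane capacitance
(pA/pF).  Ca2+ in uM, Na+/K+ in mM, time in ms, voltage in mV.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATES = 41

STATE_NAMES: tuple[str, ...] = (
    "V",
    "Cai", "Cass", "CaJSR", "CaNSR",
    "Nai", "Ki",
    "LTRPNCa", "HTRPNCa",
    "PRyR",
    "PO1", "PO2", "PC2",
    "O_CaL", "C2_CaL", "C3_CaL", "C4_CaL", "I1_CaL", "I2_CaL", "I3_CaL",
    "C2_Na", "C1_Na", "O_Na", "IF_Na", "I1_Na", "I2_Na", "IC2_Na", "IC3_Na",
    "ato_f", "ito_f", "ato_s", "ito_s", "aur", "iur", "aKss", "iKss", "nKs",
    "C1_Kr", "C2_Kr", "O_Kr", "I_Kr",
)

#: complement states not stored in the vector: name -> indices summed to 1.
COMPLEMENT_STATES = {
    "PC1": (10, 11, 12),
    "C1_CaL": (13, 14, 15, 16, 17, 18, 19),
    "C3_Na": (20, 21, 22, 23, 24, 25, 26, 27),
    "C0_Kr": (37, 38, 39, 40),
}

CURRENT_NAMES: tuple[str, ...] = (
    "INa", "ICaL", "IpCa", "INaCa", "IKtof", "IKtos", "IKr", "IKur",
    "IKss", "IK1", "IKs", "INaK", "IClCa", "ICab", "INab", "Istim",
)

FLUX_NAMES: tuple[str, ...] = ("Jup", "Jrel", "Jtr", "Jleak", "Jxfer", "Jtrpn")

#: typical magnitude of each state variable; scales absolute solver
#: tolerances and Jacobian finite-difference steps.
TYPICAL_MAGNITUDE = np.array(
    [100.0, 0.5, 1.0, 1000.0, 1000.0, 15.0, 145.0, 50.0, 100.0]
    + [1.0] * 32,
    dtype=np.float64,
)

#: initial conditions of the published model (quiescent cell, t = 0).
DEFAULT_INITIAL_STATE = np.array([
    -82.4202,                     # V
    0.115001, 0.115001,           # Cai, Cass
    1299.5, 1299.5,               # CaJSR, CaNSR
    14.2371, 143.720,             # Nai, Ki (mM)
    11.2684, 125.29,              # LTRPNCa, HTRPNCa
    0.0,                          # PRyR
    1.49102e-5, 9.51726e-11, 1.6774e-4,   # PO1, PO2, PC2
    9.30308e-19, 1.24216e-4, 5.78679e-9, 1.19816e-13,   # O, C2, C3, C4 (CaL)
    4.97923e-19, 3.45847e-14, 1.85106e-14,              # I1, I2, I3 (CaL)
    0.020752, 2.79132e-4, 7.13483e-7, 1.53176e-4,       # C2, C1, O, IF (Na)
    6.73345e-7, 1.55787e-9,                             # I1, I2 (Na)
    0.0113879, 0.34278,                                 # IC2, IC3 (Na)
    2.65563e-3, 0.999977,         # ato_f, ito_f
    4.17069e-4, 0.998543,         # ato_s, ito_s
    4.17069e-4, 0.998543,         # aur, iur
    4.17069e-4, 1.0,              # aKss, iKss
    2.62753e-4,                   # nKs
    9.92513e-4, 6.41229e-4, 1.75298e-4, 3.19129e-5,     # CK1, CK2, OK, IK
], dtype=np.float64)

# --- parameter vector indices (layout = parameters.PARAM_NAMES + scheme flag) ---
# Geometry/physics: 0 F, 1 TEMP, 2 RGAS, 3 Acap, 4 Cm, 5 Vmyo, 6 VJSR, 7 VNSR,
# 8 Vss; ions: 9 Ko, 10 Nao, 11 Cao; buffers: 12 LTRPN_tot, 13 HTRPN_tot,
# 14 kp_htrpn, 15 km_htrpn, 16 kp_ltrpn, 17 km_ltrpn, 18 CMDN_tot, 19 CSQN_tot,
# 20 Km_CMDN, 21 Km_CSQN; SR: 22 v1, 23 v2, 24 v3, 25 Km_up, 26 tau_tr,
# 27 tau_xfer; RyR: 28 kap, 29 kam, 30 kbp, 31 kbm, 32 kcp, 33 kcm;
# ICaL: 34 GCaL, 35 ECaL, 36 Kpc_max, 37 Kpc_half, 38 Kpcb, 39 ICaL_max;
# 40 GNa, 41 GNab, 42 GCab; NCX: 43 kNaCa, 44 Km_Na, 45 Km_Ca, 46 k_sat,
# 47 eta; pumps: 48 IpCa_max, 49 Km_pCa, 50 INaK_max, 51 Km_Nai, 52 Km_Ko;
# ClCa: 53 GClCa, 54 Km_Cl, 55 ECl; K: 56 GKtof, 57 GKtos, 58 GKur, 59 GKss,
# 60 GKr, 61 GKs; IK1: 62 GK1, 63 Km_K1, 64 k1_power, 65 k1_slope;
# 66 slow_inact flag (1 = full 9-state I_Na scheme, 0 = slow inactivation removed).
N_PARAMS = 67
IDX_SLOW_INACT = 66


def pack_parameters(params, slow_inactivation: bool = True) -> np.ndarray:
    """Pack a :class:`~myoburst.parameters.ModelParameters` into the engine vector."""
    vec = np.empty(N_PARAMS, dtype=np.float64)
    vec[:66] = params.to_vector()
    vec[IDX_SLOW_INACT] = 1.0 if slow_inactivation else 0.0
    return vec


@njit(cache=True)
def ina_rate_vector(V, slow_inact):
    """The 13 voltage-dependent transition rates of the I_Na Markov scheme.

    Order: a11, a12, a13, b11, b12, b13, a3, b3, a2, b2, a4, b4, a5 (b5 = a3/50
    is derived by the caller).  With ``slow_inact == 0`` the rates on every
    edge incident to I1/I2 (a4, b4, a5, b5) are zero, which is equivalent to
    deleting those states when their occupancy starts at zero.
    """
    a11 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 17.0) + 0.20 * np.exp(-(V + 2.5) / 150.0))
    a12 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 15.0) + 0.23 * np.exp(-(V + 2.5) / 150.0))
    a13 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 12.0) + 0.25 * np.exp(-(V + 2.5) / 150.0))
    b11 = 0.1917 * np.exp(-(V + 2.5) / 20.3)
    b12 = 0.20 * np.exp(-(V - 2.5) / 20.3)
    b13 = 0.22 * np.exp(-(V - 7.5) / 20.3)
    a3 = 7.0e-7 * np.exp(-(V + 7.0) / 7.7)
    b3 = 0.0084 + 0.00002 * (V + 7.0)
    a2 = 1.0 / (0.188495 * np.exp(-(V + 7.0) / 16.6) + 0.393956)
    b2 = a13 * a2 * a3 / (b13 * b3)
    if slow_inact > 0.5:
        a4 = a2 / 1000.0
        b4 = a3
        a5 = a2 / 95000.0
    else:
        a4 = 0.0
        b4 = 0.0
        a5 = 0.0
    out = np.empty(13)
    out[0] = a11; out[1] = a12; out[2] = a13
    out[3] = b11; out[4] = b12; out[5] = b13
    out[6] = a3; out[7] = b3; out[8] = a2; out[9] = b2
    out[10] = a4; out[11] = b4; out[12] = a5
    return out


@njit(cache=True)
def currents_core(y, p, istim):
    """All 15 ionic membrane currents plus the stimulus (pA/pF, outward > 0)."""
    V = y[0]
    Cai = y[1]
    Nai = y[5]
    Ki = y[6]
    O_CaL = y[13]
    O_Na = y[22]
    ato_f = y[28]; ito_f = y[29]
    ato_s = y[30]; ito_s = y[31]
    aur = y[32]; iur = y[33]
    aKss = y[34]; iKss = y[35]
    nKs = y[36]
    O_Kr = y[39]

    F = p[0]; TEMP = p[1]; RGAS = p[2]
    Ko = p[9]; Nao = p[10]; Cao = p[11]
    RT_F = RGAS * TEMP / F
    VFRT = V / RT_F

    # reversal potentials (Nernst / GHK-weighted)
    ENa = RT_F * np.log((0.9 * Nao + 0.1 * Ko) / (0.9 * Nai + 0.1 * Ki))
    EK = RT_F * np.log(Ko / Ki)
    ECaN = 0.5 * RT_F * np.log(Cao / Cai)
    EKr = RT_F * np.log((0.98 * Ko + 0.02 * Nao) / (0.98 * Ki + 0.02 * Nai))

    INa = p[40] * O_Na * (V - ENa)
    ICaL = p[34] * O_CaL * (V - p[35])
    IpCa = p[48] * Cai * Cai / (p[49] * p[49] + Cai * Cai)

    expe = np.exp(p[47] * VFRT)
    expe1 = np.exp((p[47] - 1.0) * VFRT)
    INaCa = (
        p[43]
        / (p[44] ** 3 + Nao ** 3)
        / (p[45] + Cao)
        / (1.0 + p[46] * expe1)
        * (expe * Nai ** 3 * Cao - expe1 * Nao ** 3 * Cai)
    )

    IKtof = p[56] * ato_f ** 3 * ito_f * (V - EK)
    IKtos = p[57] * ato_s * ito_s * (V - EK)
    IKr = p[60] * O_Kr * (V - EKr)
    IKur = p[58] * aur * iur * (V - EK)
    IKss = p[59] * aKss * iKss * (V - EK)
    IK1 = (
        p[62]
        * (Ko / (Ko + p[63]))
        * (V - EK)
        / (1.0 + np.exp(p[65] * (V - EK))) ** p[64]
    )
    IKs = p[61] * nKs * nKs * (V - EK)

    sigma = (np.exp(Nao / 67.3) - 1.0) / 7.0
    fNaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * VFRT) + 0.0365 * sigma * np.exp(-VFRT))
    INaK = p[50] * fNaK / (1.0 + (p[51] / Nai) ** 1.5) * Ko / (Ko + p[52])

    O_ClCa = 0.2 / (1.0 + np.exp(-(V - 46.7) / 7.8))
    IClCa = p[53] * O_ClCa * Cai / (Cai + p[54]) * (V - p[55])

    ICab = p[42] * (V - ECaN)
    INab = p[41] * (V - ENa)

    out = np.empty(16)
    out[0] = INa; out[1] = ICaL; out[2] = IpCa; out[3] = INaCa
    out[4] = IKtof; out[5] = IKtos; out[6] = IKr; out[7] = IKur
    out[8] = IKss; out[9] = IK1; out[10] = IKs; out[11] = INaK
    out[12] = IClCa; out[13] = ICab; out[14] = INab; out[15] = istim
    return out


@njit(cache=True)
def fluxes_core(y, p):
    """The six Ca2+ fluxes (uM/ms in their target compartments).

    Sign conventions: Jup cytosol->NSR, Jrel JSR->subspace, Jtr NSR->JSR,
    Jleak NSR->cytosol, Jxfer subspace->cytosol, Jtrpn cytosol->troponin
    (all positive in the direction named).
    """
    Cai = y[1]; Cass = y[2]; CaJSR = y[3]; CaNSR = y[4]
    LT = y[7]; HT = y[8]
    PRyR = y[9]
    PO1 = y[10]; PO2 = y[11]

    Jup = p[24] * Cai * Cai / (p[25] * p[25] + Cai * Cai)
    Jrel = p[22] * (PO1 + PO2) * (CaJSR - Cass) * PRyR
    Jtr = (CaNSR - CaJSR) / p[26]
    Jleak = p[23] * (CaNSR - Cai)
    Jxfer = (Cass - Cai) / p[27]
    Jtrpn = (
        p[14] * Cai * (p[13] - HT) - p[15] * HT
        + p[16] * Cai * (p[12] - LT) - p[17] * LT
    )
    out = np.empty(6)
    out[0] = Jup; out[1] = Jrel; out[2] = Jtr
    out[3] = Jleak; out[4] = Jxfer; out[5] = Jtrpn
    return out


@njit(cache=True)
def rhs_core(t, y, p, istim):
    """Time derivative of the full state vector."""
    dy = np.zeros(N_STATES)
    V = y[0]
    Cai = y[1]; Cass = y[2]; CaJSR = y[3]; CaNSR = y[4]
    LT = y[7]; HT = y[8]
    PRyR = y[9]
    PO1 = y[10]; PO2 = y[11]; PC2 = y[12]
    PC1 = 1.0 - PO1 - PO2 - PC2
    O_L = y[13]; C2_L = y[14]; C3_L = y[15]; C4_L = y[16]
    I1_L = y[17]; I2_L = y[18]; I3_L = y[19]
    C1_L = 1.0 - (O_L + C2_L + C3_L + C4_L + I1_L + I2_L + I3_L)
    CNa2 = y[20]; CNa1 = y[21]; ONa = y[22]; IFNa = y[23]
    I1Na = y[24]; I2Na = y[25]; ICNa2 = y[26]; ICNa3 = y[27]
    CNa3 = 1.0 - (CNa2 + CNa1 + ONa + IFNa + I1Na + I2Na + ICNa2 + ICNa3)
    ato_f = y[28]; ito_f = y[29]
    ato_s = y[30]; ito_s = y[31]
    aur = y[32]; iur = y[33]
    aKss = y[34]
    nKs = y[36]
    CK1 = y[37]; CK2 = y[38]; OK = y[39]; IKI = y[40]
    CK0 = 1.0 - (CK1 + CK2 + OK + IKI)

    cur = currents_core(y, p, istim)
    flx = fluxes_core(y, p)
    INa = cur[0]; ICaL = cur[1]; IpCa = cur[2]; INaCa = cur[3]
    IKtof = cur[4]; IKtos = cur[5]; IKr = cur[6]; IKur = cur[7]
    IKss = cur[8]; IK1 = cur[9]; IKs = cur[10]; INaK = cur[11]
    IClCa = cur[12]; ICab = cur[13]; INab = cur[14]
    Jup = flx[0]; Jrel = flx[1]; Jtr = flx[2]
    Jleak = flx[3]; Jxfer = flx[4]; Jtrpn = flx[5]

    # membrane potential (outward positive; +istim depolarizes)
    I_ion = (INa + ICaL + IpCa + INaCa + ICab + INab + INaK
             + IKtof + IKtos + IK1 + IKs + IKur + IKss + IKr + IClCa)
    dy[0] = -I_ion + istim

    F = p[0]
    Acap = p[3]; Cm = p[4]
    Vmyo = p[5]; VJSR = p[6]; VNSR = p[7]; Vss = p[8]
    conv = Acap * Cm / (Vmyo * F)  # pA/pF -> uM/ms in the cytosol

    Bi = 1.0 / (1.0 + p[18] * p[20] / (p[20] + Cai) ** 2)
    Bss = 1.0 / (1.0 + p[18] * p[20] / (p[20] + Cass) ** 2)
    BJSR = 1.0 / (1.0 + p[19] * p[21] / (p[21] + CaJSR) ** 2)

    dy[1] = Bi * (Jleak + Jxfer - Jup - Jtrpn - (ICab - 2.0 * INaCa + IpCa) * conv / 2.0)
    dy[2] = Bss * (Jrel * VJSR / Vss - Jxfer * Vmyo / Vss - ICaL * Acap * Cm / (2.0 * Vss * F))
    dy[3] = BJSR * (Jtr - Jrel)
    dy[4] = (Jup - Jleak) * Vmyo / VNSR - Jtr * VJSR / VNSR
    dy[5] = -(INa + INab + 3.0 * INaCa + 3.0 * INaK) * conv / 1000.0   # mM/ms
    dy[6] = -(IKtof + IKtos + IK1 + IKs + IKss + IKur + IKr - 2.0 * INaK) * conv / 1000.0

    # troponin buffers
    dy[7] = p[16] * Cai * (p[12] - LT) - p[17] * LT
    dy[8] = p[14] * Cai * (p[13] - HT) - p[15] * HT

    # RyR release channel (4-state) + release gating variable
    dy[9] = -0.04 * PRyR - 0.1 * (ICaL / p[39]) * np.exp(-(V - 5.0) ** 2 / 648.0)
    c4 = Cass ** 4
    c3 = Cass ** 3
    dy[10] = p[28] * c4 * PC1 - p[29] * PO1 - p[30] * c3 * PO1 + p[31] * PO2 - p[32] * PO1 + p[33] * PC2
    dy[11] = p[30] * c3 * PO1 - p[31] * PO2
    dy[12] = p[32] * PO1 - p[33] * PC2

    # L-type Ca2+ channel (8-state Markov)
    alpha = (
        0.4 * np.exp((V + 12.0) / 10.0)
        * (1.0 + 0.7 * np.exp(-(V + 40.0) ** 2 / 10.0) - 0.75 * np.exp(-(V + 20.0) ** 2 / 400.0))
        / (1.0 + 0.12 * np.exp((V + 12.0) / 10.0))
    )
    beta = 0.05 * np.exp(-(V + 12.0) / 13.0)
    gamma = p[36] * Cass / (p[37] + Cass)
    Kpcf = 13.0 * (1.0 - np.exp(-(V + 14.5) ** 2 / 100.0))
    Kpcb = p[38]
    dy[13] = (alpha * C4_L - 4.0 * beta * O_L + Kpcb * I1_L - gamma * O_L
              + 0.001 * (alpha * I2_L - Kpcf * O_L))
    dy[14] = 4.0 * alpha * C1_L - beta * C2_L + 2.0 * beta * C3_L - 3.0 * alpha * C2_L
    dy[15] = 3.0 * alpha * C2_L - 2.0 * beta * C3_L + 3.0 * beta * C4_L - 2.0 * alpha * C3_L
    dy[16] = (2.0 * alpha * C3_L - 3.0 * beta * C4_L + 4.0 * beta * O_L - alpha * C4_L
              + 0.01 * (4.0 * Kpcb * beta * I1_L - alpha * gamma * C4_L)
              + 0.002 * (4.0 * beta * I2_L - Kpcf * C4_L)
              + 4.0 * beta * Kpcb * I3_L - gamma * Kpcf * C4_L)
    dy[17] = (gamma * O_L - Kpcb * I1_L + 0.001 * (alpha * I3_L - Kpcf * I1_L)
              + 0.01 * (alpha * gamma * C4_L - 4.0 * beta * Kpcb * I1_L))
    dy[18] = (0.001 * (Kpcf * O_L - alpha * I2_L) + Kpcb * I3_L - gamma * I2_L
              + 0.002 * (Kpcf * C4_L - 4.0 * beta * I2_L))
    dy[19] = (0.001 * (Kpcf * I1_L - alpha * I3_L) + gamma * I2_L - Kpcb * I3_L
              + gamma * Kpcf * C4_L - 4.0 * beta * Kpcb * I3_L)

    # fast Na+ channel (9-state Markov; slow inactivation removable)
    r = ina_rate_vector(V, p[IDX_SLOW_INACT])
    a11 = r[0]; a12 = r[1]; a13 = r[2]
    b11 = r[3]; b12 = r[4]; b13 = r[5]
    a3 = r[6]; b3 = r[7]; a2 = r[8]; b2 = r[9]
    a4 = r[10]; b4 = r[11]; a5 = r[12]
    b5 = a3 / 50.0 if p[IDX_SLOW_INACT] > 0.5 else 0.0
    dy[20] = (a11 * CNa3 - b11 * CNa2 + b12 * CNa1 - a12 * CNa2
              + a3 * ICNa2 - b3 * CNa2)
    dy[21] = (a12 * CNa2 - b12 * CNa1 + b13 * ONa - a13 * CNa1
              + a3 * IFNa - b3 * CNa1)
    dy[22] = a13 * CNa1 - b13 * ONa + b2 * IFNa - a2 * ONa
    dy[23] = (a2 * ONa - b2 * IFNa + b3 * CNa1 - a3 * IFNa
              + b4 * I1Na - a4 * IFNa + a12 * ICNa2 - b12 * IFNa)
    dy[24] = a4 * IFNa - b4 * I1Na + b5 * I2Na - a5 * I1Na
    dy[25] = a5 * I1Na - b5 * I2Na
    dy[26] = (a11 * ICNa3 - b11 * ICNa2 + b12 * IFNa - a12 * ICNa2
              + b3 * CNa2 - a3 * ICNa2)
    dy[27] = b11 * ICNa2 - a11 * ICNa3 + b3 * CNa3 - a3 * ICNa3

    # transient outward K+ (fast), Hodgkin-Huxley
    aa = 0.18064 * np.exp(0.03577 * (V + 30.0))
    ba = 0.3956 * np.exp(-0.06237 * (V + 30.0))
    ai = (0.000152 * np.exp(-(V + 13.5) / 7.0)
          / (0.0067083 * np.exp(-(V + 33.5) / 7.0) + 1.0))
    bi = (0.00095 * np.exp((V + 33.5) / 7.0)
          / (0.051335 * np.exp((V + 33.5) / 7.0) + 1.0))
    dy[28] = aa * (1.0 - ato_f) - ba * ato_f
    dy[29] = ai * (1.0 - ito_f) - bi * ito_f

    # slow transient outward / ultrarapid / steady-state K+ activation
    ass = 1.0 / (1.0 + np.exp(-(V + 22.5) / 7.7))
    iss = 1.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    tau_tas = 0.493 * np.exp(-0.0629 * V) + 2.058
    tau_tis = 270.0 + 1050.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    dy[30] = (ass - ato_s) / tau_tas
    dy[31] = (iss - ito_s) / tau_tis
    tau_aur = tau_tas
    tau_iur = 1200.0 - 170.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    dy[32] = (ass - aur) / tau_aur
    dy[33] = (iss - iur) / tau_iur
    tau_Kss = 39.3 * np.exp(-0.0862 * V) + 13.17
    dy[34] = (ass - aKss) / tau_Kss
    dy[35] = 0.0  # iKss is constant in the published model

    # slow delayed rectifier
    dv = V + 26.5
    if np.abs(dv) < 1.0e-6:
        an = 4.81333e-6 / 0.128
    else:
        an = 4.81333e-6 * dv / (1.0 - np.exp(-0.128 * dv))
    bn = 9.53333e-5 * np.exp(-0.038 * dv)
    dy[36] = an * (1.0 - nKs) - bn * nKs

    # rapid delayed rectifier (5-state Markov)
    aa0 = 0.022348 * np.exp(0.01176 * V)
    ba0 = 0.047002 * np.exp(-0.0631 * V)
    aa1 = 0.013733 * np.exp(0.038198 * V)
    ba1 = 6.89e-5 * np.exp(-0.04178 * V)
    kf = 0.023761
    kb = 0.036778
    ai_kr = 0.090821 * np.exp(0.023391 * (V + 5.0))
    bi_kr = 0.006497 * np.exp(-0.03268 * (V + 5.0))
    dy[37] = aa0 * CK0 - ba0 * CK1 + kb * CK2 - kf * CK1
    dy[38] = kf * CK1 - kb * CK2 + ba1 * OK - aa1 * CK2
    dy[39] = aa1 * CK2 - ba1 * OK + bi_kr * IKI - ai_kr * OK
    dy[40] = ai_kr * OK - bi_kr * IKI

    return dy


_JAC_H = 1.0e-7 * TYPICAL_MAGNITUDE


@njit(cache=True)
def jac_core(t, y, p, istim):
    """Finite-difference Jacobian of :func:`rhs_core` (forward differences)."""
    f0 = rhs_core(t, y, p, istim)
    J = np.empty((N_STATES, N_STATES))
    yp = y.copy()
    for j in range(N_STATES):
        h = _JAC_H[j] if np.abs(y[j]) < TYPICAL_MAGNITUDE[j] else 1.0e-7 * np.abs(y[j])
        yp[j] = y[j] + h
        fj = rhs_core(t, yp, p, istim)
        for i in range(N_STATES):
            J[i, j] = (fj[i] - f0[i]) / h
        yp[j] = y[j]
    return J
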
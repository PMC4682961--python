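"""Numba kernels for the modified O'Hara-Rudy (2011) human ventricular myocyte.

The endocardial parameterization of the ORd model is implemented with the
fast Na+ current replaced by the Ten Tusscher-Panfilov (2006) formulation
(the replacement recommended for tissue-level conduction).  The late Na+
current of the original model is not part of the 14-current roster used
here and is omitted.

State layout (flat float64 vector of length ``N_STATES``):

======  ==========  ===========================================
index   name        meaning
======  ==========  ===========================================
0       v           membrane potential, mV
1-8     (conc)      nai, nass, ki, kss, cai, cass, cansr, cajsr  [mM]
9-11    m, h, j     TP06 fast Na+ gates
12-17   (Ito)       a, iF, iS, ap, iFp, iSp
18-25   (ICaL)      d, ff, fs, fcaf, fcas, jca, ffp, fcafp
26      nca         fraction of ICaL channels in Ca/CaM mode
27-31   (IK)        xrf, xrs, xs1, xs2, xk1
32-33   (Jrel)      Jrel_np, Jrel_p
34      CaMKt       fraction of trapped CaMK
======  ==========  ===========================================

States 9..33 obey ``dy/dt = (y_inf - y)/tau``.  The rates of the 22 gates
whose ``y_inf``/``tau`` depend on voltage only are produced by
:func:`vdep_gates`; the remaining three (nca, Jrel_np, Jrel_p) depend on
other state variables and are produced by :func:`cell_assemble` together
with the 14 membrane currents.  Splitting the voltage-only factors out
lets the tissue solver replace them with lookup tables
(:func:`build_tables`) without duplicating the model equations.

Gate variables are integrated with the exact exponential (Rush-Larsen)
update.  Plain forward Euler is unconditionally unstable for the TP06
m-gate at the operating time step (tau_m < 1 us near rest), so the
explicit-Euler choice applies to the voltage, concentration, and CaMK
equations only.
"""

import numpy as np
from numba import njit

N_STATES = 35
N_CURRENTS = 14
GATE0 = 9
N_VGATES = 22      # voltage-only gates
N_MISC = 13        # voltage-only current factors

# voltage-only gate slots -> state indices (excludes nca=26, Jrel=32,33)
VGATE_STATES = np.array(
    [9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25,
     27, 28, 29, 30, 31], dtype=np.int64)

# current indices (order of the model's current roster)
CUR_NA = 0
CUR_TO = 1
CUR_CAL = 2
CUR_CANA = 3
CUR_CAK = 4
CUR_KR = 5
CUR_KS = 6
CUR_K1 = 7
CUR_NACA = 8
CUR_NAK = 9
CUR_NAB = 10
CUR_CAB = 11
CUR_KB = 12
CUR_PCA = 13

CURRENT_ORDER = (
    "I_Na", "I_to", "I_CaL", "I_CaNa", "I_CaK", "I_Kr", "I_Ks",
    "I_K1", "I_NaCa", "I_NaK", "I_Nab", "I_Cab", "I_Kb", "I_pCa",
)

# misc voltage-factor slots
_M_E1 = 0      # exp(vfrt)
_M_E2 = 1      # exp(2 vfrt)
_M_ER1 = 2     # vfrt/(exp(vfrt)-1) regularized
_M_ER2 = 3     # 2 vfrt/(exp(2 vfrt)-1) regularized
_M_HCA = 4
_M_HNA = 5
_M_EKNAI = 6
_M_EKNAO = 7
_M_XKB = 8
_M_RKR = 9
_M_RK1 = 10
_M_AIF = 11
_M_AFCAF = 12

# ---- physical constants / cell geometry (ORd 2011) ----
NAO = 140.0
CAO = 1.8
KO = 5.4
RGAS = 8314.0
TEMP = 310.0
FARADAY = 96485.0
RTF = RGAS * TEMP / FARADAY

_L = 0.01
_RAD = 0.0011
VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL


def initial_state() -> np.ndarray:
    """Published model initial conditions (endo), TP06 Na+ gates at rest."""
    y = np.zeros(N_STATES)
    y[0] = -87.5
    y[1] = 7.0            # nai
    y[2] = 7.0            # nass
    y[3] = 145.0          # ki
    y[4] = 145.0          # kss
    y[5] = 1.0e-4         # cai
    y[6] = 1.0e-4         # cass
    y[7] = 1.2            # cansr
    y[8] = 1.2            # cajsr
    y[9] = 0.0            # m
    y[10] = 0.75          # h
    y[11] = 0.75          # j
    y[13] = 1.0           # iF
    y[14] = 1.0           # iS
    y[16] = 1.0           # iFp
    y[17] = 1.0           # iSp
    y[19] = 1.0           # ff
    y[20] = 1.0           # fs
    y[21] = 1.0           # fcaf
    y[22] = 1.0           # fcas
    y[23] = 1.0           # jca
    y[24] = 1.0           # ffp
    y[25] = 1.0           # fcafp
    y[31] = 1.0           # xk1
    return y


@njit(cache=True, inline="always")
def _exprel_inv(z):
    # z / (exp(z) - 1), stable near z = 0
    if abs(z) < 1e-5:
        return 1.0 - 0.5 * z + z * z / 12.0
    return z / np.expm1(z)


@njit(cache=True, inline="always")
def _rl_decay(x):
    # exp(-x) for x >= 0; cheap series for the common small-x case
    # (matches exp to < 1e-8 at the 0.08 branch point)
    if x > 0.08:
        return np.exp(-x)
    return 1.0 - x * (1.0 - 0.5 * x * (1.0 - x / 3.0 * (1.0 - 0.25 * x)))


@njit(cache=True, fastmath=True, error_model="numpy")
def vdep_gates(v, ginf, gtau):
    """Steady states and time constants (ms) of the 22 voltage-only gates.

    Slot order follows ``VGATE_STATES``.
    """
    # I_Na gates (TP06)
    mss = 1.0 / ((1.0 + np.exp((-56.86 - v) / 9.03)) ** 2)
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    tm = am * bm
    hss = 1.0 / ((1.0 + np.exp((v + 71.55) / 7.43)) ** 2)
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    th = 1.0 / (ah + bh)
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
              * (v + 37.78)) / (1.0 + np.exp(0.311 * (v + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    tj = 1.0 / (aj + bj)
    ginf[0] = mss
    gtau[0] = tm
    ginf[1] = hss
    gtau[1] = th
    ginf[2] = hss
    gtau[2] = tj

    # I_to gates (endo: no epi scaling of inactivation taus)
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                    + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    ginf[3] = ass
    gtau[3] = ta
    ginf[4] = iss
    gtau[4] = tiF
    ginf[5] = iss
    gtau[5] = tiS
    ginf[6] = assp
    gtau[6] = ta
    ginf[7] = iss
    gtau[7] = dti_develop * dti_recover * tiF
    ginf[8] = iss
    gtau[8] = dti_develop * dti_recover * tiS

    # I_CaL gates
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0) + 0.00012 * np.exp(v / 7.0))
    ginf[9] = dss
    gtau[9] = td
    ginf[10] = fss
    gtau[10] = tff
    ginf[11] = fss
    gtau[11] = tfs
    ginf[12] = fss      # fcass = fss
    gtau[12] = tfcaf
    ginf[13] = fss
    gtau[13] = tfcas
    ginf[14] = fss      # jca
    gtau[14] = 75.0
    ginf[15] = fss      # ffp
    gtau[15] = 2.5 * tff
    ginf[16] = fss      # fcafp
    gtau[16] = 2.5 * tfcaf

    # I_Kr gates
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    ginf[17] = xrss
    gtau[17] = txrf
    ginf[18] = xrss
    gtau[18] = txrs

    # I_Ks gates
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    ginf[19] = xs1ss
    gtau[19] = txs1
    ginf[20] = xs1ss
    gtau[20] = txs2

    # I_K1 gate
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * KO + 144.59) / (1.5692 * KO + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    ginf[21] = xk1ss
    gtau[21] = txk1


@njit(cache=True, fastmath=True, error_model="numpy")
def vdep_misc(v, misc):
    """Voltage-only current factors (slot order: ``_M_*`` constants)."""
    vfrt = v / RTF
    misc[_M_E1] = np.exp(vfrt)
    misc[_M_E2] = np.exp(2.0 * vfrt)
    misc[_M_ER1] = _exprel_inv(vfrt)
    misc[_M_ER2] = _exprel_inv(2.0 * vfrt)
    misc[_M_HCA] = np.exp(0.1670 * vfrt)
    misc[_M_HNA] = np.exp(0.5224 * vfrt)
    misc[_M_EKNAI] = np.exp(-0.1550 * vfrt / 3.0)
    misc[_M_EKNAO] = np.exp((1.0 + 0.1550) * vfrt / 3.0)
    misc[_M_XKB] = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    misc[_M_RKR] = (1.0 / (1.0 + np.exp((v + 55.0) / 75.0))) \
        * (1.0 / (1.0 + np.exp((v - 10.0) / 30.0)))
    misc[_M_RK1] = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * KO) / 9.493))
    misc[_M_AIF] = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    misc[_M_AFCAF] = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))


@njit(cache=True, fastmath=True, error_model="numpy")
def cell_assemble(y, mult, misc, currents, dother, sd_inf, sd_tau):
    """Membrane currents and non-gate dynamics from state + voltage factors.

    Parameters
    ----------
    y : (N_STATES,) state vector.
    mult : (N_CURRENTS,) per-current conductance multipliers.
    misc : (N_MISC,) voltage factors from :func:`vdep_misc` (or a table row).
    currents : (N_CURRENTS,) out; scaled currents, uA/uF.
    dother : (9,) out; derivatives of states 1..8 and 34.
    sd_inf, sd_tau : (3,) out; rates of the state-dependent gates
        (nca, Jrel_np, Jrel_p).

    Returns
    -------
    I_ion : total membrane current, uA/uF (stimulus excluded).
    """
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]

    ENa = RTF * np.log(NAO / nai)
    EK = RTF * np.log(KO / ki)
    EKs = RTF * np.log((KO + 0.01833 * NAO) / (ki + 0.01833 * nai))

    # CaMK (trapping model)
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKt = y[34]
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    fphos = 1.0 / (1.0 + KmCaMK / CaMKa)

    GNa = 14.838
    INa = GNa * y[9] * y[9] * y[9] * y[10] * y[11] * (v - ENa)

    Gto = 0.02
    AiF = misc[_M_AIF]
    AiS = 1.0 - AiF
    i_np = AiF * y[13] + AiS * y[14]
    i_p = AiF * y[16] + AiS * y[17]
    Ito = Gto * (v - EK) * ((1.0 - fphos) * y[12] * i_np + fphos * y[15] * i_p)

    # I_CaL / I_CaNa / I_CaK
    d = y[18]
    Aff = 0.6
    Afs = 0.4
    f = Aff * y[19] + Afs * y[20]
    Afcaf = misc[_M_AFCAF]
    Afcas = 1.0 - Afcaf
    fca = Afcaf * y[21] + Afcas * y[22]
    jca = y[23]
    fp = Aff * y[24] + Afs * y[20]
    fcap = Afcaf * y[25] + Afcas * y[22]
    nca = y[26]
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    sd_inf[0] = anca * k2n / km2n
    sd_tau[0] = 1.0 / km2n
    e1 = misc[_M_E1]
    e2 = misc[_M_E2]
    PhiCaL = 2.0 * FARADAY * misc[_M_ER2] * (cass * e2 - 0.341 * CAO)
    PhiCaNa = FARADAY * misc[_M_ER1] * (0.75 * nass * e1 - 0.75 * NAO)
    PhiCaK = FARADAY * misc[_M_ER1] * (0.75 * kss * e1 - 0.75 * KO)
    PCa = 0.0001
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    pmix = (1.0 - fphos) * gate_np + fphos * 1.1 * gate_p
    ICaL = PCa * PhiCaL * pmix
    ICaNa = 0.00125 * PCa * PhiCaNa * pmix
    ICaK = 3.574e-4 * PCa * PhiCaK * pmix

    GKr = 0.046
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    xr = Axrf * y[27] + (1.0 - Axrf) * y[28]
    IKr = GKr * np.sqrt(KO / 5.4) * xr * misc[_M_RKR] * (v - EK)

    GKs = 0.0034
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    IKs = GKs * KsCa * y[29] * y[30] * (v - EKs)

    GK1 = 0.1908
    IK1 = GK1 * np.sqrt(KO) * misc[_M_RK1] * y[31] * (v - EK)

    # I_NaCa
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    hca = misc[_M_HCA]
    hna = misc[_M_HNA]
    zca = 2.0
    zna = 1.0
    Gncx = 0.0008
    KmCaAct = 150.0e-6

    h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
    h11 = NAO * NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * CAO * kcaon
    k2 = kcaoff
    k3 = h9 * wca + h8 * wnaca
    k5 = kcaoff
    k8 = h8 * h11 * wna

    # myoplasmic component
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4pp = h2 * wnaca
    k4 = h3 * wca / hca + k4pp
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    inv_s = 1.0 / (x1 + x2 + x3 + x4)
    E1 = x1 * inv_s
    E2 = x2 * inv_s
    E3 = x3 * inv_s
    E4 = x4 * inv_s
    k3pp = h8 * wnaca
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4pp = h2 * wnaca
    k4 = h3 * wca / hca + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    inv_s = 1.0 / (x1 + x2 + x3 + x4)
    E1 = x1 * inv_s
    E2 = x2 * inv_s
    E3 = x3 * inv_s
    E4 = x4 * inv_s
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # I_NaK
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    Knai = 9.073 * misc[_M_EKNAI]
    Knao = 27.78 * misc[_M_EKNAO]
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    rnai = nai / Knai
    rki = ki / Kki
    inv_den_i = 1.0 / ((1.0 + rnai) ** 3 + (1.0 + rki) ** 2 - 1.0)
    rnao = NAO / Knao
    rko = KO / Kko
    inv_den_o = 1.0 / ((1.0 + rnao) ** 3 + (1.0 + rko) ** 2 - 1.0)
    a1 = k1p * rnai ** 3 * inv_den_i
    b1 = k1m * MgADP
    a2 = k2p
    b2 = k2m * rnao ** 3 * inv_den_o
    a3 = k3p * rko ** 2 * inv_den_o
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = k4m * rki ** 2 * inv_den_i
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    inv_s = 1.0 / (x1 + x2 + x3 + x4)
    E1 = x1 * inv_s
    E2 = x2 * inv_s
    E3 = x3 * inv_s
    E4 = x4 * inv_s
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    INaK = 30.0 * (zna * JnakNa + zk * JnakK)

    IKb = 0.003 * misc[_M_XKB] * (v - EK)
    INab = 3.75e-10 * FARADAY * misc[_M_ER1] * (nai * e1 - NAO)
    ICab = 2.5e-8 * 2.0 * FARADAY * misc[_M_ER2] * (cai * e2 - 0.341 * CAO)
    IpCa = 0.0005 * cai / (0.0005 + cai)

    # apply multipliers (concentration dynamics below see scaled currents)
    INa *= mult[CUR_NA]
    Ito *= mult[CUR_TO]
    ICaL *= mult[CUR_CAL]
    ICaNa *= mult[CUR_CANA]
    ICaK *= mult[CUR_CAK]
    IKr *= mult[CUR_KR]
    IKs *= mult[CUR_KS]
    IK1 *= mult[CUR_K1]
    INaCa_i *= mult[CUR_NACA]
    INaCa_ss *= mult[CUR_NACA]
    INaK *= mult[CUR_NAK]
    INab *= mult[CUR_NAB]
    ICab *= mult[CUR_CAB]
    IKb *= mult[CUR_KB]
    IpCa *= mult[CUR_PCA]

    currents[CUR_NA] = INa
    currents[CUR_TO] = Ito
    currents[CUR_CAL] = ICaL
    currents[CUR_CANA] = ICaNa
    currents[CUR_CAK] = ICaK
    currents[CUR_KR] = IKr
    currents[CUR_KS] = IKs
    currents[CUR_K1] = IK1
    currents[CUR_NACA] = INaCa_i + INaCa_ss
    currents[CUR_NAK] = INaK
    currents[CUR_NAB] = INab
    currents[CUR_CAB] = ICab
    currents[CUR_KB] = IKb
    currents[CUR_PCA] = IpCa

    # SR release (CaMK-sensitive), via the scaled trigger current
    bt = 4.75
    rel_drive = (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    sd_inf[1] = 0.5 * bt * rel_drive
    sd_tau[1] = tau_rel
    sd_inf[2] = 0.5 * btp * rel_drive
    sd_tau[2] = tau_relp
    Jrel = (1.0 - fphos) * y[32] + fphos * y[33]

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fphos) * Jupnp + fphos * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    acf = ACAP / (FARADAY * VMYO)
    acs = ACAP / (FARADAY * VSS)
    dother[0] = -(INa + 3.0 * INaCa_i + 3.0 * INaK + INab) * acf + JdiffNa * VSS / VMYO
    dother[1] = -(ICaNa + 3.0 * INaCa_ss) * acs - JdiffNa
    dother[2] = -(Ito + IKr + IKs + IK1 + IKb - 2.0 * INaK) * acf + JdiffK * VSS / VMYO
    dother[3] = -ICaK * acs - JdiffK

    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dother[4] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * ACAP / (2.0 * FARADAY * VMYO)
                        - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dother[5] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * ACAP / (2.0 * FARADAY * VSS)
                         + Jrel * VJSR / VSS - Jdiff)
    dother[6] = Jup - Jtr * VJSR / VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dother[7] = Bcajsr * (Jtr - Jrel)

    dother[8] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt

    return (INa + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + ICab + IKb + IpCa)


@njit(cache=True, fastmath=True, error_model="numpy")
def cell_rhs(y, mult, currents, dy):
    """Full time-derivative vector; dy[0] excludes stimulus/gap/diffusion."""
    ginf = np.empty(N_VGATES)
    gtau = np.empty(N_VGATES)
    misc = np.empty(N_MISC)
    dother = np.empty(9)
    sd_inf = np.empty(3)
    sd_tau = np.empty(3)
    vdep_gates(y[0], ginf, gtau)
    vdep_misc(y[0], misc)
    iion = cell_assemble(y, mult, misc, currents, dother, sd_inf, sd_tau)
    dy[0] = -iion
    for k in range(8):
        dy[1 + k] = dother[k]
    for g in range(N_VGATES):
        s = VGATE_STATES[g]
        dy[s] = (ginf[g] - y[s]) / gtau[g]
    dy[26] = (sd_inf[0] - y[26]) / sd_tau[0]
    dy[32] = (sd_inf[1] - y[32]) / sd_tau[1]
    dy[33] = (sd_inf[2] - y[33]) / sd_tau[2]
    dy[34] = dother[8]
    return iion


@njit(cache=True, fastmath=True, error_model="numpy")
def step_cell(y, mult, dt, i_ext):
    """Advance one myocyte one step in place (analytic rate evaluation).

    ``i_ext`` is the total extra current density (uA/uF) entering the
    voltage equation alongside I_ion: dv/dt = -(I_ion + i_ext).  Voltage,
    concentrations, and CaMKt use forward Euler; gates use Rush-Larsen.
    Returns I_ion.
    """
    ginf = np.empty(N_VGATES)
    gtau = np.empty(N_VGATES)
    misc = np.empty(N_MISC)
    currents = np.empty(N_CURRENTS)
    dother = np.empty(9)
    sd_inf = np.empty(3)
    sd_tau = np.empty(3)
    vdep_gates(y[0], ginf, gtau)
    vdep_misc(y[0], misc)
    iion = cell_assemble(y, mult, misc, currents, dother, sd_inf, sd_tau)
    y[0] += dt * (-(iion + i_ext))
    for k in range(8):
        y[1 + k] += dt * dother[k]
    for g in range(N_VGATES):
        s = VGATE_STATES[g]
        y[s] = ginf[g] + (y[s] - ginf[g]) * _rl_decay(dt / gtau[g])
    y[26] = sd_inf[0] + (y[26] - sd_inf[0]) * _rl_decay(dt / sd_tau[0])
    y[32] = sd_inf[1] + (y[32] - sd_inf[1]) * _rl_decay(dt / sd_tau[1])
    y[33] = sd_inf[2] + (y[33] - sd_inf[2]) * _rl_decay(dt / sd_tau[2])
    y[34] += dt * dother[8]
    return iion


# combined-table layout: [ginf(22) | rush-larsen decay(22) | misc(13)]
TAB_GINF = 0
TAB_ERL = N_VGATES
TAB_MISC = 2 * N_VGATES
TAB_WIDTH = 2 * N_VGATES + N_MISC


def build_tables(dt, vmin=-150.0, vmax=150.0, dv=0.01):
    """Tabulate voltage-only factors on a uniform grid for a fixed dt.

    Returns ``(tab, vmin, inv_dv)``; each row of ``tab`` holds the 22 gate
    steady states, the 22 Rush-Larsen decay factors exp(-dt/tau(v)), and
    the 13 misc current factors, ready for linear interpolation in the
    tissue kernel.
    """
    nv = int(round((vmax - vmin) / dv)) + 1
    tab = np.empty((nv, TAB_WIDTH))
    _fill_tables(dt, vmin, dv, nv, tab)
    return tab, vmin, 1.0 / dv


@njit(cache=True, fastmath=True, error_model="numpy")
def _fill_tables(dt, vmin, dv, nv, tab):
    gtau = np.empty(N_VGATES)
    for i in range(nv):
        v = vmin + i * dv
        vdep_gates(v, tab[i, TAB_GINF:TAB_ERL], gtau)
        for g in range(N_VGATES):
            tab[i, TAB_ERL + g] = np.exp(-dt / gtau[g])
        vdep_misc(v, tab[i, TAB_MISC:])
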
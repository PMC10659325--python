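"""Compiled right-hand side of the atrial myocyte ODE system.

One function, :func:`calc`, evaluates every membrane current, transporter and
SR flux, the full derivative vector, and the linear-relaxation rate ``b`` of
each state that obeys ``dy/dt = a - b*y`` (gates, buffers, RyR occupancies).
The fixed-step integrator uses ``b`` for exponential (Rush-Larsen-type)
updates; the adaptive solver route uses the derivative vector alone.

All algebra lives here so the derivative, the current bookkeeping, and the
integrator advance from a single equation source.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .parameters import PARAM_INDEX
from .states import (  # noqa: F401
    N_STATES, I_V, I_M, I_H, I_J, I_ML, I_HL, I_D, I_F, I_FCABJ, I_FCABSL,
    I_XTO, I_YTO, I_XKUR, I_YKUR, I_XKR, I_XKS, I_RYRR, I_RYRO, I_RYRI,
    I_NABJ, I_NABSL, I_TNCL, I_TNCHC, I_TNCHM, I_CAM, I_MYOC, I_MYOM, I_SRB,
    I_SLLJ, I_SLLSL, I_SLHJ, I_SLHSL, I_CSQNB, I_CASR,
    I_NAJ, I_NASL, I_NAI, I_KI, I_CAJ, I_CASL, I_CAI,
)

# Parameter index constants (compile-time for numba): P_<NAME>
_g = globals()
for _name, _idx in PARAM_INDEX.items():
    _g["P_" + _name.upper()] = _idx
del _g, _name, _idx

R_GAS = 8314.0
FARADAY = 96485.0

CURRENT_NAMES: tuple = (
    "i_na", "i_nal", "i_nab", "i_nak",
    "i_kr", "i_ks", "i_k1", "i_kp", "i_to", "i_kur", "i_k2p", "i_sk",
    "i_clca", "i_clb",
    "i_cal", "i_cal_k", "i_cal_na",
    "i_ncx", "i_pmca", "i_cab",
    "i_stim", "i_tot",
    "j_rel", "j_serca", "j_leak",
)
N_CURRENTS = len(CURRENT_NAMES)
CURRENT_INDEX = {name: i for i, name in enumerate(CURRENT_NAMES)}

(C_INA, C_INAL, C_INAB, C_INAK, C_IKR, C_IKS, C_IK1, C_IKP, C_ITO, C_IKUR,
 C_IK2P, C_ISK, C_ICLCA, C_ICLB, C_ICAL, C_ICALK, C_ICALNA, C_INCX, C_IPMCA,
 C_ICAB, C_ISTIM, C_ITOT, C_JREL, C_JSERCA, C_JLEAK) = range(N_CURRENTS)


@njit(cache=True, fastmath=False, error_model="numpy")
def calc(y, p, i_app, dydt, bcoef, cur):  # noqa: C901  (single equation source)
    """Evaluate derivatives, linear rates and currents in place.

    ``i_app`` is the applied stimulus in A/F (positive = depolarizing).
    """
    v = y[I_V]
    caj = y[I_CAJ]
    casl = y[I_CASL]
    cai = y[I_CAI]
    casr = y[I_CASR]
    naj = y[I_NAJ]
    nasl = y[I_NASL]
    nai = y[I_NAI]
    ki = y[I_KI]

    temp = p[P_TEMP]
    fort = FARADAY / (R_GAS * temp)       # 1/mV
    qpow = (temp - 310.0) / 10.0

    fjunc = p[P_FJUNC]
    fsl = 1.0 - fjunc
    fjunc_cal = p[P_FJUNC_CAL]
    fsl_cal = 1.0 - fjunc_cal

    nao = p[P_NAO]
    ko = p[P_KO]
    cao = p[P_CAO]

    # Reversal potentials
    ena_j = (1.0 / fort) * math.log(nao / naj)
    ena_sl = (1.0 / fort) * math.log(nao / nasl)
    ek = (1.0 / fort) * math.log(ko / ki)
    eca_j = (1.0 / (2.0 * fort)) * math.log(cao / caj)
    eca_sl = (1.0 / (2.0 * fort)) * math.log(cao / casl)
    ecl = (1.0 / fort) * math.log(p[P_CLI] / p[P_CLO])

    # ---------------- fast Na+ current (Courtemanche kinetics) --------------
    if abs(v + 47.13) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * math.exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * math.exp(-(v + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = ((-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))

    dydt[I_M] = am * (1.0 - y[I_M]) - bm * y[I_M]
    bcoef[I_M] = am + bm
    dydt[I_H] = ah * (1.0 - y[I_H]) - bh * y[I_H]
    bcoef[I_H] = ah + bh
    dydt[I_J] = aj * (1.0 - y[I_J]) - bj * y[I_J]
    bcoef[I_J] = aj + bj

    m3hj = y[I_M] ** 3 * y[I_H] * y[I_J]
    i_na_j = fjunc * p[P_G_NA] * m3hj * (v - ena_j)
    i_na_sl = fsl * p[P_G_NA] * m3hj * (v - ena_sl)
    i_na = i_na_j + i_na_sl

    # ---------------- late Na+ current ---------------------------------------
    # activation shares the fast-Na m kinetics; inactivation V1/2 carries the
    # configured rightward shift and a scaled time constant
    dydt[I_ML] = am * (1.0 - y[I_ML]) - bm * y[I_ML]
    bcoef[I_ML] = am + bm
    hlss = 1.0 / (1.0 + math.exp((v + 91.0 - p[P_INAL_VSHIFT]) / 6.1))
    tauhl = 600.0 * p[P_INAL_TAU_SCALE]
    dydt[I_HL] = (hlss - y[I_HL]) / tauhl
    bcoef[I_HL] = 1.0 / tauhl
    ml3 = y[I_ML] ** 3
    i_nal_j = fjunc * p[P_G_NAL] * ml3 * y[I_HL] * (v - ena_j)
    i_nal_sl = fsl * p[P_G_NAL] * ml3 * y[I_HL] * (v - ena_sl)
    i_nal = i_nal_j + i_nal_sl

    # ---------------- background Na+ -----------------------------------------
    i_nab_j = fjunc * p[P_G_NAB] * (v - ena_j)
    i_nab_sl = fsl * p[P_G_NAB] * (v - ena_sl)
    i_nab = i_nab_j + i_nab_sl

    # ---------------- Na+/K+ ATPase ------------------------------------------
    sigma = (math.exp(nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v * fort)
                  + 0.0365 * sigma * math.exp(-v * fort))
    kmnaip = p[P_KM_NAIP]
    i_nak_j = (fjunc * p[P_IBAR_NAK] * fnak * ko
               / (1.0 + (kmnaip / naj) ** 4) / (ko + p[P_KM_KO]))
    i_nak_sl = (fsl * p[P_IBAR_NAK] * fnak * ko
                / (1.0 + (kmnaip / nasl) ** 4) / (ko + p[P_KM_KO]))
    i_nak = i_nak_j + i_nak_sl

    # ---------------- rapid delayed rectifier K+ -----------------------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 10.0) / 5.0))
    tauxr = (550.0 / (1.0 + math.exp((-22.0 - v) / 9.0))
             * 6.0 / (1.0 + math.exp((v + 11.0) / 9.0))
             + 230.0 / (1.0 + math.exp((v + 40.0) / 20.0)))
    dydt[I_XKR] = (xrss - y[I_XKR]) / tauxr
    bcoef[I_XKR] = 1.0 / tauxr
    rkr = 1.0 / (1.0 + math.exp((v + 74.0) / 24.0))
    i_kr = p[P_G_KR] * math.sqrt(ko / 5.4) * y[I_XKR] * rkr * (v - ek)

    # ---------------- slow delayed rectifier K+ ------------------------------
    eks = (1.0 / fort) * math.log((ko + p[P_PNAK] * nao) / (ki + p[P_PNAK] * nai))
    vks = v + p[P_IKS_VSHIFT]
    xsss = 1.0 / (1.0 + math.exp(-(vks + 3.8) / 14.25))
    tauxs = 990.1 / (1.0 + math.exp(-(vks + 2.436) / 14.12))
    dydt[I_XKS] = (xsss - y[I_XKS]) / tauxs
    bcoef[I_XKS] = 1.0 / tauxs
    i_ks = p[P_G_KS] * y[I_XKS] ** 2 * (v - eks)

    # ---------------- transient outward K+ -----------------------------------
    xtss = 1.0 / (1.0 + math.exp(-(v + 1.0) / 11.0))
    tauxtf = 3.5 * math.exp(-((v / 30.0) ** 2)) + 1.5
    ytss = 1.0 / (1.0 + math.exp((v + 40.5) / 11.5))
    tauytf = 25.635 * math.exp(-(((v + 52.45) / 15.8827) ** 2)) + 24.14
    dydt[I_XTO] = (xtss - y[I_XTO]) / tauxtf
    bcoef[I_XTO] = 1.0 / tauxtf
    dydt[I_YTO] = (ytss - y[I_YTO]) / tauytf
    bcoef[I_YTO] = 1.0 / tauytf
    i_to = p[P_G_TO] * y[I_XTO] * y[I_YTO] * (v - ek)

    # ---------------- ultrarapid K+ ------------------------------------------
    xkurss = 1.0 / (1.0 + math.exp(-(v + 6.0) / 8.6))
    tauxkur = 9.0 / (1.0 + math.exp((v + 5.0) / 12.0)) + 0.5
    ykurss = 1.0 / (1.0 + math.exp((v + 7.5) / 10.0))
    tauykur = 590.0 / (1.0 + math.exp((v + 60.0) / 10.0)) + 3050.0
    dydt[I_XKUR] = (xkurss - y[I_XKUR]) / tauxkur
    bcoef[I_XKUR] = 1.0 / tauxkur
    dydt[I_YKUR] = (ykurss - y[I_YKUR]) / tauykur
    bcoef[I_YKUR] = 1.0 / tauykur
    i_kur = p[P_G_KUR] * y[I_XKUR] * y[I_YKUR] * (v - ek)

    # ---------------- inward rectifier K+ ------------------------------------
    aki = 1.02 / (1.0 + math.exp(0.2385 * (v - ek - 59.215)))
    bki = ((0.49124 * math.exp(0.08032 * (v + 5.476 - ek))
            + math.exp(0.06175 * (v - ek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (v - ek + 4.753))))
    kiss = aki / (aki + bki)
    i_k1 = p[P_G_K1] * math.sqrt(ko / 5.4) * kiss * (v - ek)

    # ---------------- plateau K+ ----------------------------------------------
    kp_kp = 1.0 / (1.0 + math.exp(7.488 - v / 5.98))
    i_kp = p[P_G_KP] * kp_kp * (v - ek)

    # ---------------- two-pore-domain K+ --------------------------------------
    # quasi-instantaneous, mildly outwardly rectifying open probability
    a_k2p = 1.0 / (1.0 + math.exp(-(v + 15.0) / 20.0))
    i_k2p = p[P_G_K2P] * a_k2p * (v - ek)

    # ---------------- small-conductance Ca2+-activated K+ ---------------------
    # Ca2+ activation: Hill function of cleft / subsarcolemmal free Ca2+;
    # voltage dependence: mild inward rectification of the open-channel
    # conductance (sigmoid of driving force).
    kd = p[P_KD_SK]
    nhill = p[P_SK_HILL]
    caj_n = caj ** nhill
    casl_n = casl ** nhill
    kd_n = kd ** nhill
    po_j = caj_n / (caj_n + kd_n)
    po_sl = casl_n / (casl_n + kd_n)
    rect = (p[P_SK_RECT_FLOOR]
            + (1.0 - p[P_SK_RECT_FLOOR])
            / (1.0 + math.exp((v - ek - p[P_SK_RECT_VHALF]) / p[P_SK_RECT_SLOPE])))
    i_sk = p[P_G_SK] * rect * (fjunc * po_j + fsl * po_sl) * (v - ek)

    # ---------------- Ca2+-activated and background Cl- -----------------------
    kdclca = p[P_KD_CLCA]
    i_clca = (fjunc * p[P_G_CLCA] / (1.0 + kdclca / caj) * (v - ecl)
              + fsl * p[P_G_CLCA] / (1.0 + kdclca / casl) * (v - ecl))
    i_clb = p[P_G_CLB] * (v - ecl)

    # ---------------- L-type Ca2+ current (GHK) --------------------------------
    vca = v + p[P_ICAL_VSHIFT]
    dss = 1.0 / (1.0 + math.exp(-(vca + 9.0) / 6.0))
    if abs(vca + 9.0) < 1e-6:
        taud = dss / (0.035 * 6.0)  # limit of dss*(1-exp(-u/6))/(0.035*u) as u->0
    else:
        taud = dss * (1.0 - math.exp(-(vca + 9.0) / 6.0)) / (0.035 * (vca + 9.0))
    fss = (1.0 / (1.0 + math.exp((vca + 30.0) / 7.0))
           + 0.2 / (1.0 + math.exp((50.0 - vca) / 20.0)))
    tauf = 1.0 / (0.0197 * math.exp(-(0.0337 * (vca + 25.0)) ** 2) + 0.02)
    dydt[I_D] = (dss - y[I_D]) / taud
    bcoef[I_D] = 1.0 / taud
    dydt[I_F] = (fss - y[I_F]) / tauf
    bcoef[I_F] = 1.0 / tauf
    # Ca2+-dependent inactivation gates (bound-fraction form)
    dydt[I_FCABJ] = 1.7 * caj * (1.0 - y[I_FCABJ]) - 11.9e-3 * y[I_FCABJ]
    bcoef[I_FCABJ] = 1.7 * caj + 11.9e-3
    dydt[I_FCABSL] = 1.7 * casl * (1.0 - y[I_FCABSL]) - 11.9e-3 * y[I_FCABSL]
    bcoef[I_FCABSL] = 1.7 * casl + 11.9e-3

    q10cal = p[P_Q10_CAL] ** qpow
    vfort = v * fort
    ex2 = math.exp(2.0 * vfort)
    ex1 = math.exp(vfort)
    if abs(v) < 1e-6:
        # GHK limits at v -> 0
        ibarca_j = p[P_P_CA] * 2.0 * FARADAY * 0.341 * (caj - cao)
        ibarca_sl = p[P_P_CA] * 2.0 * FARADAY * 0.341 * (casl - cao)
        ibark = p[P_P_K] * FARADAY * 0.75 * (ki - ko)
        ibarna_j = p[P_P_NA] * FARADAY * 0.75 * (naj - nao)
        ibarna_sl = p[P_P_NA] * FARADAY * 0.75 * (nasl - nao)
    else:
        gz2 = 4.0 * vfort * FARADAY / (ex2 - 1.0)
        gz1 = vfort * FARADAY / (ex1 - 1.0)
        ibarca_j = p[P_P_CA] * gz2 * (0.341 * caj * ex2 - 0.341 * cao)
        ibarca_sl = p[P_P_CA] * gz2 * (0.341 * casl * ex2 - 0.341 * cao)
        ibark = p[P_P_K] * gz1 * (0.75 * ki * ex1 - 0.75 * ko)
        ibarna_j = p[P_P_NA] * gz1 * (0.75 * naj * ex1 - 0.75 * nao)
        ibarna_sl = p[P_P_NA] * gz1 * (0.75 * nasl * ex1 - 0.75 * nao)

    df = y[I_D] * y[I_F]
    i_ca_j = fjunc_cal * ibarca_j * df * (1.0 - y[I_FCABJ]) * q10cal * 0.45
    i_ca_sl = fsl_cal * ibarca_sl * df * (1.0 - y[I_FCABSL]) * q10cal * 0.45
    i_cak = (ibark * df * (fjunc_cal * (1.0 - y[I_FCABJ])
                           + fsl_cal * (1.0 - y[I_FCABSL])) * q10cal * 0.45)
    i_cana_j = fjunc_cal * ibarna_j * df * (1.0 - y[I_FCABJ]) * q10cal * 0.45
    i_cana_sl = fsl_cal * ibarna_sl * df * (1.0 - y[I_FCABSL]) * q10cal * 0.45

    # ---------------- Na+/Ca2+ exchanger ---------------------------------------
    q10ncx = p[P_Q10_NCX] ** qpow
    kdact = p[P_KD_ACT]
    nu = p[P_NU]
    ksat = p[P_KSAT]
    kmcai = p[P_KM_CAI]
    kmcao = p[P_KM_CAO]
    kmnai = p[P_KM_NAI]
    kmnao = p[P_KM_NAO]
    exnu = math.exp(nu * vfort)
    exnu1 = math.exp((nu - 1.0) * vfort)

    ka_j = 1.0 / (1.0 + (kdact / caj) ** 2)
    s1_j = exnu * naj ** 3 * cao
    s2_j = exnu1 * nao ** 3 * caj
    s3_j = (kmcai * nao ** 3 * (1.0 + (naj / kmnai) ** 3)
            + kmnao ** 3 * caj * (1.0 + caj / kmcai)
            + kmcao * naj ** 3 + naj ** 3 * cao + nao ** 3 * caj)
    i_ncx_j = (fjunc * p[P_IBAR_NCX] * q10ncx * ka_j * (s1_j - s2_j)
               / s3_j / (1.0 + ksat * exnu1))

    ka_sl = 1.0 / (1.0 + (kdact / casl) ** 2)
    s1_sl = exnu * nasl ** 3 * cao
    s2_sl = exnu1 * nao ** 3 * casl
    s3_sl = (kmcai * nao ** 3 * (1.0 + (nasl / kmnai) ** 3)
             + kmnao ** 3 * casl * (1.0 + casl / kmcai)
             + kmcao * nasl ** 3 + nasl ** 3 * cao + nao ** 3 * casl)
    i_ncx_sl = (fsl * p[P_IBAR_NCX] * q10ncx * ka_sl * (s1_sl - s2_sl)
                / s3_sl / (1.0 + ksat * exnu1))
    i_ncx = i_ncx_j + i_ncx_sl

    # ---------------- sarcolemmal Ca2+ pump and background --------------------
    q10pmca = p[P_Q10_PMCA] ** qpow
    kmpca16_j = p[P_KM_PCA] ** 1.6
    i_pca_j = (fjunc * q10pmca * p[P_IBAR_PMCA] * caj ** 1.6
               / (kmpca16_j + caj ** 1.6))
    i_pca_sl = (fsl * q10pmca * p[P_IBAR_PMCA] * casl ** 1.6
                / (kmpca16_j + casl ** 1.6))
    i_cab_j = fjunc * p[P_G_CAB] * (v - eca_j)
    i_cab_sl = fsl * p[P_G_CAB] * (v - eca_sl)

    if p[P_CLAMP_SARC_CA] > 0.5:
        i_ca_j = 0.0
        i_ca_sl = 0.0
        i_cana_j = 0.0
        i_cana_sl = 0.0
        i_cak = 0.0
        i_ncx_j = 0.0
        i_ncx_sl = 0.0
        i_ncx = 0.0
        i_pca_j = 0.0
        i_pca_sl = 0.0
        i_cab_j = 0.0
        i_cab_sl = 0.0

    i_cal = i_ca_j + i_ca_sl
    i_pca = i_pca_j + i_pca_sl
    i_cab = i_cab_j + i_cab_sl
    i_cana = i_cana_j + i_cana_sl

    # ---------------- SR fluxes -------------------------------------------------
    # RyR with luminal Ca2+ regulation; EC50 of the luminal sensor is the
    # cAF-remodeled quantity (halved in cAF).
    kcasr = (p[P_MAX_SR]
             - (p[P_MAX_SR] - p[P_MIN_SR])
             / (1.0 + (p[P_EC50_SR] / casr) ** 2.5))
    kosrca = p[P_KO_CA] / kcasr
    kisrca = p[P_KI_CA] * kcasr
    kim = p[P_KIM_RYR]
    kom = p[P_KOM_RYR]
    r_ryr = y[I_RYRR]
    o_ryr = y[I_RYRO]
    i_ryr = y[I_RYRI]
    ri = 1.0 - r_ryr - o_ryr - i_ryr
    dydt[I_RYRR] = (kim * ri - kisrca * caj * r_ryr
                    - (kosrca * caj ** 2 * r_ryr - kom * o_ryr))
    bcoef[I_RYRR] = kim + kisrca * caj + kosrca * caj ** 2
    dydt[I_RYRO] = (kosrca * caj ** 2 * r_ryr - kom * o_ryr
                    - (kisrca * caj * o_ryr - kim * i_ryr))
    bcoef[I_RYRO] = kom + kisrca * caj
    dydt[I_RYRI] = (kisrca * caj * o_ryr - kim * i_ryr
                    - (kom * i_ryr - kosrca * caj ** 2 * ri))
    bcoef[I_RYRI] = kim + kom + kosrca * caj ** 2
    j_rel = p[P_KS_RYR] * o_ryr * (casr - caj)

    q10serca = p[P_Q10_SERCA] ** qpow
    hserca = p[P_HILL_SERCA]
    upf = (cai / p[P_KMF_SERCA]) ** hserca
    upr = (casr / p[P_KMR_SERCA]) ** hserca
    j_serca = q10serca * p[P_VMAX_SERCA] * (upf - upr) / (1.0 + upf + upr)

    j_leak = p[P_KLEAK_SR] * (casr - caj)

    # ---------------- buffering --------------------------------------------------
    # Na+
    dydt[I_NABJ] = p[P_KON_NA] * naj * (p[P_BMAX_NAJ] - y[I_NABJ]) - p[P_KOFF_NA] * y[I_NABJ]
    bcoef[I_NABJ] = p[P_KON_NA] * naj + p[P_KOFF_NA]
    dydt[I_NABSL] = p[P_KON_NA] * nasl * (p[P_BMAX_NASL] - y[I_NABSL]) - p[P_KOFF_NA] * y[I_NABSL]
    bcoef[I_NABSL] = p[P_KON_NA] * nasl + p[P_KOFF_NA]

    # cytosolic Ca2+ buffers
    mgi = p[P_MGI]
    dydt[I_TNCL] = p[P_KON_TNCL] * cai * (p[P_BMAX_TNCL] - y[I_TNCL]) - p[P_KOFF_TNCL] * y[I_TNCL]
    bcoef[I_TNCL] = p[P_KON_TNCL] * cai + p[P_KOFF_TNCL]
    tnch_free = p[P_BMAX_TNCH] - y[I_TNCHC] - y[I_TNCHM]
    dydt[I_TNCHC] = p[P_KON_TNCHCA] * cai * tnch_free - p[P_KOFF_TNCHCA] * y[I_TNCHC]
    bcoef[I_TNCHC] = p[P_KON_TNCHCA] * cai + p[P_KOFF_TNCHCA]
    dydt[I_TNCHM] = p[P_KON_TNCHMG] * mgi * tnch_free - p[P_KOFF_TNCHMG] * y[I_TNCHM]
    bcoef[I_TNCHM] = p[P_KON_TNCHMG] * mgi + p[P_KOFF_TNCHMG]
    dydt[I_CAM] = p[P_KON_CAM] * cai * (p[P_BMAX_CAM] - y[I_CAM]) - p[P_KOFF_CAM] * y[I_CAM]
    bcoef[I_CAM] = p[P_KON_CAM] * cai + p[P_KOFF_CAM]
    myo_free = p[P_BMAX_MYOSIN] - y[I_MYOC] - y[I_MYOM]
    dydt[I_MYOC] = p[P_KON_MYOCA] * cai * myo_free - p[P_KOFF_MYOCA] * y[I_MYOC]
    bcoef[I_MYOC] = p[P_KON_MYOCA] * cai + p[P_KOFF_MYOCA]
    dydt[I_MYOM] = p[P_KON_MYOMG] * mgi * myo_free - p[P_KOFF_MYOMG] * y[I_MYOM]
    bcoef[I_MYOM] = p[P_KON_MYOMG] * mgi + p[P_KOFF_MYOMG]
    dydt[I_SRB] = p[P_KON_SR] * cai * (p[P_BMAX_SR] - y[I_SRB]) - p[P_KOFF_SR] * y[I_SRB]
    bcoef[I_SRB] = p[P_KON_SR] * cai + p[P_KOFF_SR]
    j_cab_cytosol = (dydt[I_TNCL] + dydt[I_TNCHC] + dydt[I_CAM]
                     + dydt[I_MYOC] + dydt[I_SRB])

    # junctional and subsarcolemmal buffers
    dydt[I_SLLJ] = p[P_KON_SLL] * caj * (p[P_BMAX_SLL_J] - y[I_SLLJ]) - p[P_KOFF_SLL] * y[I_SLLJ]
    bcoef[I_SLLJ] = p[P_KON_SLL] * caj + p[P_KOFF_SLL]
    dydt[I_SLLSL] = p[P_KON_SLL] * casl * (p[P_BMAX_SLL_SL] - y[I_SLLSL]) - p[P_KOFF_SLL] * y[I_SLLSL]
    bcoef[I_SLLSL] = p[P_KON_SLL] * casl + p[P_KOFF_SLL]
    dydt[I_SLHJ] = p[P_KON_SLH] * caj * (p[P_BMAX_SLH_J] - y[I_SLHJ]) - p[P_KOFF_SLH] * y[I_SLHJ]
    bcoef[I_SLHJ] = p[P_KON_SLH] * caj + p[P_KOFF_SLH]
    dydt[I_SLHSL] = p[P_KON_SLH] * casl * (p[P_BMAX_SLH_SL] - y[I_SLHSL]) - p[P_KOFF_SLH] * y[I_SLHSL]
    bcoef[I_SLHSL] = p[P_KON_SLH] * casl + p[P_KOFF_SLH]
    j_cab_junc = dydt[I_SLLJ] + dydt[I_SLHJ]
    j_cab_sl = dydt[I_SLLSL] + dydt[I_SLHSL]

    # calsequestrin (SR lumen)
    dydt[I_CSQNB] = (p[P_KON_CSQN] * casr * (p[P_BMAX_CSQN] - y[I_CSQNB])
                     - p[P_KOFF_CSQN] * y[I_CSQNB])
    bcoef[I_CSQNB] = p[P_KON_CSQN] * casr + p[P_KOFF_CSQN]

    # ---------------- ion balances ------------------------------------------------
    cmem = p[P_CMEM]
    vjunc = p[P_V_JUNC]
    vsl = p[P_V_SL]
    vmyo = p[P_V_MYO]
    vsr = p[P_V_SR]

    i_na_tot_j = i_na_j + i_nal_j + i_nab_j + 3.0 * i_ncx_j + 3.0 * i_nak_j + i_cana_j
    i_na_tot_sl = i_na_sl + i_nal_sl + i_nab_sl + 3.0 * i_ncx_sl + 3.0 * i_nak_sl + i_cana_sl

    dydt[I_NAJ] = (-i_na_tot_j * cmem / (vjunc * FARADAY)
                   + p[P_J_NA_JUNCSL] / vjunc * (nasl - naj) - dydt[I_NABJ])
    bcoef[I_NAJ] = 0.0
    dydt[I_NASL] = (-i_na_tot_sl * cmem / (vsl * FARADAY)
                    + p[P_J_NA_JUNCSL] / vsl * (naj - nasl)
                    + p[P_J_NA_SLMYO] / vsl * (nai - nasl) - dydt[I_NABSL])
    bcoef[I_NASL] = 0.0
    dydt[I_NAI] = p[P_J_NA_SLMYO] / vmyo * (nasl - nai)
    bcoef[I_NAI] = 0.0

    dydt[I_KI] = 0.0  # intracellular K+ clamped (lineage convention)
    bcoef[I_KI] = 0.0

    i_ca_tot_j = i_ca_j + i_cab_j + i_pca_j - 2.0 * i_ncx_j
    i_ca_tot_sl = i_ca_sl + i_cab_sl + i_pca_sl - 2.0 * i_ncx_sl

    dydt[I_CAJ] = (-i_ca_tot_j * cmem / (vjunc * 2.0 * FARADAY)
                   + p[P_J_CA_JUNCSL] / vjunc * (casl - caj) - j_cab_junc
                   + j_rel * vsr / vjunc + j_leak * vmyo / vjunc)
    bcoef[I_CAJ] = 0.0
    dydt[I_CASL] = (-i_ca_tot_sl * cmem / (vsl * 2.0 * FARADAY)
                    + p[P_J_CA_JUNCSL] / vsl * (caj - casl)
                    + p[P_J_CA_SLMYO] / vsl * (cai - casl) - j_cab_sl)
    bcoef[I_CASL] = 0.0
    dydt[I_CAI] = (-j_serca * vsr / vmyo - j_cab_cytosol
                   + p[P_J_CA_SLMYO] / vmyo * (casl - cai))
    bcoef[I_CAI] = 0.0
    dydt[I_CASR] = j_serca - (j_leak * vmyo / vsr + j_rel) - dydt[I_CSQNB]
    bcoef[I_CASR] = 0.0

    # ---------------- membrane potential -------------------------------------------
    i_cl_tot = i_clca + i_clb
    i_na_tot = i_na_tot_j + i_na_tot_sl
    i_ca_tot = i_ca_tot_j + i_ca_tot_sl
    i_k_tot = (i_to + i_kr + i_ks + i_k1 + i_kp + i_kur + i_k2p + i_sk
               - 2.0 * i_nak + i_cak)
    i_tot = i_na_tot + i_cl_tot + i_ca_tot + i_k_tot
    dydt[I_V] = -(i_tot - i_app)
    bcoef[I_V] = 0.0

    # ---------------- current bookkeeping -------------------------------------------
    cur[C_INA] = i_na
    cur[C_INAL] = i_nal
    cur[C_INAB] = i_nab
    cur[C_INAK] = i_nak
    cur[C_IKR] = i_kr
    cur[C_IKS] = i_ks
    cur[C_IK1] = i_k1
    cur[C_IKP] = i_kp
    cur[C_ITO] = i_to
    cur[C_IKUR] = i_kur
    cur[C_IK2P] = i_k2p
    cur[C_ISK] = i_sk
    cur[C_ICLCA] = i_clca
    cur[C_ICLB] = i_clb
    cur[C_ICAL] = i_cal
    cur[C_ICALK] = i_cak
    cur[C_ICALNA] = i_cana
    cur[C_INCX] = i_ncx
    cur[C_IPMCA] = i_pca
    cur[C_ICAB] = i_cab
    cur[C_ISTIM] = i_app
    cur[C_ITOT] = i_tot
    cur[C_JREL] = j_rel
    cur[C_JSERCA] = j_serca
    cur[C_JLEAK] = j_leak


@njit(cache=True)
def rhs_only(t, y, p, i_app):
    """Derivative vector for adaptive solvers (allocates per call)."""
    dydt = np.empty(y.shape[0])
    bcoef = np.empty(y.shape[0])
    cur = np.empty(N_CURRENTS)
    calc(y, p, i_app, dydt, bcoef, cur)
    return dydt


@njit(cache=True)
def currents_over(states, p, i_app_vec):
    """Current matrix (n_points x N_CURRENTS) for recorded states."""
    n = states.shape[0]
    out = np.empty((n, N_CURRENTS))
    dydt = np.empty(states.shape[1])
    bcoef = np.empty(states.shape[1])
    cur = np.empty(N_CURRENTS)
    for k in range(n):
        calc(states[k], p, i_app_vec[k], dydt, bcoef, cur)
        for c in range(N_CURRENTS):
            out[k, c] = cur[c]
    return out
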
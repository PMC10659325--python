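"""State vector layout and initial conditions.

The state comprises membrane potential, Hodgkin-Huxley gates, RyR state
occupancies, buffer-bound species, and free Na+/Ca2+/K+ per compartment.
Index constants are module-level integers so the numba-compiled right-hand
side treats them as compile-time constants.
"""

from __future__ import annotations

import numpy as np

STATE_NAMES: tuple = (
    "v",            # mV, membrane potential
    "m", "h", "j",              # fast Na+ gates (Courtemanche kinetics)
    "ml", "hl",                 # late Na+ gates
    "d", "f", "fcab_j", "fcab_sl",  # L-type Ca2+ gates / Ca-dependent inactivation
    "xto", "yto",               # transient outward K+
    "xkur", "ykur",             # ultrarapid K+
    "xkr",                      # rapid delayed rectifier
    "xks",                      # slow delayed rectifier
    "ryr_r", "ryr_o", "ryr_i",  # RyR resting / open / inactivated fractions
    "nab_j", "nab_sl",          # buffered Na+ (mM)
    "tncl", "tnchc", "tnchm",   # troponin buffers (mM)
    "cam", "myoc", "myom", "srb",   # calmodulin, myosin, SR-membrane buffers (mM)
    "sll_j", "sll_sl", "slh_j", "slh_sl",  # sarcolemmal buffers (mM)
    "csqnb",        # calsequestrin-bound Ca2+ (mM)
    "ca_sr",        # free SR Ca2+ (mM)
    "na_j", "na_sl", "na_i",    # free Na+ (mM)
    "k_i",          # free K+ (mM), clamped
    "ca_j", "ca_sl", "ca_i",    # free Ca2+ (mM)
)

N_STATES = len(STATE_NAMES)
STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

# Individual index constants used by the compiled RHS.
(I_V, I_M, I_H, I_J, I_ML, I_HL, I_D, I_F, I_FCABJ, I_FCABSL,
 I_XTO, I_YTO, I_XKUR, I_YKUR, I_XKR, I_XKS,
 I_RYRR, I_RYRO, I_RYRI,
 I_NABJ, I_NABSL,
 I_TNCL, I_TNCHC, I_TNCHM, I_CAM, I_MYOC, I_MYOM, I_SRB,
 I_SLLJ, I_SLLSL, I_SLHJ, I_SLHSL,
 I_CSQNB, I_CASR,
 I_NAJ, I_NASL, I_NAI, I_KI,
 I_CAJ, I_CASL, I_CAI) = range(N_STATES)

GATE_INDICES = (I_M, I_H, I_J, I_ML, I_HL, I_D, I_F, I_FCABJ, I_FCABSL,
                I_XTO, I_YTO, I_XKUR, I_YKUR, I_XKR, I_XKS)
FRACTION_INDICES = GATE_INDICES + (I_RYRR, I_RYRO, I_RYRI)
CONCENTRATION_INDICES = tuple(range(I_NABJ, N_STATES))


def initial_state(v0: float = -75.0) -> np.ndarray:
    """Approximate diastolic state; pace to steady state before measurements.

    Gates are set to their steady-state values at ``v0``; concentrations and
    buffer occupancies to typical diastolic levels for the lineage.
    """
    y = np.zeros(N_STATES)
    y[I_V] = v0
    # Na gates (Courtemanche/Luo-Rudy kinetics steady state at v0)
    am = 0.32 * (v0 + 47.13) / (1.0 - np.exp(-0.1 * (v0 + 47.13)))
    bm = 0.08 * np.exp(-v0 / 11.0)
    y[I_M] = am / (am + bm)
    if v0 >= -40.0:
        ah, aj = 0.0, 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(v0 + 10.66) / 11.1)))
        bj = 0.3 * np.exp(-2.535e-7 * v0) / (1.0 + np.exp(-0.1 * (v0 + 32.0)))
    else:
        ah = 0.135 * np.exp(-(v0 + 80.0) / 6.8)
        bh = 3.56 * np.exp(0.079 * v0) + 3.1e5 * np.exp(0.35 * v0)
        aj = ((-1.2714e5 * np.exp(0.2444 * v0) - 3.474e-5 * np.exp(-0.04391 * v0))
              * (v0 + 37.78) / (1.0 + np.exp(0.311 * (v0 + 79.23))))
        bj = 0.1212 * np.exp(-0.01052 * v0) / (1.0 + np.exp(-0.1378 * (v0 + 40.14)))
    y[I_H] = ah / (ah + bh) if (ah + bh) > 0 else 1.0 / (1.0 + np.exp((v0 + 66.0) / 6.0))
    y[I_J] = aj / (aj + bj) if (aj + bj) > 0 else y[I_H]
    if v0 >= -40.0:
        y[I_H] = 1.0 / (1.0 + np.exp((v0 + 66.0) / 6.0))
        y[I_J] = y[I_H]
    y[I_ML] = y[I_M]
    y[I_HL] = 1.0 / (1.0 + np.exp((v0 + 70.0) / 6.1))
    y[I_D] = 1.0 / (1.0 + np.exp(-(v0 + 9.0) / 6.0))
    y[I_F] = 1.0 / (1.0 + np.exp((v0 + 30.0) / 7.0)) + 0.2 / (1.0 + np.exp((50.0 - v0) / 20.0))
    y[I_FCABJ] = 0.025
    y[I_FCABSL] = 0.015
    y[I_XTO] = 1.0 / (1.0 + np.exp(-(v0 + 1.0) / 11.0))
    y[I_YTO] = 1.0 / (1.0 + np.exp((v0 + 40.5) / 11.5))
    y[I_XKUR] = 1.0 / (1.0 + np.exp(-(v0 + 6.0) / 8.6))
    y[I_YKUR] = 1.0 / (1.0 + np.exp((v0 + 7.5) / 10.0))
    y[I_XKR] = 1.0 / (1.0 + np.exp(-(v0 + 10.0) / 5.0))
    y[I_XKS] = 1.0 / (1.0 + np.exp(-(v0 + 3.8) / 14.25))
    # RyR
    y[I_RYRR] = 0.89
    y[I_RYRO] = 1e-6
    y[I_RYRI] = 1e-7
    # Buffers (mM)
    y[I_NABJ] = 3.54
    y[I_NABSL] = 0.77
    y[I_TNCL] = 8.77e-3
    y[I_TNCHC] = 0.108
    y[I_TNCHM] = 0.0152
    y[I_CAM] = 2.91e-4
    y[I_MYOC] = 1.30e-3
    y[I_MYOM] = 0.138
    y[I_SRB] = 2.14e-3
    y[I_SLLJ] = 9.57e-3
    y[I_SLLSL] = 1.11e-2
    y[I_SLHJ] = 7.35e-3
    y[I_SLHSL] = 7.30e-2
    y[I_CSQNB] = 1.24
    y[I_CASR] = 0.55
    y[I_NAJ] = 9.14
    y[I_NASL] = 9.14
    y[I_NAI] = 9.14
    y[I_KI] = 120.0
    y[I_CAJ] = 1.74e-4
    y[I_CASL] = 1.03e-4
    y[I_CAI] = 8.60e-5
    return y
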
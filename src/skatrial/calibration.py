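"""Calibration routines for the Na+ current modifications.

Two calibrations accompany the fast/late Na+ current substitutions:

* the fast Na+ conductance is set so the maximal AP upstroke velocity at
  1-Hz pacing in the nSR model falls in the physiological 150-300 V/s band
  (:func:`check_upstroke`);
* the late Na+ conductance is set so that, after the +21 mV shift of the
  inactivation voltage dependence and the faster inactivation time constant,
  the AP-clamp charge carried by the current over a 1-Hz nSR beat matches
  the unmodified formulation (:func:`calibrate_gnal`). The reference
  formulation uses the lineage's native half-inactivation (-91 mV) and
  600-ms time constant with its native conductance.
"""

from __future__ import annotations

import numpy as np

from .integrate import integrate
from .parameters import ModelParameters
from .states import initial_state

#: lineage-native late Na+ conductance (mS/uF) used as calibration reference
GNAL_REFERENCE = 0.0025
#: physiological band for the maximal upstroke velocity (V/s)
UPSTROKE_BAND = (150.0, 300.0)


def ap_clamp_inal(v_t: np.ndarray, v_mv: np.ndarray, g_nal: float,
                  vshift: float, tau_scale: float,
                  e_na: float = 70.0) -> float:
    """Time integral of |I_NaL| (A/F*ms) under an AP voltage clamp.

    Gates are integrated over the clamp with the same kinetics as the model
    RHS (activation shares the fast-Na m gate; inactivation is a shifted
    Boltzmann with scaled time constant).
    """
    ml, hl = 0.0, 1.0
    # initialize at the first clamp potential's steady state
    v0 = v_mv[0]
    am0 = 3.2 if abs(v0 + 47.13) < 1e-6 else \
        0.32 * (v0 + 47.13) / (1 - np.exp(-0.1 * (v0 + 47.13)))
    bm0 = 0.08 * np.exp(-v0 / 11.0)
    ml = am0 / (am0 + bm0)
    hl = 1.0 / (1.0 + np.exp((v0 + 91.0 - vshift) / 6.1))
    integral = 0.0
    for k in range(1, len(v_t)):
        dt = v_t[k] - v_t[k - 1]
        v = v_mv[k]
        am = 3.2 if abs(v + 47.13) < 1e-6 else \
            0.32 * (v + 47.13) / (1 - np.exp(-0.1 * (v + 47.13)))
        bm = 0.08 * np.exp(-v / 11.0)
        mlss = am / (am + bm)
        taum = 1.0 / (am + bm)
        ml = mlss + (ml - mlss) * np.exp(-dt / taum)
        hlss = 1.0 / (1.0 + np.exp((v + 91.0 - vshift) / 6.1))
        tauhl = 600.0 * tau_scale
        hl = hlss + (hl - hlss) * np.exp(-dt / tauhl)
        integral += abs(g_nal * ml**3 * hl * (v - e_na)) * dt
    return integral


def reference_ap_trace(params: ModelParameters, n_beats: int = 40
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Voltage trace of one 1-Hz beat after burn-in pacing."""
    y = initial_state()
    y, _ = integrate(params, y, (n_beats - 1) * 1000.0,
                     stim_times=np.arange(0, (n_beats - 1) * 1000.0, 1000.0),
                     record_dt=None)
    _, tr = integrate(params, y, 1000.0, stim_times=[0.0])
    return tr.t, tr.v


def calibrate_gnal(params: ModelParameters | None = None,
                   n_beats: int = 40) -> float:
    """Late Na+ conductance matching the pre-modification AP-clamp charge."""
    from .parameters import nsr_parameters

    params = params or nsr_parameters()
    t, v = reference_ap_trace(params, n_beats)
    q_ref = ap_clamp_inal(t, v, GNAL_REFERENCE, vshift=0.0, tau_scale=1.0)
    q_mod_unit = ap_clamp_inal(t, v, 1.0, vshift=params.inal_vshift,
                               tau_scale=params.inal_tau_scale)
    return q_ref / q_mod_unit


def check_upstroke(params: ModelParameters, n_beats: int = 40) -> float:
    """Maximal upstroke velocity (V/s) at 1-Hz steady pacing."""
    t, v = reference_ap_trace(params, n_beats)
    return float(np.max(np.diff(v) / np.diff(t)))
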
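"""User-facing evaluation of the myocyte model: derivatives and currents.

Thin validated wrappers around the compiled equation source in
:mod:`skatrial.rhs`; single-current probes (``i_sk``, ``i_nal``) evaluate the
same compiled algebra rather than re-stating formulas.
"""

from __future__ import annotations

import numpy as np

from .integrate import integrate
from .parameters import ModelParameters
from .rhs import CURRENT_INDEX, CURRENT_NAMES, N_CURRENTS, calc
from .states import (I_CAJ, I_CASL, I_HL, I_ML, I_V, N_STATES, STATE_NAMES,
                     initial_state)


def derivatives(t: float, state: np.ndarray, params: ModelParameters,
                i_app: float = 0.0) -> np.ndarray:
    """Time derivative of every state variable (units per ms).

    Raises ``ValueError`` naming the first non-finite state variable.
    """
    state = np.asarray(state, dtype=np.float64)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},)")
    bad = np.flatnonzero(~np.isfinite(state))
    if bad.size:
        raise ValueError(f"non-finite state variable {STATE_NAMES[bad[0]]!r}")
    dydt = np.empty(N_STATES)
    bcoef = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    calc(state, params.to_vector(), i_app, dydt, bcoef, cur)
    return dydt


def currents(state: np.ndarray, params: ModelParameters,
             i_app: float = 0.0) -> dict:
    """All membrane currents (A/F) and SR fluxes (mM/ms) at one state."""
    state = np.asarray(state, dtype=np.float64)
    dydt = np.empty(N_STATES)
    bcoef = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    calc(state, params.to_vector(), i_app, dydt, bcoef, cur)
    return {name: cur[i] for i, name in enumerate(CURRENT_NAMES)}


def i_sk(em_mv: float, ca_local_nm: float, params: ModelParameters) -> float:
    """SK current (A/F) at a membrane potential and local free [Ca2+] (nM).

    The local Ca2+ is imposed on both the cleft and subsarcolemmal
    compartments the channel senses.
    """
    if ca_local_nm < 0:
        raise ValueError("local Ca2+ must be >= 0")
    y = initial_state()
    y[I_V] = em_mv
    y[I_CAJ] = ca_local_nm * 1e-6  # nM -> mM
    y[I_CASL] = ca_local_nm * 1e-6
    return currents(y, params)["i_sk"]


def i_nal(em_mv: float, ml: float, hl: float, params: ModelParameters) -> float:
    """Late Na+ current (A/F) for given activation/inactivation gate values."""
    if not (0.0 <= ml <= 1.0 and 0.0 <= hl <= 1.0):
        raise ValueError("gates must lie in [0, 1]")
    y = initial_state()
    y[I_V] = em_mv
    y[I_ML] = ml
    y[I_HL] = hl
    c = currents(y, params)
    return c["i_nal"]


def inal_inactivation_ss(em_mv: float, params: ModelParameters) -> float:
    """Steady-state late-Na+ inactivation, including the configured V-shift."""
    return 1.0 / (1.0 + np.exp((em_mv + 91.0 - params.inal_vshift) / 6.1))


def resting_state(params: ModelParameters, duration_ms: float = 20000.0,
                  y0: np.ndarray | None = None) -> np.ndarray:
    """Relax the unstimulated model toward its resting fixed point."""
    if y0 is None:
        y0 = initial_state()
    y, _ = integrate(params, y0, duration_ms, stim_times=(), record_dt=None)
    return y
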
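"""Time integration of the myocyte ODE system.

Two routes share the single equation source in :mod:`skatrial.rhs`:

* ``hybrid`` (default): fixed-step exponential/forward-Euler hybrid compiled
  with numba. Gates, buffers and RyR occupancies — every state of the form
  ``dy/dt = a - b*y`` — advance by the exact exponential relaxation over the
  step (Rush-Larsen generalized to buffers); membrane potential and free ion
  concentrations advance by forward Euler. Free/bound ion bookkeeping is
  exact: the buffered amount removed from a compartment equals the amount
  the buffer update actually bound. Default step 0.01 ms resolves the
  stiffest process (cleft Ca2+ exchange/buffering, tau ~ 0.02 ms).
* ``lsoda``: scipy's adaptive stiff solver on the same derivative function,
  used as an independent numerical cross-check.

Output is resampled on a uniform grid (default 0.1 ms) for feature
extraction regardless of the internal step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import rhs as _rhs
from .parameters import ModelParameters
from .rhs import (N_CURRENTS, calc,
                  P_KS_RYR as _P_KS_RYR, P_V_SR as _P_V_SR,
                  P_V_JUNC as _P_V_JUNC, P_J_CA_JUNCSL as _P_J_CA_JUNCSL,
                  P_KON_SLL as _P_KON_SLL, P_BMAX_SLL_J as _P_BMAX_SLL_J,
                  P_KON_SLH as _P_KON_SLH, P_BMAX_SLH_J as _P_BMAX_SLH_J,
                  P_KON_CSQN as _P_KON_CSQN, P_BMAX_CSQN as _P_BMAX_CSQN)
from .states import (
    N_STATES, STATE_INDEX, I_V, I_CAI, I_CASR, I_CAJ, I_CASL, I_RYRO,
    I_NABJ, I_NABSL, I_NAJ, I_NASL, I_NAI, I_KI,
    I_TNCL, I_TNCHC, I_CAM, I_MYOC, I_SRB,
    I_SLLJ, I_SLLSL, I_SLHJ, I_SLHSL, I_CSQNB,
)

DT_DEFAULT = 0.01          # ms, internal fixed step
RECORD_DT_DEFAULT = 0.1    # ms, output cadence

_LINEAR_FIRST = 1   # states 1..32 obey dy/dt = a - b*y (gates, RyR, buffers)
_LINEAR_LAST = I_CSQNB


class SolverError(RuntimeError):
    """Integration failed; carries the last valid time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid t = {t_last:.3f} ms)")
        self.t_last = t_last


@njit(cache=True)
def _step(y, ynew, p, i_app, dt, dydt, bcoef, cur):
    calc(y, p, i_app, dydt, bcoef, cur)
    # exponential relaxation for linear states
    for i in range(_LINEAR_FIRST, _LINEAR_LAST + 1):
        b = bcoef[i]
        bdt = b * dt
        if bdt > 1e-9:
            ynew[i] = y[i] + dydt[i] * (1.0 - math.exp(-bdt)) / b
        else:
            ynew[i] = y[i] + dt * dydt[i]
    # buffer deltas actually applied this step
    d_nabj = ynew[I_NABJ] - y[I_NABJ]
    d_nabsl = ynew[I_NABSL] - y[I_NABSL]
    d_cyto = ((ynew[I_TNCL] - y[I_TNCL]) + (ynew[I_TNCHC] - y[I_TNCHC])
              + (ynew[I_CAM] - y[I_CAM]) + (ynew[I_MYOC] - y[I_MYOC])
              + (ynew[I_SRB] - y[I_SRB]))
    d_junc = (ynew[I_SLLJ] - y[I_SLLJ]) + (ynew[I_SLHJ] - y[I_SLHJ])
    d_sl = (ynew[I_SLLSL] - y[I_SLLSL]) + (ynew[I_SLHSL] - y[I_SLHSL])
    d_csqn = ynew[I_CSQNB] - y[I_CSQNB]

    # free ions: forward Euler on the buffer-free flux, then subtract the
    # amount the buffers actually bound (exact free+bound conservation)
    ynew[I_V] = y[I_V] + dt * dydt[I_V]
    ynew[I_NAJ] = y[I_NAJ] + dt * (dydt[I_NAJ] + dydt[I_NABJ]) - d_nabj
    ynew[I_NASL] = y[I_NASL] + dt * (dydt[I_NASL] + dydt[I_NABSL]) - d_nabsl
    ynew[I_NAI] = y[I_NAI] + dt * dydt[I_NAI]
    ynew[I_KI] = y[I_KI] + dt * dydt[I_KI]
    ynew[I_CAJ] = y[I_CAJ] + dt * (dydt[I_CAJ] + dydt[I_SLLJ] + dydt[I_SLHJ]) - d_junc
    ynew[I_CASL] = (y[I_CASL] + dt * (dydt[I_CASL] + dydt[I_SLLSL] + dydt[I_SLHSL]) - d_sl)
    ynew[I_CAI] = (y[I_CAI]
                   + dt * (dydt[I_CAI] + dydt[I_TNCL] + dydt[I_TNCHC]
                           + dydt[I_CAM] + dydt[I_MYOC] + dydt[I_SRB])
                   - d_cyto)
    ynew[I_CASR] = y[I_CASR] + dt * (dydt[I_CASR] + dydt[I_CSQNB]) - d_csqn
    # guard against forward-Euler undershoot of tiny concentrations
    if ynew[I_CAJ] < 1e-12:
        ynew[I_CAJ] = 1e-12
    if ynew[I_CASL] < 1e-12:
        ynew[I_CASL] = 1e-12
    if ynew[I_CAI] < 1e-12:
        ynew[I_CAI] = 1e-12


@njit(cache=True)
def _stiff_rate(y, p):
    """Fastest forward-Euler-limited rate (1/ms) at the current state.

    The stiff processes outside the exponential updates are the cleft Ca2+
    balance (RyR release flux, cleft-subsarcolemma exchange, sarcolemmal
    buffer on-rates) and the SR free-Ca2+/calsequestrin coupling; both peak
    with the RyR open fraction and with calsequestrin unloading.
    """
    lam_caj = (p[_P_KS_RYR] * y[I_RYRO] * p[_P_V_SR] / p[_P_V_JUNC]
               + p[_P_J_CA_JUNCSL] / p[_P_V_JUNC]
               + p[_P_KON_SLL] * (p[_P_BMAX_SLL_J] - y[I_SLLJ])
               + p[_P_KON_SLH] * (p[_P_BMAX_SLH_J] - y[I_SLHJ]))
    lam_casr = (p[_P_KON_CSQN] * (p[_P_BMAX_CSQN] - y[I_CSQNB])
                + p[_P_KS_RYR] * y[I_RYRO])
    return max(lam_caj, lam_casr)


@njit(cache=True)
def _integrate_fixed(y, p, t0, duration, stim_starts, stim_dur, stim_amp,
                     dt, rec_stride):
    """Advance ``y`` in place over ``duration``; record every ``rec_stride`` steps.

    Each nominal step is subdivided so the stiffest explicit rate stays
    within the forward-Euler stability region. Returns (status, t_fail,
    times, states). status 0 = ok, 1 = non-finite state encountered.
    ``stim_starts`` are absolute times (ms), sorted.
    """
    n_steps = int(round(duration / dt))
    if rec_stride > 0:
        n_rec = n_steps // rec_stride + 1
    else:
        n_rec = 1
    times = np.empty(n_rec)
    states = np.empty((n_rec, y.shape[0]))
    dydt = np.empty(y.shape[0])
    bcoef = np.empty(y.shape[0])
    cur = np.empty(N_CURRENTS)
    ynew = np.empty(y.shape[0])

    rec = 0
    if rec_stride > 0:
        times[0] = t0
        states[0] = y
        rec = 1

    sp = 0  # stimulus pointer
    n_stim = stim_starts.shape[0]
    for k in range(n_steps):
        t = t0 + k * dt
        while sp < n_stim and t >= stim_starts[sp] + stim_dur - 0.5 * dt:
            sp += 1
        i_app = 0.0
        if sp < n_stim and stim_starts[sp] - 0.5 * dt <= t:
            i_app = stim_amp
        # keep the stiffest explicit rate inside the Euler stability region
        lam = _stiff_rate(y, p)
        nsub = 1 + int(dt * lam / 1.4)
        if nsub > 400:
            nsub = 400
        if nsub == 1:
            _step(y, ynew, p, i_app, dt, dydt, bcoef, cur)
            y[:] = ynew
        else:
            dts = dt / nsub
            for _ in range(nsub):
                _step(y, ynew, p, i_app, dts, dydt, bcoef, cur)
                y[:] = ynew
        if not math.isfinite(y[I_V]):
            return 1, t, times[:rec], states[:rec]
        if rec_stride > 0 and (k + 1) % rec_stride == 0:
            times[rec] = t0 + (k + 1) * dt
            states[rec] = y
            rec += 1
    return 0, t0 + n_steps * dt, times[:rec], states[:rec]


@dataclass
class SimulationTrace:
    """Uniformly sampled trajectory of one or more beats."""

    t: np.ndarray                    # ms, strictly increasing
    states: np.ndarray               # (n, N_STATES)
    stim_times: np.ndarray           # ms, stimulus onsets within the trace
    params: ModelParameters
    currents: np.ndarray | None = None   # (n, N_CURRENTS) if computed

    def __post_init__(self):
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace time grid must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        if name in STATE_INDEX:
            return self.states[:, STATE_INDEX[name]]
        if self.currents is not None and name in _rhs.CURRENT_INDEX:
            return self.currents[:, _rhs.CURRENT_INDEX[name]]
        raise KeyError(name)

    @property
    def v(self) -> np.ndarray:
        return self.states[:, I_V]

    @property
    def cai(self) -> np.ndarray:
        return self.states[:, I_CAI]

    @property
    def ca_sr(self) -> np.ndarray:
        return self.states[:, I_CASR]

    def with_currents(self) -> "SimulationTrace":
        """Attach per-point currents (stimulus reconstructed from onsets)."""
        amp = self.params.stim_amp
        dur = self.params.stim_dur
        iapp = np.zeros_like(self.t)
        for s in self.stim_times:
            iapp[(self.t >= s) & (self.t < s + dur)] = amp
        p = self.params.to_vector()
        self.currents = _rhs.currents_over(self.states, p, iapp)
        return self

    def to_dataframe(self):
        import pandas as pd

        data = {"time_ms": self.t, "Em_mV": self.v,
                "Cai_mM": self.cai, "CaSR_mM": self.ca_sr}
        if self.currents is not None:
            for name, idx in _rhs.CURRENT_INDEX.items():
                data[f"{name}_ApF"] = self.currents[:, idx]
        return pd.DataFrame(data)


def integrate(params: ModelParameters,
              initial: np.ndarray,
              duration: float,
              stim_times=(),
              method: str = "hybrid",
              dt: float = DT_DEFAULT,
              record_dt: float | None = RECORD_DT_DEFAULT,
              t0: float = 0.0) -> tuple[np.ndarray, SimulationTrace | None]:
    """Integrate the model; returns (final_state, trace or None).

    ``record_dt=None`` disables recording (final state only). Stimulus onsets
    outside [t0, t0+duration] raise. Identical inputs yield bit-identical
    output.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    stim_times = np.asarray(sorted(stim_times), dtype=np.float64)
    if stim_times.size and (stim_times[0] < t0 - 1e-9
                            or stim_times[-1] > t0 + duration + 1e-9):
        raise ValueError("stimulus times must lie within the integration window")
    y = np.array(initial, dtype=np.float64, copy=True)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},)")
    p = params.to_vector()

    if duration == 0:
        trace = None
        if record_dt is not None:
            trace = SimulationTrace(np.array([t0]), y[None, :].copy(),
                                    stim_times, params)
        return y, trace

    if method == "hybrid":
        rec_stride = 0 if record_dt is None else max(1, int(round(record_dt / dt)))
        status, t_last, times, states = _integrate_fixed(
            y, p, t0, duration, stim_times, params.stim_dur, params.stim_amp,
            dt, rec_stride)
        if status != 0:
            raise SolverError("non-finite membrane potential", t_last)
        trace = None
        if record_dt is not None:
            trace = SimulationTrace(times, states, stim_times, params)
        return y, trace

    if method == "lsoda":
        return _integrate_lsoda(params, y, p, duration, stim_times,
                                record_dt, t0)

    raise ValueError(f"unknown method {method!r}")


def _default_atol() -> np.ndarray:
    atol = np.full(N_STATES, 1e-8)
    atol[I_V] = 1e-5
    atol[I_CAJ] = 1e-9
    atol[I_CASL] = 1e-9
    atol[I_CAI] = 1e-10
    atol[I_CASR] = 1e-7
    return atol


def _integrate_lsoda(params, y, p, duration, stim_times, record_dt, t0):
    """Adaptive stiff route: piecewise integration between stimulus edges."""
    from scipy.integrate import solve_ivp

    edges = [t0]
    for s in stim_times:
        edges += [s, min(s + params.stim_dur, t0 + duration)]
    edges.append(t0 + duration)
    edges = sorted(set(e for e in edges if t0 <= e <= t0 + duration))

    ts_all, ys_all = [np.array([t0])], [y[None, :].copy()]
    atol = _default_atol()
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 0:
            continue
        mid = 0.5 * (a + b)
        on = any(s <= mid < s + params.stim_dur for s in stim_times)
        i_app = params.stim_amp if on else 0.0
        t_eval = None
        if record_dt is not None:
            t_eval = np.arange(a, b + 1e-9, record_dt)
            t_eval = t_eval[(t_eval > a) & (t_eval <= b)]
        sol = solve_ivp(_rhs.rhs_only, (a, b), y, method="LSODA",
                        args=(p, i_app), rtol=1e-6, atol=atol,
                        max_step=max(params.stim_dur, 1.0),
                        t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise SolverError(f"LSODA failed: {sol.message}", sol.t[-1] if sol.t.size else a)
        y = sol.y[:, -1].copy() if sol.t.size else y
        # ensure the endpoint state is exact even when t_eval skips it
        if sol.t.size == 0 or sol.t[-1] < b - 1e-9:
            sol2 = solve_ivp(_rhs.rhs_only, (sol.t[-1] if sol.t.size else a, b),
                             y, method="LSODA", args=(p, i_app),
                             rtol=1e-6, atol=atol)
            if not sol2.success:
                raise SolverError(f"LSODA failed: {sol2.message}", b)
            y = sol2.y[:, -1].copy()
        if record_dt is not None and sol.t.size:
            ts_all.append(sol.t)
            ys_all.append(sol.y.T)
    trace = None
    if record_dt is not None:
        t_cat = np.concatenate(ts_all)
        y_cat = np.vstack(ys_all)
        keep = np.concatenate([[True], np.diff(t_cat) > 1e-12])
        trace = SimulationTrace(t_cat[keep], y_cat[keep],
                                np.asarray(stim_times), params)
    return y, trace
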
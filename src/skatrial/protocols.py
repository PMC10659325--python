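"""Electrophysiological protocols: steady pacing, frequency sweep, DTE,
S1-S2 effective refractory period, and alternans / DAD pacing thresholds.

Threshold semantics follow the descending-scan convention: the reported
threshold is the *largest* basic cycle length (BCL) at which the phenomenon
is present. Searches bracket by bisection and refine with a descending
fine scan; equivalence with a pure descending scan is covered by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (BeatFeatures, alternans_magnitudes, extract_features,
                       UPSTROKE_THRESHOLD)
from .integrate import integrate
from .model import resting_state
from .parameters import ModelParameters, apply_iso
from .states import (I_KI, I_NABJ, I_NABSL, I_NAI, I_NAJ, I_NASL, N_STATES,
                     initial_state)

#: beat-to-beat APD(-60 mV) difference defining voltage-driven alternans (ms)
ALTERNANS_DAPD_MS = 5.0
#: beat-to-beat CaT-amplitude difference defining Ca2+-driven alternans (nM)
ALTERNANS_DCAT_NM = 10.0
#: diastolic voltage oscillation defining a DAD (mV)
DAD_DELTA_EM_MV = 10.0
#: default BCL search windows (ms)
ALTERNANS_BCL_RANGE = (150.0, 450.0)
DAD_BCL_RANGE = (200.0, 800.0)
#: drive and observation windows of the DAD protocol (ms)
DAD_DRIVE_MS = 10_000.0
DAD_PAUSE_MS = 5_000.0


@dataclass
class ThresholdResult:
    """Outcome of a BCL or stimulus-amplitude search."""

    value: float            # ms for BCL searches, A/F for DTE; NaN if not detected
    resolution: float
    detected: bool
    units: str
    trials: list = field(default_factory=list)   # (tested value, bool outcome)

    def to_dict(self) -> dict:
        return {"value": None if not self.detected else self.value,
                "resolution": self.resolution, "detected": self.detected,
                "units": self.units, "trials": [(float(v), bool(o)) for v, o in self.trials]}


@dataclass
class PacingResult:
    """Steady-state pacing outcome: end-diastolic state + final beats."""

    state: np.ndarray
    trace: "object"                 # SimulationTrace of the final beats
    beats: list
    converged: bool
    n_beats: int
    repolarization_ok: bool

    @property
    def last(self) -> BeatFeatures:
        return self.beats[-1]


_REL_FLOOR = 1e-6   # denominator floor for the steady-state criterion

# The intracellular Na+ pool (and clamped K+) equilibrates over hundreds of
# seconds and is quasi-static on the beat-pair timescale; it is excluded from
# the convergence test so trials terminate on the Ca2+/electrical dynamics.
_SS_MASK = np.ones(N_STATES, dtype=bool)
_SS_MASK[[I_NAJ, I_NASL, I_NAI, I_NABJ, I_NABSL, I_KI]] = False


def pace_to_steady_state(params: ModelParameters, bcl: float,
                         y0: np.ndarray | None = None,
                         min_beats: int = 100, max_beats: int = 500,
                         tol: float = 1e-3, record_beats: int = 2,
                         with_currents: bool = False) -> PacingResult:
    """Pace at ``bcl`` until the beat-pair steady-state criterion is met.

    The criterion compares end-diastolic states one beat-*pair* apart (so
    stable alternans is itself a steady state): converged when every state
    variable changes by less than ``tol`` relative. Returns the end-diastolic
    state plus the final ``record_beats`` beats for feature extraction.
    """
    if bcl <= params.stim_dur:
        raise ValueError("BCL must exceed the stimulus duration")
    y = initial_state() if y0 is None else np.array(y0, dtype=float)
    # burn-in to the minimum beat count (even count keeps pair phase)
    n0 = min_beats if min_beats % 2 == 0 else min_beats + 1
    y, _ = integrate(params, y, n0 * bcl,
                     stim_times=np.arange(0, n0 * bcl, bcl), record_dt=None)
    n = n0
    converged = False
    prev = y.copy()
    while n < max_beats:
        y, _ = integrate(params, y, 2 * bcl, stim_times=[0.0, bcl],
                         record_dt=None)
        n += 2
        rel = np.abs(y - prev) / np.maximum(np.abs(prev), _REL_FLOOR)
        prev = y.copy()
        if rel[_SS_MASK].max() < tol:
            converged = True
            break
    stims = np.arange(0, record_beats * bcl, bcl)
    y_end, trace = integrate(params, y, record_beats * bcl, stim_times=stims)
    if with_currents:
        trace.with_currents()
    beats = extract_features(trace)
    # repolarization failure: E_m never below -40 mV between stimuli
    repol_ok = True
    for k, s in enumerate(stims):
        hi = stims[k + 1] if k + 1 < len(stims) else trace.t[-1]
        win = (trace.t >= s) & (trace.t <= hi)
        if trace.v[win].min() > -40.0:
            repol_ok = False
    return PacingResult(state=y_end, trace=trace, beats=beats,
                        converged=converged, n_beats=n + record_beats,
                        repolarization_ok=repol_ok)


def frequency_sweep(params: ModelParameters, rates_hz=None,
                    y0: np.ndarray | None = None, **pace_kw) -> pd.DataFrame:
    """Steady-state AP/CaT features per pacing rate.

    Default rates: 0.5 to 4 Hz in 0.5-Hz increments. When the final two
    beats alternate, both are reported (two rows per rate).
    """
    if rates_hz is None:
        rates_hz = np.arange(0.5, 4.01, 0.5)
    rows = []
    for rate in rates_hz:
        bcl = 1000.0 / rate
        res = pace_to_steady_state(params, bcl, y0=y0, **pace_kw)
        d_apd, d_cat = alternans_magnitudes(res.beats)
        alternating = ((math.isfinite(d_apd) and d_apd >= ALTERNANS_DAPD_MS)
                       or d_cat >= ALTERNANS_DCAT_NM or math.isinf(d_apd))
        report = res.beats[-2:] if alternating else res.beats[-1:]
        for b in report:
            rows.append({"rate_hz": float(rate), "bcl_ms": bcl,
                         "apd90_ms": b.apd90, "apd_minus60_ms": b.apd_minus60,
                         "rmp_mV": b.rmp, "cat_amp_nM": b.cat_amp,
                         "cat_diastolic_nM": b.cat_diastolic,
                         "dvdt_max_Vps": b.dvdt_max,
                         "peak_isk_ApF": b.peak_isk,
                         "alternans": bool(alternating),
                         "converged": res.converged,
                         "repolarization_ok": res.repolarization_ok})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# excitability: diastolic threshold and ERP
# ---------------------------------------------------------------------------

def _test_stimulus_elicits(params: ModelParameters, y_dia: np.ndarray,
                           amplitude: float, ref_amplitude_mv: float | None
                           ) -> bool:
    """Apply one test stimulus from a diastolic state; AP success criterion:
    upstroke >= 5 V/s and amplitude >= 50% of the reference AP amplitude."""
    test = params.replace(stim_amp=amplitude)
    _, tr = integrate(test, y_dia, 300.0, stim_times=[0.0])
    beats = extract_features(tr)
    if not beats:
        return False
    b = beats[0]
    if b.dvdt_max < UPSTROKE_THRESHOLD:
        return False
    if ref_amplitude_mv is not None and b.ap_amplitude < 0.5 * ref_amplitude_mv:
        return False
    return True


def find_dte(params: ModelParameters, bcl: float = 1000.0,
             y0: np.ndarray | None = None, resolution: float = 0.05,
             amp_cap: float = 40.0, pace_kw: dict | None = None
             ) -> ThresholdResult:
    """Diastolic threshold of excitation: minimal amplitude of a 5-ms
    stimulus that elicits an AP at steady pacing (bisection)."""
    res = pace_to_steady_state(params, bcl, y0=y0, **(pace_kw or {}))
    ref_amp = res.last.ap_amplitude
    trials = []
    lo, hi = 0.0, amp_cap
    if not _test_stimulus_elicits(params, res.state, hi, ref_amp):
        return ThresholdResult(math.nan, resolution, False, "A/F",
                               [(hi, False)])
    trials.append((hi, True))
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        ok = _test_stimulus_elicits(params, res.state, mid, ref_amp)
        trials.append((mid, ok))
        if ok:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(hi, resolution, True, "A/F", trials)


def with_standard_stimulus(params: ModelParameters, bcl: float = 1000.0,
                           y0: np.ndarray | None = None,
                           pace_kw: dict | None = None) -> ModelParameters:
    """Return parameters whose stimulus is the protocol standard:
    5 ms duration, twice the diastolic threshold measured at 1-Hz pacing."""
    dte = find_dte(params.replace(stim_dur=5.0), bcl, y0=y0, pace_kw=pace_kw)
    if not dte.detected:
        raise RuntimeError("no excitation up to the amplitude cap")
    return params.replace(stim_dur=5.0, stim_amp=2.0 * dte.value)


def measure_erp(params: ModelParameters, bcl: float = 1000.0,
                y0: np.ndarray | None = None, coarse: float = 25.0,
                fine: float = 5.0, s2_start: float | None = None,
                pace_kw: dict | None = None) -> ThresholdResult:
    """S1-S2 effective refractory period.

    S1 = the configured stimulus (use :func:`with_standard_stimulus` for the
    2xDTE convention); S2 identical to S1, delivered at decreasing coupling
    intervals (5-ms decrements). ERP = the longest S1-S2 interval that fails
    to elicit an AP (upstroke >= 5 V/s and amplitude >= 50% of the S1 beat).
    """
    res = pace_to_steady_state(params, bcl, y0=y0, **(pace_kw or {}))
    s1_amp_mv = res.last.ap_amplitude
    y_dia = res.state

    def s2_success(interval: float) -> bool:
        _, tr = integrate(params, y_dia, interval + 400.0,
                          stim_times=[0.0, interval])
        beats = extract_features(tr)
        if len(beats) < 2:
            return False
        b = beats[1]
        return (b.dvdt_max >= UPSTROKE_THRESHOLD
                and b.ap_amplitude >= 0.5 * s1_amp_mv)

    trials = []
    start = min(bcl - fine, s2_start if s2_start is not None else 500.0)
    # make sure the scan starts above the ERP
    while start < bcl - fine and not s2_success(start):
        trials.append((start, False))
        start = min(bcl - fine, start + 4 * coarse)
    # coarse descent to the first failing interval
    interval = start
    first_fail = None
    while interval > params.stim_dur:
        ok = s2_success(interval)
        trials.append((interval, ok))
        if not ok:
            first_fail = interval
            break
        interval -= coarse
    if first_fail is None:
        return ThresholdResult(math.nan, fine, False, "ms", trials)
    # the ERP lies in [first_fail, first_fail + coarse): ascend in fine steps
    erp = first_fail
    probe = first_fail + fine
    while probe < first_fail + coarse and probe <= start:
        ok = s2_success(probe)
        trials.append((probe, ok))
        if ok:
            break
        erp = probe
        probe += fine
    return ThresholdResult(erp, fine, True, "ms", trials)


# ---------------------------------------------------------------------------
# BCL threshold searches (alternans, DADs)
# ---------------------------------------------------------------------------

def _descending_bcl_search(predicate, lo: float, hi: float,
                           coarse: float = 10.0, fine: float = 1.0,
                           bracket: float = 4.0) -> ThresholdResult:
    """Largest BCL in [lo, hi] where ``predicate`` holds, at ``fine`` resolution.

    Bisection of the upper positive/negative boundary (the phenomenon is
    assumed present for all BCL at or below the threshold and absent above
    it) narrows to a ``bracket``-wide interval; a descending fine scan then
    pins the threshold, reproducing the descending-scan convention. If
    bisection finds no positive trial, a full descending coarse scan is run
    before declaring the phenomenon absent (the short-BCL end of the range
    can be non-monotone, e.g. 2:1 capture).
    """
    trials = []

    def test(bcl):
        out = bool(predicate(bcl))
        trials.append((bcl, out))
        return out

    if test(hi):
        return ThresholdResult(hi, fine, True, "ms", trials)
    lo_pos = None
    hi_neg = hi
    while hi_neg - (lo_pos if lo_pos is not None else lo) > bracket:
        mid = float(round(0.5 * (hi_neg + (lo_pos if lo_pos is not None else lo))))
        if mid <= lo or mid >= hi_neg:
            break
        if test(mid):
            lo_pos = mid
        else:
            hi_neg = mid
    if lo_pos is None:
        if test(lo):
            lo_pos = lo
        else:
            b = hi - coarse
            while b > lo and not test(b):
                b -= coarse
            if b <= lo:
                return ThresholdResult(math.nan, fine, False, "ms", trials)
            lo_pos, hi_neg = b, b + coarse
    # descending fine scan in (lo_pos, hi_neg)
    b = hi_neg - fine
    while b > lo_pos:
        if test(b):
            return ThresholdResult(b, fine, True, "ms", trials)
        b -= fine
    return ThresholdResult(lo_pos, fine, True, "ms", trials)


def alternans_threshold(params: ModelParameters, mode: str = "voltage",
                        bcl_range: tuple = ALTERNANS_BCL_RANGE,
                        coarse: float = 10.0, fine: float = 1.0,
                        y0: np.ndarray | None = None,
                        pace_kw: dict | None = None) -> ThresholdResult:
    """Maximal BCL producing alternans (1-ms resolution by default).

    ``mode='voltage'``: beat-to-beat APD(-60 mV) difference >= 5 ms;
    ``mode='calcium'``: beat-to-beat CaT amplitude difference >= 10 nM.
    Each BCL trial paces to steady state from the same initial state.
    """
    if mode not in ("voltage", "calcium"):
        raise ValueError("mode must be 'voltage' or 'calcium'")
    kw = pace_kw or {}

    def predicate(bcl: float) -> bool:
        res = pace_to_steady_state(params, bcl, y0=y0, **kw)
        d_apd, d_cat = alternans_magnitudes(res.beats)
        if mode == "voltage":
            return (math.isinf(d_apd)
                    or (math.isfinite(d_apd) and d_apd >= ALTERNANS_DAPD_MS))
        return d_cat >= ALTERNANS_DCAT_NM

    return _descending_bcl_search(predicate, bcl_range[0], bcl_range[1],
                                  coarse, fine)


def dad_trial(params_iso: ModelParameters, bcl: float, y_start: np.ndarray,
              drive_ms: float = DAD_DRIVE_MS, pause_ms: float = DAD_PAUSE_MS
              ) -> tuple[bool, float]:
    """One DAD protocol trial: drive at ``bcl`` for ``drive_ms`` under the
    supplied (ISO) parameters, pause, and score the largest diastolic
    voltage oscillation. Returns (positive, oscillation amplitude in mV)."""
    stims = np.arange(0.0, drive_ms, bcl)
    y, _ = integrate(params_iso, y_start, drive_ms, stim_times=stims,
                     record_dt=None)
    _, tr = integrate(params_iso, y, pause_ms, stim_times=())
    v = tr.v
    # skip the terminal repolarization of the last driven AP
    below = np.flatnonzero(v < -60.0)
    if below.size == 0:
        return False, 0.0   # repolarization failure; no diastolic baseline
    seg = v[below[0]:]
    running_min = np.minimum.accumulate(seg)
    amp = float(np.max(seg - running_min))
    return amp >= DAD_DELTA_EM_MV, amp


def dad_threshold(params: ModelParameters, iso_um: float = 1.0,
                  bcl_range: tuple = DAD_BCL_RANGE, coarse: float = 10.0,
                  fine: float = 1.0, y0: np.ndarray | None = None,
                  pace_kw: dict | None = None) -> ThresholdResult:
    """Maximal BCL whose post-drive pause contains a DAD (>= 10 mV).

    The 10-s drive starts from the drug-free 1-Hz steady state; isoproterenol
    is applied for the drive and pause. Trials are mutually independent.
    """
    if y0 is None:
        base = pace_to_steady_state(params, 1000.0, **(pace_kw or {}))
        y0 = base.state
    p_iso = apply_iso(params, iso_um)

    def predicate(bcl: float) -> bool:
        positive, _ = dad_trial(p_iso, bcl, y0)
        return positive

    return _descending_bcl_search(predicate, bcl_range[0], bcl_range[1],
                                  coarse, fine)


def classify_dad_at_bcl(params: ModelParameters, bcl: float = 500.0,
                        iso_um: float = 1.0, y0: np.ndarray | None = None,
                        pace_kw: dict | None = None) -> tuple[bool, float]:
    """Single-BCL DAD classification (the 2-Hz pacing criterion)."""
    if y0 is None:
        base = pace_to_steady_state(params, 1000.0, **(pace_kw or {}))
        y0 = base.state
    p_iso = apply_iso(params, iso_um)
    return dad_trial(p_iso, bcl, y0)
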
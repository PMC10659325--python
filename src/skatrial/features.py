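"""Per-beat action-potential and Ca2+-transient feature extraction.

Conventions:

* AP onset = time of maximum upstroke velocity within the beat window;
* APD90 = onset to 90% repolarization, where the repolarization level is
  ``peak - 0.9 * (peak - preceding diastolic E_m)``;
* APD(-60 mV) = onset to the downward crossing of -60 mV (the level used to
  score voltage-driven alternans);
* CaT amplitude = per-beat max - min of bulk cytosolic free Ca2+;
* RMP = minimum E_m over the beat's diastolic interval.

Crossing times are linearly interpolated between output samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .integrate import SimulationTrace

#: an AP is "elicited" if the upstroke reaches at least this velocity (V/s)
UPSTROKE_THRESHOLD = 5.0
#: voltage level for the alternans-scoring APD (mV)
APD_LEVEL_MV = -60.0


@dataclass
class BeatFeatures:
    """Features of a single paced beat; NaN marks undefined quantities."""

    t_onset: float          # ms, absolute time of max upstroke velocity
    apd90: float            # ms
    apd_minus60: float      # ms, APD at the -60 mV downward crossing
    rmp: float              # mV
    cat_amp: float          # nM
    cat_diastolic: float    # nM
    dvdt_max: float         # V/s
    ap_amplitude: float     # mV, peak minus preceding diastolic E_m
    peak_isk: float = float("nan")   # A/F, if currents present

    @property
    def ap_detected(self) -> bool:
        return self.dvdt_max >= UPSTROKE_THRESHOLD and self.ap_amplitude > 0


def _cross_down(t: np.ndarray, v: np.ndarray, level: float, start: int) -> float:
    """Time of first downward crossing of ``level`` at/after index ``start``."""
    seg = v[start:]
    idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if idx.size == 0:
        return math.nan
    i = start + idx[0]
    frac = (v[i] - level) / (v[i] - v[i + 1])
    return t[i] + frac * (t[i + 1] - t[i])


def extract_features(trace: SimulationTrace) -> list[BeatFeatures]:
    """Per-beat features for every stimulated beat of a trace."""
    t = trace.t
    v = trace.v
    cai = trace.cai
    stims = np.asarray(trace.stim_times, dtype=float)
    if stims.size == 0:
        raise ValueError("trace carries no stimulated beats")
    isk = trace["i_sk"] if trace.currents is not None else None

    # beat windows: [stim_k, stim_{k+1}) and last window to trace end
    edges = list(stims) + [t[-1] + 1e-9]
    out: list[BeatFeatures] = []
    dvdt = np.gradient(v, t)
    for k in range(len(stims)):
        sel = (t >= edges[k]) & (t < edges[k + 1])
        if sel.sum() < 5:
            continue
        tb, vb, cab = t[sel], v[sel], cai[sel]
        dvb = dvdt[sel]
        i_on = int(np.argmax(dvb))
        dvdt_max = float(dvb[i_on])
        v_dias = float(vb[0])
        peak = float(vb.max())
        amp = peak - v_dias
        t_onset = float(tb[i_on])
        i_pk = int(vb.argmax())
        lvl90 = peak - 0.9 * (peak - v_dias)
        apd90 = _cross_down(tb, vb, lvl90, i_pk) - t_onset
        apd60 = _cross_down(tb, vb, APD_LEVEL_MV, i_pk) - t_onset
        # diastolic interval: after repolarization (fall below -60 mV) to beat
        # end; fall back to the whole beat when the AP never repolarizes
        t_rep = _cross_down(tb, vb, APD_LEVEL_MV, i_pk)
        if math.isfinite(t_rep):
            dias = vb[tb >= t_rep]
            rmp = float(dias.min()) if dias.size else float(vb.min())
        else:
            rmp = float(vb.min())
        cat_dia = float(cab.min()) * 1e6   # mM -> nM
        cat_amp = float(cab.max() - cab.min()) * 1e6
        pk_isk = float(isk[sel].max()) if isk is not None else math.nan
        out.append(BeatFeatures(
            t_onset=t_onset, apd90=float(apd90), apd_minus60=float(apd60),
            rmp=rmp, cat_amp=cat_amp, cat_diastolic=cat_dia,
            dvdt_max=dvdt_max, ap_amplitude=amp, peak_isk=pk_isk))
    return out


def alternans_magnitudes(beats: list[BeatFeatures]) -> tuple[float, float]:
    """(|dAPD(-60)| in ms, |dCaT amplitude| in nM) of the last beat pair.

    An undefined APD(-60) on exactly one of the two beats (e.g. 2:1 capture)
    counts as maximal APD alternation (+inf).
    """
    if len(beats) < 2:
        raise ValueError("need at least two beats to score alternans")
    b1, b2 = beats[-2], beats[-1]
    if math.isnan(b1.apd_minus60) and math.isnan(b2.apd_minus60):
        d_apd = math.nan
    elif math.isnan(b1.apd_minus60) or math.isnan(b2.apd_minus60):
        d_apd = math.inf
    else:
        d_apd = abs(b1.apd_minus60 - b2.apd_minus60)
    d_cat = abs(b1.cat_amp - b2.cat_amp)
    return d_apd, d_cat
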
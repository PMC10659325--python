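"""Protocol tests: steady pacing, DTE, ERP and search-vs-scan equivalence."""

import math

import numpy as np
import pytest

from skatrial import integrate, nsr_parameters
from skatrial.features import extract_features
from skatrial.protocols import (_descending_bcl_search, _test_stimulus_elicits,
                                dad_trial, find_dte, frequency_sweep,
                                measure_erp, pace_to_steady_state)


@pytest.fixture(scope="module")
def dte_nsr(steady):
    p, res = steady("nsr")
    return find_dte(p, y0=res.state, pace_kw=dict(min_beats=10, max_beats=40))


def test_steady_state_postcondition(steady):
    """Two consecutive beats from the returned state change APD90 by less
    than the steady-state tolerance."""
    p, res = steady("nsr")
    _, tr = integrate(p, res.state, 2000.0, stim_times=[0.0, 1000.0])
    beats = extract_features(tr)
    assert abs(beats[1].apd90 - beats[0].apd90) < 1.0


def test_repolarization_failure_is_flagged_not_raised():
    """A cell held depolarized between stimuli is flagged, not raised."""
    p = nsr_parameters(stim_dur=240.0, stim_amp=6.0)
    res = pace_to_steady_state(p, 250.0, min_beats=6, max_beats=10)
    assert not res.repolarization_ok


def test_dte_bisection_brackets_excitation(steady, dte_nsr):
    """Amplitude 2xDTE elicits an AP; zero amplitude does not; the bisection
    agrees with a descending amplitude scan at the same resolution."""
    p, res = steady("nsr")
    assert dte_nsr.detected
    ref_amp = res.beats[-1].ap_amplitude
    assert _test_stimulus_elicits(p, res.state, 2.0 * dte_nsr.value, ref_amp)
    assert not _test_stimulus_elicits(p, res.state, 0.0, ref_amp)
    # brute-force oracle: descending scan at the bisection resolution
    step = dte_nsr.resolution
    amp = 2.0 * dte_nsr.value
    last_ok = amp
    while amp > 0:
        if not _test_stimulus_elicits(p, res.state, amp, ref_amp):
            break
        last_ok = amp
        amp -= step
    assert last_ok == pytest.approx(dte_nsr.value, abs=step + 1e-9)


def test_erp_postconditions_and_gsk_ordering(steady, dte_nsr):
    """S2 fails at the ERP and succeeds at ERP+5; higher G_SK shortens the
    ERP in the same direction as APD90."""
    erps = {}
    apds = {}
    for gsk in (0.5, 2.0):
        p, res = steady("nsr", gsk)
        p2 = p.replace(stim_amp=2.0 * dte_nsr.value)
        r = measure_erp(p2, 1000.0, y0=res.state,
                        pace_kw=dict(min_beats=10, max_beats=40))
        assert r.detected
        outcomes = dict(r.trials)
        assert outcomes[r.value] is False
        assert outcomes.get(r.value + r.resolution, True) is True
        erps[gsk] = r.value
        apds[gsk] = res.beats[-1].apd90
    assert erps[2.0] < erps[0.5]
    assert apds[2.0] < apds[0.5]           # ERP moves with APD90


def test_search_equals_descending_scan_on_synthetic_predicates():
    """The bisection+fine search reproduces the descending 1-ms scan for
    thresholds across the range, including a non-monotone short-BCL region."""
    for threshold in (203.0, 347.0, 449.0):
        for floor_breaks in (False, True):
            def pred(bcl, thr=threshold, fb=floor_breaks):
                if fb and bcl < 170.0:
                    return False        # e.g. 2:1 capture scored negative
                return bcl <= thr

            res = _descending_bcl_search(pred, 150.0, 450.0)
            assert res.detected
            assert res.value == pytest.approx(threshold, abs=1e-9)
    # phenomenon absent everywhere
    res = _descending_bcl_search(lambda b: False, 150.0, 450.0)
    assert not res.detected and math.isnan(res.value)


def test_dad_trial_determinism(steady):
    """Re-running a positive DAD trial reproduces the oscillation exactly."""
    from skatrial import apply_iso

    p, res = steady("caf")
    piso = apply_iso(p, 1.0)
    out1 = dad_trial(piso, 400.0, res.state)
    out2 = dad_trial(piso, 400.0, res.state)
    assert out1 == out2
    assert out1[0]          # cAF at fast drive develops DADs


def test_frequency_sweep_reports_both_alternating_beats(steady):
    """At a rate past the alternans onset the sweep reports two rows."""
    p, _ = steady("caf")
    table = frequency_sweep(p, rates_hz=[1.0, 3.0],
                            min_beats=30, max_beats=80)
    assert (table.rate_hz == 1.0).sum() == 1
    assert (table.rate_hz == 3.0).sum() == 2
    assert bool(table.loc[table.rate_hz == 3.0, "alternans"].iloc[0])


def test_gsk_scaling_monotonicity_at_1hz(steady):
    """APD90, CaT amplitude strictly decreasing and RMP non-increasing over
    50% -> 100% -> 200% G_SK in both conditions."""
    for cond in ("nsr", "caf"):
        feats = [steady(cond, g)[1].beats[-1] for g in (0.5, 1.0, 2.0)]
        apd = [b.apd90 for b in feats]
        cat = [b.cat_amp for b in feats]
        rmp = [b.rmp for b in feats]
        assert apd[0] > apd[1] > apd[2], cond
        assert cat[0] > cat[1] > cat[2], cond
        assert rmp[0] >= rmp[1] >= rmp[2], cond
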
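"""Core model tests: derivatives, single currents, condition transforms,
integration, and the conservation/boundedness properties."""

import math

import numpy as np
import pytest

from skatrial import (apply_caf, apply_iso, caf_parameters, currents,
                      derivatives, i_nal, i_sk, integrate, initial_state,
                      nsr_parameters, resting_state)
from skatrial.calibration import (GNAL_REFERENCE, UPSTROKE_BAND,
                                  ap_clamp_inal, calibrate_gnal,
                                  check_upstroke, reference_ap_trace)
from skatrial.model import inal_inactivation_ss
from skatrial.parameters import CAF_SCALARS, PARAM_NAMES
from skatrial.states import (FRACTION_INDICES, I_CAI, I_CAJ, I_CASL, I_CASR,
                             I_CSQNB, I_M, I_RYRI, I_RYRO, I_RYRR, I_SLHJ,
                             I_SLHSL, I_SLLJ, I_SLLSL, I_SRB, I_TNCHC, I_TNCL,
                             I_CAM, I_MYOC, I_V, N_STATES, STATE_NAMES)


@pytest.fixture(scope="module")
def rest_nsr():
    return resting_state(nsr_parameters(), 20000.0)


@pytest.fixture(scope="module")
def rest_caf():
    return resting_state(caf_parameters(), 20000.0)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def test_quiescent_state_is_a_fixed_point(rest_nsr):
    """After a long unstimulated relaxation, all derivatives are tiny."""
    dydt = derivatives(0.0, rest_nsr, nsr_parameters())
    assert abs(dydt[I_V]) < 5e-3          # mV/ms
    # gates/fractions drift below 1e-5 per ms, concentrations below 1e-7 mM/ms
    for i in FRACTION_INDICES:
        assert abs(dydt[i]) < 1e-5, STATE_NAMES[i]
    assert abs(dydt[I_CAI]) < 1e-7
    assert abs(dydt[I_CASR]) < 1e-5


def test_gate_relaxes_toward_steady_state(rest_nsr):
    """A gate forced to 0 with a positive steady state gets a positive rate."""
    y = rest_nsr.copy()
    y[I_V] = -20.0          # m-gate steady state is near 1 here
    y[I_M] = 0.0
    dydt = derivatives(0.0, y, nsr_parameters())
    assert dydt[I_M] > 0


def test_nonfinite_state_names_offending_variable(rest_nsr):
    y = rest_nsr.copy()
    y[I_CASR] = np.nan
    with pytest.raises(ValueError, match="ca_sr"):
        derivatives(0.0, y, nsr_parameters())


def test_ca_compartment_fluxes_conserve_mass(rest_nsr):
    """Volume-weighted Ca2+ derivatives sum to zero when sarcolemmal fluxes
    are disabled (oracle: direct summation of inter-compartment fluxes)."""
    p = nsr_parameters(clamp_sarc_ca=1.0)
    y = rest_nsr.copy()
    y[I_CASR] = 0.7          # provoke nonzero release/uptake/leak fluxes
    y[I_CAJ] = 5e-4
    dydt = derivatives(0.0, y, p)
    cyto_buf = [I_TNCL, I_TNCHC, I_CAM, I_MYOC, I_SRB]
    total = (p.v_myo * (dydt[I_CAI] + sum(dydt[i] for i in cyto_buf))
             + p.v_sl * (dydt[I_CASL] + dydt[I_SLLSL] + dydt[I_SLHSL])
             + p.v_junc * (dydt[I_CAJ] + dydt[I_SLLJ] + dydt[I_SLHJ])
             + p.v_sr * (dydt[I_CASR] + dydt[I_CSQNB]))
    gross = (p.v_sr * abs(dydt[I_CASR]) + p.v_myo * abs(dydt[I_CAI]) + 1e-30)
    assert abs(total) / gross < 1e-10


# ---------------------------------------------------------------------------
# single currents
# ---------------------------------------------------------------------------

def test_isk_zero_at_reversal_potential():
    p = nsr_parameters()
    ek = (8314.0 * p.temp / 96485.0) * math.log(p.ko / 120.0)
    assert i_sk(ek, 500.0, p) == pytest.approx(0.0, abs=1e-12)


def test_isk_half_activation_at_kd():
    """350 nM local Ca2+ activates the channel to exactly half saturation."""
    p = nsr_parameters()
    em = -40.0
    half = i_sk(em, 350.0, p)
    sat = i_sk(em, 3.5e8, p)
    assert half / sat == pytest.approx(0.5, rel=1e-6)


def test_isk_saturation_limits_and_monotonicity():
    p = nsr_parameters()
    em = -40.0
    vals = [i_sk(em, ca, p) for ca in (0.0, 50.0, 350.0, 2000.0, 1e7)]
    assert vals[0] == pytest.approx(0.0, abs=1e-12)
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert vals[-1] / i_sk(em, 1e12, p) == pytest.approx(1.0, rel=1e-3)


def test_isk_negative_calcium_rejected():
    with pytest.raises(ValueError):
        i_sk(-40.0, -1.0, nsr_parameters())


def test_inal_shift_displaces_inactivation_curve():
    shifted = nsr_parameters()
    unshifted = nsr_parameters(inal_vshift=0.0)
    for v0 in (-90.0, -75.0, -60.0):
        assert inal_inactivation_ss(v0 + 21.0, shifted) == pytest.approx(
            inal_inactivation_ss(v0, unshifted), rel=1e-12)


def test_inal_fully_inactivated_gives_zero_current():
    assert i_nal(-20.0, 1.0, 0.0, nsr_parameters()) == pytest.approx(0.0, abs=1e-12)


def test_inal_calibrated_conductance_matches_reference_ap_charge():
    """AP-clamp integral of the shifted/rescaled current within 5% of the
    unmodified formulation at 1-Hz nSR (oracle: AP-clamp on a shared trace)."""
    params = nsr_parameters()
    t, v = reference_ap_trace(params, n_beats=30)
    q_ref = ap_clamp_inal(t, v, GNAL_REFERENCE, vshift=0.0, tau_scale=1.0)
    q_mod = ap_clamp_inal(t, v, params.g_nal, vshift=params.inal_vshift,
                          tau_scale=params.inal_tau_scale)
    assert q_mod == pytest.approx(q_ref, rel=0.05)


def test_upstroke_velocity_in_physiological_band():
    assert UPSTROKE_BAND[0] <= check_upstroke(nsr_parameters(), 30) <= UPSTROKE_BAND[1]


# ---------------------------------------------------------------------------
# condition transforms
# ---------------------------------------------------------------------------

def test_caf_halves_ryr_luminal_ec50():
    nsr = nsr_parameters()
    caf = apply_caf(nsr)
    assert caf.ec50_sr == pytest.approx(0.5 * nsr.ec50_sr)


def test_caf_leaves_sk_untouched_by_default():
    nsr = nsr_parameters()
    caf = apply_caf(nsr)
    assert caf.g_sk == nsr.g_sk
    assert caf.kd_sk == nsr.kd_sk


def test_caf_sk_remodeling_flag_doubles_gsk():
    nsr = nsr_parameters()
    caf = apply_caf(nsr, sk_remodeling=True)
    assert caf.g_sk == pytest.approx(2.0 * nsr.g_sk)
    assert caf.kd_sk == pytest.approx(0.5 * nsr.kd_sk)


def test_caf_applied_twice_raises():
    with pytest.raises(ValueError):
        apply_caf(caf_parameters())


def test_caf_differs_only_by_documented_scalars():
    nsr = nsr_parameters()
    caf = apply_caf(nsr)
    changed = {n for n in PARAM_NAMES
               if getattr(nsr, n) != getattr(caf, n)}
    assert changed == set(CAF_SCALARS)


def test_iso_zero_concentration_is_identity():
    p = nsr_parameters()
    assert apply_iso(p, 0.0) == p


def test_iso_negative_concentration_rejected():
    with pytest.raises(ValueError):
        apply_iso(nsr_parameters(), -0.5)


def test_iso_saturates_at_one_micromolar():
    from skatrial.parameters import ISO_SCALARS

    p = nsr_parameters()
    piso = apply_iso(p, 1.0)
    for name, sat in ISO_SCALARS.items():
        assert getattr(piso, name) / getattr(p, name) == pytest.approx(sat, rel=1e-3)


def test_iso_increases_cat_amplitude(steady):
    """Paired paced runs: beta-adrenergic stimulation boosts the Ca2+
    transient (oracle: direct comparison of steady 1-Hz runs)."""
    from skatrial.protocols import pace_to_steady_state

    _, base = steady("nsr")
    piso = apply_iso(nsr_parameters(), 1.0)
    res = pace_to_steady_state(piso, 1000.0, y0=base.state,
                               min_beats=30, max_beats=80)
    assert res.beats[-1].cat_amp > base.beats[-1].cat_amp


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_zero_duration_returns_initial_state_only():
    y0 = initial_state()
    y, tr = integrate(nsr_parameters(), y0, 0.0)
    assert np.array_equal(y, y0)
    assert tr.states.shape == (1, N_STATES)


def test_integration_is_deterministic():
    y0 = initial_state()
    p = nsr_parameters()
    y1, tr1 = integrate(p, y0, 600.0, stim_times=[0.0])
    y2, tr2 = integrate(p, y0, 600.0, stim_times=[0.0])
    assert np.array_equal(y1, y2)
    assert np.array_equal(tr1.states, tr2.states)


def test_hybrid_matches_adaptive_stiff_solver():
    """Fixed-step hybrid and LSODA agree on a paced beat."""
    y0 = initial_state()
    p = nsr_parameters()
    _, tr_h = integrate(p, y0, 800.0, stim_times=[0.0])
    _, tr_l = integrate(p, y0, 800.0, stim_times=[0.0], method="lsoda")
    v_l = np.interp(tr_h.t, tr_l.t, tr_l.v)
    # peak shift of a fraction of a ms dominates the pointwise difference
    assert np.max(np.abs(tr_h.v - v_l)) < 5.0
    assert abs(tr_h.v[-1] - v_l[-1]) < 0.5


def test_stimulus_outside_window_rejected():
    with pytest.raises(ValueError):
        integrate(nsr_parameters(), initial_state(), 100.0, stim_times=[200.0])


# ---------------------------------------------------------------------------
# conservation / boundedness / stability properties
# ---------------------------------------------------------------------------

def test_charge_consistency(steady):
    """Reconstructed -(total ionic - stimulus)/C matches the numerical dV/dt."""
    _, res = steady("nsr")
    tr = res.trace
    itot = tr["i_tot"] - tr["i_stim"]
    dvdt = np.gradient(tr.v, tr.t)
    # integral form: net charge balances the voltage change
    # stimulus on/off edges are quantized to the 0.1-ms output grid, which
    # bounds the quadrature error at ~ stim_amp * output_dt per beat
    q = -np.trapezoid(itot, tr.t)
    assert q == pytest.approx(tr.v[-1] - tr.v[0], abs=2.0)
    # pointwise away from the stimulus edges and the steep upstroke; the
    # finite-difference dV/dt carries O(h^2 V''') noise where the trajectory
    # bends sharply, so the check is on the bulk of the points
    quiet = np.abs(dvdt) < 50.0
    for s in tr.stim_times:
        quiet &= np.abs(tr.t - s) > 1.0
        quiet &= np.abs(tr.t - (s + res.trace.params.stim_dur)) > 1.0
    resid = np.abs(dvdt[quiet] + itot[quiet])
    assert np.median(resid) < 0.05
    assert np.percentile(resid, 99) < 0.5


@pytest.mark.parametrize("condition", ["nsr", "caf"])
def test_ca_mass_balance_without_sarcolemmal_fluxes(steady, condition):
    """Total Ca2+ (free + buffered, volume-weighted) drifts < 0.1% over 10 s
    of pacing when every sarcolemmal Ca2+ flux is disabled."""
    p, res = steady(condition)
    pc = p.replace(clamp_sarc_ca=1.0)

    def total_ca(y):
        cyto = y[I_CAI] + y[I_TNCL] + y[I_TNCHC] + y[I_CAM] + y[I_MYOC] + y[I_SRB]
        sl = y[I_CASL] + y[I_SLLSL] + y[I_SLHSL]
        junc = y[I_CAJ] + y[I_SLLJ] + y[I_SLHJ]
        sr = y[I_CASR] + y[I_CSQNB]
        return (p.v_myo * cyto + p.v_sl * sl + p.v_junc * junc + p.v_sr * sr)

    y0 = res.state
    y1, _ = integrate(pc, y0, 10_000.0,
                      stim_times=np.arange(0, 10_000.0, 1000.0),
                      record_dt=None)
    drift = abs(total_ca(y1) - total_ca(y0)) / total_ca(y0)
    assert drift < 1e-3


@pytest.mark.parametrize("condition", ["nsr", "caf"])
def test_gates_bounded_and_concentrations_positive(steady, condition):
    _, res = steady(condition)
    states = res.trace.states
    for i in FRACTION_INDICES:
        assert states[:, i].min() >= 0.0, STATE_NAMES[i]
        assert states[:, i].max() <= 1.0, STATE_NAMES[i]
    ryr_sum = states[:, [I_RYRR, I_RYRO, I_RYRI]].sum(axis=1)
    assert ryr_sum.max() <= 1.0 + 1e-9
    conc = states[:, [I_CAI, I_CAJ, I_CASL, I_CASR]]
    assert conc.min() > 0.0


@pytest.mark.parametrize("condition", ["nsr", "caf"])
def test_resting_membrane_potential_stable(condition, rest_nsr, rest_caf):
    """Unstimulated models hold their RMP within 1 mV over 10 s."""
    y0 = rest_nsr if condition == "nsr" else rest_caf
    p = nsr_parameters() if condition == "nsr" else caf_parameters()
    _, tr = integrate(p, y0, 10_000.0, record_dt=1.0)
    assert tr.v.max() - tr.v.min() < 1.0


def test_caf_vs_nsr_orderings_at_1hz(steady):
    """cAF: shorter APD90, more polarized RMP, smaller CaT amplitude."""
    _, nsr = steady("nsr")
    _, caf = steady("caf")
    b_n, b_c = nsr.beats[-1], caf.beats[-1]
    assert b_c.apd90 < b_n.apd90
    assert b_c.rmp < b_n.rmp
    assert b_c.cat_amp < b_n.cat_amp


def test_isk_peak_comparable_between_conditions(steady):
    """Without SK remodeling, peak I_SK in cAF stays comparable to nSR
    (cleft/subsarcolemmal Ca2+ rises well above K_d in both)."""
    _, nsr = steady("nsr")
    _, caf = steady("caf")
    ratio = caf.beats[-1].peak_isk / nsr.beats[-1].peak_isk
    assert 0.5 < ratio < 1.5
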
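# Methods

## The model

`skatrial` implements a compartmental (0-D) human atrial cardiomyocyte in
the established four-compartment architecture — junctional cleft,
subsarcolemmal space, bulk cytosol and sarcoplasmic reticulum (SR) — with
explicit buffering in each, Hodgkin–Huxley sarcolemmal currents, and
Shannon-style SR Ca²⁺ release with luminal regulation of the ryanodine
receptor (RyR). The membrane carries I_Na (Courtemanche kinetics), I_NaL,
I_CaL (GHK formulation split 90/10 between cleft and subsarcolemmal
membrane), I_to, I_Kur, I_Kr, I_Ks, I_K1, I_Kp, I_K2P, I_SK, Ca²⁺-activated
and background Cl⁻ currents, NCX, NKA, PMCA and Na⁺/Ca²⁺ background
currents. Intracellular K⁺ is clamped (lineage convention). 41 state
variables in total.

The SK current is

I_SK = G_SK · r(E_m − E_K) · [F_junc·P_o([Ca]_j) + F_sl·P_o([Ca]_sl)] · (E_m − E_K)

with Ca²⁺ activation P_o(Ca) = Ca^n / (Ca^n + K_d^n), K_d = 350 nM, Hill
coefficient n = 2, and a mild inward rectification
r(ΔV) = 0.1 + 0.9 / (1 + exp((ΔV − 40 mV)/20 mV)). The channel senses the
cleft and subsarcolemmal Ca²⁺ pools (weighted like other sarcolemmal
currents, 11% / 89%), which rise well above K_d during every action
potential — this is why the cAF model, despite a depressed cytosolic Ca²⁺
transient, produces a near-normal peak I_SK.

Late Na⁺ current: the inactivation midpoint is shifted +21 mV (to −70 mV)
to match the fast-Na⁺ half-activation, and the inactivation time constant
is scaled by 1/3 (600 → 200 ms, physiological-temperature kinetics). The
conductance is then re-calibrated so the AP-clamp charge over a 1-Hz nSR
beat matches the unmodified formulation at its native conductance
(`skatrial.calibration.calibrate_gnal`; result G_NaL = 2.852·10⁻⁴ mS/µF).
The fast-Na⁺ conductance (10 mS/µF) is set so the maximal upstroke
velocity at 1-Hz nSR pacing falls in the physiological 150–300 V/s band.

### Conditions

Conditions are parameter transforms, applied in this order:
`nsr_parameters()` → `apply_caf()` → `apply_iso()`.

Chronic AF (`apply_caf`) multiplies the nSR set by: G_Na ×0.9, G_to ×0.3,
G_Kur ×0.5, G_K1 ×2, G_Ks ×2, G_K2P ×2, P_CaL ×0.5, NCX ×1.4, RyR opening
rate ×3, SR leak ×1.25, SERCA forward K_m ×0.7 (sarcolipin
downregulation), and — the remodeling singled out in this study — the RyR
luminal-Ca²⁺ EC₅₀ ×0.5. By default G_SK and K_d,SK are untouched (no
AF-associated SK remodeling); `apply_caf(sk_remodeling=True)` additionally
doubles G_SK and halves K_d,SK.

Isoproterenol (`apply_iso`) applies a saturating β-adrenergic scalar set:
I_CaL ×2.2 with a 3-mV activation shift, I_Ks ×3 with a 40-mV activation
shift, I_Kur ×3, SERCA K_m ×0.5 and V_max ×1.5, RyR opening ×2 (not
stacked on the cAF surrogate), troponin-C off-rate ×1.5, NKA ×1.25.
Intermediate concentrations interpolate exponentially
(fraction = 1 − e^(−[ISO]/0.1 µM)); 1 µM is saturating to within 5·10⁻⁵.

Because the lineage publications do not restate these scalar values, the
cAF Ca²⁺-handling and ISO sets were calibrated once against the study-level
electrophysiology this package reproduces (AP/CaT/refractoriness orderings
and baseline threshold windows) and then frozen; every individually
documented quantity (K_d,SK = 350 nM, EC₅₀ ×0.5, +21 mV I_NaL shift, G_SK
50/100/200%) is hard-coded from its stated value.

## Numerics

The primary integrator is a fixed-step hybrid compiled with numba:
all states of the form dy/dt = a − b·y (gates, RyR occupancies, every
buffer) advance by their exact exponential relaxation over the step
(Rush–Larsen generalized to buffers); membrane potential and free ion
concentrations advance by forward Euler. Free/bound bookkeeping is exact:
the flux removed from a free pool equals the amount its buffers actually
bound that step, so total Ca²⁺ is conserved to round-off when sarcolemmal
fluxes are disabled. The nominal step is 0.01 ms; each step is subdivided
automatically so the stiffest explicitly-integrated rate (cleft Ca²⁺
balance during RyR release, SR-free-Ca²⁺/calsequestrin coupling) stays
inside the Euler stability region (λ·Δt ≤ 1.4). Output is resampled on a
uniform 0.1-ms grid for feature extraction.

scipy's LSODA (rtol 10⁻⁶, per-state atol down to 10⁻⁹ mM for cleft Ca²⁺)
runs the same compiled right-hand side and serves as the independent
numerical cross-check; the suite verifies beat-level agreement between the
two routes. The hybrid route is bit-reproducible for identical inputs.

Degenerate inputs: GHK fluxes use their analytic limits at E_m = 0; the
d-gate time constant uses its limit at E_m = −9 mV; zero local Ca²⁺
evaluates the NCX/SK activation limits (0) rather than raising; a
non-finite state aborts integration with the last valid time.

## Protocols

* **Steady pacing** — stimulate (12.5 A/F, 5 ms) until the *beat-pair*
  steady-state criterion: every state variable sampled at end-diastole
  changes < 10⁻³ relative across one beat pair (so stable alternans is a
  steady state), minimum 100 beats, cap 500. The slowly-equilibrating Na⁺
  pool (hundreds of seconds) is excluded from the criterion. Repolarization
  failure (E_m never below −40 mV between stimuli) is flagged, not raised.
* **Feature extraction** — APD90 from AP onset (max dV/dt) to 90%
  repolarization toward the preceding diastolic E_m; APD(−60 mV) to the
  −60 mV downward crossing (the alternans-scoring level); CaT amplitude =
  per-beat max − min of bulk cytosolic Ca²⁺ (reported in nM); RMP = the
  diastolic E_m minimum; crossings linearly interpolated on the 0.1-ms grid.
* **DTE / ERP** — diastolic threshold of excitation by bisection on the
  amplitude of a 5-ms test stimulus (resolution 0.05 A/F; success =
  upstroke ≥ 5 V/s). ERP by S1–S2: S1 = 5 ms at 2×DTE, S2 identical,
  coupling interval decreased in 5-ms steps; ERP is the longest failing
  interval (failure = upstroke < 5 V/s or amplitude < 50% of the S1 beat).
  Non-ERP protocols keep the fixed default stimulus; thresholds are
  insensitive to suprathreshold amplitude.
* **Alternans threshold** — largest BCL whose steady state shows a
  beat-to-beat APD(−60 mV) difference ≥ 5 ms (voltage mode) or CaT
  amplitude difference ≥ 10 nM (calcium mode), searched over 150–450 ms.
  If exactly one of the final two beats lacks a −60 mV crossing the pair
  counts as maximal APD alternation; if both lack it the trial is scored
  as repolarization failure, not alternans.
* **DAD threshold** — largest BCL for which a 10-s drive under 1 µM
  isoproterenol, started from the drug-free 1-Hz steady state, is followed
  by a diastolic voltage oscillation ≥ 10 mV during a 5-s pause (measured
  as any rise above the running post-repolarization minimum). Search range
  200–800 ms; trials are mutually independent.
* **Searches** — thresholds follow the descending-scan convention (largest
  positive BCL). The implementation bisects the upper positive/negative
  boundary to a 4-ms bracket and finishes with a descending 1-ms scan;
  equivalence with exhaustive descending scans is tested (synthetic
  predicates including a non-monotone short-BCL region, plus a brute-force
  DTE scan oracle).

## Population analysis

Cell-to-cell variability is emulated by multiplying 20 maximal
conductances/transport rates (all G_x, P_CaL, v_NCX, v_NKA, v_SERCA,
RyR release and leak rates, PMCA) by independent log-normal factors,
σ = 0.1 on the natural-log scale, mean 0 — σ = 0 reproduces the baseline
exactly. Per-variant sub-seeds derive from (master seed, variant index),
so any subset can be regenerated and results are independent of
evaluation order.

Exclusions mirror the study's rules: variants with AP irregularities at
the base rate (repolarization failure, alternans, or spontaneous diastolic
depolarization ≥ 10 mV) are excluded from the linear feature regressions;
variants exhibiting a phenomenon already at the base rate, or never, are
excluded from the corresponding threshold regression. Every exclusion
records which rule fired.

Linear sensitivity regresses z-scored log features on z-scored log factors
(OLS, statsmodels); coefficients are therefore standardized and comparable
across parameters. Logistic sensitivity fits DAD occurrence at 2-Hz pacing
(BCL threshold ≥ 500 ms) by unpenalized maximum likelihood, falling back
to a small ridge (10⁻⁴, logged) only on complete separation. Synthetic
fixture generators with planted coefficients back the recovery tests
(noise-free recovery to 10⁻⁶; noisy within 2 SE).

## What the generator emulates — and what it does not

The log-normal population emulates graded, static cell-to-cell variability
of channel expression around a single lineage. It does not emulate
correlated channel remodeling, temporal expression drift, stochastic
channel gating or spatial Ca²⁺ wave propagation (this is a common-pool
0-D model: no Ca²⁺ sparks, no intra-cell heterogeneity). Passing tests
therefore demonstrate correct implementation of the stated model and
protocols and qualitative agreement with the study's orderings — not
validation against new experimental data.

## Problem sizes and fidelity

Everything runs on one CPU. The acceptance script paces each BCL trial
with the beat-pair criterion at minimum 80 / cap 200 beats (the package's
desk-scale choice; thresholds move by ~1–3 ms versus longer budgets). The
test suite uses min 40 / cap 100–120 beats for searches, and populations
of n = 30 per condition for the DAD-prevalence check with an a priori
3-σ binomial tolerance; model-based regression sign checks are restricted
to the dominant effects (G_SK on APD90, logistic DAD) at that size, while
full-fidelity coefficient recovery runs on the synthetic fixtures.

## Known limitations

* The lineage's exact cAF and β-adrenergic scalar sets are not public in
  the sources available here; the calibrated surrogates reproduce the
  study's orderings and threshold windows but not every printed threshold
  to the millisecond (observed offsets: alternans within ~3 ms for nSR and
  ~+20 ms for cAF; DAD thresholds within ~10–80 ms). Orderings,
  monotonicities and population prevalences are reproduced.
* Voltage-gated alternans detection near the repolarization-failure
  boundary (fast nSR pacing) depends on the undefined-APD convention
  documented above.
* No PKA/CaMKII dynamic signaling, no 3-D Ca²⁺ diffusion, no stochastic
  RyR gating, no tissue coupling; I_K,ACh is inactive.
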
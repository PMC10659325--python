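"""Parameter set for the compartmental human atrial myocyte model.

The model follows the established human atrial cell architecture: four
Ca2+ compartments (junctional cleft, subsarcolemmal space, bulk cytosol, SR),
Hodgkin-Huxley sarcolemmal currents including the small-conductance
Ca2+-activated K+ current (I_SK), Courtemanche-type fast Na+ current, and
Shannon-style SR Ca2+ release/uptake with luminal RyR regulation.

Three physiological conditions are expressed as parameter transforms:

* ``nsr_parameters()``  -- normal sinus rhythm baseline,
* ``apply_caf()``       -- chronic atrial fibrillation remodeling (ion-channel
  scalars plus a 50% reduction of the RyR luminal EC50),
* ``apply_iso()``       -- saturating beta-adrenergic stimulation
  (isoproterenol), graded with concentration.

All conductances are in mS/uF (equivalently nS/pF), permeabilities in
cm/s-derived model-native units, concentrations in mM, volumes in L, time in
ms, voltage in mV, currents in A/F.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np

# Physical constants
R_GAS = 8314.0  # J/(kmol K)
FARADAY = 96485.0  # C/mol

# Cell geometry (100 um long, 10.25 um radius cylinder)
_CELL_LENGTH = 100.0  # um
_CELL_RADIUS = 10.25  # um
V_CELL = math.pi * _CELL_RADIUS**2 * _CELL_LENGTH * 1e-15  # L
V_MYO = 0.65 * V_CELL
V_SR = 0.035 * V_CELL
V_SL = 0.02 * V_CELL
V_JUNC = 0.0539 * 0.01 * V_CELL


@dataclass
class ModelParameters:
    """Full parameter set; numeric fields map 1:1 onto the solver vector.

    ``condition``, ``iso_concentration`` and ``af_sk_remodeling`` are
    bookkeeping attributes recording which transforms produced this set.
    """

    # --- membrane & geometry -------------------------------------------------
    cmem: float = 1.10e-10          # F, membrane capacitance
    temp: float = 310.0             # K
    v_junc: float = V_JUNC          # L
    v_sl: float = V_SL
    v_myo: float = V_MYO
    v_sr: float = V_SR
    j_ca_juncsl: float = 1.0 / 1.2134e12   # L/ms, cleft<->subsarcolemma Ca2+ exchange
    j_ca_slmyo: float = 1.0 / 2.68510e11   # L/ms
    j_na_juncsl: float = 1.0 / (1.6382e12 / 3 * 100)  # L/ms
    j_na_slmyo: float = 1.0 / (1.8308e10 / 3 * 100)   # L/ms
    fjunc: float = 0.11             # fraction of sarcolemmal current in cleft
    fjunc_cal: float = 0.9          # L-type channels concentrated at the cleft

    # --- external / fixed ion concentrations (mM) ---------------------------
    nao: float = 140.0
    ko: float = 5.4
    cao: float = 1.8
    cli: float = 15.0
    clo: float = 150.0
    mgi: float = 1.0

    # --- Na+ currents --------------------------------------------------------
    g_na: float = 10.0              # mS/uF, Courtemanche kinetics; calibrated for
                                    # a physiological upstroke velocity (see docs)
    g_nal: float = 2.852e-4         # mS/uF, late Na+; AP-clamp calibrated after
                                    # the inactivation shift (calibration.py)
    inal_vshift: float = 21.0       # mV rightward shift of inactivation V1/2
    inal_tau_scale: float = 1.0 / 3.0  # scale on inactivation time constant
    g_nab: float = 0.597e-3
    ibar_nak: float = 1.26          # A/F
    km_naip: float = 11.0           # mM
    km_ko: float = 1.5              # mM

    # --- K+ currents ---------------------------------------------------------
    g_to: float = 0.165
    g_kur: float = 0.045
    g_kr: float = 0.035             # scaled by sqrt(Ko/5.4) in the RHS
    g_ks: float = 0.0035
    iks_vshift: float = 0.0         # mV (beta-adrenergic shift)
    g_kp: float = 0.002
    g_k1: float = 0.0525            # scaled by sqrt(Ko/5.4) in the RHS
    g_k2p: float = 0.005
    pnak: float = 0.01833           # Na+ permeability ratio for E_Ks

    # --- SK current ----------------------------------------------------------
    g_sk: float = 0.01              # mS/uF nominal (100% G_SK)
    kd_sk: float = 350e-6           # mM  == 350 nM half-activation
    sk_hill: float = 2.0            # Hill coefficient of Ca2+ activation
    sk_rect_vhalf: float = 40.0     # mV above E_K, inward-rectification midpoint
    sk_rect_slope: float = 20.0     # mV
    sk_rect_floor: float = 0.1      # residual conductance at depolarized E_m

    # --- Ca2+ currents / transporters ---------------------------------------
    p_ca: float = 2.7e-4            # cm/s, L-type Ca2+ permeability
    p_k: float = 1.35e-7
    p_na: float = 0.75e-8
    ical_vshift: float = 0.0        # mV (beta-adrenergic shift)
    q10_cal: float = 1.8
    ibar_ncx: float = 3.15          # A/F
    km_cai: float = 3.59e-3
    km_cao: float = 1.3
    km_nai: float = 12.29
    km_nao: float = 87.5
    ksat: float = 0.27
    nu: float = 0.35
    kd_act: float = 0.384e-3        # mM, NCX allosteric Ca2+ activation
    q10_ncx: float = 1.57
    ibar_pmca: float = 0.0471       # A/F
    km_pca: float = 0.5e-3
    q10_pmca: float = 2.35
    g_cab: float = 6.0643e-4
    g_clca: float = 0.0548
    kd_clca: float = 0.1            # mM
    g_clb: float = 9e-3

    # --- SR Ca2+ handling ----------------------------------------------------
    vmax_serca: float = 5.3114e-3   # mM/ms
    kmf_serca: float = 0.615e-3     # mM, forward Km (halved by ISO)
    kmr_serca: float = 1.7          # mM
    hill_serca: float = 1.787
    q10_serca: float = 2.6
    ks_ryr: float = 25.0            # 1/ms, release rate constant
    ko_ca: float = 10.0             # 1/(mM^2 ms), RyR opening
    kom_ryr: float = 0.06           # 1/ms
    ki_ca: float = 0.5              # 1/(mM ms), RyR inactivation
    kim_ryr: float = 0.005          # 1/ms
    ec50_sr: float = 0.45           # mM, luminal [Ca]SR EC50 of RyR activation
    max_sr: float = 15.0
    min_sr: float = 1.0
    kleak_sr: float = 5.348e-6      # 1/ms

    # --- cytosolic & SL buffering (mM, 1/ms, 1/(mM ms)) ----------------------
    bmax_naj: float = 7.561
    bmax_nasl: float = 1.65
    koff_na: float = 1e-3
    kon_na: float = 1e-4
    bmax_tncl: float = 70e-3
    koff_tncl: float = 19.6e-3
    kon_tncl: float = 32.7
    bmax_tnch: float = 140e-3
    koff_tnchca: float = 0.032e-3
    kon_tnchca: float = 2.37
    koff_tnchmg: float = 3.33e-3
    kon_tnchmg: float = 3e-3
    bmax_cam: float = 24e-3
    koff_cam: float = 238e-3
    kon_cam: float = 34.0
    bmax_myosin: float = 140e-3
    koff_myoca: float = 0.46e-3
    kon_myoca: float = 13.8
    koff_myomg: float = 0.057e-3
    kon_myomg: float = 0.0157
    bmax_sr: float = 17.1e-3
    koff_sr: float = 60e-3
    kon_sr: float = 100.0
    bmax_sll_j: float = 4.6e-3 * V_MYO / V_JUNC * 0.1
    bmax_sll_sl: float = 37.4e-3 * V_MYO / V_SL
    koff_sll: float = 1.3
    kon_sll: float = 100.0
    bmax_slh_j: float = 1.65e-3 * V_MYO / V_JUNC * 0.1
    bmax_slh_sl: float = 13.4e-3 * V_MYO / V_SL
    koff_slh: float = 30e-3
    kon_slh: float = 100.0
    bmax_csqn: float = 140e-3 * V_MYO / V_SR
    koff_csqn: float = 65.0
    kon_csqn: float = 100.0

    # --- stimulus & numerical switches ---------------------------------------
    stim_amp: float = 12.5          # A/F, depolarizing
    stim_dur: float = 5.0           # ms
    clamp_sarc_ca: float = 0.0      # 1.0 disables all sarcolemmal Ca2+ fluxes
                                    # (mass-balance diagnostics only)

    # --- condition bookkeeping (not part of the numeric vector) --------------
    condition: str = "nsr"
    iso_concentration: float = 0.0  # uM
    af_sk_remodeling: bool = False

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite")
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0")

    def to_vector(self) -> np.ndarray:
        """Flatten numeric fields into the solver parameter vector."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def scaled(self, **scales: float) -> "ModelParameters":
        """Multiply named parameters, e.g. ``scaled(g_sk=2.0)`` for 200% G_SK."""
        updates = {}
        for name, factor in scales.items():
            if name not in PARAM_NAMES:
                raise KeyError(f"unknown parameter {name!r}")
            updates[name] = getattr(self, name) * factor
        return self.replace(**updates)

    def content_hash(self) -> str:
        payload = {n: getattr(self, n) for n in PARAM_NAMES}
        payload["condition"] = self.condition
        payload["iso_concentration"] = self.iso_concentration
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# Ordered numeric field names; defines the layout of the solver vector.
PARAM_NAMES: tuple = tuple(
    f.name
    for f in dataclasses.fields(ModelParameters)
    if f.name not in ("condition", "iso_concentration", "af_sk_remodeling")
)

PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

_NONNEGATIVE = tuple(
    n
    for n in PARAM_NAMES
    if n.startswith(("g_", "v_", "p_", "bmax_", "kon_", "koff_", "km", "kd_"))
    or n in ("cmem", "ibar_nak", "ibar_ncx", "ibar_pmca", "vmax_serca",
             "ks_ryr", "ko_ca", "ki_ca", "kleak_sr", "stim_dur")
)

# Maximal conductances / transport rates perturbed in population studies.
PERTURBABLE_PARAMETERS: tuple = (
    "g_na", "g_nal", "g_to", "g_kur", "g_kr", "g_ks", "g_k1", "g_k2p",
    "g_sk", "p_ca", "g_clca", "g_clb", "g_nab", "g_cab",
    "ibar_ncx", "ibar_nak", "vmax_serca", "ks_ryr", "kleak_sr", "ibar_pmca",
)

# Chronic-AF ion-channel remodeling: multiplicative scalars on the nSR set.
CAF_SCALARS = {
    "g_na": 0.9,      # -10% fast Na+
    "g_to": 0.3,      # -70% transient outward
    "g_kur": 0.5,     # -50% ultrarapid K+
    "g_k1": 2.0,      # +100% inward rectifier
    "g_ks": 2.0,      # +100% slow delayed rectifier
    "g_k2p": 2.0,     # +100% two-pore-domain K+
    "p_ca": 0.5,      # -50% L-type Ca2+ permeability
    "p_k": 0.5,
    "p_na": 0.5,
    "ibar_ncx": 1.4,  # +40% Na+/Ca2+ exchange
    "ko_ca": 3.0,     # RyR opening rate x3 (hyperphosphorylation surrogate)
    "kleak_sr": 1.25, # +25% SR leak
    "ec50_sr": 0.5,   # 50% reduction of the luminal EC50 for SR Ca2+ release
    "kmf_serca": 0.7, # enhanced SERCA Ca2+ affinity (sarcolipin downregulation)
}


def nsr_parameters(**overrides) -> ModelParameters:
    """Baseline normal-sinus-rhythm parameter set (100% G_SK)."""
    return ModelParameters(**overrides)


def apply_caf(params: ModelParameters, sk_remodeling: bool = False) -> ModelParameters:
    """Chronic-AF remodeling of an nSR parameter set.

    Applies the documented ion-channel remodeling scalars plus a 50% reduction
    of the RyR luminal Ca2+ EC50. By default G_SK and K_d,SK are left at their
    nSR values (no AF-associated SK remodeling); ``sk_remodeling=True``
    additionally doubles G_SK and doubles the Ca2+ affinity (K_d,SK x 0.5).
    """
    if params.condition == "caf":
        raise ValueError("cAF remodeling already applied; refusing to reapply")
    updates = {name: getattr(params, name) * factor for name, factor in CAF_SCALARS.items()}
    if sk_remodeling:
        updates["g_sk"] = params.g_sk * 2.0
        updates["kd_sk"] = params.kd_sk * 0.5
    return params.replace(condition="caf", af_sk_remodeling=sk_remodeling, **updates)


# Saturating beta-adrenergic scalars (fully expressed at 1 uM isoproterenol).
ISO_SCALARS = {
    "p_ca": 2.2,        # L-type Ca2+ (PKA phosphorylation)
    "p_k": 2.2,
    "p_na": 2.2,
    "g_ks": 3.0,
    "g_kur": 3.0,
    "kmf_serca": 0.5,   # increased SERCA Ca2+ affinity (PLB phosphorylation)
    "vmax_serca": 1.5,  # increased maximal SERCA uptake
    "koff_tncl": 1.5,   # reduced myofilament Ca2+ affinity (TnI phosphorylation)
    "ko_ca": 2.0,       # RyR sensitization
    "ibar_nak": 1.25,   # phospholemman phosphorylation
}
ISO_SHIFTS = {
    "ical_vshift": 3.0,   # mV leftward-equivalent shift of ICaL activation
    "iks_vshift": 40.0,   # mV shift of IKs activation
}
# Effective concentration scale: effects ~saturated at 1 uM.
_ISO_CONC_SCALE = 0.1  # uM


def iso_fraction(concentration_um: float) -> float:
    """Fraction of the saturating beta-adrenergic effect at a given [ISO]."""
    if concentration_um < 0:
        raise ValueError("isoproterenol concentration must be >= 0")
    return 1.0 - math.exp(-concentration_um / _ISO_CONC_SCALE)


def apply_iso(params: ModelParameters, concentration_um: float = 1.0) -> ModelParameters:
    """Apply beta-adrenergic (isoproterenol) stimulation.

    The scalar targets follow the model lineage's saturating ISO switch;
    intermediate concentrations interpolate exponentially toward saturation.
    ``concentration_um = 0`` is the identity.
    """
    frac = iso_fraction(concentration_um)
    if frac == 0.0:
        return params
    # RyR sensitization does not stack on top of the cAF remodeling surrogate.
    updates = {}
    for name, sat in ISO_SCALARS.items():
        if name == "ko_ca" and params.condition == "caf":
            continue
        factor = 1.0 + frac * (sat - 1.0)
        updates[name] = getattr(params, name) * factor
    for name, shift in ISO_SHIFTS.items():
        updates[name] = getattr(params, name) + frac * shift
    return params.replace(iso_concentration=concentration_um, **updates)


def caf_parameters(**overrides) -> ModelParameters:
    """Convenience constructor: cAF remodeling applied to the nSR baseline."""
    return apply_caf(nsr_parameters(**overrides))
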
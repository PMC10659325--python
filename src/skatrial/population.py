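"""Populations of model variants: log-normal parameter perturbation,
per-variant protocol evaluation, and exclusion bookkeeping.

Cell-to-cell variability is emulated by multiplying every perturbable
maximal conductance / transport rate by an independent log-normal scaling
factor, ``exp(z)`` with ``z ~ Normal(0, sigma)`` and sigma = 0.1 by default.
Per-variant sub-seeds derive deterministically from the master seed, so
results are independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import alternans_magnitudes
from .parameters import PERTURBABLE_PARAMETERS, ModelParameters
from .protocols import (ALTERNANS_DAPD_MS, alternans_threshold,
                        classify_dad_at_bcl, dad_threshold, measure_erp,
                        pace_to_steady_state)

SIGMA_DEFAULT = 0.1


@dataclass
class ScalingFactorSet:
    """Multiplicative perturbation factors for one model variant."""

    variant_id: int
    factors: dict            # parameter name -> factor (> 0)
    seed: int

    def apply(self, params: ModelParameters) -> ModelParameters:
        return params.scaled(**self.factors)


def generate_population(n: int, sigma: float = SIGMA_DEFAULT,
                        seed: int = 0,
                        parameters: tuple = PERTURBABLE_PARAMETERS
                        ) -> list[ScalingFactorSet]:
    """Draw ``n`` variants with independent log-normal factors per parameter.

    ``sigma`` is the standard deviation of the natural-log factors
    (mean 0); ``sigma = 0`` returns all-ones factors. Reproducible from
    ``seed``; variant ``i`` uses sub-seed ``seed * 100003 + i`` so any
    subset can be regenerated independently.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = []
    for i in range(n):
        sub = (seed * 100003 + i) % (2**31 - 1)
        rng = np.random.default_rng(sub)
        z = rng.normal(0.0, sigma, size=len(parameters))
        out.append(ScalingFactorSet(
            variant_id=i,
            factors={p: float(math.exp(zi)) for p, zi in zip(parameters, z)},
            seed=sub))
    return out


def population_frame(population: list[ScalingFactorSet]) -> pd.DataFrame:
    """Factor matrix as a DataFrame (one row per variant)."""
    rows = [{"variant": s.variant_id, **s.factors} for s in population]
    return pd.DataFrame(rows).set_index("variant")


# ---------------------------------------------------------------------------
# per-variant protocol evaluation
# ---------------------------------------------------------------------------

#: protocol set names accepted by evaluate_population
PROTOCOLS = ("features", "erp", "alternans", "dad_threshold", "dad_class")


def _evaluate_variant(params: ModelParameters, protocols: tuple,
                      bcl: float, dad_bcl: float, pace_kw: dict,
                      search_kw: dict, y0=None) -> dict:
    row: dict = {}
    res = pace_to_steady_state(params, bcl, y0=y0, **pace_kw)
    b = res.beats[-1]
    d_apd, d_cat = alternans_magnitudes(res.beats)
    row.update(apd90_ms=b.apd90, apd_minus60_ms=b.apd_minus60, rmp_mV=b.rmp,
               cat_amp_nM=b.cat_amp, dvdt_max_Vps=b.dvdt_max)
    # exclusion screening at the base rate: AP irregularities = repolarization
    # failure, alternans, or spontaneous diastolic depolarization >= 10 mV
    irregular = None
    if not res.repolarization_ok:
        irregular = "repolarization_failure"
    elif (math.isinf(d_apd)
          or (math.isfinite(d_apd) and d_apd >= ALTERNANS_DAPD_MS)):
        irregular = "alternans_at_base_rate"
    else:
        dias = res.trace.v[res.trace.t > res.trace.stim_times[-1] + 400.0]
        if dias.size and (dias.max() - dias.min()) >= 10.0 and b.apd90 < 400.0:
            irregular = "spontaneous_depolarization"
    row["ap_irregularity"] = irregular

    if "erp" in protocols:
        erp = measure_erp(params, bcl, y0=res.state, pace_kw=pace_kw)
        row["erp_ms"] = erp.value if erp.detected else math.nan
    if "alternans" in protocols:
        alt = alternans_threshold(params, "voltage", pace_kw=pace_kw,
                                  **search_kw)
        row["alternans_bcl_ms"] = alt.value if alt.detected else math.nan
        row["alternans_detected"] = alt.detected
    if "dad_threshold" in protocols:
        dad = dad_threshold(params, y0=res.state, **search_kw)
        row["dad_bcl_ms"] = dad.value if dad.detected else math.nan
        row["dad_detected"] = dad.detected
    if "dad_class" in protocols:
        pos, amp = classify_dad_at_bcl(params, bcl=dad_bcl, y0=res.state)
        row["dad_at_bcl"] = bool(pos)
        row["dad_amplitude_mV"] = amp
    return row


def evaluate_population(population: list[ScalingFactorSet],
                        base_params: ModelParameters,
                        protocols: tuple = ("features", "dad_class"),
                        bcl: float = 1000.0, dad_bcl: float = 500.0,
                        pace_kw: dict | None = None,
                        search_kw: dict | None = None,
                        y0=None) -> pd.DataFrame:
    """Run the requested protocol set for every variant.

    Returns one row per variant: scaling factors, features/thresholds, and
    the exclusion bookkeeping. Per-variant failures are recorded in the
    ``error`` column and never abort the population. ``y0`` (e.g. the base
    model's steady state) seeds each variant's pacing equilibration.
    """
    unknown = set(protocols) - set(PROTOCOLS)
    if unknown:
        raise ValueError(f"unknown protocols: {sorted(unknown)}")
    pace_kw = dict(pace_kw or {})
    search_kw = dict(search_kw or {})
    rows = []
    for var in population:
        row = {"variant": var.variant_id,
               **{f"f_{k}": v for k, v in var.factors.items()}}
        try:
            row.update(_evaluate_variant(var.apply(base_params), protocols,
                                         bcl, dad_bcl, pace_kw, search_kw,
                                         y0=y0))
            row["error"] = None
        except Exception as exc:   # per-variant isolation
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def classify_dad_positive(table: pd.DataFrame,
                          bcl_cutoff: float = 500.0) -> np.ndarray:
    """Binary DAD outcome: detected threshold >= cutoff (default 500 ms).

    Accepts tables carrying either a full ``dad_bcl_ms`` threshold column or
    the single-BCL ``dad_at_bcl`` classification.
    """
    if "dad_bcl_ms" in table.columns:
        thr = table["dad_bcl_ms"].to_numpy(dtype=float)
        return (np.nan_to_num(thr, nan=-np.inf) >= bcl_cutoff)
    if "dad_at_bcl" in table.columns:
        return table["dad_at_bcl"].fillna(False).to_numpy(dtype=bool)
    raise KeyError("table carries no DAD outcome column")


def linear_regression_mask(table: pd.DataFrame) -> np.ndarray:
    """Variants admissible for the 1-Hz feature regressions (no AP
    irregularities, no evaluation error)."""
    ok = table["error"].isna().to_numpy()
    if "ap_irregularity" in table.columns:
        ok &= table["ap_irregularity"].isna().to_numpy()
    return ok


def threshold_regression_mask(table: pd.DataFrame, column: str,
                              base_bcl: float = 1000.0) -> np.ndarray:
    """Variants admissible for a BCL-threshold regression: the phenomenon was
    detected somewhere below the base pacing rate (present, but not already
    at the base rate)."""
    ok = table["error"].isna().to_numpy()
    thr = table[column].to_numpy(dtype=float)
    ok &= np.isfinite(thr)
    ok &= thr < base_bcl
    return ok
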
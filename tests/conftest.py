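"""Shared fixtures: baseline parameter sets and cached steady-pacing runs.

Steady states are expensive (tens of simulated seconds each), so a single
session-scope cache hands them to every test that needs a paced model.
"""

from __future__ import annotations

import pytest

from skatrial import caf_parameters, nsr_parameters
from skatrial.protocols import pace_to_steady_state

#: beat budget for test-scale steady pacing (methods note documents scales)
PACE_STD = dict(min_beats=40, max_beats=100)


@pytest.fixture(scope="session")
def base_params():
    return {"nsr": nsr_parameters(), "caf": caf_parameters()}


@pytest.fixture(scope="session")
def steady():
    """``steady(condition, gsk_scale)`` -> (params, PacingResult) cached."""
    cache = {}

    def get(condition: str, gsk: float = 1.0, bcl: float = 1000.0):
        key = (condition, gsk, bcl)
        if key not in cache:
            p = nsr_parameters() if condition == "nsr" else caf_parameters()
            if gsk != 1.0:
                p = p.scaled(g_sk=gsk)
            cache[key] = (p, pace_to_steady_state(p, bcl, with_currents=True,
                                                  **PACE_STD))
        return cache[key]

    return get
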
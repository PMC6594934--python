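"""Shared fixtures.

The expensive artefacts -- the preindustrial spin-up and the
multi-millennial forced runs -- are computed once per session and
shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import oxybox as ox

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from oxybox.ecosystem import (
    make_compensating_ecosystem,
    reference_nstar_from_state,
)


@pytest.fixture(scope="session")
def default_config() -> ox.ModelConfig:
    return ox.ModelConfig()


@pytest.fixture(scope="session")
def spun_state(default_config):
    """Preindustrial steady state of the default configuration."""
    state, report = ox.spinup(default_config)
    assert report["converged"]
    return state


@pytest.fixture(scope="session")
def warming_run(default_config, spun_state):
    """Default warming scenario, 1850-8000."""
    forcing = ox.make_warming_scenario(
        ox.ScenarioParams(), default_config.geometry
    )
    return ox.run(default_config, spun_state.copy(), forcing)


@pytest.fixture(scope="session")
def control_run(default_config, spun_state):
    """Preindustrial control over the same window."""
    forcing = ox.make_control_scenario(
        years=6150.0, geom=default_config.geometry
    )
    return ox.run(default_config, spun_state.copy(), forcing)


@pytest.fixture(scope="session")
def compensating_run(default_config, spun_state):
    """Counterfactual warming run with instantaneously compensating
    fixation, started from the same preindustrial state."""
    ref = reference_nstar_from_state(spun_state, default_config.geometry)
    cfg = ox.ModelConfig(
        ecosystem=make_compensating_ecosystem(ref, default_config.ecosystem)
    )
    forcing = ox.make_warming_scenario(
        ox.ScenarioParams(), cfg.geometry
    )
    return ox.run(cfg, spun_state.copy(), forcing)


@pytest.fixture()
def two_box_config():
    """Surface+deep reduction with a single overturning loop and no
    mixing; biology off.  Small deep volume keeps adjustment fast."""
    geom = ox.two_box_geometry(v_surface=5.0e15, v_deep=2.0e16, area=5.0e13)
    psi = 20.0 * 3.15576e13  # 20 Sv in m^3/yr
    circ = ox.CirculationScheme(
        overturning={("Surface", "Deep"): psi, ("Deep", "Surface"): psi},
        mixing={},
    )
    return ox.ModelConfig(
        geometry=geom,
        circulation=circ,
        base_temperature={"Surface": 10.0, "Deep": 10.0},
        downstream={},
        ecosystem=ox.EcosystemParams(
            partition={"Surface": {"Deep": 1.0}},
            production_scale={"Surface": 1.0},
        ),
        biology_enabled=False,
    )


def delta(frame, column):
    """End-minus-start change of a diagnostics column."""
    return float(frame[column].iloc[-1] - frame[column].iloc[0])
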
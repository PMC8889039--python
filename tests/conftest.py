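"""Shared fixtures: the expensive full-gait simulations are session-scoped
and shared across the whole suite."""

from __future__ import annotations

import numpy as np
import pytest

from treadpush import (
    ExoParams,
    build_model,
    default_config,
    make_reference,
    run_condition,
)
from treadpush.sweep_analysis import pushoff_metrics

ACTIVE_TRIPLET = (4.85, 29.0, 53.0)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def model(config):
    return build_model(config)


@pytest.fixture(scope="session")
def reference():
    return make_reference()


@pytest.fixture(scope="session")
def baseline(reference):
    """NO-EXO condition, 4 chained cycles."""
    return run_condition("NO-EXO", reference=reference)


@pytest.fixture(scope="session")
def active_runs(reference):
    """Memoized ACTIVE simulations keyed by (stiffness, engage, disengage)."""
    cache: dict[tuple, object] = {}

    def get(k, e, d):
        key = (float(k), float(e), float(d))
        if key not in cache:
            cache[key] = run_condition(
                "ACTIVE", reference=reference,
                exo_params=ExoParams(stiffness=key[0], engage_phase=key[1],
                                     disengage_phase=key[2]),
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def active(active_runs):
    return active_runs(*ACTIVE_TRIPLET)


@pytest.fixture(scope="session")
def nopower(reference):
    return run_condition("NO-POWER", reference=reference)


def _reduction(sim, baseline):
    if sim.fell:
        return np.nan
    return pushoff_metrics(sim, baseline)[2]


@pytest.fixture(scope="session")
def stiffness_reductions(active_runs, baseline):
    ks = (0.91, 1.52, 2.12, 2.73, 3.79, 4.85, 6.97, 9.09)
    return {k: _reduction(active_runs(k, 29, 53), baseline) for k in ks}


@pytest.fixture(scope="session")
def engagement_reductions(active_runs, baseline):
    es = (20.0, 23.0, 26.0, 29.0, 32.0, 35.0, 38.0)
    return {e: _reduction(active_runs(4.85, e, 53), baseline) for e in es}


@pytest.fixture(scope="session")
def disengagement_reductions(active_runs, baseline):
    ds = (44.0, 47.0, 50.0, 51.0, 52.0, 53.0, 54.0, 55.0, 59.0, 62.0)
    return {d: _reduction(active_runs(4.85, 29, d), baseline) for d in ds}
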
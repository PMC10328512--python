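"""Shared fixtures: reduced-scale trained models and their sessions.

Training the two models takes a few minutes each; they are session-scoped
so the whole suite pays the cost once.
"""

import numpy as np
import pytest

from ringremap import workflows as wf


@pytest.fixture(scope="session")
def trained_2map():
    """Reduced-scale 1D two-state model (64 units, 5,000 updates)."""
    params, task = wf.train_scaled_model(n_states=2, seed=1)
    return params, task


@pytest.fixture(scope="session")
def session_2map(trained_2map):
    params, task = trained_2map
    return wf.collect_eval_session(params, task, seed=11, n_sequences=50)


@pytest.fixture(scope="session")
def geometry_2map(trained_2map, session_2map):
    params, _ = trained_2map
    return wf.two_map_geometry(params, session_2map, seed=12, n_shuffle=300)


@pytest.fixture(scope="session")
def fixed_points_2map(trained_2map, session_2map, geometry_2map):
    params, _ = trained_2map
    return wf.fixed_point_analysis(params, session_2map,
                                   geometry_2map["tuning250"], seed=14,
                                   n_seeds=2048)


@pytest.fixture(scope="session")
def trained_3map():
    """Reduced-scale 1D three-state model."""
    params, task = wf.train_scaled_model(n_states=3, seed=2)
    return params, task
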
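"""Shared fixtures: a reference landscape and a multi-animal used–available design.

The expensive fixtures are session-scoped; everything is seeded so the suite
is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from jackalkit import rsf as rsf_mod
from jackalkit.synthetic import (
    LandscapeConfig,
    MovementConfig,
    gen_availability,
    gen_landscape,
    gen_movement,
)

#: True standardized selection coefficients used by the recovery fixtures:
#: avoid dense forest and streams (positive = selected distances), select roads.
BETA_TRUE = {"dense_forest": 0.5, "road": -0.4, "stream": 0.15}
FEATURES = ("dense_forest", "road", "stream")


@pytest.fixture(scope="session")
def landscape():
    return gen_landscape(LandscapeConfig(seed=7))


def make_design(landscape, beta_true, n_animals=5, n_fixes=500, ratio=10, seed=0):
    """Used–available design with availability drawn from the generative model."""
    tracks, avails = [], []
    for i in range(n_animals):
        mc = MovementConfig(
            center=(6000 + 2000 * i, 8000 + 1500 * (i % 2)),
            sigma=2500.0,
            beta_true=beta_true,
            n_fixes=n_fixes,
            animal_id=f"A{i + 1}",
            seed=seed * 100 + i,
        )
        tracks.append(gen_movement(landscape, mc))
        avails.append(gen_availability(landscape, mc, ratio * n_fixes))
    raw = rsf_mod.build_design(
        pd.concat(tracks, ignore_index=True),
        landscape,
        feature_types=FEATURES,
        availability=pd.concat(avails, ignore_index=True),
    )
    design, scaler, _ = rsf_mod.preprocess(raw)
    return design, scaler


@pytest.fixture(scope="session")
def strong_selection_design(landscape):
    """5 animals × 500 fixes under the strong-selection truth (session cache)."""
    design, scaler = make_design(landscape, BETA_TRUE, seed=11)
    return design, scaler


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
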
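"""Shared fixtures: one seeded synthetic study reused across the suite.

The quadruped model, synergy basis and solved programs are expensive
(each QP takes on the order of a second), so they are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

import quadbalance as qb
from quadbalance.limb import build_wrench_map
from quadbalance.synthetic import generate_hindlimb_model, generate_synergy_force_vectors

SEED = 20260925


@pytest.fixture(scope="session")
def config() -> qb.SyntheticStudyConfig:
    return qb.SyntheticStudyConfig(seed=SEED)


@pytest.fixture(scope="session")
def quadruped(config):
    """Preferred-stance synthetic quadruped (cat-bi geometry)."""
    model, grid = qb.generate_quadruped_scenario(config)
    return model


@pytest.fixture(scope="session")
def hindlimb_map(config):
    return build_wrench_map(generate_hindlimb_model(config, limb_id="RH"))


@pytest.fixture(scope="session")
def synergy_set(hindlimb_map):
    vectors = generate_synergy_force_vectors(hindlimb_map, seed=SEED + 1)
    return qb.build_synergy_basis(hindlimb_map, vectors)


@pytest.fixture(scope="session")
def mme_at_zero(quadruped):
    return qb.solve_mme(quadruped, qb.build_com_target(0.0))


@pytest.fixture(scope="session")
def mme_all_directions(quadruped):
    """MMe solutions at all 12 perturbation directions."""
    return [qb.solve_mme(quadruped, qb.build_com_target(th))
            for th in np.arange(12) * 30.0]
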
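"""Shared fixtures: synthetic embedding, full-size stimulus set and design."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from smst.cohort import default_age_assignment
from smst.design import DesignConfig, generate_all_schedules, make_rotation_plan
from smst.embedding import EmbeddingSpace
from smst.fixtures import FixtureConfig, generate_fixture_embedding
from smst.stimuli import build_stimulus_set


@pytest.fixture
def tiny_space() -> EmbeddingSpace:
    """A handcrafted 4-dim space with one-hot and mixed vectors."""
    space = EmbeddingSpace(dim=4)
    space.add("a1", np.array([1.0, 0.0, 0.0, 0.0]))
    space.add("n1", np.array([0.0, 1.0, 0.0, 0.0]))
    space.add("a2", np.array([0.0, 0.0, 1.0, 0.0]))
    space.add("n2", np.array([0.0, 0.0, 0.0, 1.0]))
    space.add("adj3", np.array([0.5, -1.0, 2.0, 0.0]))
    space.add("noun3", np.array([1.0, 1.0, -2.0, 0.0]))
    return space


@pytest.fixture(scope="session")
def synthetic_world():
    """Default-size synthetic embedding + lexicon (the study conditions)."""
    return generate_fixture_embedding(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def stimulus_set(synthetic_world):
    space, lexicon = synthetic_world
    return build_stimulus_set(lexicon, space, n_triplets=100, n_foils=125, seed=0)


@pytest.fixture(scope="session")
def design40(stimulus_set):
    """The default 40-participant design with its plan and schedules."""
    config = DesignConfig(seed=0)
    plan = make_rotation_plan(config, stimulus_set)
    schedules = generate_all_schedules(plan, stimulus_set, config)
    return config, plan, schedules


@pytest.fixture(scope="session")
def design80(stimulus_set):
    """An 80-participant version of the same design (for model fitting)."""
    config = DesignConfig(n_participants=80, seed=0)
    plan = make_rotation_plan(config, stimulus_set)
    schedules = generate_all_schedules(plan, stimulus_set, config)
    ages = default_age_assignment(config.n_participants)
    return config, schedules, ages


SMALL_PIPELINE_CONFIG = {
    "fixture": {
        "n_nouns": 120, "n_adjectives": 400, "dim": 64, "n_clusters": 8,
        "seed": 0,
    },
    "stimuli": {"n_triplets": 8, "n_foils": 4, "seed": 0},
    "design": {
        "n_participants": 4, "enc_targets": 8, "enc_fillers": 2,
        "rec_targets": 4, "rec_close": 2, "rec_distant": 2, "rec_foils": 2,
        "pool_triplets": 8, "pool_foils": 4, "seed": 0,
    },
    "cohort": {"seed": 0},
}


@pytest.fixture
def small_config():
    """A scaled-down but structurally complete pipeline configuration."""
    return {k: dict(v) for k, v in SMALL_PIPELINE_CONFIG.items()}
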
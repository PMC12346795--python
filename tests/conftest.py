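import numpy as np
import pytest

from cardioage import (AgingModel, GridSpec, InteractionPair, InteractionSet,
                       TrajectoryGrid, build_trajectories, default_catalog,
                       fixture_sets)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def all_fixture_sets():
    return fixture_sets()


@pytest.fixture
def default_grid():
    return GridSpec(dt=0.01, dx=0.001, n_steps=100)


@pytest.fixture
def constant_grid():
    """dx = 0: every trajectory is constant at its boundary value 1."""
    return GridSpec(dt=0.01, dx=0.0, n_steps=100)


def make_model(interaction_set, grid, increment_rule="unit"):
    traj = build_trajectories(grid, interaction_set.parameter_names(),
                              increment_rule)
    return AgingModel(interaction_set, traj)


@pytest.fixture
def constant_model(all_fixture_sets, constant_grid):
    """Immunological all-patients model on constant-one trajectories, so the
    aging rate is the plain coefficient sum 2.03."""
    return make_model(all_fixture_sets[(1, "A")], constant_grid)


@pytest.fixture
def default_model(all_fixture_sets, default_grid):
    return make_model(all_fixture_sets[(1, "A")], default_grid)


def toy_set(coefficients, problem=None, case=None):
    """Interaction set with synthetic pair names X0..Xk / Y0..Yk."""
    pairs = tuple(InteractionPair(f"X{i}", f"Y{i}", c)
                  for i, c in enumerate(coefficients))
    return InteractionSet(pairs, problem=problem, case=case, source="fixture")
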
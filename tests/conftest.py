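"""Shared fixtures: synthetic study data and a trained reference model.

The heavier fixtures (the default planted-signature simulation and the
model trained on it) are session-scoped so the training cost is paid once
across the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from statescore import (
    CellStateModel,
    FeatureModel,
    GeneUniverse,
    SyntheticSpec,
    TrainConfig,
    simulate_labeled,
)

# Reference study conditions: 2000 genes, 50-gene up/down signatures,
# detection shift 0.3, 500 cells per state.
DEFAULT_SPEC = SyntheticSpec(seed=7)
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def default_sim():
    """Planted-signature training data (binary mode, seed 7)."""
    return simulate_labeled(DEFAULT_SPEC)


@pytest.fixture(scope="session")
def holdout_sim():
    """Held-out cells drawn from the same planted truth as default_sim."""
    return simulate_labeled(SyntheticSpec(seed=7, replicate=1))


@pytest.fixture(scope="session")
def holdout_counts():
    """Held-out cells in count mode (same detection field as replicate 1)."""
    return simulate_labeled(SyntheticSpec(seed=7, replicate=1, emit="counts"))


@pytest.fixture(scope="session")
def fitted(default_sim):
    """CellStateResults of the reference fit on default_sim."""
    return CellStateModel(default_sim.dataset, feature_name="planted").fit(
        TrainConfig(seed=TRAIN_SEED)
    )


@pytest.fixture
def toy_model():
    """Small hand-built model for arithmetic-level checks."""
    return FeatureModel(
        universe=GeneUniverse(("A", "B", "C")),
        w=np.array([1.0, -1.0, 0.0]),
        b=0.5,
        v=np.array([-1.0, 1.0]),
        c=np.array([0.1, -0.2]),
        orientation=1,
    )


def make_expression(counts, cell_prefix="c", gene_prefix="g"):
    """Dense ExpressionMatrix from a nested list / array."""
    from statescore import ExpressionMatrix

    counts = np.asarray(counts)
    return ExpressionMatrix(
        cell_ids=[f"{cell_prefix}{i}" for i in range(counts.shape[0])],
        gene_ids=[f"{gene_prefix}{j}" for j in range(counts.shape[1])],
        counts=counts,
    )
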
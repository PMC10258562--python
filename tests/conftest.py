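"""Shared fixtures: generated datasets and trained models.

Everything is generated at test time from seeds; the heavier trained models
are session-scoped so multiple tests share one training run.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from cpax.data import SplitPlan, make_split
from cpax.synth import default_design, generate_dataset, make_truth
from cpax.train import TrainingConfig, train

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def tiny_truth(seed: int = 0, **overrides):
    kw = dict(
        n_genes=60,
        latent_dim=6,
        perturbation_names=["A", "B", "C"],
        covariate_schemas={"cell_line": ["line0", "line1"]},
    )
    kw.update(overrides)
    return make_truth(seed, **kw)


def tiny_dataset(seed: int = 0, n_cells: int = 50, pairs=(("A", "B"),)):
    truth = tiny_truth(seed)
    design = default_design(truth, n_cells_per_condition=n_cells, pairs=list(pairs))
    ds, truth = generate_dataset(truth, design, seed=seed)
    return make_split(ds, SplitPlan(test_fraction=0.2, seed=seed)), truth


def tiny_training_config(seed: int = 0, **overrides) -> TrainingConfig:
    kw = dict(
        embedding_dim=8,
        encoder_hidden=64,
        encoder_layers=2,
        doser_hidden=32,
        doser_layers=1,
        discriminator_hidden=32,
        discriminator_layers=2,
        epochs=6,
        seed=seed,
    )
    kw.update(overrides)
    return TrainingConfig(**kw)


@pytest.fixture(scope="session")
def tiny_ds():
    ds, truth = tiny_dataset(0)
    return ds


@pytest.fixture(scope="session")
def tiny_truth_obj():
    return tiny_truth(0)


@pytest.fixture(scope="session")
def tiny_trained():
    """A small model trained for a few epochs on the tiny dataset."""
    ds, truth = tiny_dataset(0)
    model, records = train(ds, tiny_training_config(0))
    return model, ds, records
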
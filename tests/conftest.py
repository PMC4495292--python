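"""Shared fixtures: small synthetic datasets and a trained model bundle."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from phospho1433 import WindowSpec
from phospho1433 import ann as ann_mod
from phospho1433 import pssm as pssm_mod
from phospho1433 import svm as svm_mod
from phospho1433.consensus import ModelBundle
from phospho1433.fixtures import (
    GeneratorConfig,
    generate_background_windows,
    generate_dataset,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def spec64() -> WindowSpec:
    return WindowSpec(6, 4)


@pytest.fixture(scope="session")
def small_dataset(spec64):
    """60 POS / 60 NEG synthetic peptides, fixed seed."""
    return generate_dataset(
        GeneratorConfig(n_pos=60, n_neg=60, window_spec=spec64, seed=7)
    )


@pytest.fixture(scope="session")
def background_windows(spec64):
    return generate_background_windows(
        GeneratorConfig(window_spec=spec64, seed=7), 300
    )


@pytest.fixture(scope="session")
def trained_bundle(small_dataset, background_windows):
    """All three models trained on the small synthetic dataset."""
    return ModelBundle(
        pssm=pssm_mod.train_pssm(small_dataset, background=background_windows),
        ann=ann_mod.train_ann(
            small_dataset, ann_mod.AnnConfig(epochs=40, seed=5)
        ),
        svm=svm_mod.train_svm(small_dataset),
    )
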
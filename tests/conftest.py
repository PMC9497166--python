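import numpy as np
import pandas as pd
import pytest

from haibrid import (
    FeatureDictionary,
    TrainingConfig,
    build_dictionary,
    default_generator_spec,
    encode,
    generate,
)


@pytest.fixture
def toy_dictionary() -> FeatureDictionary:
    """Two binary features plus the CADx pseudo-feature (width 6)."""
    return build_dictionary({
        "features": [
            {"name": "shape", "levels": ["wider", "taller"]},
            {"name": "margin", "levels": ["smooth", "irregular"]},
        ],
        "cadx": {"name": "cadx_diagnosis", "mode": "binary",
                 "threshold": 0.5},
    })


@pytest.fixture
def toy_records() -> pd.DataFrame:
    return pd.DataFrame({
        "shape": ["taller", "wider", None, "taller"],
        "margin": ["smooth", "irregular", "irregular", None],
        "cadx_score": [0.9, 0.2, np.nan, 0.5],
        "label": [1, 0, 0, 1],
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-sample default-regime cohort with its encoded dataset."""
    spec = default_generator_spec(n=400, seed=11)
    table, truth = generate(spec)
    dataset = encode(table, spec.dictionary)
    return spec, table, dataset


@pytest.fixture
def fast_config() -> TrainingConfig:
    """Small training budget for unit tests."""
    return TrainingConfig(
        embedding_dim=2, attention_hidden=4, max_epochs=30,
        batch_size=128, seed=0,
    )
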
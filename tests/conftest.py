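"""Shared fixtures: the synthetic study and its pretrained features.

Session-scoped because feature pretraining (TransE + CBOW + graph
featurization) is reused by many tests; everything is seeded, so sharing
does not couple test outcomes.
"""

import numpy as np
import pytest

from mseddi import (
    SynthConfig,
    TransEConfig,
    W2VConfig,
    generate_bundle,
    train_transe,
)
from mseddi.train import cold_start_split, prepare_features

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """The default synthetic study: 40 drugs, 4 classes, 8 events, 5% noise."""
    bundle, assignment = generate_bundle(SynthConfig(seed=STUDY_SEED))
    return bundle, assignment


@pytest.fixture(scope="session")
def features(study):
    bundle, _ = study
    return prepare_features(
        bundle,
        TransEConfig(seed=STUDY_SEED),
        W2VConfig(seed=STUDY_SEED),
    )


@pytest.fixture(scope="session")
def splits(study):
    bundle, _ = study
    return cold_start_split(bundle, 5, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def planted_kge(study):
    """TransE table trained on the planted-class toy KG."""
    bundle, assignment = study
    table, trace = train_transe(bundle.triplets, TransEConfig(seed=STUDY_SEED))
    return table, trace, assignment
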
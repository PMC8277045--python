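import numpy as np
import pytest
from hypothesis import settings

import fetmov as fm
from fetmov.classifier import CNNSpec, stratified_split, train_cnn
from fetmov.pipeline import (
    ALGORITHMS,
    PipelineConfig,
    featurize_dataset,
    run_algorithm,
    segment_corpus,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

TABLE1_MIX = (1022, 276, 1563)


@pytest.fixture(scope="session")
def small_config():
    """Reduced CNN (same kernel geometry) for desk-scale corpus runs."""
    return PipelineConfig(cnn=CNNSpec.small())


@pytest.fixture(scope="session")
def full_corpus():
    """The default synthetic study: 10 subjects x 20 min at moderate SNR,
    class mix matching the clinical tabulation (~1700 realizations)."""
    return fm.synth_dataset(
        10, 1, TABLE1_MIX, fm.SynthConfig(duration_s=1200.0, seed=0), seed=42
    )


@pytest.fixture(scope="session")
def a2_run(full_corpus, small_config):
    """A2 trained once on the full corpus: (report, model) shared by the
    detection and acceptance tests."""
    ds = segment_corpus(full_corpus, ALGORITHMS["A2"], small_config, seed=3)
    feats = featurize_dataset(ds, ALGORITHMS["A2"], small_config, seed=3)
    split = stratified_split(ds.labels, 0.8, seed=3)
    spec = small_config.cnn.with_input_shape(feats.shape[1:])
    model = train_cnn(feats, ds.labels, split, spec, seed=3)
    report = run_algorithm(
        full_corpus, "A2", small_config, seed=3, dataset=ds, features=feats
    )
    return report, model


@pytest.fixture(scope="session")
def a1_report(full_corpus, small_config):
    """A1 (no filter) on the same drift/respiration-contaminated corpus."""
    return run_algorithm(full_corpus, "A1", small_config, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
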
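import pytest

from locboost import SynthConfig, generate_dataset
from locboost.pipeline import ProteinLocalizationPipeline

# Small architecture used by pipeline-level tests: quick to train but still
# a real conv -> relu -> pool -> fc -> fc stack.
SMALL_PIPELINE = dict(
    conv_blocks=((8, 5, 2),),
    fc_sizes=(32, 16),
    epochs=10,
    batch_size=16,
    n_rounds=25,
    max_depth=3,
)


@pytest.fixture(scope="session")
def tiny_config():
    return SynthConfig(
        n_train=60,
        n_test=20,
        n_locations=3,
        seq_len_range=(40, 80),
        motif_len=5,
        motif_insert_prob=1.0,
        multilabel_prob=0.25,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def trained_pipeline(tiny_dataset):
    train, _, _ = tiny_dataset
    return ProteinLocalizationPipeline(seed=5, **SMALL_PIPELINE).fit(train)
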
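import numpy as np
import pytest

from lungrg.model import MultiSliceReportModel, TINY_CONFIG
from lungrg.synthetic import CohortSpec, generate_cohort
from lungrg.trainer import TrainConfig, prepare_samples, train, \
    train_tokenizer


@pytest.fixture(scope="session")
def small_cohort():
    """15 synthetic patients, 5 per class, at test-speed volume size."""
    return generate_cohort(CohortSpec(n_per_class=(5, 5, 5), seed=11))


@pytest.fixture(scope="session")
def tiny_tokenizer(small_cohort):
    return train_tokenizer(small_cohort, "EN", n_merges=150, vocab_size=512)


@pytest.fixture(scope="session")
def tiny_samples(small_cohort, tiny_tokenizer):
    return prepare_samples(small_cohort, TINY_CONFIG, tiny_tokenizer, "EN")


@pytest.fixture()
def tiny_model():
    """Fresh untrained tiny-profile model in eval mode."""
    return MultiSliceReportModel(TINY_CONFIG, np.random.default_rng(0)).eval()


@pytest.fixture(scope="session")
def trained_tiny(tiny_samples):
    """Tiny model briefly overfit on the session cohort, so that attention
    and saliency carry class signal."""
    model = MultiSliceReportModel(TINY_CONFIG, np.random.default_rng(3))
    cfg = TrainConfig(max_lr=3e-3, batch_size=15, max_epochs=30,
                      early_stop_patience=10 ** 9, seed=0)
    train(model, list(tiny_samples), [], cfg)
    return model.eval()
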
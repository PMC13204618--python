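import numpy as np
import pandas as pd
import pytest

from milsurv.datatypes import SlideBag, SurvivalRecord
from milsurv.mil import TrainConfig
from milsurv.prep import fit_tissue_qc
from milsurv.synthetic import Cohort, CohortConfig, make_cohort, make_qc_tiles


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(name="tiny", n_slides=30, patches_per_slide=(4, 8),
                        embed_dim=8, beta=1.5, baseline_rate=0.02, seed=0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return make_cohort(tiny_config)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """Fast cohort with real signal for training-based unit tests."""
    cfg = CohortConfig(name="small", n_slides=80, patches_per_slide=(8, 12),
                       embed_dim=16, beta=2.0, seed=1)
    return make_cohort(cfg)


@pytest.fixture(scope="session")
def fast_train_config():
    return TrainConfig(epochs=150, patience=20, seed=0)


@pytest.fixture(scope="session")
def qc_setup():
    """Trained QC model plus held-out tiles (shared: training is the slow part)."""
    tiles, labels = make_qc_tiles(400, seed=0)
    model = fit_tissue_qc(tiles, labels, seed=0)
    test_tiles, test_labels = make_qc_tiles(200, seed=1)
    return model, test_tiles, test_labels


def build_cohort_from_bags(bags, survival, config=None):
    """Assemble a Cohort around hand-built bags (truth filled with zeros)."""
    if config is None:
        config = CohortConfig(name="manual", n_slides=max(len(bags), 2),
                              embed_dim=bags[0].embeddings.shape[1])
    truth = pd.DataFrame({"slide_id": [b.slide_id for b in bags],
                          "grade": 0.0, "eta": 0.0})
    return Cohort(bags=bags, survival=survival, truth=truth, config=config)


def make_bag(n_tumor, n_other, d=4, slide_id="s", seed=0):
    rng = np.random.default_rng(seed)
    n = n_tumor + n_other
    classes = np.array(["tumor_high"] * n_tumor + ["normal"] * n_other, dtype=object)
    coords = np.stack([np.arange(n) // 10, np.arange(n) % 10], axis=1)
    return SlideBag(slide_id=slide_id, embeddings=rng.normal(size=(n, d)),
                    coords=coords, tissue_class=classes)


@pytest.fixture
def record():
    return SurvivalRecord(time=12.0, event=1)
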
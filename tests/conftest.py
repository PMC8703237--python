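import numpy as np
import pytest

import metabosurr as ms
from metabosurr.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def demo_small():
    """A small multi-cohort dataset with the four planted phenotypes."""
    cfg = ms.demo_config(seed=123, n_cohorts=6, cohort_size=150)
    ds, truth = ms.generate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def qc_small(demo_small):
    cfg, ds, _ = demo_small
    kept, report = ms.run_qc(ds, cfg.panel)
    return kept, report


@pytest.fixture(scope="session")
def fast_tc():
    """Reduced-size training configuration for unit tests."""
    return ms.TrainConfig(n_lambda=10, lambda_decades=3.0, inner_folds=3,
                          inner_repeats=1, outer_folds=3, outer_repeats=1,
                          seed=7)


@pytest.fixture(scope="session")
def trained_model(qc_small, fast_tc):
    kept, _ = qc_small
    X = kept.metabolite_matrix()
    y = kept.df["planted_auc95"].to_numpy(int)
    model = ms.train_surrogate(X, y, fast_tc,
                               marker_names=kept.metabolite_cols,
                               name="planted_auc95")
    return kept, X, y, model


def rng(seed=0):
    return np.random.default_rng(seed)
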
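import numpy as np
import pandas as pd
import pytest

from panhrd.simulate import SyntheticConfig, generate_cohort, generate_exposures


@pytest.fixture(scope="session")
def small_cohort():
    """Small seeded cohort (500 samples) shared by read-only tests."""
    cfg = SyntheticConfig(n_samples=500, seed=11)
    exposures, bundle, truth = generate_cohort(cfg)
    return cfg, exposures, bundle, truth


@pytest.fixture(scope="session")
def signal_cohort_1k():
    """1,000-sample cohort at the default effect size (planted signal)."""
    cfg = SyntheticConfig(n_samples=1000, seed=1)
    exposures, truth = generate_exposures(cfg)
    return cfg, exposures, truth


@pytest.fixture(scope="session")
def tiny_trained_model():
    """Small fitted regression for explain/ablation tests.

    200 samples, 30 features (10 informative), one tuning candidate so the
    fit stays fast; shared session-wide because several tests only read
    from it.
    """
    from panhrd.model import HRDRegressor
    from panhrd.preprocess import assemble
    from panhrd.scoring import panhrd_scores

    cfg = SyntheticConfig(
        n_samples=200,
        n_genes_per_layer={"EXP": 20, "CNV": 10},
        n_informative_per_layer={"EXP": 6, "CNV": 4},
        seed=5,
    )
    exposures, bundle, truth = generate_cohort(cfg)
    scores = panhrd_scores(exposures).scores
    features = assemble(bundle.transformed())
    reg = HRDRegressor(features, scores, exposures.tumor_labels, seed=5)
    results = reg.fit(candidates=[{"learning_rate": 0.1, "max_depth": 4,
                                   "min_child_weight": 2.0, "subsample": 0.9,
                                   "colsample_bytree": 0.9}])
    return reg, results
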
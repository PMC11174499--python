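import numpy as np
import pytest

from ramantsd import pipeline, simulate


def quiet_config(seed: int = 0, zero_background: bool = False) -> simulate.GeneratorConfig:
    """Default two-donor config with all stochastic terms switched off."""
    cfg = simulate.default_config(seed=seed, outlier_rate=0.0)
    for donor in cfg.donors:
        donor.noise.sigma_rel = 0.0
        donor.noise.spot_scale_sd = 0.0
        donor.noise.background_jitter_sd = 0.0
        donor.outlier_rate = 0.0
        if zero_background:
            donor.background.b0 = 0.0
            donor.background.b_gain = 0.0
    cfg.spots_per_map = 1
    return cfg


@pytest.fixture(scope="session")
def default_study():
    """One full default-seeded pipeline run shared across the suite."""
    cfg = pipeline.RunConfig.default(seed=1, output_dir="unused")
    report, kin_table, results = pipeline.run_pipeline(cfg, write_artifacts=False)
    return report, kin_table, results


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
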
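import dataclasses

import pytest

from ccmquant.panel import default_panel
from ccmquant.pipeline import PipelineConfig, run_pipeline

STUDY_SEED = 74


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def default_bundle():
    """Full pipeline on the default synthetic study (8 groups x 5 reps)."""
    return run_pipeline(PipelineConfig.default(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Same study with every stochastic term switched off."""
    cfg = PipelineConfig.default(seed=STUDY_SEED)
    cfg = dataclasses.replace(cfg, study=cfg.study.noiseless())
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def ablation_bundle():
    """Default study quantified without isotope-dilution correction."""
    cfg = dataclasses.replace(PipelineConfig.default(seed=STUDY_SEED), isotope_correction=False)
    return run_pipeline(cfg)
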
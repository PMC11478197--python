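import dataclasses

import pytest

from herbfp.synthetic import PanelConfig, simulate_panel
from herbfp.workflow import PipelineConfig, run_pipeline


def make_pipeline_config(seed: int = 11) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed)
    # a little detector noise so LOD/SNR paths are exercised
    cfg.panel = dataclasses.replace(cfg.panel, detector_noise_sd=2.0)
    return cfg


@pytest.fixture(scope="session")
def default_panel():
    """The default 18-batch synthetic panel (ground truth attached)."""
    return simulate_panel(PanelConfig(seed=7, detector_noise_sd=2.0))


@pytest.fixture(scope="session")
def noiseless_panel():
    return simulate_panel(PanelConfig(
        seed=3, area_noise_cv=0.0, rt_jitter_sd=0.0, rt_shift_sd=0.0,
        extra_peaks=0))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run shared by workflow and acceptance tests."""
    cfg = make_pipeline_config()
    out = tmp_path_factory.mktemp("pipeline_run")
    return run_pipeline(cfg, out), cfg
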
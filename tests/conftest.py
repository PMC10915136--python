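import numpy as np
import pytest

import embryoqpi as eq


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_embryo():
    """One small, fast blastocyst-like embryo shared across unit tests."""
    cfg = eq.SynthConfig(
        n_nuclei=12,
        embryo_radius_um=18.0,
        nucleus_radius_um_range=(2.6, 3.4),
        te_fraction=0.25,
        lateral_px_per_um=4.0,
        seed=11,
    )
    phase, channel, truth = eq.generate_embryo(cfg)
    return cfg, phase, channel, truth


@pytest.fixture(scope="session")
def small_embryo_result(small_embryo):
    cfg, phase, channel, truth = small_embryo
    pipeline = eq.PipelineConfig(lateral_px_per_um=cfg.lateral_px_per_um)
    return eq.process_embryo(phase, channel, pipeline), truth
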
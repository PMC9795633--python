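import pytest

from evotraj import presets
from evotraj.simulate import simulate_experiment


@pytest.fixture(scope="session")
def mouse_run():
    """One paper-faithful synthetic mouse study (binomial noise, seed 0)."""
    cfg = presets.mouse_study_config(seed=0)
    return simulate_experiment(cfg)
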